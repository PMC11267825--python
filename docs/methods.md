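# Methods

## Scope and design

pulmotrack analyzes a three-modality, breath-by-breath recording of a
ventilated subject: reconstructed EIT pixel frames, airway flow/pressure/CO2
signals, and an event log.  Because no animal recordings are distributed
with the package, a synthetic cohort simulator is a first-class component:
it emulates the xylazine-edema experiment (prone sheep, volume-controlled
ventilation at 10 mL/kg and 10 breaths/min, zero PEEP, EIT at 47 frames/s,
airway signals at 100 Hz, a 10-s apnea before the recording, 60 s of
baseline, a 60-s injection) and provides per-breath ground truth for every
variable the pipelines compute.  The pipeline starts from reconstructed
pixel frames; image reconstruction from electrode voltages is out of scope.

The simulator works *targets first*: for each breath it draws the feature
values the analysis should recover — baseline x edema trajectory x noise —
and then constructs pixel fields and airway waveforms that embed exactly
those values.  On noise-free runs the full analysis chain returns the
configured values to within discretization error (about 0.1 % for global
impedance quantities, below 1 % for all others); this parameter-recovery
loop is the package's main correctness argument, backed by independent
analytic oracles (brute-force centroid, closed-form Bohr arithmetic,
single-compartment plateau pressure) in the test suite.

## Edema trajectory

Every affected variable follows a logistic ramp

    x(t) = x0 * (1 + (r - 1) * L(t) / L(120 s)),
    L(t) = (sigma((t - t0)/tau) - sigma(-t0/tau)) / (1 - sigma(-t0/tau)) for t > 0,

with `L(t) = 0` for `t <= 0` (injection start), onset `t0 = 30 s` and
timescale `tau = 20 s`.  The ramp is exactly zero at and before the start of
injection, monotone afterwards, and effectively saturated by 120 s.  The
endpoint ratios `r` for the EIT variables are anchored to the published
120-s group means relative to baseline (EELI 732/2445, TIV 1309/1460,
NSS 4.09/7.04, DSS 12.4/8.42, band shares 4.81/7.64, 29.3/36.9, 45.0/41.8,
20.8/13.7).  The mechanics and capnography endpoints are set to
physiologically plausible values of similar relative magnitude: resistance
x1.5, dynamic compliance x0.7, end-tidal CO2 x0.9, airway dead space x1.1,
phase III slope x1.3.  They are configuration entries, not claims about the
biology.

The center of ventilation is not an independent dial: its shift is derived
from the band shift, `cov(t) = cov0 + implied_cov(bands(t)) -
implied_cov(bands(0))`, evaluated with the *actual* per-band pixel centroids
of the lung mask.  Nominal quarter-band midpoints (12.5/37.5/62.5/87.5)
overstate the centroid range an elliptical lung can express and would force
infeasible within-band tilts at late edema times.

## Synthetic EIT frames

The lung mask is two overlapping elliptical lobes, left-right symmetric,
connected, occupying 30-60 % of the grid (default 32x32).  Per breath the
tidal-change field `dZ` is built to satisfy simultaneously:

* sum over the mask = TIV;
* quarter-band shares = target band fractions (uniform within band, times an
  exponential tilt `exp(lam*y + mu*x)` renormalized per band; `(lam, mu)`
  are solved with a 2-D root finder so the ventilation-weighted centroid
  lands exactly on the CoV targets);
* a configured fraction of lung pixels receives zero change — the
  silent-space ground truth.  Dependent silent pixels fill from the most
  ventral rows upward (the first-flooded, gravitationally lowest lung in
  prone posture), non-dependent from the most dorsal rows downward, lateral
  pixels first within a row; at least 25 % of each band is kept ventilated.
  All ventilated pixels are checked to stay above the 10 %-of-maximum
  silent-space threshold, otherwise the combination is rejected as
  infeasible with an error naming the constraint.

Breath-level noise draws that land outside the feasible set (a fraction of
a percent at the default noise) are redrawn (rejection sampling); noise-free
targets are never adjusted.

Frames are `EELI_field + dZ * s(t)`, where the end-expiratory field spreads
the EELI target uniformly over the mask and `s(t)` is the normalized lung
volume of the ventilator model, so EIT and airway signals share one clock.
During the apnea the frames hold at the end-expiratory field, giving the
flat window used for synchronization.

## Ventilator and gas model

A single-compartment lung: constant inspiratory flow delivers VT over 90 %
of the inspiratory time (I:E = 1:2), a 10 % end-inspiratory pause yields a
plateau, and expiration is passive with time constant `Raw * C_el`.
Airway pressure follows `Paw = Raw*flow + V/C_el + PEEP`.  The configured
`Cdyn` is the *dynamic* compliance the spirometry pipeline reports
(`VT/(PIP - PEEP)`), which includes the resistive pressure; the internal
elastance is derived as `C_el = VT/(VT/Cdyn - Raw*flow_i)` so the recovered
value matches the configuration.  Expiratory flow rises over a smooth 0.7-s
onset (a stand-in for circuit impedance): this keeps trapezoidal volume
integrals stable between 50 and 500 Hz sampling and, importantly, slows the
early expiration enough that the phase II transition of the expirogram
spans several 100-Hz samples.  The ground-truth peak expiratory flow is the
maximum of the rendered waveform.

Expired CO2 follows a three-phase expirogram in the volume domain: zero
during phase I, a sigmoid of width 8 mL centered at the airway dead space,
and a linear phase III anchored so the curve reaches the configured
end-tidal tension at full VT.  Optional spontaneous-effort contamination
(off by default) subtracts a Gaussian airway-pressure deflection
mid-expiration to exercise the exclusion rule.

## Analysis conventions

* **Breath segmentation**: inspiration starts at a positive crossing of
  0.02 L/s; it ends at the last positive-flow sample before flow stays
  non-positive for 50 ms (so the zero-flow pause terminates inspiration);
  expiration runs to the next inspiration start.  Inspirations shorter than
  0.2 s are discarded.
* **Synchronization**: the end of the longest quiescent window (|flow|
  below threshold; EIT global signal flat to 0.2 % of its range) in each
  timebase; alignment maps time to frame by `frame_sync + round((t -
  t_sync) * frame_rate)`.  On synthetic data the two landmarks agree within
  one frame.
* **QC**: a breath is excluded if inspired and expired VT differ by more
  than 10 % of the first breath's expired VT (leak), if airway pressure
  dips more than 2 cmH2O below PEEP (spontaneous effort — an automatable
  surrogate for visual curve review), or if its expirogram is unanalyzable
  (incomplete).
* **EIT**: negative pixel changes are clipped before all regional measures
  (out-of-phase pixels are not ventilation); TIV itself uses the unclipped
  global curve.  CoV is normalized to the lung-region bounding extent;
  a single-row extent maps to 50 %.  The NSS/DSS split plane is the CoV_VD
  height; a pixel exactly on the plane counts as dependent.  The
  silent-space threshold uses the strict pixel maximum; a robust percentile
  is a config-visible alternative left for sensitivity analysis.
* **VCap**: expired volume by cumulative trapezoidal integration of -flow,
  resampled to a 1-mL grid; derivatives on a 5-mL moving average; the
  inflection (VDaw) is the derivative maximum; phase III is fitted over
  60-90 % of expired volume; the alpha angle uses axes normalized by VT and
  end-tidal tension, reported as 180 deg minus the angle between the two
  lines, with an effectively instantaneous phase II capped at 2000 mmHg/L.
  Note the geometric consequence: a steeper phase III moves the fitted
  lines toward parallel and the alpha angle toward 180 deg, i.e. alpha
  *increases* with SIII, consistent with its reported rise under airway
  narrowing.  CO2 volumes use the dry-gas conversion PCO2/(Pb - 47) with
  Pb = 760 mmHg configurable; no STPD correction is applied.
* **Mechanics**: `Raw = (PIP - Pplat)/mean inspiratory flow` (flow averaged
  over the central 5-95 % of the flow phase).  The dimensionally inverted
  textbook phrasing (flow divided by pressure) is available behind
  `literal_mech_formulas` for comparison only.  "Peak expiratory pressure"
  is read as measured end-expiratory pressure, the only interpretation that
  makes Cdyn a compliance.

## Statistics

Per variable, each subject's 60-s pre-injection mean is the baseline
(subjects with fewer than 3 unflagged baseline breaths are dropped);
values are expressed as percent of baseline.  A linear mixed-effects model
with a random subject intercept and breath (pooled baseline + each
post-start breath) as a categorical fixed effect is fitted by REML; each
post-start level is tested against baseline with a Wald statistic referred
to a t distribution with `n_subjects - 1` degrees of freedom — a
deliberately conservative choice in the absence of a Satterthwaite
approximation.  With breaths every 6 s in the 0-120 s window there are
m = 21 comparisons; `p_adj = min(1, m * p_raw)` and significance means
`p_adj < 0.05`.  If the fit is singular the procedure falls back to
per-breath one-sample t-tests of percent-of-baseline against 100, with a
logged warning.  First change is the earliest significant breath (an
optional two-consecutive-breath persistence rule is available); its breath
ordinal counts breaths after the start of injection (a change at 48 s is
breath 8).

Calibration: over 500 null cohorts of 15 subjects at the default noise the
family-wise proportion of cohorts with any significant breath for a given
variable measures ~0.004, comfortably below the nominal 0.05 (Bonferroni
plus the conservative df make the procedure strictly level).

## Noise model and what it does not capture

Breath-level relative noise (1-6 % depending on the variable) is sized so
cohort means wobble from breath to breath like the published baseline rows;
between-subject spread (1-25 %) loosely matches the published baseline
confidence intervals, with most of the center-of-ventilation spread carried
by a joint perturbation of the band fractions so geometry stays internally
consistent.  Noise enters at the feature level: the generator perturbs the
per-breath targets, not the sensor samples.  Consequently passing tests
demonstrate correct recovery of the encoded physiology and correct
statistical calibration; they do not exercise pixel-level reconstruction
artifacts, cardiogenic oscillations, electrode drift, irregular spontaneous
breathing patterns, or real capnograph sensor dynamics.

## Problem sizes

The test suite and the acceptance script run single-CPU in a few minutes by
choosing desk-scale problems: noise-free recovery uses one subject with a
short baseline recording (apnea + 4 breaths, 32x32 grid); trajectory
recovery runs one subject to 126 s; the null-calibration experiment uses
500 feature-level cohorts of 15 subjects (no frame rendering — the
statistics consume per-breath tables, so rendering frames would add cost
without exercising any additional code under test); the onset-detection
property uses 20 stochastic cohorts.

## Known limitations

* The edema time-course is a parametric stand-in; onset and timescale are
  configuration, not physiology.
* The expirogram's phase II width and the expiratory onset smoothing are
  tuned for resolvability at 100 Hz; very sharp real transitions would be
  aliased, biasing VDaw low.
* Silent-space placement is deterministic (most-dependent-first); real
  silent spaces are patchier.
* CoV targets far from the value implied by the band fractions are rejected
  as infeasible rather than approximated; the feasible range is reported in
  the error.
* The mixed model assumes a common residual variance across breaths;
  heteroscedastic late-edema variance is not modeled.
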