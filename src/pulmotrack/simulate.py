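"""Synthetic cohort simulator.

Generates a full virtual experiment — reconstructed EIT pixel frames, airway
signals (flow, pressure, CO2) and an event log — for a cohort of ventilated
subjects under a parametric edema trajectory, so that every downstream stage
of the analysis has ground truth.

The generator works backwards from the feature definitions: for each breath
it first draws the *target* feature values (baseline x trajectory x noise)
and then constructs a pixel tidal-change field and airway waveforms from
which the feature pipelines recover those targets.  On noise-free runs the
recovery is exact up to discretization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from .config import BAND_NAMES, SimConfig
from .io import AirwaySignals, EITSequence, EventLog, write_subject
from .trajectory import EdemaState, feature_scales, implied_cov, scaled_bands

__all__ = [
    "InfeasibleFeatureError",
    "make_lung_mask",
    "build_dz_field",
    "simulate_breath_frames",
    "simulate_airway_signals",
    "simulate_subject",
    "simulate_cohort",
    "simulate_feature_cohort",
]


class InfeasibleFeatureError(ValueError):
    """Requested feature combination cannot be realized on the pixel grid."""


# ---------------------------------------------------------------------------
# Lung mask
# ---------------------------------------------------------------------------

_DEFAULT_GEOMETRY = {
    "row_center": 0.52,
    "col_offset": 0.22,
    "semi_width": 0.24,
    "semi_height": 0.38,
}


def make_lung_mask(
    height: int, width: int, geometry: Mapping[str, float] | None = None
) -> np.ndarray:
    """Two-lobe, left-right symmetric lung mask on an H x W grid.

    The lobes are ellipses (a crude stand-in for a species-specific thorax
    model) that touch at the midline so the mask is connected.  Deterministic
    for fixed parameters.

    Raises
    ------
    InfeasibleFeatureError
        If the geometry yields an empty, disconnected or implausibly sized
        mask (outside 30-60 % of the grid).
    """
    if height < 8 or width < 8:
        raise ValueError("mask grid must be at least 8x8")
    geo = dict(_DEFAULT_GEOMETRY)
    if geometry:
        geo.update(geometry)
    rows = np.arange(height)[:, None] + 0.5
    cols = np.arange(width)[None, :] + 0.5
    rc = geo["row_center"] * height
    b = geo["semi_height"] * height
    a = geo["semi_width"] * width
    mask = np.zeros((height, width), dtype=bool)
    for cc in (width * (0.5 - geo["col_offset"]), width * (0.5 + geo["col_offset"])):
        mask |= ((rows - rc) / b) ** 2 + ((cols - cc) / a) ** 2 <= 1.0
    mask |= mask[:, ::-1]  # enforce exact left-right symmetry
    if not mask.any():
        raise InfeasibleFeatureError("degenerate geometry: empty lung mask")
    n_labels = ndimage.label(mask)[1]
    if n_labels != 1:
        raise InfeasibleFeatureError(
            f"degenerate geometry: mask has {n_labels} disconnected components"
        )
    frac = mask.mean()
    if not (0.30 <= frac <= 0.60):
        raise InfeasibleFeatureError(
            f"degenerate geometry: mask fraction {frac:.2f} outside [0.30, 0.60]"
        )
    return mask


# ---------------------------------------------------------------------------
# Tidal-change field construction
# ---------------------------------------------------------------------------


def _extent_coords(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (y, x) coordinates in % of the lung bounding extent.

    y runs 0 (ventral edge) to 100 (dorsal edge) across pixel centers; x runs
    0 (subject's right) to 100 (left).  Matches the analysis-side convention.
    """
    ridx, cidx = np.nonzero(mask)
    r0, r1 = ridx.min(), ridx.max()
    c0, c1 = cidx.min(), cidx.max()
    n_rows = r1 - r0 + 1
    n_cols = c1 - c0 + 1
    rows = np.arange(mask.shape[0])
    cols = np.arange(mask.shape[1])
    y = (rows - r0 + 0.5) / n_rows * 100.0
    x = (cols - c0 + 0.5) / n_cols * 100.0
    return np.broadcast_to(y[:, None], mask.shape), np.broadcast_to(x[None, :], mask.shape)


def _band_index(mask: np.ndarray) -> np.ndarray:
    """Ventro-dorsal band (0..3) of each pixel, by its center position."""
    y, _ = _extent_coords(mask)
    return np.minimum(3, (y / 25.0).astype(int))


def mask_band_centers(mask: np.ndarray) -> np.ndarray:
    """Mean ventro-dorsal pixel coordinate (extent-%) of each quarter band.

    For non-rectangular lungs these sit closer to mid-height than the
    nominal 12.5/37.5/62.5/87.5 band midpoints; using them keeps the
    centroid implied by a band distribution consistent with what the pixel
    grid can actually express.
    """
    y, _ = _extent_coords(mask)
    band = _band_index(mask)
    return np.array([y[mask & (band == b)].mean() for b in range(4)])


def build_dz_field(
    mask: np.ndarray,
    *,
    tiv: float,
    cov_vd: float,
    cov_rl: float,
    bands: Iterable[float],
    nss_pct: float,
    dss_pct: float,
    silent_threshold: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct a per-pixel tidal impedance change field with given features.

    The field satisfies, by construction:

    * the sum over the mask equals ``tiv``;
    * the share of each ventro-dorsal quarter-band equals ``bands`` (%);
    * the ventilation-weighted centroid sits at (``cov_vd``, ``cov_rl``) in
      extent-%, achieved with an exponential tilt of the within-band weights;
    * ``nss_pct`` (``dss_pct``) percent of mask pixels, dorsal (ventral) to
      the centroid plane, receive zero change — the silent-space ground
      truth — while every ventilated pixel stays above ``silent_threshold``
      of the maximum.

    Returns ``(dz, silent)`` where ``silent`` marks the zeroed pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    bands = np.asarray(list(bands), dtype=float)
    if bands.shape != (4,):
        raise ValueError("bands must have four entries")
    if abs(bands.sum() - 100.0) > 1e-6:
        raise InfeasibleFeatureError(
            f"band fractions must sum to 100, got {bands.sum():.4f}"
        )
    if tiv <= 0:
        raise InfeasibleFeatureError("tiv must be positive")
    y, x = _extent_coords(mask)
    band = _band_index(mask)
    n_mask = int(mask.sum())

    # --- silent-space pixel selection (deterministic, outer shell first) ---
    n_nss = int(round(nss_pct / 100.0 * n_mask))
    n_dss = int(round(dss_pct / 100.0 * n_mask))
    ridx, cidx = np.nonzero(mask)
    yc, xc = y[mask], x[mask]
    # Dependent silent space fills from the most ventral (gravitationally
    # lowest, first-flooded) pixels upward; non-dependent from the most
    # dorsal pixels downward.  Lateral pixels go first within a row.  This
    # also keeps the per-pixel ventilation density of the thinned dependent
    # bands high enough to clear the silent-space threshold.
    lateral = -np.abs(xc - 50.0)
    ventral_order = np.lexsort((cidx, lateral, yc))  # most ventral first
    dorsal_order = np.lexsort((cidx, lateral, -yc))  # most dorsal first
    band_flat = band[mask]
    n_band = np.array([(band_flat == b).sum() for b in range(4)])
    reserve = np.maximum(1, n_band // 4)  # keep >=25 % of each band ventilated

    per_band = np.zeros(4, dtype=int)  # silent picks per band, both sides

    def pick(order: np.ndarray, side: np.ndarray, count: int) -> np.ndarray:
        taken: list[int] = []
        for idx in order[side[order]]:
            b = band_flat[idx]
            if n_band[b] - per_band[b] <= reserve[b]:
                continue
            taken.append(int(idx))
            per_band[b] += 1
            if len(taken) == count:
                break
        return np.asarray(taken, dtype=int)

    dorsal_pick = pick(dorsal_order, yc > cov_vd, n_nss)
    ventral_pick = pick(ventral_order, yc <= cov_vd, n_dss)
    if len(dorsal_pick) < n_nss or len(ventral_pick) < n_dss:
        raise InfeasibleFeatureError(
            "silent-space fractions exceed the pixels available on the "
            "requested side of the CoV plane"
        )
    silent = np.zeros_like(mask)
    silent[ridx[dorsal_pick], cidx[dorsal_pick]] = True
    silent[ridx[ventral_pick], cidx[ventral_pick]] = True

    active = mask & ~silent
    frac = bands / 100.0
    for b in range(4):
        if frac[b] > 0 and not (active & (band == b)).any():
            raise InfeasibleFeatureError(
                f"band {BAND_NAMES[b]} has weight {bands[b]:.2f}% but no "
                "ventilated pixels remain in it"
            )

    ya, xa = y[active], x[active]
    ba = band[active]

    def weights(lam: float, mu: float) -> np.ndarray:
        u = np.exp(lam * (ya - 50.0) / 100.0 + mu * (xa - 50.0) / 100.0)
        w = np.empty_like(u)
        for b in range(4):
            sel = ba == b
            if sel.any():
                w[sel] = frac[b] * u[sel] / u[sel].sum()
        return w

    def residual(p: np.ndarray) -> np.ndarray:
        w = weights(p[0], p[1])
        return np.array([w @ ya - cov_vd, w @ xa - cov_rl])

    sol = optimize.root(residual, np.zeros(2), method="hybr")
    if np.max(np.abs(residual(sol.x))) > 1e-7:
        lo = sum(f * ya[ba == b].min() for b, f in enumerate(frac) if (ba == b).any())
        hi = sum(f * ya[ba == b].max() for b, f in enumerate(frac) if (ba == b).any())
        raise InfeasibleFeatureError(
            f"requested CoV ({cov_vd:.1f}, {cov_rl:.1f}) is not achievable "
            f"with the given band fractions (CoV_VD range [{lo:.1f}, {hi:.1f}] "
            "for the masked grid)"
        )
    w = weights(*sol.x)
    dz = np.zeros(mask.shape, dtype=float)
    dz[active] = tiv * w
    ratio = dz[active].min() / dz[active].max()
    if ratio < silent_threshold * 1.001:
        raise InfeasibleFeatureError(
            f"ventilated-pixel contrast {ratio:.3f} violates the silent-space "
            f"threshold {silent_threshold}: band fractions too uneven for this mask"
        )
    return dz, silent


# ---------------------------------------------------------------------------
# Single-compartment ventilator waveform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathWaveform:
    """Dense single-compartment volume/flow model for one ventilator cycle.

    Volume-controlled breath: constant inspiratory flow over ``flow_time``,
    an end-inspiratory pause to ``insp_time``, then passive exponential
    expiration with time constant ``raw * c_el`` whose onset is smoothed over
    ``onset_s`` so the sampled flow signal has no step discontinuity.  The
    expiratory flow amplitude is normalized so the expired volume equals the
    inspired VT exactly within the cycle.
    """

    period: float
    flow_time: float
    insp_time: float
    vt_l: float
    t_exp: np.ndarray  # dense grid of the expiration phase, s from insp_time
    flow_exp: np.ndarray
    vol_exp: np.ndarray
    pef_lps: float

    def flow(self, t_rel: np.ndarray) -> np.ndarray:
        t = np.asarray(t_rel, dtype=float)
        out = np.where(t <= self.flow_time + 1e-12, self.vt_l / self.flow_time, 0.0)
        exp_sel = t > self.insp_time
        out = np.where(exp_sel, np.interp(t - self.insp_time, self.t_exp, self.flow_exp), out)
        return out

    def volume(self, t_rel: np.ndarray) -> np.ndarray:
        t = np.asarray(t_rel, dtype=float)
        out = np.minimum(t / self.flow_time, 1.0) * self.vt_l
        exp_sel = t > self.insp_time
        out = np.where(exp_sel, np.interp(t - self.insp_time, self.t_exp, self.vol_exp), out)
        return out


def single_compartment_breath(
    vt_l: float,
    raw: float,
    c_el_l_per_cmh2o: float,
    period: float,
    insp_fraction: float,
    pause_fraction: float,
    onset_s: float,
    dense_rate: float = 4000.0,
) -> BreathWaveform:
    if min(vt_l, raw, c_el_l_per_cmh2o, period) <= 0:
        raise ValueError("mechanical parameters must be positive")
    ti = period * insp_fraction
    tf = ti * (1.0 - pause_fraction)
    tau = raw * c_el_l_per_cmh2o
    te = period - ti
    n = max(64, int(round(te * dense_rate)))
    t_exp = np.linspace(0.0, te, n)
    s = np.clip(t_exp / max(onset_s, 1e-9), 0.0, 1.0)
    shape = (3.0 * s**2 - 2.0 * s**3) * np.exp(-t_exp / tau)
    integral = np.trapezoid(shape, t_exp)
    amp = vt_l / integral
    flow_exp = -amp * shape
    vol_exp = vt_l + np.concatenate(
        ([0.0], np.cumsum((flow_exp[1:] + flow_exp[:-1]) / 2.0 * np.diff(t_exp)))
    )
    return BreathWaveform(
        period=period,
        flow_time=tf,
        insp_time=ti,
        vt_l=vt_l,
        t_exp=t_exp,
        flow_exp=flow_exp,
        vol_exp=vol_exp,
        pef_lps=float(amp * shape.max()),
    )


def elastic_compliance(vt_ml: float, raw: float, cdyn_ml_per_cmh2o: float, flow_i_lps: float) -> float:
    """Single-compartment elastance (as compliance, L/cmH2O) that yields the
    requested *dynamic* compliance.

    The spirometric Cdyn = VT / (PIP - PEEP) includes the resistive pressure
    Raw * inspiratory flow, so the tissue compliance must be stiffer than the
    dynamic target: ``C_el = VT / (VT/Cdyn - Raw*flow)``.
    """
    vt_l = vt_ml / 1000.0
    cdyn_l = cdyn_ml_per_cmh2o / 1000.0
    denom = vt_l / cdyn_l - raw * flow_i_lps
    if denom <= 0:
        raise InfeasibleFeatureError(
            "dynamic compliance target unreachable: resistive pressure exceeds "
            "the total driving pressure"
        )
    return vt_l / denom


# ---------------------------------------------------------------------------
# Expirogram model (generator side)
# ---------------------------------------------------------------------------


def expirogram_model(
    v_ml: np.ndarray,
    *,
    vt_ml: float,
    vdaw_ml: float,
    siii_mmhg_per_l: float,
    etco2_mmhg: float,
    width_ml: float,
) -> np.ndarray:
    """Three-phase expired CO2 tension as a function of expired volume (mL).

    Phase I is CO2-free airway gas, phase II a sigmoid centered at the airway
    dead space, phase III a linear alveolar plateau with the given slope,
    anchored so the curve reaches ``etco2`` at full tidal volume.
    """
    s3 = siii_mmhg_per_l / 1000.0  # mmHg per mL
    p0 = etco2_mmhg - s3 * (vt_ml - vdaw_ml)
    if p0 <= 0:
        raise InfeasibleFeatureError(
            "phase III slope too steep for the configured end-tidal CO2"
        )
    p = (p0 + s3 * (np.asarray(v_ml, dtype=float) - vdaw_ml)) * expit(
        (np.asarray(v_ml, dtype=float) - vdaw_ml) / width_ml
    )
    return np.clip(p, 0.0, None)


def _expirogram_truth(targets: Mapping[str, float], width_ml: float) -> dict[str, float]:
    """Closed-ish-form capnographic ground truth for a target breath."""
    vt, vdaw = targets["vt"], targets["vdaw"]
    v = np.linspace(0.0, vt, 4001)
    p = expirogram_model(
        v,
        vt_ml=vt,
        vdaw_ml=vdaw,
        siii_mmhg_per_l=targets["siii"],
        etco2_mmhg=targets["etco2"],
        width_ml=width_ml,
    )
    pe = float(np.trapezoid(p, v) / vt)
    s3 = targets["siii"] / 1000.0
    pa = float(targets["etco2"] - s3 * (vt - vdaw) + s3 * (0.75 * vt - vdaw))
    vd_bohr = (pa - pe) / pa
    return {"pe_co2": pe, "pa_co2": pa, "vd_bohr": vd_bohr}


# ---------------------------------------------------------------------------
# Per-breath targets
# ---------------------------------------------------------------------------


def subject_baselines(
    config: SimConfig,
    rng: np.random.Generator,
    band_centers: np.ndarray | None = None,
) -> dict[str, float | tuple]:
    """Draw subject-level baseline targets around the configured means.

    ``band_centers`` (the mask's actual per-band centroids) keep the
    subject's center of ventilation consistent with its drawn band
    distribution; the nominal quarter-band midpoints are used by default.
    """
    from .config import BAND_CENTERS

    if band_centers is None:
        band_centers = np.asarray(BAND_CENTERS)
    isd = config.inter_subject_sd
    bf = config.baseline_features

    def draw(mean: float, key: str) -> float:
        sd = isd.get(key, 0.0)
        if sd == 0.0:
            return mean
        return mean * float(np.clip(1.0 + sd * rng.standard_normal(), 0.3, 2.5))

    bands = np.asarray(config.band_fractions())
    sd_b = isd.get("dz", 0.0)
    if sd_b > 0:
        bands = bands * np.clip(1.0 + sd_b * rng.standard_normal(4), 0.5, 1.5)
        bands *= 100.0 / bands.sum()
    # The subject's CoV moves with its band perturbation; an extra draw adds
    # independent geometric spread on top.
    cov_vd = bf["cov_vd"] + (
        implied_cov(bands, band_centers) - implied_cov(config.band_fractions(), band_centers)
    )
    cov_vd = draw(cov_vd, "cov_vd")
    return {
        "tiv": draw(bf["tiv"], "tiv"),
        "eeli": draw(bf["eeli"], "eeli"),
        "cov_vd": cov_vd,
        "cov_rl": draw(bf["cov_rl"], "cov_rl"),
        "nss": draw(bf["nss"], "nss"),
        "dss": draw(bf["dss"], "dss"),
        "bands": tuple(float(x) for x in bands),
        "raw": draw(config.mech_baseline["raw"], "raw"),
        "cdyn": draw(config.mech_baseline["cdyn"], "cdyn"),
        "etco2": draw(config.capno_baseline["etco2"], "etco2"),
        "vdaw": draw(config.capno_baseline["vdaw_frac"] * config.vt_ml, "vdaw"),
        "siii": draw(config.capno_baseline["siii"], "siii"),
        "vt": config.vt_ml,
    }


def breath_targets(
    config: SimConfig,
    base: Mapping[str, float | tuple],
    t: float,
    rng: np.random.Generator | None = None,
    band_centers: np.ndarray | None = None,
) -> dict[str, float | tuple]:
    """Feature targets for the breath starting at time ``t`` (s from injection)."""
    from .config import BAND_CENTERS

    if band_centers is None:
        band_centers = np.asarray(BAND_CENTERS)
    scales = feature_scales(config, t)
    nsd = config.noise_sd

    def noisy(value: float, key: str) -> float:
        sd = nsd.get(key, 0.0)
        if rng is None or sd == 0.0:
            return value
        return value * float(np.clip(1.0 + sd * rng.standard_normal(), 0.3, 2.5))

    bands = np.asarray(base["bands"]) * np.array([scales[k] for k in BAND_NAMES])
    bands *= 100.0 / bands.sum()
    cov_shift = implied_cov(bands, band_centers) - implied_cov(base["bands"], band_centers)
    if rng is not None:
        perturbed = np.array(
            [noisy(b, k) for b, k in zip(bands, BAND_NAMES)], dtype=float
        )
        bands = perturbed * 100.0 / perturbed.sum()
    out = {
        "t": t,
        "tiv": noisy(base["tiv"] * scales["tiv"], "tiv"),
        "eeli": noisy(base["eeli"] * scales["eeli"], "eeli"),
        "cov_vd": noisy(base["cov_vd"] + cov_shift, "cov_vd"),
        "cov_rl": noisy(base["cov_rl"], "cov_rl"),
        "nss": noisy(base["nss"] * scales["nss"], "nss"),
        "dss": noisy(base["dss"] * scales["dss"], "dss"),
        "bands": tuple(float(x) for x in bands),
        "raw": noisy(base["raw"] * scales["raw"], "raw"),
        "cdyn": noisy(base["cdyn"] * scales["cdyn"], "cdyn"),
        "etco2": noisy(base["etco2"] * scales["etco2"], "etco2"),
        "vdaw": noisy(base["vdaw"] * scales["vdaw"], "vdaw"),
        "siii": noisy(base["siii"] * scales["siii"], "siii"),
        "vt": noisy(base["vt"], "vt"),
    }
    return out


def _targets_from_state(
    config: SimConfig, state: EdemaState, band_centers=None
) -> dict[str, float | tuple]:
    """Population-level (noise-free) targets for a given edema state."""
    base = {
        "tiv": config.baseline_features["tiv"],
        "eeli": config.baseline_features["eeli"],
        "cov_vd": config.baseline_features["cov_vd"],
        "cov_rl": config.baseline_features["cov_rl"],
        "nss": config.baseline_features["nss"],
        "dss": config.baseline_features["dss"],
        "bands": config.band_fractions(),
        "raw": config.mech_baseline["raw"],
        "cdyn": config.mech_baseline["cdyn"],
        "etco2": config.capno_baseline["etco2"],
        "vdaw": config.capno_baseline["vdaw_frac"] * config.vt_ml,
        "siii": config.capno_baseline["siii"],
        "vt": config.vt_ml,
    }
    return breath_targets(config, base, state.t, rng=None, band_centers=band_centers)


# ---------------------------------------------------------------------------
# Rendering one breath
# ---------------------------------------------------------------------------


def _breath_mechanics(config: SimConfig, targets: Mapping[str, float | tuple]) -> BreathWaveform:
    vt_l = targets["vt"] / 1000.0
    flow_i = vt_l / config.flow_time_s
    c_el = elastic_compliance(targets["vt"], targets["raw"], targets["cdyn"], flow_i)
    return single_compartment_breath(
        vt_l,
        targets["raw"],
        c_el,
        config.breath_period_s,
        config.insp_fraction,
        config.pause_fraction,
        config.exp_onset_s,
    )


def simulate_breath_frames(
    config: SimConfig,
    state: EdemaState,
    breath_phase: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """EIT frame stack for one breath at the given within-breath times (s).

    Per-pixel impedance is an end-expiratory spatial baseline (scaled by the
    edema state) plus the tidal-change field modulated by the normalized lung
    volume waveform of the ventilator model.
    """
    if mask is None:
        mask = make_lung_mask(config.grid_height, config.grid_width)
    targets = _targets_from_state(config, state, mask_band_centers(mask))
    wf = _breath_mechanics(config, targets)
    dz, _ = build_dz_field(
        mask,
        tiv=targets["tiv"],
        cov_vd=targets["cov_vd"],
        cov_rl=targets["cov_rl"],
        bands=targets["bands"],
        nss_pct=targets["nss"],
        dss_pct=targets["dss"],
    )
    b = np.where(mask, targets["eeli"] / mask.sum(), 0.0)
    s = wf.volume(np.asarray(breath_phase)) / wf.vt_l
    return b[None, :, :] + s[:, None, None] * dz[None, :, :]


def simulate_airway_signals(
    config: SimConfig, state: EdemaState, breath_index: int = 0
) -> AirwaySignals:
    """Airway signal segment (one ventilator cycle) for a given edema state."""
    targets = _targets_from_state(config, state)
    wf = _breath_mechanics(config, targets)
    sr = config.airway_sample_rate
    t = np.arange(int(round(config.breath_period_s * sr))) / sr
    flow, paw, pco2 = _render_airway_breath(config, targets, wf, t)
    t0 = config.timeline.baseline_start + breath_index * config.breath_period_s
    return AirwaySignals(time=t + t0, flow=flow, paw=paw, pco2=pco2, sample_rate=sr)


def _render_airway_breath(
    config: SimConfig,
    targets: Mapping[str, float | tuple],
    wf: BreathWaveform,
    t_rel: np.ndarray,
    effort: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    flow = wf.flow(t_rel)
    vol = wf.volume(t_rel)
    flow_i = wf.vt_l / wf.flow_time
    c_el = elastic_compliance(targets["vt"], targets["raw"], targets["cdyn"], flow_i)
    paw = targets["raw"] * flow + vol / c_el + config.peep
    if effort:
        mid = wf.insp_time + 0.4 * (wf.period - wf.insp_time)
        paw = paw - config.spont_effort_depth_cmh2o * np.exp(
            -(((t_rel - mid) / 0.3) ** 2)
        )
    pco2 = np.zeros_like(t_rel)
    exp_sel = t_rel > wf.insp_time
    ve = (wf.vt_l - vol[exp_sel]) * 1000.0
    pco2[exp_sel] = expirogram_model(
        ve,
        vt_ml=targets["vt"],
        vdaw_ml=targets["vdaw"],
        siii_mmhg_per_l=targets["siii"],
        etco2_mmhg=targets["etco2"],
        width_ml=config.phase2_width_ml,
    )
    return flow, paw, pco2


# ---------------------------------------------------------------------------
# Full subject and cohort
# ---------------------------------------------------------------------------


def _subject_rng(config: SimConfig, subject_index: int) -> np.random.Generator:
    # Fixed per-subject stream: adding subjects never reshuffles earlier ones.
    return np.random.default_rng([config.seed, subject_index])


def simulate_subject(
    config: SimConfig,
    subject_index: int = 0,
    t_end: float | None = None,
) -> tuple[EITSequence, AirwaySignals, EventLog, pd.DataFrame]:
    """Simulate one subject's full synchronized recording.

    Returns the EIT sequence, airway signals, event log and a ground-truth
    table with one row per breath holding the feature targets actually used
    (after subject-level and breath-level noise), plus derived mechanical and
    capnographic truths.
    """
    tl = config.timeline
    if t_end is None:
        t_end = tl.record_end
    period = config.breath_period_s
    n_breaths = int(np.floor((t_end - tl.baseline_start) / period + 1e-9))
    if n_breaths < 1:
        raise ValueError("t_end leaves no room for a single breath")
    t_stop = tl.baseline_start + n_breaths * period

    rng = _subject_rng(config, subject_index)
    mask = make_lung_mask(config.grid_height, config.grid_width)
    centers = mask_band_centers(mask)
    base = subject_baselines(config, rng, centers)
    n_mask = int(mask.sum())

    sr = config.airway_sample_rate
    fr = config.eit_frame_rate
    t_air = tl.apnea_start + np.arange(int(round((t_stop - tl.apnea_start) * sr)) + 1) / sr
    t_frames = tl.apnea_start + np.arange(int(round((t_stop - tl.apnea_start) * fr)) + 1) / fr

    flow = np.zeros_like(t_air)
    paw = np.full_like(t_air, config.peep)
    pco2 = np.zeros_like(t_air)
    frames = np.empty((len(t_frames), config.grid_height, config.grid_width), dtype=np.float32)
    # Apnea: ventilation stopped, lungs at end-expiratory level.
    b_apnea = np.where(mask, base["eeli"] / n_mask, 0.0)
    frames[:] = b_apnea[None, :, :].astype(np.float32)

    truth_rows = []
    for k in range(n_breaths):
        t0 = tl.baseline_start + k * period
        # Breath-level noise is rejection-sampled to the feasible set: the
        # rare draw whose feature combination cannot be realized on the pixel
        # grid (a fraction of a percent at the default settings) is redrawn.
        for attempt in range(12):
            targets = breath_targets(config, base, t0, rng, centers)
            try:
                dz, _ = build_dz_field(
                    mask,
                    tiv=targets["tiv"],
                    cov_vd=targets["cov_vd"],
                    cov_rl=targets["cov_rl"],
                    bands=targets["bands"],
                    nss_pct=targets["nss"],
                    dss_pct=targets["dss"],
                )
                break
            except InfeasibleFeatureError:
                if rng is None or attempt == 11:
                    raise
        wf = _breath_mechanics(config, targets)
        effort = config.spont_effort_rate > 0 and rng.random() < config.spont_effort_rate
        b_field = np.where(mask, targets["eeli"] / n_mask, 0.0)

        a_sel = (t_air >= t0 - 1e-9) & (t_air < t0 + period - 1e-9)
        f, p, c = _render_airway_breath(config, targets, wf, t_air[a_sel] - t0, effort)
        flow[a_sel], paw[a_sel], pco2[a_sel] = f, p, c

        f_sel = (t_frames >= t0 - 1e-9) & (t_frames < t0 + period - 1e-9)
        s = wf.volume(t_frames[f_sel] - t0) / wf.vt_l
        frames[f_sel] = (b_field[None, :, :] + s[:, None, None] * dz[None, :, :]).astype(
            np.float32
        )

        flow_i = wf.vt_l / wf.flow_time
        c_el = elastic_compliance(targets["vt"], targets["raw"], targets["cdyn"], flow_i)
        cap = _expirogram_truth(targets, config.phase2_width_ml)
        row = {k2: v for k2, v in targets.items() if k2 != "bands"}
        row.update({f"band_{n}": v for n, v in zip(BAND_NAMES, targets["bands"])})
        row.update(
            {
                "subject": subject_index,
                "ordinal": k + 1,
                "t_start": t0,
                "pip": targets["raw"] * flow_i + wf.vt_l / c_el + config.peep,
                "p_plat": wf.vt_l / c_el + config.peep,
                "pef": wf.pef_lps,
                "effort": effort,
                **cap,
            }
        )
        truth_rows.append(row)

    eit = EITSequence(frames=frames, frame_rate=fr, lung_mask=mask)
    airway = AirwaySignals(time=t_air, flow=flow, paw=paw, pco2=pco2, sample_rate=sr)
    events = EventLog(
        apnea_start=tl.apnea_start,
        apnea_end=tl.apnea_end,
        injection_start=tl.injection_start,
        injection_end=tl.injection_end,
    )
    return eit, airway, events, pd.DataFrame(truth_rows)


def simulate_cohort(config: SimConfig, out_path: str | Path, t_end: float | None = None) -> list[Path]:
    """Write the full on-disk dataset layout for all subjects.

    Fully reproducible from the configured seed.  Returns subject directories.
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    dirs = []
    truths = []
    for i in range(config.n_subjects):
        eit, airway, events, truth = simulate_subject(config, i, t_end=t_end)
        subj_dir = out / f"subject_{i + 1:02d}"
        write_subject(subj_dir, eit, airway, events)
        truths.append(truth)
        dirs.append(subj_dir)
    pd.concat(truths, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    return dirs


# ---------------------------------------------------------------------------
# Feature-level cohort (no frame rendering) for statistical experiments
# ---------------------------------------------------------------------------

#: Mapping from generator target keys to the feature-table variable names.
FEATURE_VARIABLES = {
    "tiv": "tiv_au",
    "eeli": "eeli_au",
    "cov_vd": "cov_vd_pct",
    "cov_rl": "cov_rl_pct",
    "nss": "nss_pct",
    "dss": "dss_pct",
    "raw": "raw_cmh2o_per_lps",
    "cdyn": "cdyn_ml_per_cmh2o",
    "etco2": "pa_co2_mmhg",
    "vdaw": "vd_aw_ml",
    "siii": "s3_mmhg_per_l",
    "vt": "vt_exp_ml",
}


def simulate_feature_cohort(
    config: SimConfig,
    *,
    effect: bool = True,
    t_end: float | None = None,
    variables: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-breath feature table drawn directly from the noise model.

    Bypasses frame/waveform rendering: values are the same per-breath targets
    the renderer would embed, so this is the fast path for repeated-cohort
    statistical experiments (e.g. null calibration of the testing procedure).
    With ``effect=False`` the edema trajectory is suppressed entirely.
    """
    if t_end is None:
        t_end = config.timeline.injection_end + 60.0
    period = config.breath_period_s
    n_breaths = int(np.floor((t_end - config.timeline.baseline_start) / period + 1e-9)) + 1
    centers = mask_band_centers(make_lung_mask(config.grid_height, config.grid_width))
    keys = list(FEATURE_VARIABLES) if variables is None else [
        k for k, v in FEATURE_VARIABLES.items() if v in set(variables) or k in set(variables)
    ]
    rows = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        base = subject_baselines(config, rng, centers)
        for k in range(n_breaths):
            t0 = config.timeline.baseline_start + k * period
            t_eff = t0 if effect else config.timeline.baseline_start
            targets = breath_targets(config, base, t_eff, rng, centers)
            for key in keys:
                rows.append(
                    (f"subject_{i + 1:02d}", FEATURE_VARIABLES[key], k + 1, t0, targets[key])
                )
    return pd.DataFrame(
        rows, columns=["subject", "variable", "breath_ordinal", "t_s", "value"]
    )
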