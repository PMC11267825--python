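"""Parametric time-course of the simulated edema.

The xylazine model produces, within roughly two minutes of the start of the
injection, a fall in end-expiratory lung impedance (alveolar flooding of the
dependent, i.e. ventral, lung in prone posture), a shift of tidal ventilation
from the ventral toward the dorsal bands, a fall in dynamic compliance and a
rise in airway resistance.  We model each affected variable as a logistic
ramp from its baseline toward a plateau: identity at and before the start of
injection, monotone afterwards, with a configurable onset and timescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .config import BAND_CENTERS, BAND_NAMES, SimConfig

__all__ = ["EdemaState", "edema_trajectory", "logistic_level", "feature_scales", "implied_cov"]


def logistic_level(t: float, onset_s: float, tau_s: float) -> float:
    """Normalized logistic ramp: 0 for ``t <= 0``, approaching 1 as t grows.

    The raw logistic ``expit((t - onset)/tau)`` is nonzero at t = 0; it is
    shifted and rescaled so the ramp is *exactly* zero at the start of the
    injection and still saturates at 1.
    """
    if t <= 0.0:
        return 0.0
    s0 = expit(-onset_s / tau_s)
    return float((expit((t - onset_s) / tau_s) - s0) / (1.0 - s0))


def feature_scales(config: SimConfig, t: float) -> dict[str, float]:
    """Per-variable multiplicative scales at time ``t`` (1.0 at baseline).

    Scales are anchored so that at ``kinetics.plateau_s`` each variable sits
    exactly at its configured endpoint ratio.  Band scales are returned
    unnormalized; callers renormalize the four band fractions to sum to 100.
    """
    kin = config.kinetics
    level = logistic_level(t, kin.onset_s, kin.tau_s)
    level_plateau = logistic_level(kin.plateau_s, kin.onset_s, kin.tau_s)
    rel = level / level_plateau
    return {k: 1.0 + (r - 1.0) * rel for k, r in kin.endpoint_ratios.items()}


def implied_cov(
    bands: tuple[float, ...] | np.ndarray,
    band_centers: tuple[float, ...] | np.ndarray = BAND_CENTERS,
) -> float:
    """Ventro-dorsal centroid implied by band fractions at the band centers.

    ``band_centers`` defaults to the nominal quarter-band midpoints; pass the
    actual per-band pixel centroids of a lung mask for geometry-consistent
    values.
    """
    b = np.asarray(bands, dtype=float)
    return float(np.dot(b, np.asarray(band_centers, dtype=float)) / b.sum())


def scaled_bands(config: SimConfig, t: float) -> tuple[float, ...]:
    """Band fractions at time ``t``, renormalized to sum exactly to 100."""
    scales = feature_scales(config, t)
    base = np.asarray(config.band_fractions())
    b = base * np.array([scales[k] for k in BAND_NAMES])
    b *= 100.0 / b.sum()
    return tuple(float(x) for x in b)


@dataclass(frozen=True)
class EdemaState:
    """Dimensionless summary of the edema severity at one instant.

    ``ventral_loss`` is the fraction of the baseline dependent-band (ventral
    plus centro-ventral) share of ventilation that has been reassigned
    dorsally.
    """

    t: float
    eeli_scale: float
    ventral_loss: float
    raw_scale: float
    cdyn_scale: float
    siii_scale: float

    def __post_init__(self) -> None:
        if not (0.0 < self.eeli_scale <= 1.0):
            raise ValueError("eeli_scale must lie in (0, 1]")
        if not (0.0 <= self.ventral_loss < 1.0):
            raise ValueError("ventral_loss must lie in [0, 1)")
        if self.raw_scale < 1.0:
            raise ValueError("raw_scale must be >= 1")
        if not (0.0 < self.cdyn_scale <= 1.0):
            raise ValueError("cdyn_scale must lie in (0, 1]")


def edema_trajectory(t: float, config: SimConfig) -> EdemaState:
    """Edema state at time ``t`` (seconds relative to the start of injection)."""
    tl = config.timeline
    if not (tl.apnea_start <= t <= tl.record_end):
        raise ValueError(f"t={t} outside the configured timeline")
    scales = feature_scales(config, t)
    base = config.band_fractions()
    bands = scaled_bands(config, t)
    dep0 = base[0] + base[1]
    dep = bands[0] + bands[1]
    return EdemaState(
        t=t,
        eeli_scale=scales["eeli"],
        ventral_loss=max(0.0, 1.0 - dep / dep0),
        raw_scale=scales["raw"],
        cdyn_scale=scales["cdyn"],
        siii_scale=scales["siii"],
    )
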