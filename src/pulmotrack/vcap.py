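"""Volumetric capnography: per-breath expirogram construction and analysis.

The expirogram plots expired CO2 tension against expired volume (integrated
from the expiratory flow signal).  Its three phases — CO2-free airway gas, a
steep transition, and the alveolar plateau — yield the airway (Fowler-type)
dead space at the inflection point, the phase II and III slopes, the alpha
angle between them, and, via the mean alveolar and mixed-expired CO2
tensions, the Bohr dead-space ratio::

    VDBohr = (PACO2 - PECO2) / PACO2

with PACO2 read from the fitted phase III line at the midpoint of the
plateau window and PECO2 the volume-weighted mean expired tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import AirwaySignals, Breath

__all__ = [
    "Expirogram",
    "PhaseFits",
    "GasExchange",
    "BreathTooSmallError",
    "FlatExpirogramError",
    "build_expirogram",
    "fit_phases",
    "dead_spaces",
    "gas_exchange",
    "compute_breath_vcap",
]


class BreathTooSmallError(ValueError):
    """Expired volume below the analyzable minimum; breath is incomplete."""


class FlatExpirogramError(ValueError):
    """No phase II detected (CO2 curve flat or empty)."""


@dataclass
class Expirogram:
    """Expired CO2 tension on an expired-volume grid for one breath."""

    volume: np.ndarray  # mL, strictly increasing from 0 to vt
    pco2: np.ndarray  # mmHg
    vt: float  # mL

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if len(self.volume) != len(self.pco2):
            raise ValueError("volume and pco2 must have equal length")
        if np.any(np.diff(self.volume) <= 0):
            raise ValueError("volume must be strictly increasing")
        if np.any(self.pco2 < -1e-9):
            raise ValueError("pco2 must be non-negative")

    @property
    def end_tidal(self) -> float:
        return float(self.pco2[-1])


@dataclass
class PhaseFits:
    s2: float  # mmHg/L, phase II slope (tangent at the steepest point)
    s3: float  # mmHg/L, phase III slope (least squares on the plateau window)
    alpha_deg: float  # angle between phase II and III lines, normalized axes
    y_int: float  # mmHg, phase III line at volume 0
    x_int: float  # mL, phase II line at pco2 0
    v_star: float  # mL, volume of the steepest point (inflection)
    p_star: float  # mmHg, smoothed pco2 at the steepest point


@dataclass
class GasExchange:
    vco2_br: float  # mL CO2 per breath, at measurement conditions
    pe_co2: float  # mmHg, mixed expired
    pa_co2: float  # mmHg, mean alveolar (phase III midpoint)
    vd_bohr: float  # ratio
    vd_alv: float  # mL


def build_expirogram(
    signals: AirwaySignals,
    breath: Breath,
    grid_ml: float = 1.0,
    min_vt_ml: float = 50.0,
) -> Expirogram:
    """Integrate expiratory flow into an expired-volume grid and resample CO2.

    The cumulative trapezoidal integral of -flow over the expiration segment
    gives expired volume; PCO2 is interpolated onto a uniform ``grid_ml``
    grid from 0 to the expired tidal volume.
    """
    sel = slice(breath.insp_end + 1, breath.exp_end + 1)
    t = signals.time[sel]
    flow = -signals.flow[sel] * 1000.0  # mL/s, positive during expiration
    pco2 = signals.pco2[sel]
    if len(t) < 3:
        raise BreathTooSmallError("expiration segment is empty")
    vol = np.concatenate(([0.0], np.cumsum((flow[1:] + flow[:-1]) / 2.0 * np.diff(t))))
    vt = float(vol[-1])
    if vt < min_vt_ml:
        raise BreathTooSmallError(f"expired volume {vt:.1f} mL below minimum {min_vt_ml} mL")
    # Keep strictly increasing volume samples (drop the zero-flow pause).
    keep = np.concatenate(([True], np.diff(vol) > 1e-9))
    vol, pco2 = vol[keep], pco2[keep]
    grid = np.arange(0.0, vt, grid_ml)
    if grid[-1] < vt:
        grid = np.concatenate([grid, [vt]])
    return Expirogram(volume=grid, pco2=np.interp(grid, vol, pco2), vt=vt)


def _smoothed(e: Expirogram, smooth_ml: float) -> np.ndarray:
    dv = float(np.median(np.diff(e.volume)))
    k = max(1, int(round(smooth_ml / dv)))
    if k % 2 == 0:
        k += 1
    if k == 1:
        return e.pco2
    pad = k // 2
    padded = np.concatenate([np.full(pad, e.pco2[0]), e.pco2, np.full(pad, e.pco2[-1])])
    return np.convolve(padded, np.ones(k) / k, mode="valid")


def fit_phases(
    e: Expirogram,
    window: tuple[float, float] = (0.60, 0.90),
    smooth_ml: float = 5.0,
    s2_cap: float = 2000.0,
) -> PhaseFits:
    """Fit the phase II tangent and the phase III regression line.

    Phase III is the least-squares line over the ``window`` fraction of
    expired volume; phase II is the tangent at the maximum of the smoothed
    dPCO2/dV.  The alpha angle is 180 degrees minus the angle between the
    two lines with axes normalized by VT and end-tidal PCO2; an effectively
    instantaneous phase II is reported at the ``s2_cap`` slope.
    """
    if np.ptp(e.pco2) < 1e-9:
        raise FlatExpirogramError("no phase II detected: expirogram is flat")
    smooth = _smoothed(e, smooth_ml)
    deriv = np.gradient(smooth, e.volume)
    interior = slice(1, max(2, len(deriv) - 1))
    i_star = 1 + int(np.argmax(deriv[interior]))
    s2_ml = float(deriv[i_star])  # mmHg per mL
    if s2_ml <= 0:
        raise FlatExpirogramError("no phase II detected: non-increasing expirogram")
    v_star = float(e.volume[i_star])
    p_star = float(smooth[i_star])
    s2 = min(s2_ml * 1000.0, s2_cap)

    lo, hi = window[0] * e.vt, window[1] * e.vt
    sel = (e.volume >= lo) & (e.volume <= hi)
    if sel.sum() < 2:
        raise FlatExpirogramError("phase III window contains fewer than two samples")
    slope_ml, y_int = np.polyfit(e.volume[sel], e.pco2[sel], 1)
    s3 = float(slope_ml * 1000.0)

    x_int = v_star - p_star / (s2 / 1000.0)

    et = e.end_tidal if e.end_tidal > 0 else 1.0
    m2 = (s2 / 1000.0) * e.vt / et
    m3 = (s3 / 1000.0) * e.vt / et
    alpha = 180.0 - math.degrees(abs(math.atan(m2) - math.atan(m3)))
    return PhaseFits(
        s2=s2,
        s3=s3,
        alpha_deg=alpha,
        y_int=float(y_int),
        x_int=float(x_int),
        v_star=v_star,
        p_star=p_star,
    )


def dead_spaces(e: Expirogram, fits: PhaseFits) -> tuple[float, float]:
    """Airway dead space and alveolar tidal volume (mL).

    VDaw is the expired volume at the inflection point of the smoothed
    expirogram (the maximum of dPCO2/dV); VTalv is the remainder of VT.
    """
    vd_aw = fits.v_star
    if not (0.0 < vd_aw < e.vt):
        raise FlatExpirogramError("inflection point not found inside the breath")
    return float(vd_aw), float(e.vt - vd_aw)


def gas_exchange(
    e: Expirogram,
    vd_aw: float,
    fits: PhaseFits,
    window: tuple[float, float] = (0.60, 0.90),
    pb_mmhg: float = 760.0,
    ph2o_mmhg: float = 47.0,
) -> GasExchange | None:
    """CO2 elimination, mixed-expired and alveolar tensions, Bohr dead space.

    ``vco2_br`` integrates the CO2 fraction (dry-gas barometric conversion,
    PCO2 / (Pb - PH2O)) over expired volume; no STPD correction is applied.
    Returns ``None`` when the alveolar tension is non-positive (features
    missing for the breath).
    """
    fco2 = e.pco2 / (pb_mmhg - ph2o_mmhg)
    vco2_br = float(np.trapezoid(fco2, e.volume))
    pe_co2 = float(np.trapezoid(e.pco2, e.volume) / e.vt)
    v_mid = 0.5 * (window[0] + window[1]) * e.vt
    pa_co2 = fits.s3 / 1000.0 * v_mid + fits.y_int
    if pa_co2 <= 0:
        return None
    vd_bohr = (pa_co2 - pe_co2) / pa_co2
    vd_alv = vd_bohr * e.vt - vd_aw
    return GasExchange(
        vco2_br=vco2_br,
        pe_co2=pe_co2,
        pa_co2=float(pa_co2),
        vd_bohr=float(vd_bohr),
        vd_alv=float(vd_alv),
    )


def compute_breath_vcap(
    signals: AirwaySignals,
    breath: Breath,
    grid_ml: float = 1.0,
    min_vt_ml: float = 50.0,
    window: tuple[float, float] = (0.60, 0.90),
    smooth_ml: float = 5.0,
    s2_cap: float = 2000.0,
    pb_mmhg: float = 760.0,
    ph2o_mmhg: float = 47.0,
) -> dict[str, float] | None:
    """All capnographic variables for one breath; ``None`` if unanalyzable."""
    try:
        e = build_expirogram(signals, breath, grid_ml=grid_ml, min_vt_ml=min_vt_ml)
        fits = fit_phases(e, window=window, smooth_ml=smooth_ml, s2_cap=s2_cap)
        vd_aw, vt_alv = dead_spaces(e, fits)
    except (BreathTooSmallError, FlatExpirogramError):
        return None
    gx = gas_exchange(e, vd_aw, fits, window=window, pb_mmhg=pb_mmhg, ph2o_mmhg=ph2o_mmhg)
    out = {
        "vt_ml": e.vt,
        "vd_aw_ml": vd_aw,
        "vt_alv_ml": vt_alv,
        "s2_mmhg_per_l": fits.s2,
        "s3_mmhg_per_l": fits.s3,
        "alpha_deg": fits.alpha_deg,
        "y_int_mmhg": fits.y_int,
        "x_int_ml": fits.x_int,
    }
    if gx is None:
        out.update(
            {
                "vco2_br_ml": float("nan"),
                "pe_co2_mmhg": float("nan"),
                "pa_co2_mmhg": float("nan"),
                "vd_bohr": float("nan"),
                "vd_alv_ml": float("nan"),
            }
        )
    else:
        out.update(
            {
                "vco2_br_ml": gx.vco2_br,
                "pe_co2_mmhg": gx.pe_co2,
                "pa_co2_mmhg": gx.pa_co2,
                "vd_bohr": gx.vd_bohr,
                "vd_alv_ml": gx.vd_alv,
            }
        )
    return out
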