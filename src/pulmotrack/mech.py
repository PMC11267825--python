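"""Per-breath spirometry and respiratory mechanics from flow and pressure.

Tidal volumes are time integrals of the flow signal; peak and plateau
pressures come from the inspiratory segment (the plateau requires a
zero-flow end-inspiratory pause); airway resistance and dynamic compliance
are::

    Raw  = (PIP - Pplat) / mean inspiratory flow
    Cdyn = VTexp / (PIP - PEEP)

Note the resistance form: dividing the resistive pressure drop by flow is
the only dimensionally consistent reading (the literal inverted form, flow
divided by pressure, is available behind the ``literal`` switch for
comparison).  "Peak expiratory pressure" is read as the measured
end-expiratory pressure, the only interpretation that makes Cdyn a
compliance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AirwaySignals, Breath

__all__ = [
    "MechFeatures",
    "volumes",
    "pressures",
    "mean_inspiratory_flow",
    "resistance_compliance",
    "compute_breath_mech",
]


@dataclass
class MechFeatures:
    vt_exp: float  # mL
    vt_insp: float  # mL
    pip: float  # cmH2O
    p_plat: float  # cmH2O (nan when no end-inspiratory pause exists)
    peep: float  # cmH2O
    pef: float  # L/s
    raw: float  # cmH2O/(L/s)
    cdyn: float  # mL/cmH2O
    f_r: float  # breaths/min


def volumes(signals: AirwaySignals, breath: Breath) -> tuple[float, float]:
    """(VTinsp, VTexp) in mL by trapezoidal integration of the flow signal."""
    t = signals.time
    insp = slice(breath.insp_start, breath.insp_end + 1)
    exp = slice(breath.insp_end + 1, breath.exp_end + 1)
    vt_insp = float(np.trapezoid(signals.flow[insp], t[insp]) * 1000.0)
    vt_exp = float(np.trapezoid(-signals.flow[exp], t[exp]) * 1000.0)
    return vt_insp, vt_exp


def pressures(
    signals: AirwaySignals, breath: Breath, pause_flow_threshold: float = 0.02
) -> tuple[float, float, float, float]:
    """(PIP, Pplat, PEEP, PEF) for one breath.

    PIP is the maximum airway pressure during inspiration.  Pplat is the
    mean pressure over the zero-flow end-inspiratory pause (the contiguous
    low-flow run at the start of the expiratory segment, before expiratory
    flow begins); nan when no pause exists.  PEEP is the mean pressure over
    the final 10 % of expiration, PEF the peak expiratory flow.
    """
    paw = signals.paw
    flow = signals.flow
    pip = float(paw[breath.insp_start : breath.insp_end + 1].max())
    exp0, exp1 = breath.insp_end + 1, breath.exp_end + 1
    pause_end = exp0
    while pause_end < exp1 and abs(flow[pause_end]) < pause_flow_threshold:
        pause_end += 1
    p_plat = float(paw[exp0:pause_end].mean()) if pause_end - exp0 >= 2 else float("nan")
    n_exp = exp1 - pause_end
    tail = max(1, int(round(0.10 * n_exp)))
    peep = float(paw[exp1 - tail : exp1].mean())
    pef = float(np.max(-flow[exp0:exp1])) if exp1 > exp0 else float("nan")
    return pip, p_plat, peep, pef


def mean_inspiratory_flow(signals: AirwaySignals, breath: Breath) -> float:
    """Mean flow (L/s) over the central 5-95 % of the inspiratory flow phase."""
    seg = signals.flow[breath.insp_start : breath.insp_end + 1]
    n = len(seg)
    i0 = int(np.floor(0.05 * n))
    i1 = max(i0 + 1, int(np.ceil(0.95 * n)))
    return float(seg[i0:i1].mean())


def resistance_compliance(
    pip: float,
    p_plat: float,
    peep: float,
    vt_exp: float,
    mean_insp_flow: float,
    literal: bool = False,
) -> tuple[float, float]:
    """(Raw, Cdyn); missing (nan) where the denominators degenerate."""
    if mean_insp_flow > 0 and np.isfinite(p_plat) and pip > p_plat:
        raw = (
            mean_insp_flow / (pip - p_plat) if literal else (pip - p_plat) / mean_insp_flow
        )
    else:
        raw = float("nan")
    cdyn = vt_exp / (pip - peep) if pip > peep else float("nan")
    return float(raw), float(cdyn)


def compute_breath_mech(
    signals: AirwaySignals,
    breath: Breath,
    pause_flow_threshold: float = 0.02,
    literal: bool = False,
    period_s: float | None = None,
) -> MechFeatures:
    """All spirometric variables for one breath."""
    vt_insp, vt_exp = volumes(signals, breath)
    pip, p_plat, peep, pef = pressures(signals, breath, pause_flow_threshold)
    flow_i = mean_inspiratory_flow(signals, breath)
    raw, cdyn = resistance_compliance(pip, p_plat, peep, vt_exp, flow_i, literal=literal)
    if period_s is None:
        period_s = (breath.exp_end + 1 - breath.insp_start) / signals.sample_rate
    return MechFeatures(
        vt_exp=vt_exp,
        vt_insp=vt_insp,
        pip=pip,
        p_plat=p_plat,
        peep=peep,
        pef=pef,
        raw=raw,
        cdyn=cdyn,
        f_r=60.0 / period_s,
    )
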