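"""Breath segmentation, multimodal synchronization and per-breath QC.

Mechanical breaths are segmented from the airway flow signal; the EIT and
airway timebases are aligned on the ventilator pause (apnea) that precedes
the recording — the longest window in which both the flow signal and the
global impedance signal are quiescent.
"""

from __future__ import annotations

import numpy as np

from .eit import global_signal
from .io import AirwaySignals, Breath, EITSequence

__all__ = ["SyncError", "detect_breaths", "detect_apnea_sync", "map_time_to_frame", "qc_breath"]


class SyncError(RuntimeError):
    """No common quiescent (apnea) window could be found; align manually."""


def detect_breaths(
    signals: AirwaySignals,
    min_insp_s: float = 0.2,
    flow_threshold: float = 0.02,
    hysteresis_s: float = 0.05,
) -> list[Breath]:
    """Segment mechanical breaths from the flow signal.

    Inspiration starts at a positive crossing of ``flow_threshold`` and ends
    at the last positive-flow sample before flow stays non-positive for at
    least ``hysteresis_s`` (so brief zero-flow dips inside an inspiration do
    not split a breath).  Expiration ends at the next inspiration start (or
    the record end).  Breaths with an inspiration shorter than ``min_insp_s``
    are discarded; ordinals are assigned in time order.
    """
    flow = signals.flow
    n = len(flow)
    h = max(1, int(round(hysteresis_s * signals.sample_rate)))
    min_len = int(round(min_insp_s * signals.sample_rate))

    nonpos = flow <= 0.0
    # Length of the non-positive run starting at each index.
    run = np.zeros(n + 1, dtype=int)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if nonpos[i] else 0
    sustained = run[:n] >= h

    above = flow > flow_threshold
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate(([0], edges))

    breaths: list[Breath] = []
    raw: list[tuple[int, int]] = []
    last_end = -1
    for e in edges:
        if e <= last_end:
            continue
        j_candidates = np.flatnonzero(sustained[e:])
        if len(j_candidates) == 0:
            insp_end = n - 1 - int(np.argmax((flow[::-1] > 0.0)))
            if insp_end <= e:
                break
            raw.append((int(e), int(insp_end)))
            last_end = n
            break
        j = e + int(j_candidates[0])
        insp_end = j - 1
        if insp_end <= e:
            last_end = j + h
            continue
        raw.append((int(e), int(insp_end)))
        last_end = insp_end

    kept = [(s, ie) for s, ie in raw if ie - s + 1 >= min_len]
    for k, (s, ie) in enumerate(kept):
        exp_end = kept[k + 1][0] - 1 if k + 1 < len(kept) else n - 1
        if exp_end <= ie:
            continue
        breaths.append(Breath(ordinal=k + 1, insp_start=s, insp_end=ie, exp_end=exp_end))
    return breaths


def _longest_run_end(flat: np.ndarray) -> tuple[int, int]:
    """(start, end) indices of the longest True run; (-1, -1) if none."""
    best = (-1, -1)
    best_len = 0
    start = None
    for i, v in enumerate(flat):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_len = i - start
                best = (start, i - 1)
            start = None
    if start is not None and len(flat) - start > best_len:
        best = (start, len(flat) - 1)
    return best


def detect_apnea_sync(
    signals: AirwaySignals,
    eit: EITSequence,
    min_apnea_s: float = 5.0,
    flow_threshold: float = 0.02,
    eit_flat_tol: float = 0.002,
) -> tuple[float, int]:
    """Locate the end of the pre-recording apnea in both timebases.

    Returns ``(t_sync_airway, frame_sync)``: the last quiescent airway sample
    time and the last flat EIT frame of the longest common quiescent window.
    Downstream, airway time ``t`` maps to frame
    ``frame_sync + round((t - t_sync_airway) * frame_rate)``.
    """
    quiet = np.abs(signals.flow) <= flow_threshold
    a0, a1 = _longest_run_end(quiet)
    if a0 < 0 or (a1 - a0 + 1) / signals.sample_rate < min_apnea_s:
        raise SyncError(
            f"no airway quiescent window of at least {min_apnea_s} s found; "
            "align the modalities manually"
        )
    g = global_signal(eit)
    rng = float(g.max() - g.min())
    if rng <= 0:
        raise SyncError("EIT global signal is constant; cannot synchronize")
    flat = np.abs(np.diff(g)) <= eit_flat_tol * rng
    f0, f1 = _longest_run_end(flat)
    if f0 < 0 or (f1 - f0 + 2) / eit.frame_rate < min_apnea_s:
        raise SyncError(
            f"no flat EIT window of at least {min_apnea_s} s found; "
            "align the modalities manually"
        )
    return float(signals.time[a1]), int(f1 + 1)


def map_time_to_frame(t: float, t_sync: float, frame_sync: int, frame_rate: float) -> int:
    return int(frame_sync + round((t - t_sync) * frame_rate))


def qc_breath(
    breath: Breath,
    signals: AirwaySignals,
    vt_insp: float,
    vt_exp: float,
    vt_exp_first: float,
    peep: float = 0.0,
    leak_fraction: float = 0.10,
    spont_paw_drop: float = 2.0,
) -> dict[str, bool]:
    """Apply the leak and spontaneous-effort exclusion rules for one breath.

    A leak is flagged when inspired and expired tidal volumes differ by more
    than ``leak_fraction`` of the first breath's expired volume.  A
    spontaneous effort is flagged when airway pressure dips more than
    ``spont_paw_drop`` cmH2O below PEEP anywhere within the breath.
    """
    flags = dict(breath.flags)
    flags["leak"] = bool(abs(vt_insp - vt_exp) > leak_fraction * vt_exp_first)
    paw = signals.paw[breath.insp_start : breath.exp_end + 1]
    flags["spontaneous_effort"] = bool(paw.min() < peep - spont_paw_drop)
    return flags
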