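"""End-to-end feature extraction: dataset -> per-breath feature tables.

Ties the modality pipelines together for one subject: segment breaths from
flow, synchronize the EIT frames on the apnea, refine the EIT landmarks on
the global impedance curve, apply QC, and compute the EIT, capnography and
mechanics variables per breath.  Output tables use one row per subject and
breath; flagged breaths carry their flags in ``breaths.csv`` and are
excluded from the long-format statistics table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .breaths import detect_apnea_sync, detect_breaths, map_time_to_frame, qc_breath
from .config import AnalysisParams
from .eit import breath_landmarks_eit, compute_breath_features, global_signal
from .io import AirwaySignals, EITSequence, EventLog, read_dataset, write_features
from .mech import compute_breath_mech
from .vcap import compute_breath_vcap

__all__ = ["extract_subject", "long_table", "analyze_directory"]

EIT_COLUMNS = [
    "tiv_au",
    "eeli_au",
    "cov_vd_pct",
    "cov_rl_pct",
    "nss_pct",
    "dss_pct",
    "dz_v_pct",
    "dz_cv_pct",
    "dz_cd_pct",
    "dz_d_pct",
]
VCAP_COLUMNS = [
    "vt_ml",
    "vd_aw_ml",
    "vt_alv_ml",
    "s2_mmhg_per_l",
    "s3_mmhg_per_l",
    "alpha_deg",
    "y_int_mmhg",
    "x_int_ml",
    "vco2_br_ml",
    "pe_co2_mmhg",
    "pa_co2_mmhg",
    "vd_bohr",
    "vd_alv_ml",
]
MECH_COLUMNS = [
    "vt_insp_ml",
    "vt_exp_ml",
    "pip_cmh2o",
    "p_plat_cmh2o",
    "peep_cmh2o",
    "pef_lps",
    "raw_cmh2o_per_lps",
    "cdyn_ml_per_cmh2o",
    "f_r_bpm",
]


def extract_subject(
    subject: str,
    eit: EITSequence,
    airway: AirwaySignals,
    events: EventLog,
    params: AnalysisParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-breath feature tables (breaths, features_eit, features_vcap,
    features_mech) for one subject's synchronized recording."""
    if params is None:
        params = AnalysisParams()
    t_sync, frame_sync = detect_apnea_sync(
        airway,
        eit,
        min_apnea_s=params.min_apnea_s,
        flow_threshold=params.flow_threshold_lps,
        eit_flat_tol=params.eit_flat_tol,
    )
    breaths = detect_breaths(
        airway,
        min_insp_s=params.min_insp_s,
        flow_threshold=params.flow_threshold_lps,
        hysteresis_s=params.hysteresis_s,
    )
    g = global_signal(eit)
    t0_inj = events.injection_start

    breath_rows, eit_rows, vcap_rows, mech_rows = [], [], [], []
    vt_exp_first = None
    for br in breaths:
        t_insp = airway.time[br.insp_start]
        t_exp_end = airway.time[br.exp_end]
        period = (br.exp_end + 1 - br.insp_start) / airway.sample_rate
        # EIT landmarks: map the flow-derived times, then refine on the curve.
        guess = map_time_to_frame(t_insp, t_sync, frame_sync, eit.frame_rate)
        frame_end = map_time_to_frame(t_exp_end, t_sync, frame_sync, eit.frame_rate)
        frame_end = min(frame_end, len(g) - 1)
        fs, fe = breath_landmarks_eit(
            g, guess, frame_end, eit.frame_rate, window_s=params.landmark_window_s
        )
        br.frame_insp_start, br.frame_insp_end = fs, fe
        br.t_mid = float(0.5 * (t_insp + airway.time[br.insp_end]) - t0_inj)

        mech = compute_breath_mech(
            airway,
            br,
            pause_flow_threshold=params.pause_flow_threshold_lps,
            literal=params.literal_mech_formulas,
            period_s=period,
        )
        if vt_exp_first is None:
            vt_exp_first = mech.vt_exp
        br.flags.update(
            qc_breath(
                br,
                airway,
                mech.vt_insp,
                mech.vt_exp,
                vt_exp_first,
                peep=mech.peep if np.isfinite(mech.peep) else 0.0,
                leak_fraction=params.leak_fraction,
                spont_paw_drop=params.spont_paw_drop_cmh2o,
            )
        )

        ef = compute_breath_features(eit, fs, fe, silent_threshold=params.silent_threshold)
        if ef.tiv < 0:
            br.flags["incomplete"] = True

        t_exp_mid = float(0.5 * (airway.time[br.insp_end + 1] + t_exp_end) - t0_inj)
        vcap = compute_breath_vcap(
            airway,
            br,
            grid_ml=params.expirogram_grid_ml,
            min_vt_ml=params.min_vt_ml,
            window=params.phase3_window,
            smooth_ml=params.deriv_smooth_ml,
            s2_cap=params.s2_cap_mmhg_per_l,
            pb_mmhg=params.pb_mmhg,
            ph2o_mmhg=params.ph2o_mmhg,
        )
        if vcap is None:
            br.flags["incomplete"] = True

        t_start = float(t_insp - t0_inj)
        breath_rows.append(
            {
                "subject": subject,
                "breath_ordinal": br.ordinal,
                "t_start_s": t_start,
                "insp_start": br.insp_start,
                "insp_end": br.insp_end,
                "exp_end": br.exp_end,
                "frame_insp_start": fs,
                "frame_insp_end": fe,
                "spontaneous_effort": br.flags.get("spontaneous_effort", False),
                "leak": br.flags.get("leak", False),
                "incomplete": br.flags.get("incomplete", False),
            }
        )
        eit_rows.append(
            {
                "subject": subject,
                "breath_ordinal": br.ordinal,
                "t_mid_s": br.t_mid,
                "tiv_au": ef.tiv,
                "eeli_au": ef.eeli,
                "cov_vd_pct": ef.cov_vd,
                "cov_rl_pct": ef.cov_rl,
                "nss_pct": ef.nss,
                "dss_pct": ef.dss,
                "dz_v_pct": ef.dz_v,
                "dz_cv_pct": ef.dz_cv,
                "dz_cd_pct": ef.dz_cd,
                "dz_d_pct": ef.dz_d,
            }
        )
        row = {"subject": subject, "breath_ordinal": br.ordinal, "t_mid_s": t_exp_mid}
        row.update(vcap if vcap is not None else {c: float("nan") for c in VCAP_COLUMNS})
        vcap_rows.append(row)
        mech_rows.append(
            {
                "subject": subject,
                "breath_ordinal": br.ordinal,
                "t_mid_s": br.t_mid,
                "vt_insp_ml": mech.vt_insp,
                "vt_exp_ml": mech.vt_exp,
                "pip_cmh2o": mech.pip,
                "p_plat_cmh2o": mech.p_plat,
                "peep_cmh2o": mech.peep,
                "pef_lps": mech.pef,
                "raw_cmh2o_per_lps": mech.raw,
                "cdyn_ml_per_cmh2o": mech.cdyn,
                "f_r_bpm": mech.f_r,
            }
        )
    return {
        "breaths": pd.DataFrame(breath_rows),
        "features_eit": pd.DataFrame(eit_rows),
        "features_vcap": pd.DataFrame(vcap_rows),
        "features_mech": pd.DataFrame(mech_rows),
    }


def long_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format (subject, variable, breath_ordinal, t_s, value) table for
    the statistics module.  Flagged breaths are excluded."""
    breaths = tables["breaths"]
    ok = breaths[~(breaths["spontaneous_effort"] | breaths["leak"] | breaths["incomplete"])]
    key = ok[["subject", "breath_ordinal", "t_start_s"]]
    frames = []
    for name, cols in (
        ("features_eit", EIT_COLUMNS),
        ("features_vcap", VCAP_COLUMNS),
        ("features_mech", MECH_COLUMNS),
    ):
        df = tables[name].merge(key, on=["subject", "breath_ordinal"])
        melted = df.melt(
            id_vars=["subject", "breath_ordinal", "t_start_s"],
            value_vars=[c for c in cols if c in df.columns],
            var_name="variable",
            value_name="value",
        )
        frames.append(melted)
    out = pd.concat(frames, ignore_index=True).rename(columns={"t_start_s": "t_s"})
    return out.dropna(subset=["value"])[
        ["subject", "variable", "breath_ordinal", "t_s", "value"]
    ]


def analyze_directory(
    root: str | Path, out_path: str | Path | None = None, params: AnalysisParams | None = None
) -> dict[str, pd.DataFrame]:
    """Extract features for every subject under ``root``; optionally write CSVs."""
    data = read_dataset(root)
    merged: dict[str, list[pd.DataFrame]] = {}
    for subject, (eit, airway, events) in data.items():
        tables = extract_subject(subject, eit, airway, events, params)
        for name, df in tables.items():
            merged.setdefault(name, []).append(df)
    out = {name: pd.concat(dfs, ignore_index=True) for name, dfs in merged.items()}
    if out_path is not None:
        write_features(out, out_path)
    return out
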