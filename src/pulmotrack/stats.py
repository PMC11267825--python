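"""Cohort statistics: per-breath comparison to baseline.

Each variable is averaged over the 60-s pre-injection window to form a
per-subject baseline, expressed as a percentage of that baseline, and each
post-injection breath is compared to the pooled baseline level with a linear
mixed-effects model (random subject intercept, breath as a categorical fixed
effect).  Raw p-values are Bonferroni-adjusted by the number of post-start
breaths in the analysis window, and the first significant breath per
variable is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "FirstChange",
    "baseline_means",
    "normalize",
    "per_breath_tests",
    "first_change",
    "summary_table",
]

REQUIRED_COLUMNS = ("subject", "variable", "breath_ordinal", "t_s", "value")


@dataclass
class ComparisonResult:
    variable: str
    t_s: float
    n_subjects: int
    mean_pct: float
    ci95_lo: float
    ci95_hi: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class FirstChange:
    variable: str
    first_t_s: float | None
    first_breath_ordinal: int | None  # breaths after the start of injection
    direction: str | None  # "increase" or "decrease"


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"breath table is missing columns {missing}")


def baseline_means(
    table: pd.DataFrame,
    baseline_window: tuple[float, float] = (-60.0, 0.0),
    min_breaths: int = 3,
) -> pd.DataFrame:
    """Per-subject, per-variable arithmetic mean over the baseline window.

    Subjects with fewer than ``min_breaths`` unflagged baseline breaths for a
    variable are dropped for that variable (logged).
    """
    _check_table(table)
    lo, hi = baseline_window
    base = table[(table["t_s"] >= lo) & (table["t_s"] < hi)]
    g = base.groupby(["subject", "variable"])["value"].agg(["mean", "count"]).reset_index()
    low = g[g["count"] < min_breaths]
    for _, row in low.iterrows():
        logger.warning(
            "subject %s dropped for %s: only %d baseline breaths",
            row["subject"],
            row["variable"],
            row["count"],
        )
    g = g[g["count"] >= min_breaths]
    return g.rename(columns={"mean": "baseline", "count": "n_baseline"})


def normalize(table: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Add ``value_pct_baseline`` = 100 * value / subject baseline.

    Records whose subject baseline is zero (or missing) are dropped, logged.
    """
    _check_table(table)
    merged = table.merge(baselines[["subject", "variable", "baseline"]], on=["subject", "variable"])
    zero = merged["baseline"] == 0
    if zero.any():
        logger.warning("dropping %d records with zero baseline", int(zero.sum()))
        merged = merged[~zero]
    merged = merged.copy()
    merged["value_pct_baseline"] = 100.0 * merged["value"] / merged["baseline"]
    return merged


def _sample_summary(values: np.ndarray) -> tuple[float, float, float]:
    n = len(values)
    m = float(values.mean())
    if n < 2:
        return m, m, m
    half = float(sps.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half


def _mixed_model_pvalues(
    sub: pd.DataFrame, levels: list[str]
) -> dict[str, float] | None:
    """Wald p-values (t reference, df = subjects - 1) for each post level
    against the pooled baseline, from a random-intercept mixed model."""
    import statsmodels.formula.api as smf

    n_subjects = sub["subject"].nunique()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value_pct_baseline ~ C(level, Treatment('baseline'))",
                sub,
                groups=sub["subject"],
            )
            fit = model.fit(reml=True)
    except Exception:  # singular / non-converging fit
        return None
    out = {}
    for lv in levels:
        name = f"C(level, Treatment('baseline'))[T.{lv}]"
        if name not in fit.params.index:
            return None
        coef, se = fit.params[name], fit.bse[name]
        if not np.isfinite(se) or se <= 0:
            return None
        tstat = coef / se
        out[lv] = float(2.0 * sps.t.sf(abs(tstat), df=max(1, n_subjects - 1)))
    return out


def _paired_pvalues(sub: pd.DataFrame, levels: list[str]) -> dict[str, float]:
    """Fallback: per-breath one-sample t of percent-of-baseline against 100."""
    out = {}
    for lv in levels:
        d = sub.loc[sub["level"] == lv, "value_pct_baseline"].to_numpy() - 100.0
        if len(d) < 2 or np.allclose(d, d[0]):
            out[lv] = float("nan")
            continue
        out[lv] = float(sps.ttest_1samp(d, 0.0).pvalue)
    return out


def per_breath_tests(
    table: pd.DataFrame,
    alpha: float = 0.05,
    window: tuple[float, float] = (0.0, 120.0),
    baseline_window: tuple[float, float] = (-60.0, 0.0),
) -> pd.DataFrame:
    """Compare each post-start breath to baseline, per variable.

    ``table`` must be normalized (have ``value_pct_baseline``).  Returns one
    row per variable and post-start breath with the cohort mean percent of
    baseline, its 95 % CI, raw and Bonferroni-adjusted p-values
    (``p_adj = min(1, m * p_raw)`` with ``m`` the number of post-start
    breaths in the window) and the significance verdict ``p_adj < alpha``.
    """
    _check_table(table)
    if "value_pct_baseline" not in table.columns:
        raise ValueError("table must be normalized first (value_pct_baseline missing)")
    if table["subject"].nunique() < 2:
        raise ValueError("at least two subjects are required")
    blo, bhi = baseline_window
    wlo, whi = window
    rows: list[ComparisonResult] = []
    for var, sub in table.groupby("variable"):
        sub = sub.copy()
        is_base = (sub["t_s"] >= blo) & (sub["t_s"] < bhi)
        is_post = (sub["t_s"] >= wlo) & (sub["t_s"] <= whi) & (sub["t_s"] >= 0)
        sub = sub[is_base | is_post].copy()
        sub["level"] = np.where(
            sub["t_s"] < bhi,
            "baseline",
            "b" + sub["breath_ordinal"].astype(int).astype(str).str.zfill(3),
        )
        post = sub[sub["level"] != "baseline"]
        level_info = (
            post.groupby("level")
            .agg(t_s=("t_s", "first"), ordinal=("breath_ordinal", "first"))
            .sort_values("t_s")
        )
        levels = list(level_info.index)
        m = len(levels)
        if m == 0:
            continue
        pvals = _mixed_model_pvalues(sub, levels)
        if pvals is None:
            logger.warning(
                "mixed model failed for %s; falling back to paired t-tests", var
            )
            pvals = _paired_pvalues(sub, levels)
        for lv in levels:
            vals = post.loc[post["level"] == lv, "value_pct_baseline"].to_numpy()
            mean_pct, lo, hi = _sample_summary(vals)
            p_raw = pvals[lv]
            p_adj = min(1.0, m * p_raw) if np.isfinite(p_raw) else float("nan")
            rows.append(
                ComparisonResult(
                    variable=var,
                    t_s=float(level_info.loc[lv, "t_s"]),
                    n_subjects=len(vals),
                    mean_pct=mean_pct,
                    ci95_lo=lo,
                    ci95_hi=hi,
                    p_raw=p_raw,
                    p_adj=p_adj,
                    significant=bool(np.isfinite(p_adj) and p_adj < alpha),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def _breath_spacing(results: pd.DataFrame) -> float:
    ts = np.sort(results["t_s"].unique())
    if len(ts) < 2:
        return float("nan")
    return float(np.median(np.diff(ts)))


def first_change(results: pd.DataFrame, require_persistence: bool = False) -> pd.DataFrame:
    """Earliest significant breath per variable.

    With ``require_persistence`` the change must hold for two consecutive
    breaths.  The breath ordinal is counted from the start of injection
    (breath k at t = k * period).
    """
    period = _breath_spacing(results)
    out: list[FirstChange] = []
    for var, sub in results.groupby("variable"):
        sub = sub.sort_values("t_s").reset_index(drop=True)
        sig = sub["significant"].to_numpy()
        if require_persistence:
            sig = sig & np.concatenate([sig[1:], [False]])
        idx = np.flatnonzero(sig)
        if len(idx) == 0:
            out.append(FirstChange(var, None, None, None))
            continue
        row = sub.iloc[idx[0]]
        ordinal = int(round(row["t_s"] / period)) if np.isfinite(period) else None
        direction = "increase" if row["mean_pct"] >= 100.0 else "decrease"
        out.append(FirstChange(var, float(row["t_s"]), ordinal, direction))
    return pd.DataFrame([f.__dict__ for f in out])


def summary_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-breath mean [95 % CI] table, one row per time, one column per
    variable; significant cells are starred."""
    def cell(row: pd.Series) -> str:
        star = "*" if row["significant"] else ""
        return f"{row['mean_pct']:.1f} [{row['ci95_lo']:.1f}-{row['ci95_hi']:.1f}]{star}"

    df = results.copy()
    df["cell"] = df.apply(cell, axis=1)
    return df.pivot(index="t_s", columns="variable", values="cell").sort_index()
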