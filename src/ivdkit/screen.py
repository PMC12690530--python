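"""Differential cytokine screening, fold-change analysis, and GTT phenotyping.

Panels are wide DataFrames (``animal_id, group, replicate`` then one column
per cytokine, concentrations in pg/ml).  Out-of-range (OOR) multiplex
readings are NaN in memory and the literal token ``OOR`` on disk; they are
excluded from every median, mean and variance and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import META_COLS

__all__ = [
    "WelchResult",
    "GttResult",
    "cytokine_columns",
    "collapse_pseudoreplicates",
    "filter_missingness",
    "welch_test",
    "differential_screen",
    "fold_change_analysis",
    "compare_fold_changes",
    "gtt_auc",
]


def cytokine_columns(panel: pd.DataFrame) -> list[str]:
    """Cytokine (non-metadata) columns of a wide panel."""
    return [c for c in panel.columns if c not in META_COLS]


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test between two samples."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


@dataclass(frozen=True)
class GttResult:
    """Glucose-tolerance-test area under the curve and diabetic call."""

    auc: float  # mg·h/dl
    cutoff: float
    diabetic: bool


def collapse_pseudoreplicates(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical pseudo-replicates to one row per animal.

    Each entry becomes the median of that animal's detected replicate
    values; an entry stays flagged (NaN) only when every replicate was
    flagged.  Idempotent: collapsing a collapsed panel is the identity.
    """
    if panel.empty:
        raise ValueError("empty panel")
    cyts = cytokine_columns(panel)
    grouped = panel.groupby("animal_id", sort=False)
    out = grouped[cyts].median()  # skips NaN; all-NaN -> NaN
    out.insert(0, "group", grouped["group"].first())
    out = out.reset_index()
    out.insert(2, "replicate", 1)
    return out[META_COLS + cyts]


def filter_missingness(
    panel: pd.DataFrame, max_fraction: float = 0.25
) -> tuple[pd.DataFrame, list[str]]:
    """Drop cytokines whose missingness exceeds ``max_fraction``.

    The fraction is flagged animals over all animals pooled across groups;
    exclusion is strict (a cytokine at exactly the threshold is retained).
    Returns the filtered panel and the excluded cytokine names.
    """
    if panel.empty:
        raise ValueError("empty panel")
    cyts = cytokine_columns(panel)
    frac = panel[cyts].isna().mean()
    excluded = [c for c in cyts if frac[c] > max_fraction]
    return panel.drop(columns=excluded), excluded


def welch_test(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch's two-sided t-test on two detected-value vectors.

    t = (mean_a - mean_b) / sqrt(s²_a/n_a + s²_b/n_b), with the
    Welch–Satterthwaite degrees of freedom and a two-sided p-value from
    Student's t distribution.  Requires >= 2 values per sample.  When both
    samples have zero variance the statistic is degenerate: p = 1 if the
    means agree, else p = 0 with the result flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 detected values")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        if ma == mb:
            return WelchResult(0.0, float(min(na, nb) - 1), 1.0, ma, mb, True)
        return WelchResult(np.inf if ma > mb else -np.inf,
                           float(min(na, nb) - 1), 0.0, ma, mb, True)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(ma), float(mb))


def differential_screen(
    panel: pd.DataFrame,
    case_group: str,
    control_group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cytokine Welch screen of a case group against its control.

    A cytokine is called upregulated when the two-sided Welch p-value is
    below ``alpha`` AND the case mean exceeds the control mean (one
    direction only; no multiple-testing correction, matching the screening
    convention of small-panel multiplex studies).  Returns a tidy table
    ``cytokine, mean_case, mean_control, t, df, p, upregulated`` sorted by
    p-value.
    """
    for g in (case_group, control_group):
        if g not in set(panel["group"]):
            raise ValueError(f"unknown group label {g!r}")
    cyts = cytokine_columns(panel)
    case = panel[panel["group"] == case_group]
    control = panel[panel["group"] == control_group]
    rows = []
    for cyt in cyts:
        a = case[cyt].to_numpy(dtype=float)
        b = control[cyt].to_numpy(dtype=float)
        if np.sum(~np.isnan(a)) < 2 or np.sum(~np.isnan(b)) < 2:
            continue  # not testable after OOR removal
        res = welch_test(a, b)
        rows.append(
            {
                "cytokine": cyt,
                "mean_case": res.mean_a,
                "mean_control": res.mean_b,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "upregulated": bool(res.p < alpha and res.mean_a > res.mean_b),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cytokine", "mean_case", "mean_control", "t", "df", "p",
                 "upregulated"],
    )
    return table.sort_values(["p", "cytokine"], kind="mergesort").reset_index(
        drop=True
    )


def fold_change_analysis(
    panel: pd.DataFrame,
    model_case: str,
    model_control: str,
    cytokines: list[str] | None = None,
) -> pd.DataFrame:
    """Per-animal fold change of case values over the control-group mean.

    For every case animal and cytokine, FC = value / mean of the control
    group's detected values for that cytokine.  ``cytokines`` restricts the
    table (typically to the upregulated set from :func:`differential_screen`);
    default is every cytokine in the panel.  Returns a long table
    ``model, animal_id, cytokine, fc``.
    """
    cyts = cytokines if cytokines is not None else cytokine_columns(panel)
    missing = set(cyts) - set(panel.columns)
    if missing:
        raise ValueError(f"cytokines absent from panel: {sorted(missing)}")
    case = panel[panel["group"] == model_case]
    control = panel[panel["group"] == model_control]
    if case.empty or control.empty:
        raise ValueError("case or control group absent from panel")
    rows = []
    for cyt in cyts:
        ctrl_mean = control[cyt].mean()  # detected values only
        if not np.isfinite(ctrl_mean) or ctrl_mean <= 0:
            raise ValueError(f"control mean undefined or non-positive for {cyt!r}")
        for _, r in case.iterrows():
            if pd.isna(r[cyt]):
                continue
            rows.append(
                {
                    "model": model_case,
                    "animal_id": r["animal_id"],
                    "cytokine": cyt,
                    "fc": float(r[cyt] / ctrl_mean),
                }
            )
    return pd.DataFrame(rows, columns=["model", "animal_id", "cytokine", "fc"])


def compare_fold_changes(
    fc_model1: pd.DataFrame, fc_model2: pd.DataFrame
) -> pd.DataFrame:
    """Welch-compare per-cytokine fold changes between two models.

    Both tables must be long fold-change tables from
    :func:`fold_change_analysis` and must share every compared cytokine — a
    cytokine absent from either is an error, not a silent NA.  Returns
    ``cytokine, mean_fc_1, mean_fc_2, t, df, p, higher`` where ``higher``
    names the model with the larger mean fold change.
    """
    set1 = set(fc_model1["cytokine"])
    set2 = set(fc_model2["cytokine"])
    if set1 != set2:
        raise ValueError(
            f"cytokine sets differ: only in first {sorted(set1 - set2)}, "
            f"only in second {sorted(set2 - set1)}"
        )
    name1 = fc_model1["model"].iloc[0] if len(fc_model1) else "model1"
    name2 = fc_model2["model"].iloc[0] if len(fc_model2) else "model2"
    rows = []
    for cyt in sorted(set1):
        fc1 = fc_model1.loc[fc_model1["cytokine"] == cyt, "fc"].to_numpy()
        fc2 = fc_model2.loc[fc_model2["cytokine"] == cyt, "fc"].to_numpy()
        res = welch_test(fc1, fc2)
        rows.append(
            {
                "cytokine": cyt,
                "mean_fc_1": res.mean_a,
                "mean_fc_2": res.mean_b,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "higher": name1 if res.mean_a >= res.mean_b else name2,
            }
        )
    return pd.DataFrame(rows)


def gtt_auc(series: pd.DataFrame, cutoff: float = 435.0) -> GttResult:
    """Trapezoidal AUC of a glucose tolerance test, in mg·h/dl.

    ``series`` needs ``time_h`` (strictly increasing, hours) and
    ``glucose_mg_dl`` columns.  The diabetic call is strict: AUC must
    exceed the cutoff (default 435 mg·h/dl).
    """
    t = series["time_h"].to_numpy(dtype=float)
    g = series["glucose_mg_dl"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(g < 0):
        raise ValueError("negative glucose")
    auc = float(np.trapezoid(g, t))
    return GttResult(auc=auc, cutoff=cutoff, diabetic=bool(auc > cutoff))
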