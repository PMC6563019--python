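"""Volcano statistics, top-feature selection, and heat-map ratio matrices.

Per-feature differential statistics between a case and a control group:
the mean fold change (case mean / control mean) and a two-sample t-test
p-value (Welch by default).  A feature is flagged significant when
p < 0.05 **and** the fold change is < 0.7 or > 1.5.  A
Benjamini-Hochberg FDR column is emitted for information but does not
gate significance.

The heat-map matrix expresses every sample's level of a selected feature
as a ratio to the control-group mean of that feature, binned on a
log10-uniform color scale running from < 0.1 (brightest green) to > 10
(brightest red).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

#: inner bin edges of the heat-map color scale: 9 log10-uniform bins over
#: [0.1, 10] plus the two overflow bins (11 bins total, index 5 = ratio 1)
HEATMAP_EDGES = np.logspace(-1.0, 1.0, 10)


def volcano(table: FeatureTable | pd.DataFrame, labels: pd.Series,
            case: str, control: str, alpha: float = 0.05,
            fold_lo: float = 0.7, fold_hi: float = 1.5,
            equal_var: bool = False) -> pd.DataFrame:
    """Per-feature fold change and t-test p-value between two groups.

    Parameters
    ----------
    table : FeatureTable or DataFrame (features x samples)
    labels : Series mapping sample id -> group label
    case, control : the two labels to compare (fold = case / control)
    equal_var : False (default) for Welch's unequal-variance t-test,
        True for Student's.

    Returns one row per feature: ``mean_fold``, ``log2fc``, ``p_value``,
    ``minus_log10_p``, ``significant``, ``bh_fdr`` and a ``flagged`` column
    marking undefined folds (zero/absent control mean).
    """
    areas = table.areas if isinstance(table, FeatureTable) else table
    labels = pd.Series(labels)
    case_cols = [c for c in labels.index[labels == case] if c in areas.columns]
    ctrl_cols = [c for c in labels.index[labels == control] if c in areas.columns]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    A = areas[case_cols].to_numpy(dtype=float)
    B = areas[ctrl_cols].to_numpy(dtype=float)
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance identical groups: no evidence of difference
    same = np.isnan(p) & np.isclose(mean_a, mean_b)
    p[same] = 1.0

    flagged = ~np.isfinite(mean_b) | (mean_b == 0) | ~np.isfinite(mean_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(flagged, np.nan, np.divide(mean_a, np.where(mean_b == 0, np.nan, mean_b)))
        log2fc = np.log2(fold)

    ok = np.isfinite(p)
    bh = np.full(len(p), np.nan)
    if ok.any():
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]

    significant = (p < alpha) & ((fold < fold_lo) | (fold > fold_hi))
    significant = np.where(flagged | ~np.isfinite(p), False, significant)

    return pd.DataFrame(
        {
            "mean_fold": fold,
            "log2fc": log2fc,
            "p_value": p,
            "minus_log10_p": -np.log10(p),
            "significant": significant.astype(bool),
            "bh_fdr": bh,
            "flagged": flagged,
        },
        index=areas.index.rename("feature_id"),
    )


def select_top(volcano_rows: pd.DataFrame, n: int = 300) -> list[str]:
    """The ``n`` features with the smallest p-values.

    Ties are broken by larger |log2 fold change|, then by feature id.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(volcano_rows):
        raise ValueError(f"n={n} exceeds the {len(volcano_rows)} available rows")
    df = volcano_rows.copy()
    df["_abs_lfc"] = df["log2fc"].abs().fillna(0.0)
    df["_p"] = df["p_value"].fillna(np.inf)
    df = df.sort_values(["_p", "_abs_lfc"], ascending=[True, False], kind="mergesort")
    # mergesort is stable, so equal (p, |lfc|) pairs stay in index order;
    # enforce id order explicitly for full determinism
    df = df.reset_index().sort_values(["_p", "_abs_lfc", "feature_id"],
                                      ascending=[True, False, True], kind="mergesort")
    return df["feature_id"].head(n).tolist()


@dataclass
class HeatmapMatrix:
    """Ratio-to-control-mean matrix of selected features.

    ``ratios``: features (rows, given order) x samples (control group first,
    then cases, each sorted by id); ``bins``: integer color-bin index per
    cell, 0 = below 0.1 ... 10 = above 10 (bin 5 contains ratio 1);
    ``dropped``: features excluded for an undefined control mean.
    """

    ratios: pd.DataFrame
    bins: pd.DataFrame
    edges: np.ndarray
    dropped: list[str]

    def to_csv(self, path_ratios, path_bins=None) -> None:
        self.ratios.to_csv(path_ratios)
        if path_bins is not None:
            self.bins.to_csv(path_bins)


def heatmap_matrix(table: FeatureTable | pd.DataFrame, feature_ids,
                   control_ids, case_ids) -> HeatmapMatrix:
    """Build the ratio/bin matrices for ``feature_ids`` (row order kept)."""
    areas = table.areas if isinstance(table, FeatureTable) else table
    control_ids = [c for c in control_ids if c in areas.columns]
    case_ids = [c for c in case_ids if c in areas.columns]
    if not control_ids:
        raise ValueError("control group is empty")
    missing = [f for f in feature_ids if f not in areas.index]
    if missing:
        raise ValueError(f"features not in table: {missing[:5]}")

    sub = areas.loc[feature_ids, sorted(control_ids) + sorted(case_ids)]
    ctrl_mean = sub[sorted(control_ids)].mean(axis=1, skipna=True)
    bad = ~np.isfinite(ctrl_mean) | (ctrl_mean == 0)
    dropped = sub.index[bad].tolist()
    sub = sub.loc[~bad]
    ratios = sub.div(ctrl_mean[~bad], axis=0)
    if ratios.empty:
        bins = ratios.astype(int)
    else:
        bins = ratios.apply(lambda col: np.digitize(col, HEATMAP_EDGES))
        bins = bins.where(ratios.notna(), other=-1).astype(int)
    return HeatmapMatrix(ratios=ratios, bins=bins, edges=HEATMAP_EDGES.copy(),
                         dropped=dropped)
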