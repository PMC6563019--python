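"""QC-ratio normalization and assay coefficient-of-variation reporting.

Pooled-serum QC injections interleaved with the study sequence serve two
purposes: their replicate peak areas quantify assay precision (intra- and
inter-assay CV per feature), and their per-feature mean is the
normalization denominator — every study area is expressed as a ratio to
the mean QC area of that feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


def compute_cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sample sd).

    Returns NaN (undefined) when the mean is zero or fewer than two values
    are supplied.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class CvReport:
    """Per-feature assay precision.

    ``table`` columns: ``intra_cv`` (mean over batches of the within-batch
    CV, worst pool), ``inter_cv`` (CV across all of a pool's QC injections,
    worst pool) plus the per-pool inter-assay columns.  CVs are percentages;
    NaN flags an undefined CV (zero or absent QC mean).
    """

    table: pd.DataFrame

    def cv_for(self, feature_ids, column: str = "inter_cv") -> pd.Series:
        return self.table.loc[feature_ids, column]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def qc_cv_report(table: FeatureTable, manifest: pd.DataFrame) -> CvReport:
    """Intra-/inter-assay CVs from the QC injections in ``table``.

    QC injections may come from more than one pool (e.g. a cancer pool and
    a benign pool); the reported ``intra_cv``/``inter_cv`` take the maximum
    over pools — the conservative reading when a feature must be precise in
    every pool.  The manifest's ``batch`` column defines the intra-assay
    grouping; with a single batch the two coincide.
    """
    qc = manifest[manifest.run_type == "qc"]
    if qc.empty:
        raise ValueError("no QC samples in manifest")
    pools = qc["qc_pool"].unique() if "qc_pool" in qc else np.array([""])

    out = pd.DataFrame(index=table.feature_ids)
    inter_cols, intra_cols = [], []
    for pool in pools:
        sel = qc if pool == "" else qc[qc.qc_pool == pool]
        cols = [c for c in sel.sample_id if c in table.sample_ids]
        if len(cols) < 2:
            continue
        vals = table.areas[cols]
        name = f"inter_cv_{pool or 'qc'}"
        out[name] = vals.apply(compute_cv, axis=1)
        inter_cols.append(name)
        if "batch" in sel.columns:
            batch_cvs = []
            for _, grp in sel.groupby("batch"):
                bcols = [c for c in grp.sample_id if c in table.sample_ids]
                if len(bcols) >= 2:
                    batch_cvs.append(table.areas[bcols].apply(compute_cv, axis=1))
            if batch_cvs:
                iname = f"intra_cv_{pool or 'qc'}"
                out[iname] = pd.concat(batch_cvs, axis=1).mean(axis=1)
                intra_cols.append(iname)
    if not inter_cols:
        raise ValueError("need at least 2 QC injections in some pool to compute CVs")
    out["inter_cv"] = out[inter_cols].max(axis=1)
    out["intra_cv"] = out[intra_cols].max(axis=1) if intra_cols else out["inter_cv"]
    return CvReport(out)


def normalize_to_qc(table: FeatureTable, manifest: pd.DataFrame,
                    scope: str = "all") -> tuple[FeatureTable, list[str]]:
    """Express every area as its ratio to the feature's mean QC area.

    QC columns are retained with their own ratios (their per-feature mean
    is 1 by construction).  Features whose QC mean is zero or undefined are
    not divided; they are returned as the second element for explicit
    removal by the caller.

    ``scope='all'`` uses every QC injection as the denominator;
    ``scope='batch'`` uses batch-local QC means for the study samples of
    each batch.
    """
    qc = manifest[manifest.run_type == "qc"]
    qc_cols = [c for c in qc.sample_id if c in table.sample_ids]
    if not qc_cols:
        raise ValueError("no QC samples present in the feature table")

    areas = table.areas.copy()
    if scope == "all":
        denom = areas[qc_cols].mean(axis=1, skipna=True)
        bad = denom.isna() | (denom == 0)
        good = ~bad
        areas.loc[good] = areas.loc[good].div(denom[good], axis=0)
    elif scope == "batch":
        denom_all = areas[qc_cols].mean(axis=1, skipna=True)
        bad = denom_all.isna() | (denom_all == 0)
        good = ~bad
        lookup = manifest.set_index("sample_id")
        new = areas.copy()
        for batch, grp in manifest.groupby("batch"):
            bqc = [c for c in grp.loc[grp.run_type == "qc", "sample_id"] if c in areas.columns]
            denom = areas[bqc].mean(axis=1, skipna=True) if bqc else denom_all
            denom = denom.where(denom.notna() & (denom != 0), denom_all)
            bcols = [c for c in grp.sample_id if c in areas.columns]
            new.loc[good, bcols] = areas.loc[good, bcols].div(denom[good], axis=0)
        areas = new
    else:
        raise ValueError(f"unknown scope {scope!r}")

    flagged = table.feature_ids[bad].tolist()
    out = FeatureTable(areas, table.features.copy())
    out.features["qc_undefined"] = bad
    return out, flagged
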