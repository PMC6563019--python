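"""Four-stage feature selection cascade with full per-stage accounting.

Untargeted serum glycopeptide tables start with tens of thousands of
detected features, most of which are background, imprecise, faint, or
redundant satellite ions.  The cascade removes, in order:

1. **blank** — features not sufficiently above the blank-injection level
   (study mean below ``min_ratio`` times the blank mean);
2. **cv** — features whose QC coefficient of variation exceeds ``max_cv``
   percent (strictly "more than");
3. **sn** — features whose representative signal-to-noise ratio is below
   ``min_sn`` (strictly "less than");
4. **satellite** — isotopologues, adducts and in-source fragments of a
   more intense co-eluting feature.

Every removal is recorded with its stage and reason; the
:class:`FilterReport` enforces the accounting identity (stage outputs chain
and removals plus survivors sum to the input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, blank_ids, qc_ids, study_ids
from .qcnorm import CvReport
from .simdata import ADDUCT_DELTAS, ISOTOPE_SPACING


@dataclass(frozen=True)
class FilterParams:
    """Tunables of the cascade (defaults follow common untargeted practice
    where the wider protocol leaves them open)."""

    blank_min_ratio: float = 5.0     # study mean must exceed ratio x blank mean
    max_cv: float = 50.0             # percent, strict >
    min_sn: float = 100.0            # strict <
    cv_column: str = "inter_cv"
    sat_rt_tol: float = 0.1          # min, co-elution window for satellites
    iso_mz_tol: float = 0.01         # Da
    charges: tuple[int, ...] = (1, 2)
    adduct_deltas: tuple[float, ...] = tuple(ADDUCT_DELTAS.values())
    fragment_corr: float = 0.95      # Pearson r with a heavier, more intense feature
    skip_blank: bool = False


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    stages: list[StageRecord] = field(default_factory=list)
    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["feature_id", "stage", "reason"]))
    final_ids: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, removed_ids: list[str], reasons=None) -> None:
        n_rm = len(removed_ids)
        self.stages.append(StageRecord(name, n_in, n_rm, n_in - n_rm))
        if removed_ids:
            if reasons is None:
                reasons = [name] * n_rm
            add = pd.DataFrame({"feature_id": removed_ids, "stage": name, "reason": reasons})
            self.removed = pd.concat([self.removed, add], ignore_index=True)

    def validate(self) -> None:
        """Accounting identity: stage outputs chain, removals + final = initial."""
        for a, b in zip(self.stages, self.stages[1:]):
            if a.n_out != b.n_in:
                raise AssertionError(f"stage chaining broken: {a.name}.n_out={a.n_out} != {b.name}.n_in={b.n_in}")
        if self.stages:
            total_removed = sum(s.n_removed for s in self.stages)
            if self.stages[0].n_in != total_removed + len(self.final_ids):
                raise AssertionError("removals + survivors != initial feature count")

    @property
    def counts(self) -> list[int]:
        """[n_in stage 1, n_out stage 1, n_out stage 2, ...]"""
        if not self.stages:
            return []
        return [self.stages[0].n_in] + [s.n_out for s in self.stages]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(s.name, s.n_in, s.n_removed, s.n_out) for s in self.stages],
                            columns=["stage", "n_in", "n_removed", "n_out"])

    def to_json(self, path=None):
        obj = {
            "stages": [vars(s) for s in self.stages],
            "final_ids": list(self.final_ids),
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stages


def _group_means(table: FeatureTable, cols: list[str]) -> pd.Series:
    """Per-feature mean over ``cols`` with missing (undetected) cells as 0."""
    if not cols:
        return pd.Series(0.0, index=table.feature_ids)
    return table.areas[cols].fillna(0.0).mean(axis=1)


def filter_blank(table: FeatureTable, manifest: pd.DataFrame,
                 min_ratio: float = 5.0) -> tuple[FeatureTable, list[str]]:
    """Remove features whose study mean is below ``min_ratio`` times the
    blank mean (background not sufficiently above the blank level)."""
    blanks = [c for c in blank_ids(manifest) if c in table.sample_ids]
    if not blanks:
        raise ValueError(
            "no blank runs present; pass skip_blank=True to run the cascade without this stage"
        )
    study = [c for c in study_ids(manifest) if c in table.sample_ids]
    study_mean = _group_means(table, study)
    blank_mean = _group_means(table, blanks)
    removed = table.feature_ids[(blank_mean > 0) & (study_mean < min_ratio * blank_mean)].tolist()
    return table.drop(removed), removed


def filter_cv(table: FeatureTable, cv_report: CvReport, max_cv: float = 50.0,
              cv_column: str = "inter_cv") -> tuple[FeatureTable, list[str]]:
    """Remove features with QC CV strictly above ``max_cv`` percent.
    Undefined CVs are removed (conservative)."""
    missing = table.feature_ids.difference(cv_report.table.index)
    if len(missing):
        raise ValueError(f"cv_report does not cover {len(missing)} features")
    cv = cv_report.cv_for(table.feature_ids, cv_column)
    removed = table.feature_ids[(cv > max_cv) | cv.isna()].tolist()
    return table.drop(removed), removed


def filter_sn(table: FeatureTable, min_sn: float = 100.0,
              sn: pd.Series | None = None) -> tuple[FeatureTable, list[str]]:
    """Remove features with representative S/N strictly below ``min_sn``.
    A zero/undefined noise estimate yields S/N = inf and is retained."""
    if sn is None:
        sn = table.features["sn"]
    sn = sn.reindex(table.feature_ids).astype(float)
    sn = sn.fillna(np.inf)
    removed = table.feature_ids[sn < min_sn].tolist()
    return table.drop(removed), removed


def filter_satellites(table: FeatureTable, manifest: pd.DataFrame | None = None,
                      params: FilterParams = FilterParams()
                      ) -> tuple[FeatureTable, list[str], list[str]]:
    """Remove isotopologue, adduct and in-source fragment features.

    A feature is removed as an **isotope** when a more intense feature sits
    at its m/z minus 1.0033/z (z in ``params.charges``) within
    ``iso_mz_tol`` and co-elutes within ``sat_rt_tol``; as an **adduct**
    when a more intense co-eluting feature sits one configured adduct mass
    below it; as an **in-source fragment** when a co-eluting feature with
    both higher m/z and higher intensity tracks it across samples with
    Pearson r >= ``fragment_corr``.

    Returns (table, removed_ids, reasons).
    """
    rt = table.features["rt"].to_numpy(dtype=float)
    mz = table.features["mz"].to_numpy(dtype=float)
    if manifest is not None:
        cols = [c for c in study_ids(manifest) + qc_ids(manifest) if c in table.sample_ids]
    else:
        cols = list(table.sample_ids)
    vals = table.areas[cols]
    intensity = vals.median(axis=1, skipna=True).fillna(0.0).to_numpy()
    X = vals.to_numpy(dtype=float)

    n = len(table)
    removed: list[str] = []
    reasons: list[str] = []
    order = np.argsort(mz, kind="mergesort")
    mz_sorted = mz[order]

    def candidates(target_mz, tol):
        lo = np.searchsorted(mz_sorted, target_mz - tol)
        hi = np.searchsorted(mz_sorted, target_mz + tol)
        return order[lo:hi]

    for i in range(n):
        reason = None
        # isotope: parent one isotope spacing below
        for z in params.charges:
            for j in candidates(mz[i] - ISOTOPE_SPACING / z, params.iso_mz_tol):
                if j != i and abs(rt[j] - rt[i]) <= params.sat_rt_tol and intensity[j] > intensity[i]:
                    reason = "isotope"
                    break
            if reason:
                break
        if reason is None:
            for delta in params.adduct_deltas:
                for j in candidates(mz[i] - delta, params.iso_mz_tol):
                    if j != i and abs(rt[j] - rt[i]) <= params.sat_rt_tol and intensity[j] > intensity[i]:
                        reason = "adduct"
                        break
                if reason:
                    break
        if reason is None:
            # fragment: heavier, more intense, co-eluting, correlated profile
            co = np.where((np.abs(rt - rt[i]) <= params.sat_rt_tol)
                          & (mz > mz[i]) & (intensity > intensity[i]))[0]
            xi = X[i]
            for j in co:
                r = _pearson(xi, X[j])
                if r >= params.fragment_corr:
                    reason = "fragment"
                    break
        if reason is not None:
            removed.append(table.feature_ids[i])
            reasons.append(reason)

    return table.drop(removed), removed, reasons


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return 0.0
    a, b = a[mask], b[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


# ---------------------------------------------------------------------------
# cascade


def run_cascade(table: FeatureTable, manifest: pd.DataFrame, cv_report: CvReport,
                params: FilterParams = FilterParams()
                ) -> tuple[FeatureTable, FilterReport]:
    """Apply blank -> CV -> S/N -> satellite in order with accounting."""
    report = FilterReport()

    if params.skip_blank:
        report.add_stage("blank", len(table), [])
    else:
        n_in = len(table)
        table, rm = filter_blank(table, manifest, params.blank_min_ratio)
        report.add_stage("blank", n_in, rm)

    n_in = len(table)
    table, rm = filter_cv(table, cv_report, params.max_cv, params.cv_column)
    report.add_stage("cv", n_in, rm)

    n_in = len(table)
    table, rm = filter_sn(table, params.min_sn)
    report.add_stage("sn", n_in, rm)

    n_in = len(table)
    table, rm, reasons = filter_satellites(table, manifest, params)
    report.add_stage("satellite", n_in, rm, reasons)

    report.final_ids = list(table.feature_ids)
    report.validate()
    return table, report
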