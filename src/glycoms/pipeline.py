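"""End-to-end orchestration: simulate/load -> peaks -> align -> normalize ->
filter -> discriminant model -> differential statistics.

A single :class:`PipelineConfig` holds every tunable; :func:`run_pipeline`
executes the stages in order, writes every artifact (peak CSVs, feature
table, CV report, filter report, model JSON, scores, volcano and heat-map
tables) plus a run manifest recording the resolved config, its hash, the
master seed, stage timings and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable, class_labels, study_ids
from .diffstats import heatmap_matrix, select_top, volcano
from .featfilter import FilterParams, run_cascade
from .multivariate import (OPLSDA, PCA, hotelling_ellipse, make_split)
from .peakproc import (AlignmentParams, align_runs, apply_drift, fit_drift,
                       frame_to_peaks, peaks_to_frame, pick_run_peaks)
from .qcnorm import normalize_to_qc, qc_cv_report
from .simdata import CohortConfig, generate_cohort, internal_standard_references


@dataclass(frozen=True)
class PeakParams:
    window: int = 7
    polyorder: int = 2
    zero_eps: float = 1e-3
    mz_cluster_gap: float = 0.02
    min_points: int = 5


@dataclass(frozen=True)
class ModelParams:
    n_ortho: int = 1
    select_n_ortho: bool = False      # pick n_ortho in 0..3 by CV Q2
    k_folds: int = 7
    split_fraction: float = 0.8
    train_counts: dict | None = None  # explicit per-class training sizes
    impute: str = "half_min"          # missing cells before modelling
    case_class: str = "cancer"
    control_class: str = "control"


@dataclass(frozen=True)
class DiffParams:
    n_top: int = 300
    alpha: float = 0.05
    fold_lo: float = 0.7
    fold_hi: float = 1.5
    equal_var: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    peaks: PeakParams = field(default_factory=PeakParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    filters: FilterParams = field(default_factory=FilterParams)
    model: ModelParams = field(default_factory=ModelParams)
    diff: DiffParams = field(default_factory=DiffParams)
    qc_scope: str = "all"
    seed: int = 0

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {
            "cohort": conv(self.cohort), "peaks": conv(self.peaks),
            "alignment": conv(self.alignment), "filters": conv(self.filters),
            "model": conv(self.model), "diff": conv(self.diff),
            "qc_scope": self.qc_scope, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "cohort": CohortConfig, "peaks": PeakParams, "alignment": AlignmentParams,
            "filters": FilterParams, "model": ModelParams, "diff": DiffParams,
        }
        kwargs = {}
        for name, typ in sections.items():
            sub = dict(d.pop(name, {}))
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            for f in dataclasses.fields(typ):
                if f.name in sub and isinstance(f.default, tuple):
                    sub[f.name] = tuple(sub[f.name])
                if f.name in sub and isinstance(sub[f.name], list):
                    sub[f.name] = tuple(sub[f.name])
            kwargs[name] = typ(**sub)
        scalars = {"qc_scope": "all", "seed": 0}
        for k, default in scalars.items():
            kwargs[k] = d.pop(k, default)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace missing cells by half the feature's minimum observed value
    (applied only at the modelling stage; the stored table keeps NaN)."""
    areas = table.areas.copy()
    fill = areas.min(axis=1, skipna=True) / 2.0
    fill = fill.fillna(0.0)
    for fid in areas.index[areas.isna().any(axis=1)]:
        areas.loc[fid] = areas.loc[fid].fillna(fill[fid])
    return FeatureTable(areas, table.features.copy())


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline on a simulated cohort; returns a result
    dict (tables, reports, fitted model, accuracy) and writes artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
        return _T()

    cfg = config.cohort if config.cohort.seed == config.seed else \
        config.cohort.replace(seed=config.seed)

    with stage("simulate"):
        runs, manifest, truth = generate_cohort(cfg)
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "truth")

    with stage("detect"):
        refs = internal_standard_references(truth)
        per_run = {}
        frames = []
        pk = config.peaks
        for run in runs:
            peaks = pick_run_peaks(run, window=pk.window, polyorder=pk.polyorder,
                                   zero_eps=pk.zero_eps,
                                   mz_cluster_gap=pk.mz_cluster_gap,
                                   min_points=pk.min_points)
            model = fit_drift(peaks, refs, run_id=run.run_id)
            per_run[run.run_id] = apply_drift(peaks, model)
            frames.append(peaks_to_frame(per_run[run.run_id]))
        pd.concat(frames, ignore_index=True).to_csv(out / "peaks.csv", index=False)

    with stage("align"):
        table = align_runs(per_run, config.alignment)
        table.to_csv(out / "feature_table_raw.csv")
        results["n_features_aligned"] = len(table)

    with stage("normalize"):
        cv_report = qc_cv_report(table, manifest)
        cv_report.to_csv(out / "cv_report.csv")
        table, qc_flagged = normalize_to_qc(table, manifest, scope=config.qc_scope)
        if qc_flagged:
            table = table.drop(qc_flagged)
        table.to_csv(out / "feature_table_normalized.csv")
        results["n_qc_flagged"] = len(qc_flagged)

    with stage("filter"):
        table, report = run_cascade(table, manifest, cv_report, config.filters)
        report.to_csv(out / "filter_report.csv")
        report.to_json(out / "filter_report.json")
        report.removed.to_csv(out / "removed_features.csv", index=False)
        table.to_csv(out / "feature_table_filtered.csv")
        results["filter_report"] = report
        results["n_features_final"] = len(table)

    with stage("model"):
        mp = config.model
        sids = study_ids(manifest)
        labels = class_labels(manifest, sids)
        X = impute_half_min(table).areas[sids].T  # samples x features
        split = make_split(labels, fraction=mp.split_fraction,
                           seed=config.seed, train_counts=mp.train_counts)
        X_train, X_test = X.loc[list(split.train_ids)], X.loc[list(split.test_ids)]
        y_train, y_test = labels[list(split.train_ids)], labels[list(split.test_ids)]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = PCA(X_train, n_components=2).fit()
            n_ortho = mp.n_ortho
            if mp.select_n_ortho:
                from .multivariate import select_n_ortho
                n_ortho, _ = select_n_ortho(X_train, y_train, k=mp.k_folds,
                                            seed=config.seed)
            opls = OPLSDA(X_train, y_train, n_ortho=n_ortho).fit()
            opls.cross_val_q2(k=mp.k_folds, seed=config.seed)
            pred = opls.predict(X_test)

        acc = float((pred["class"].to_numpy() == y_test.to_numpy()).mean())
        results.update(model=opls, pca=pca, split=split, accuracy=acc,
                       q2=opls.q2, r2x=opls.r2x, r2y=opls.r2y)
        opls.to_json(out / "oplsda_model.json")

        scores = pd.DataFrame({
            "sample_id": list(opls.t.index) + list(pred.index),
            "class": list(y_train) + list(y_test),
            "t_pred": list(opls.t) + list(pred["t_pred"]),
            "set": ["train"] * len(y_train) + ["test"] * len(y_test),
        })
        if opls.n_ortho > 0:
            scores["t_ortho1"] = list(opls.T_o.iloc[:, 0]) + list(pred["to1"])
            try:
                ell = hotelling_ellipse(np.column_stack([opls.t, opls.T_o.iloc[:, 0]]))
                pd.DataFrame([{
                    "cx": ell.center[0], "cy": ell.center[1],
                    "a": ell.semi_axes[0], "b": ell.semi_axes[1], "angle": ell.angle,
                }]).to_csv(out / "ellipse.csv", index=False)
            except ValueError:
                pass
        scores.to_csv(out / "scores.csv", index=False)

    with stage("diffstats"):
        dp = config.diff
        vol = volcano(table, class_labels(manifest, sids), case=mp.case_class,
                      control=mp.control_class, alpha=dp.alpha,
                      fold_lo=dp.fold_lo, fold_hi=dp.fold_hi,
                      equal_var=dp.equal_var)
        vol.to_csv(out / "volcano.csv")
        n_top = min(dp.n_top, len(vol))
        top = select_top(vol, n_top)
        case_ids = [s for s in sids if labels[s] == mp.case_class]
        ctrl_ids = [s for s in sids if labels[s] == mp.control_class]
        hm = heatmap_matrix(table, top, ctrl_ids, case_ids)
        hm.to_csv(out / "heatmap_ratios.csv", out / "heatmap_bins.csv")
        results["volcano"] = vol
        results["top_features"] = top

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "timings_s": timings,
        "versions": {"glycoms": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    results["run_manifest"] = run_manifest
    results["manifest"] = manifest
    results["truth"] = truth
    results["table"] = table
    return results
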