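"""Synthetic two-class serum glycopeptide LC-MS cohorts with ground truth.

The generator emulates the data model of an untargeted serum glycopeptide
profiling study: a case/control cohort (default 39 cancer / 45 control)
acquired as one injection sequence with pooled-serum QC injections after
every ten study samples and blank injections, centroided negative-mode
Q-TOF spectra over a short reversed-phase gradient, run-to-run retention
time and m/z drift, isotopologue/adduct/in-source-fragment satellite
peaks, and a set of spiked internal-standard (fetuin-like) reference
peaks present in every run.

Two entry points exist: :func:`generate_cohort` produces raw ion lists
(one :class:`~glycoms.containers.RawRun` per injection) for exercising the
full peak-extraction path, and :func:`generate_feature_table` produces the
feature x sample area matrix that ideal peak extraction of the same cohort
would yield, for testing the filtering and modelling stages in isolation.
Both are deterministic functions of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, RawRun

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: mass difference between successive isotopologues (13C - 12C), Da
ISOTOPE_SPACING = 1.0033

#: negative-mode adduct mass offsets relative to [M-H]-, Da
ADDUCT_DELTAS = {"formate": 46.0055, "Na-H": 21.9819, "Cl": 34.9689}

ROLES = ("monoisotopic", "isotope", "adduct", "fragment", "noise", "internal_standard")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and instrument parameters of a simulated cohort.

    The defaults describe the reference study conditions: 39 cancer and 45
    control sera, a QC injection after every 10 study samples, a 1-14 min
    gradient window, glycopeptide masses in 1000-3000 Da, ~3 s wide
    chromatographic peaks and drift well inside the 0.3 min / 0.06 Da
    alignment tolerances.
    """

    n_cancer: int = 39
    n_control: int = 45
    n_features: int = 300              # true monoisotopic glycopeptide features
    frac_differential: float = 0.1
    effect_log2fc: float = 1.0         # mean |log2 fold change| of differential features
    rt_range: tuple[float, float] = (1.0, 14.0)   # minutes
    mz_range: tuple[float, float] = (1000.0, 3000.0)  # Da
    peak_sigma_rt: float = 0.05        # minutes (Gaussian peak sd)
    noise_sd_rel: float = 0.1          # multiplicative measurement noise (lognormal sd)
    rt_drift_sd: float = 0.05          # minutes, run-level offset
    mz_drift_sd: float = 0.005         # Da, run-level offset
    qc_interval: int = 10              # QC injection after every k study samples
    n_blanks: int = 3
    isotope_prob: float = 0.6
    adduct_prob: float = 0.2
    fragment_prob: float = 0.1
    seed: int = 0
    # realism knobs beyond the core study design
    bio_cv: float = 0.3                # biological log-sd of per-sample true levels
    sample_scale_sd: float = 0.1       # per-injection global scale (log-sd)
    scan_interval: float = 0.02        # minutes between scans
    scan_noise_sd: float = 30.0        # additive detector noise per scan, counts
    rt_jitter_sd: float = 0.01         # per-peak RT jitter, minutes
    mz_jitter_sd: float = 0.002        # per-ion m/z jitter, Da
    n_noise: int = 30                  # background features present in blanks too
    noise_feature_area: float = 200.0  # median area of background features
    base_log10_area: float = 5.0       # median log10 area of real features
    base_log10_area_sd: float = 0.6
    n_internal_standards: int = 5
    n_batches: int = 1
    charge_states: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        for name in ("frac_differential", "isotope_prob", "adduct_prob", "fragment_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_cancer < 1 or self.n_control < 1:
            raise ConfigurationError("both classes need at least one sample")
        if not self.rt_range[0] < self.rt_range[1]:
            raise ConfigurationError(f"empty rt_range {self.rt_range}")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ConfigurationError(f"empty mz_range {self.mz_range}")
        # drift must stay inside half the alignment tolerances so that
        # ground-truth matching after correction is well defined
        if self.rt_drift_sd >= 0.3 / 2:
            raise ConfigurationError("rt_drift_sd must be < 0.15 min")
        if self.mz_drift_sd >= 0.06 / 2:
            raise ConfigurationError("mz_drift_sd must be < 0.03 Da")
        if self.qc_interval < 1:
            raise ConfigurationError("qc_interval must be >= 1")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    Attributes
    ----------
    features : pandas.DataFrame
        One row per simulated feature: ``rt``, ``mz`` (reference, drift-free
        coordinates), ``role`` (monoisotopic / isotope / adduct / fragment /
        noise / internal_standard), ``parent_id`` (for satellites), ``z``,
        ``differential`` flag and signed ``log2fc``.
    areas : pandas.DataFrame
        True per-sample areas (features x all injections) before measurement
        noise and injection-scale effects; NaN where a feature is absent
        from a run (e.g. real glycopeptides in blanks).
    drift : pandas.DataFrame
        Per-run true RT/mz offsets (``rt_offset``, ``mz_offset``).
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    drift: pd.DataFrame

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(directory / "truth_features.csv")
        self.areas.to_csv(directory / "truth_areas.csv")
        self.drift.to_csv(directory / "truth_drift.csv")


# ---------------------------------------------------------------------------
# manifest


def _make_manifest(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Injection sequence: blanks first, then study samples in randomized
    order with a QC injection (alternating cancer/benign pool) after every
    ``qc_interval`` study samples."""
    cancer = [f"C{i+1:03d}" for i in range(cfg.n_cancer)]
    control = [f"N{i+1:03d}" for i in range(cfg.n_control)]
    study = np.array(cancer + control)
    order = rng.permutation(len(study))
    study = study[order]
    classes = {s: "cancer" for s in cancer}
    classes.update({s: "control" for s in control})

    rows = []
    for i in range(cfg.n_blanks):
        rows.append((f"BLK{i+1:02d}", "blank", "blank", ""))
    n_qc = 0
    for i, sid in enumerate(study, start=1):
        rows.append((sid, classes[sid], "study", ""))
        if i % cfg.qc_interval == 0 and i < len(study):
            n_qc += 1
            pool = "cancer" if n_qc % 2 == 1 else "control"
            rows.append((f"QC{n_qc:02d}", "qc", "qc", pool))
    # always close the sequence with one QC of each pool so that every pool
    # has >= 2 injections (CVs need replication)
    for pool in ("cancer", "control"):
        existing = sum(1 for r in rows if r[3] == pool)
        while existing < 2:
            n_qc += 1
            rows.append((f"QC{n_qc:02d}", "qc", "qc", pool))
            existing += 1

    manifest = pd.DataFrame(rows, columns=["sample_id", "class", "run_type", "qc_pool"])
    manifest["injection_order"] = np.arange(1, len(manifest) + 1)
    # batches partition the injection sequence contiguously
    manifest["batch"] = pd.cut(
        manifest["injection_order"], bins=cfg.n_batches, labels=False
    ).astype(int) + 1
    return manifest[["sample_id", "class", "run_type", "injection_order", "batch", "qc_pool"]]


# ---------------------------------------------------------------------------
# feature truth


def _make_features(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo_rt, hi_rt = cfg.rt_range
    lo_mz, hi_mz = cfg.mz_range
    margin = 4 * cfg.peak_sigma_rt + 0.2

    recs: list[dict] = []

    def add(role, rt, mz, base_area, parent_id=None, z=1, frac=np.nan):
        recs.append(
            dict(role=role, rt=rt, mz=mz, base_area=base_area,
                 parent_id=parent_id, z=z, differential=False, log2fc=0.0,
                 sat_frac=frac)
        )

    # internal standards: fixed anchors spanning the gradient
    for k in range(cfg.n_internal_standards):
        frac_pos = (k + 0.5) / max(cfg.n_internal_standards, 1)
        rt = lo_rt + margin + frac_pos * (hi_rt - lo_rt - 2 * margin)
        mz = lo_mz + 10.0 + frac_pos * (hi_mz - lo_mz - 20.0)
        add("internal_standard", rt, mz, 2.0e5)

    # true glycopeptide features
    n_diff = int(round(cfg.frac_differential * cfg.n_features))
    diff_idx = set(rng.choice(cfg.n_features, size=n_diff, replace=False)) if n_diff else set()
    mono_rows = []
    for i in range(cfg.n_features):
        rt = rng.uniform(lo_rt + margin, hi_rt - margin)
        mz = rng.uniform(lo_mz + 5.0, hi_mz - 50.0)
        area = 10.0 ** rng.normal(cfg.base_log10_area, cfg.base_log10_area_sd)
        z = int(rng.choice(cfg.charge_states))
        add("monoisotopic", rt, mz, area, z=z)
        idx = len(recs) - 1
        if i in diff_idx:
            mag = cfg.effect_log2fc * float(np.exp(rng.normal(0.0, 0.25)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            recs[idx]["differential"] = True
            recs[idx]["log2fc"] = sign * mag
        mono_rows.append(idx)

    # satellites hanging off monoisotopic parents
    adduct_names = list(ADDUCT_DELTAS)
    for idx in mono_rows:
        parent = recs[idx]
        pid = idx
        if rng.random() < cfg.isotope_prob:
            mz = parent["mz"] + ISOTOPE_SPACING / parent["z"]
            if mz < hi_mz:
                add("isotope", parent["rt"], mz,
                    parent["base_area"] * rng.uniform(0.2, 0.6),
                    parent_id=pid, z=parent["z"], frac=1.0)
        if rng.random() < cfg.adduct_prob:
            delta = ADDUCT_DELTAS[adduct_names[int(rng.integers(len(adduct_names)))]]
            mz = parent["mz"] + delta
            if mz < hi_mz:
                add("adduct", parent["rt"], mz,
                    parent["base_area"] * rng.uniform(0.1, 0.4),
                    parent_id=pid, z=parent["z"], frac=1.0)
        if rng.random() < cfg.fragment_prob:
            mz = parent["mz"] - rng.uniform(150.0, 600.0)
            if mz > lo_mz:
                add("fragment", parent["rt"], mz,
                    parent["base_area"] * rng.uniform(0.1, 0.5),
                    parent_id=pid, z=parent["z"], frac=1.0)

    # background (noise) features, present in blanks as well
    for _ in range(cfg.n_noise):
        rt = rng.uniform(lo_rt + margin, hi_rt - margin)
        mz = rng.uniform(lo_mz + 5.0, hi_mz - 5.0)
        area = cfg.noise_feature_area * float(np.exp(rng.normal(0.0, 0.3)))
        add("noise", rt, mz, area)

    feats = pd.DataFrame(recs)
    feats.index = pd.Index([f"F{i+1:05d}" for i in range(len(feats))], name="feature_id")
    # remap integer parent positions to feature ids
    pos_to_id = {i: feats.index[i] for i in range(len(feats))}
    feats["parent_id"] = feats["parent_id"].map(lambda p: pos_to_id.get(p) if p is not None else None)
    return feats


def _true_areas(cfg: CohortConfig, feats: pd.DataFrame, manifest: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """True per-sample area of every feature in every injection.

    Includes class fold changes and biological variation but *not*
    measurement noise or injection scale (applied at measurement time).
    QC injections carry the pooled mean of ten randomly chosen study
    samples of the pool's arm; blanks carry only noise features and
    internal standards.
    """
    study = manifest[manifest.run_type == "study"]
    study_ids = study.sample_id.tolist()
    is_cancer = (study["class"] == "cancer").to_numpy()

    n_f = len(feats)
    base = feats["base_area"].to_numpy()
    lfc = feats["log2fc"].to_numpy()
    role = feats["role"].to_numpy()
    is_mono = role == "monoisotopic"
    is_noise = role == "noise"
    is_std = role == "internal_standard"
    is_sat = ~(is_mono | is_noise | is_std)

    # study-sample true levels for parents (mono + noise + standards)
    levels = np.empty((n_f, len(study_ids)))
    fold = np.where(is_cancer[None, :], 2.0 ** lfc[:, None], 1.0)
    bio = np.exp(rng.normal(0.0, cfg.bio_cv, size=(n_f, len(study_ids))))
    levels = base[:, None] * fold * bio
    levels[is_std, :] = base[is_std, None]           # standards: constant spike
    if cfg.bio_cv > 0:
        # background features vary only mildly
        levels[is_noise, :] = base[is_noise, None] * np.exp(
            rng.normal(0.0, 0.1, size=(int(is_noise.sum()), len(study_ids)))
        )
    # satellites are strict fractions of their parent's per-sample level
    idx_of = {fid: k for k, fid in enumerate(feats.index)}
    sat_rows = np.where(is_sat)[0]
    for r in sat_rows:
        p = idx_of[feats["parent_id"].iloc[r]]
        ratio = feats["base_area"].iloc[r] / feats["base_area"].iloc[p]
        levels[r, :] = levels[p, :] * ratio

    areas = pd.DataFrame(np.nan, index=feats.index, columns=manifest.sample_id.tolist())
    areas.loc[:, study_ids] = levels

    # QC pools: mean of ten random study samples per arm (fixed per cohort)
    for pool, mask in (("cancer", is_cancer), ("control", ~is_cancer)):
        arm = np.where(mask)[0]
        take = rng.choice(arm, size=min(10, len(arm)), replace=False)
        pool_level = levels[:, take].mean(axis=1)
        qc_cols = manifest.loc[manifest.qc_pool == pool, "sample_id"]
        for c in qc_cols:
            areas[c] = pool_level

    # blanks: only background + internal standards
    blank_cols = manifest.loc[manifest.run_type == "blank", "sample_id"]
    for c in blank_cols:
        col = np.full(n_f, np.nan)
        col[is_noise] = base[is_noise]
        col[is_std] = base[is_std]
        areas[c] = col

    return areas


def _measure(cfg: CohortConfig, areas: pd.DataFrame, feats: pd.DataFrame,
             rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    """Apply per-injection scale and multiplicative measurement noise.

    Satellite ions (isotopologues, adducts, in-source fragments) are formed
    from the parent's ion current in the source, so their measured area is a
    fixed fraction of the parent's *measured* area per injection, with only
    a small independent integration error (~3%), not a fresh draw of the
    full measurement noise.
    """
    scale = pd.Series(
        np.exp(rng.normal(0.0, cfg.sample_scale_sd, size=areas.shape[1])),
        index=areas.columns,
    )
    noise = np.exp(rng.normal(0.0, cfg.noise_sd_rel, size=areas.shape))
    measured = areas * noise * scale.to_numpy()[None, :]

    sat_mask = feats["role"].isin(["isotope", "adduct", "fragment"]).to_numpy()
    if sat_mask.any():
        pos = {fid: k for k, fid in enumerate(feats.index)}
        M = measured.to_numpy()
        integ_sd = min(0.03, cfg.noise_sd_rel) if cfg.noise_sd_rel > 0 else 0.0
        for r in np.where(sat_mask)[0]:
            p = pos[feats["parent_id"].iloc[r]]
            ratio = feats["base_area"].iloc[r] / feats["base_area"].iloc[p]
            row = M[p] * ratio
            if integ_sd > 0:
                row = row * np.exp(rng.normal(0.0, integ_sd, size=row.size))
            M[r] = row
        measured = pd.DataFrame(M, index=measured.index, columns=measured.columns)
    return measured, scale


def _feature_sn(cfg: CohortConfig, measured: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Representative S/N per feature: median peak height over the additive
    scan-noise floor the instrument model uses."""
    cols = manifest.loc[manifest.run_type.isin(["study", "qc"]), "sample_id"]
    med_area = measured[cols].median(axis=1)
    height = med_area / (cfg.peak_sigma_rt * SQRT_2PI)
    if cfg.scan_noise_sd <= 0:
        return pd.Series(np.inf, index=measured.index)
    return height / cfg.scan_noise_sd


# ---------------------------------------------------------------------------
# public entry points


def generate_feature_table(config: CohortConfig) -> tuple[FeatureTable, pd.DataFrame, GroundTruth]:
    """Feature x sample area table as ideal peak extraction would yield it.

    Returns the measured :class:`FeatureTable` (true coordinates, measured
    areas, simulated S/N), the sample manifest and the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    manifest = _make_manifest(config, rng)
    feats = _make_features(config, rng)
    areas = _true_areas(config, feats, manifest, rng)
    measured, _scale = _measure(config, areas, feats, rng)

    meta = feats[["rt", "mz", "role", "parent_id", "differential", "log2fc", "z"]].copy()
    meta["sn"] = _feature_sn(config, measured, manifest)
    drift = pd.DataFrame(
        {"rt_offset": 0.0, "mz_offset": 0.0}, index=manifest.sample_id
    )
    truth = GroundTruth(features=feats, areas=areas, drift=drift)
    return FeatureTable(measured, meta), manifest, truth


def generate_cohort(config: CohortConfig) -> tuple[list[RawRun], pd.DataFrame, GroundTruth]:
    """Full raw-data path: centroided ion lists for every injection.

    Each feature present in a run becomes a Gaussian chromatographic peak
    (sd ``peak_sigma_rt``) sampled on the shared scan grid, with run-level
    RT/m/z drift, per-peak RT jitter, per-ion m/z jitter and additive
    detector noise on ion intensities.
    """
    rng = np.random.default_rng(config.seed)
    manifest = _make_manifest(config, rng)
    feats = _make_features(config, rng)
    areas = _true_areas(config, feats, manifest, rng)
    measured, _scale = _measure(config, areas, feats, rng)

    lo, hi = config.rt_range
    grid = np.arange(lo, hi, config.scan_interval)

    rt0 = feats["rt"].to_numpy()
    mz0 = feats["mz"].to_numpy()
    sigma = config.peak_sigma_rt

    runs: list[RawRun] = []
    drift_rows = []
    for _, row in manifest.iterrows():
        sid = row.sample_id
        rt_off = rng.normal(0.0, config.rt_drift_sd)
        mz_off = rng.normal(0.0, config.mz_drift_sd)
        drift_rows.append((sid, rt_off, mz_off))

        vals = measured[sid].to_numpy()
        present = np.where(np.isfinite(vals) & (vals > 0))[0]
        rts, mzs, ints = [], [], []
        for f in present:
            apex = rt0[f] + rt_off + rng.normal(0.0, config.rt_jitter_sd)
            h = vals[f] / (sigma * SQRT_2PI)
            i0 = np.searchsorted(grid, apex - 4 * sigma)
            i1 = np.searchsorted(grid, apex + 4 * sigma)
            if i1 - i0 < 3:
                continue
            t = grid[i0:i1]
            y = h * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
            if config.scan_noise_sd > 0:
                y = y + rng.normal(0.0, config.scan_noise_sd, size=y.size)
            keep = y > 0
            t, y = t[keep], y[keep]
            m = mz0[f] + mz_off + rng.normal(0.0, config.mz_jitter_sd, size=t.size)
            rts.append(t)
            mzs.append(m)
            ints.append(y[: t.size] if y.size != t.size else y)
        if rts:
            ions = pd.DataFrame(
                {
                    "scan_rt_min": np.concatenate(rts),
                    "mz": np.concatenate(mzs),
                    "intensity": np.concatenate(ints),
                }
            ).sort_values(["scan_rt_min", "mz"], kind="mergesort", ignore_index=True)
        else:  # pragma: no cover - degenerate empty run
            ions = pd.DataFrame(columns=["scan_rt_min", "mz", "intensity"])
        runs.append(RawRun(run_id=sid, run_type=row.run_type, ions=ions))

    drift = pd.DataFrame(drift_rows, columns=["sample_id", "rt_offset", "mz_offset"]).set_index("sample_id")
    truth = GroundTruth(features=feats, areas=areas, drift=drift)
    return runs, manifest, truth


def internal_standard_references(truth: GroundTruth) -> pd.DataFrame:
    """Reference (drift-free) coordinates of the internal-standard anchors."""
    std = truth.features[truth.features.role == "internal_standard"]
    return std[["rt", "mz"]].copy()


# ---------------------------------------------------------------------------
# io


def write_cohort(directory, runs: list[RawRun], manifest: pd.DataFrame,
                 truth: GroundTruth | None = None) -> None:
    """Write runs as peak-list CSVs plus manifest (and truth) CSVs."""
    directory = Path(directory)
    (directory / "runs").mkdir(parents=True, exist_ok=True)
    for run in runs:
        run.ions.to_csv(directory / "runs" / f"{run.run_id}.csv", index=False)
    manifest.to_csv(directory / "manifest.csv", index=False)
    if truth is not None:
        truth.to_csv(directory / "truth")
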