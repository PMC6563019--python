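"""Core in-memory containers shared across the pipeline.

The pipeline moves data through three containers: :class:`RawRun` (one
LC-MS injection as a centroided ion list), a *sample manifest*
(a plain :class:`pandas.DataFrame` with one row per injection), and
:class:`FeatureTable` (aligned features x samples areas plus feature
coordinates).  All three round-trip losslessly through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ION_COLUMNS = ["scan_rt_min", "mz", "intensity"]
MANIFEST_COLUMNS = ["sample_id", "class", "run_type", "injection_order"]

RUN_TYPES = ("study", "qc", "blank")


@dataclass
class RawRun:
    """A single centroided LC-MS injection.

    Parameters
    ----------
    run_id : str
        Unique injection identifier (matches ``sample_id`` in the manifest).
    run_type : str
        One of ``study``, ``qc``, ``blank``.
    ions : pandas.DataFrame
        One row per ion observation with columns ``scan_rt_min`` (minutes),
        ``mz`` (Da) and ``intensity`` (counts), sorted by retention time.
    """

    run_id: str
    run_type: str
    ions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.run_type not in RUN_TYPES:
            raise ValueError(f"run_type must be one of {RUN_TYPES}, got {self.run_type!r}")
        missing = [c for c in ION_COLUMNS if c not in self.ions.columns]
        if missing:
            raise ValueError(f"ion table of run {self.run_id} lacks columns {missing}")

    @property
    def scan_times(self) -> np.ndarray:
        """Sorted unique scan retention times (minutes)."""
        return np.unique(self.ions["scan_rt_min"].to_numpy())

    @property
    def n_ions(self) -> int:
        return len(self.ions)


# feature metadata columns always present in a FeatureTable
FEATURE_META = ["rt", "mz", "sn"]


class FeatureTable:
    """Aligned features x samples matrix of (normalized) peak areas.

    Attributes
    ----------
    areas : pandas.DataFrame
        Rows indexed by feature id, columns by sample id; cells are peak
        areas (counts*min) or QC-ratio values after normalization.  Missing
        cells (a run contributed no peak) are NaN.
    features : pandas.DataFrame
        Per-feature metadata indexed like ``areas``: consensus ``rt``
        (minutes), ``mz`` (Da), representative ``sn`` and any extra columns
        (ground-truth roles, filter flags ...).
    """

    def __init__(self, areas: pd.DataFrame, features: pd.DataFrame):
        if not areas.index.equals(features.index):
            features = features.reindex(areas.index)
        for col in FEATURE_META:
            if col not in features.columns:
                features[col] = np.nan
        self.areas = areas
        self.features = features

    # -- basic protocol ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.areas.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.areas.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def __len__(self) -> int:
        return len(self.areas)

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order kept)."""
        return FeatureTable(self.areas.loc[feature_ids].copy(), self.features.loc[feature_ids].copy())

    def drop(self, feature_ids) -> "FeatureTable":
        keep = self.feature_ids.difference(pd.Index(feature_ids), sort=False)
        return self.subset(keep)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.areas.copy(), self.features.copy())

    # -- io ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write a single wide CSV: feature metadata columns then samples."""
        out = pd.concat([self.features, self.areas], axis=1)
        out.index.name = "feature_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, n_meta: int | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="feature_id")
        if n_meta is None:
            # metadata columns are the non-sample ones written by to_csv;
            # detect by the known names plus anything before the first
            # column absent from FEATURE_META-extras is fragile, so store
            # every non-numeric-id column heuristically: sample columns are
            # whatever follows the last known meta column.
            meta_cols = [c for c in df.columns if c in FEATURE_META or c in _EXTRA_META]
        else:
            meta_cols = list(df.columns[:n_meta])
        sample_cols = [c for c in df.columns if c not in meta_cols]
        return cls(df[sample_cols], df[meta_cols].copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FeatureTable {self.shape[0]} features x {self.shape[1]} samples>"


_EXTRA_META = {"role", "parent_id", "differential", "log2fc", "z"}


# -- manifest helpers ------------------------------------------------------

def check_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    bad = set(manifest["run_type"]) - set(RUN_TYPES)
    if bad:
        raise ValueError(f"unknown run types in manifest: {sorted(bad)}")
    return manifest


def ids_of_type(manifest: pd.DataFrame, run_type: str) -> list[str]:
    return manifest.loc[manifest["run_type"] == run_type, "sample_id"].tolist()


def study_ids(manifest: pd.DataFrame) -> list[str]:
    return ids_of_type(manifest, "study")


def qc_ids(manifest: pd.DataFrame) -> list[str]:
    return ids_of_type(manifest, "qc")


def blank_ids(manifest: pd.DataFrame) -> list[str]:
    return ids_of_type(manifest, "blank")


def class_labels(manifest: pd.DataFrame, sample_ids) -> pd.Series:
    lookup = manifest.set_index("sample_id")["class"]
    return lookup.loc[list(sample_ids)]
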