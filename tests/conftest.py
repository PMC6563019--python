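import numpy as np
import pandas as pd
import pytest

from glycoms import CohortConfig, FeatureTable, generate_feature_table


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    """A small but complete cohort: both classes, QCs, blanks, satellites."""
    return CohortConfig(seed=42, n_features=60, n_cancer=10, n_control=12,
                        n_blanks=2, qc_interval=5, n_noise=8)


@pytest.fixture(scope="session")
def tiny_table(tiny_config):
    return generate_feature_table(tiny_config)


@pytest.fixture(scope="session")
def study_table():
    """Study-shaped satellite-free table for modelling tests."""
    cfg = CohortConfig(seed=7, n_features=400, isotope_prob=0, adduct_prob=0,
                       fragment_prob=0, n_noise=0, n_internal_standards=0,
                       frac_differential=0.1, effect_log2fc=1.0)
    return generate_feature_table(cfg)


def make_table(areas: dict, rt=None, mz=None, sn=None) -> FeatureTable:
    """Hand-build a FeatureTable from {feature_id: {sample_id: area}}."""
    df = pd.DataFrame(areas).T
    meta = pd.DataFrame(index=df.index)
    meta["rt"] = pd.Series(rt) if rt else 5.0
    meta["mz"] = pd.Series(mz) if mz else 1000.0
    meta["sn"] = pd.Series(sn) if sn else np.inf
    return FeatureTable(df, meta)
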