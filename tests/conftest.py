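"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

from methylong.pipeline import AnalysisParams, preprocess_study, run_adms
from methylong.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_probes=2000, n_snps=600, n_children_per_cohort=125,
        n_control_probes=150, n_causal_meqtl=20, seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_params():
    return AnalysisParams(pca_n_perm=100)


@pytest.fixture(scope="session")
def small_pre(small_study, small_params):
    return preprocess_study(small_study, small_params, random_state=7)


@pytest.fixture(scope="session")
def small_adms(small_pre):
    return run_adms(small_pre)
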