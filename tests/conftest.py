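"""Shared fixtures: synthetic study datasets generated once per session."""

from __future__ import annotations

import pytest

from enhancerlink.config import PipelineConfig
from enhancerlink.simulate import TruthSpec, generate_dataset

# one canonical seed per fixture; derived datasets are deterministic
SMALL_SEED = 9
RECOVERY_SEED = 7
LINK_SEED = 8


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_ds():
    """Compact 13-cohort study for pipeline and unit tests."""
    return generate_dataset(seed=SMALL_SEED, n_genes=200, n_enhancers=100,
                            n_tumor=20, n_normal=20, n_disruptive=8, n_neutral=8)


@pytest.fixture(scope="session")
def small_ds_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    return generate_dataset(out, seed=SMALL_SEED, n_genes=200, n_enhancers=100,
                            n_tumor=20, n_normal=20, n_disruptive=8, n_neutral=8)


@pytest.fixture(scope="session")
def recovery_ds():
    """Planted-truth recovery fixture: 13 cohorts, 50/50 samples each,
    500 enhancers / 1000 genes with the default planted effects."""
    return generate_dataset(seed=RECOVERY_SEED, n_genes=1000, n_enhancers=500,
                            truth_spec=TruthSpec())


@pytest.fixture(scope="session")
def link_ds():
    """Link-recovery fixture: 100 tumor samples per cohort so correlations
    are screened at the n = 100 the planted rho is calibrated for."""
    return generate_dataset(seed=LINK_SEED, n_genes=600, n_enhancers=300,
                            n_tumor=100, n_normal=10, truth_spec=TruthSpec())
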