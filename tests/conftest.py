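import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxseq.simulate import (
    TruthConfig,
    generate_counts,
    generate_design,
    generate_genes,
    generate_pathways,
    generate_tft_sets,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    return generate_design(["HeLa", "SHSY5Y"], ["control", "starvation"], [0, 15, 30], 3)


@pytest.fixture(scope="session")
def small_genes():
    return generate_genes(400, seed=11)


@pytest.fixture(scope="session")
def small_study(small_design, small_genes):
    cm, truth = generate_counts(
        small_design, small_genes, TruthConfig(frac_de=0.15), seed=12
    )
    return cm, truth


@pytest.fixture(scope="session")
def small_pathways(small_genes):
    return generate_pathways(small_genes, n_pathways=10, size_range=(8, 25), seed=13)


@pytest.fixture(scope="session")
def small_tft(small_genes, small_pathways):
    return generate_tft_sets(
        small_genes, small_pathways, n_sets=8, size_range=(15, 40), seed=14
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
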