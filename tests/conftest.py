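import numpy as np
import pytest
from hypothesis import settings

from nbsig import CohortTruth, PlantedTruth, simulate_cellline_counts, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_truth():
    return PlantedTruth(
        module_genes=tuple(f"MOD{i}" for i in range(20)),
        tsp53_genes=tuple(f"P53_{i}" for i in range(20)),
        temp_genes=tuple(f"TMP{i}" for i in range(20)),
        effect_log2fc=3.0,
        dispersion=0.05,
    )


@pytest.fixture(scope="session")
def planted_counts(planted_truth):
    return simulate_cellline_counts(1000, planted_truth, seed=11)


@pytest.fixture(scope="session")
def planted_cohort():
    """n=300 cohort with a strong planted 5-gene signal plus 5 noise genes."""
    genes = [f"sig{i}" for i in range(5)] + [f"noise{i}" for i in range(5)]
    truth = CohortTruth(signature_genes=tuple(genes[:5]), beta=0.8)
    expr, clin = simulate_cohort(300, genes, truth, seed=5)
    return expr, clin, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
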