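import numpy as np
import pytest

from embayesb import SimParams, simulate_qtlmas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


def standardized_design(rng, n, m):
    """Random dense design standardized like a genotype matrix."""
    B = rng.standard_normal((n, m))
    B = (B - B.mean(axis=0)) / B.std(axis=0)
    return B


@pytest.fixture(scope="session")
def small_design():
    rng = np.random.default_rng(7)
    n, m = 120, 15
    B = standardized_design(rng, n, m)
    g = np.zeros(m)
    g[[1, 6, 11]] = [0.9, -0.7, 0.5]
    y = B @ g + rng.normal(0.0, 0.4, n)
    return B, y, g


@pytest.fixture(scope="session")
def small_simulation():
    """A drift-scale down-sized population (fast; keeps the full pipeline)."""
    params = SimParams(
        n_chrom=3,
        markers_per_chrom=150,
        spacing_cm=0.5,
        n_qtl=12,
        qtl_chromosomes=(1, 2),
        n_random_generations=20,
        random_males=25,
        random_females=25,
        n_sires=5,
        n_dams=30,
        progeny_per_dam=10,
        n_selected_generations=5,
        n_training_selected_generations=3,
        validation_sample_per_generation=80,
        seed=11,
    )
    return simulate_qtlmas(params)
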