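import numpy as np
import pytest

from gsbench.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """Mid-sized simulated dataset shared across test modules.

    222 individuals (6 sires x 4 dams x 8 offspring), 5 chromosomes x 80
    loci, modest LD history; big enough for REML/BLUP/scan behaviour,
    small enough to simulate once per session.
    """
    params = SimParams(n_sires=6, dams_per_sire=4, offspring_per_dam=8,
                       snps_per_chrom=80, ne=40, n_hist_generations=20)
    return simulate_dataset(params, seed=11)


@pytest.fixture(scope="session")
def sparse_regression_problem():
    """Sparse linear-model data for sampler tests: 100 ind x 50 SNP, 5 causal."""
    rng = np.random.default_rng(42)
    n, m = 100, 50
    Z = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
    beta = np.zeros(m)
    causal = rng.choice(m, 5, replace=False)
    beta[causal] = rng.normal(0, 0.8, 5)
    g = Z @ beta
    y = 2.0 + g + rng.normal(0, g.std() + 0.5, n)
    return {"Z": Z, "y": y, "g": g, "beta": beta}
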