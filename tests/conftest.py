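import numpy as np
import pytest

from twinclocks import (TwinDataset, TwinPair, UnivariateSimSpec, Zygosity,
                        simulate_univariate_twins)


def make_pair(pid, zyg, values, n_waves=1, **covs):
    pheno = np.asarray(values, dtype=float).reshape(2, n_waves)
    return TwinPair(pid, Zygosity.parse(zyg), pheno,
                    {k: np.asarray(v, dtype=float) for k, v in covs.items()})


@pytest.fixture
def small_dataset():
    """Ten deterministic pairs, one wave, no covariates."""
    rng = np.random.default_rng(42)
    pairs = []
    for i in range(6):
        y = rng.normal(0, 1, 2) + rng.normal(0, 1)
        pairs.append(make_pair(f"MZ{i}", "MZ", y))
    for i in range(4):
        y = rng.normal(0, 1, 2)
        pairs.append(make_pair(f"DZ{i}", "DZ", y))
    return TwinDataset(pairs, n_waves=1)


@pytest.fixture
def ae_dataset():
    """Moderate AE-generated sample for fitting tests (h2 = 0.6)."""
    spec = UnivariateSimSpec(n_mz=600, n_dz=600, components="AE",
                             a2=0.6, e2=0.4, seed=7)
    return simulate_univariate_twins(spec)
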