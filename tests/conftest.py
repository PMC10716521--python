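import numpy as np
import pandas as pd
import pytest

from isletepi import CohortConfig, MethylationMatrix, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small cohort with planted signal (seeded)."""
    cfg = CohortConfig(
        n_controls=75, n_cases=25, n_sites=1000, n_genes=120,
        frac_differential=0.04, planted_delta_pp=10.0, seed=42,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_probes=20, n_samples=10):
    beta = rng.random((n_probes, n_samples))
    return MethylationMatrix(
        pd.DataFrame(
            beta,
            index=[f"cg{i:05d}" for i in range(n_probes)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        )
    )
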