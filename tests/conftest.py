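import numpy as np
import pytest
from hypothesis import settings

import puregxe as pgx

# deterministic, CI-friendly hypothesis defaults
settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort():
    """A 40-sample, 12-SNP null cohort with all three environments."""
    cfg = pgx.SimConfig(n_samples=40, n_snps=12, seed=7)
    g, c, truth = pgx.simulate_cohort(cfg)
    return g, c, truth


def naive_i_score(response, cell_index):
    """Independent double-loop evaluation of the influence measure."""
    response = np.asarray(response, dtype=float)
    n = response.size
    overall = response.mean()
    total = 0.0
    for cell in np.unique(cell_index):
        members = [i for i in range(n) if cell_index[i] == cell]
        n_i = len(members)
        mean_i = sum(response[i] for i in members) / n_i
        total += n_i**2 * (mean_i - overall) ** 2
    return total / n
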