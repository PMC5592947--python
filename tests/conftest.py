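import numpy as np
import pytest
from hypothesis import settings

from prfsim import MutationArray, Scenario

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def neutral_scenario(
    n: float = 100,
    generations: int = 10,
    *,
    mu: float = 0.0,
    num_sites: float = 1e6,
    seed: int = 0,
    **kwargs,
) -> Scenario:
    """Single constant-size population, neutral by default."""
    return Scenario(
        num_populations=1,
        num_sites=num_sites,
        num_generations=generations,
        mutation_rate=lambda j, t: mu,
        census_size=lambda j, t: n,
        seed=seed,
        **kwargs,
    )


def replicate_array(num_replicates: int, freq: float, num_pops: int = 1) -> MutationArray:
    """Array of independent replicate 'mutations' all starting at ``freq``.

    Under the PRF every row evolves independently, so one array of R
    rows is R independent replicate chains of the same single-locus
    process -- the cheap way to estimate absorption probabilities and
    finite-time distributions.
    """
    block = np.full((num_replicates, num_pops), freq)
    return MutationArray.from_arrays(
        block,
        np.zeros(num_replicates, dtype=np.int64),
        np.zeros(num_replicates, dtype=np.int64),
        np.arange(num_replicates, dtype=np.int64),
    )


@pytest.fixture
def three_row_array():
    """Two populations; rows: lost everywhere, fixed everywhere, segregating."""
    return MutationArray.from_arrays(
        np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.2]]),
        np.array([0, 0, 1]),
        np.array([0, 0, 0]),
        np.array([0, 1, 0]),
    )
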