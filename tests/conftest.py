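import numpy as np
import pytest

import connectolesion as cl


@pytest.fixture(scope="session")
def parc():
    return cl.make_parcellation(1)


@pytest.fixture(scope="session")
def healthy_connectomes(parc):
    """Ten healthy whole-brain connectomes from the default generator."""
    return [
        cl.weights_from_counts(
            cl.sample_healthy_counts(parc, seed), parc.volumes, nodes=parc.nodes
        )
        for seed in range(10)
    ]


@pytest.fixture(scope="session")
def hemi_average(healthy_connectomes):
    """Unthresholded 41-node healthy-average left-hemisphere network."""
    left = [cl.hemisphere_submatrix(c, "left") for c in healthy_connectomes]
    return cl.group_average(left)


@pytest.fixture(scope="session")
def hemi_fixture(hemi_average):
    """The healthy-average hemisphere network thresholded at density 0.5."""
    return cl.apply_mask(hemi_average, cl.density_mask(hemi_average, 0.5))


@pytest.fixture(scope="session")
def default_cohort():
    return cl.sample_cohort(seed=7)


def random_toy_graph(rng: np.random.Generator, n: int, density: float = 0.6):
    """Random symmetric weighted toy graph used against brute-force oracles."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.1, 2.0, len(iu[0])) * present
    w[iu] = vals
    return w + w.T
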