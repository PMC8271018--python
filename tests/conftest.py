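import numpy as np
import pytest

import hubwire


@pytest.fixture(scope="session")
def cohort():
    """Small planted-hub subject cohort shared across topology tests."""
    spec = hubwire.SyntheticCohortSpec(n_nodes=80, n_subjects=12, seed=7)
    return hubwire.simulate_cohort_connectomes(spec)


@pytest.fixture(scope="session")
def group_conn(cohort):
    return hubwire.build_group_connectome(
        cohort.sc,
        density_target=0.15,
        coords=cohort.nodes[["x", "y", "z"]].to_numpy(),
    )


@pytest.fixture(scope="session")
def distances(cohort):
    xyz = cohort.nodes[["x", "y", "z"]].to_numpy()
    return np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)


def random_symmetric(n, rng, density=0.4, weighted=True):
    """Random simple weighted graph for oracle comparisons."""
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w = np.zeros((n, n))
    vals = rng.uniform(0.5, 5.0, size=iu.size) if weighted else np.ones(iu.size)
    w[iu[present], ju[present]] = vals[present]
    return w + w.T
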