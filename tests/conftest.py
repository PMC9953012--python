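import numpy as np
import pytest

from thermadapt.structures import Structure
from thermadapt.synthetic import (
    StateTrajectorySpec,
    gen_peptide_structure,
    gen_state_trajectory,
    make_site_centroids,
)


@pytest.fixture(scope="session")
def helix10() -> Structure:
    return gen_peptide_structure(10, "helix")


@pytest.fixture(scope="session")
def helix12_h() -> Structure:
    return gen_peptide_structure(12, "helix", hydrogens=True)


@pytest.fixture(scope="session")
def separated4() -> Structure:
    return gen_peptide_structure(4, "separated")


@pytest.fixture(scope="session")
def two_state_series():
    """A 2-state catalytic-site trajectory with labels and distance vectors."""
    from thermadapt import statedyn

    spec = StateTrajectorySpec(
        n_states=2,
        n_frames=1000,
        transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
        noise_sd=0.2,
        seed=3,
    )
    traj, labels = gen_state_trajectory(spec)
    series = statedyn.catalytic_distance_series(traj, (0, 1, 2))
    return series, labels


def sticky_chain(k: int, stay: float = 0.95) -> np.ndarray:
    P = np.full((k, k), (1 - stay) / (k - 1)) if k > 1 else np.array([[1.0]])
    if k > 1:
        np.fill_diagonal(P, stay)
    return P


@pytest.fixture(scope="session")
def shared_centroids3():
    return make_site_centroids(3, seed=42, separation=2.0)
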