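import numpy as np
import pytest

from cypdyn.structio import Structure
from cypdyn.synthetic import SyntheticSpec, generate_two_state_trajectory


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Down-scaled two-state generator spec for fast unit tests."""
    return SyntheticSpec(
        n_domain1=24, n_domain2=24, n_linker=6,
        p_ec=0.02, p_ce=0.04, noise_sigma=1.0,
        n_frames=400, seed=7,
    )


@pytest.fixture(scope="session")
def two_state(small_spec):
    """(Trajectory, GroundTruth) from the down-scaled two-state generator."""
    return generate_two_state_trajectory(small_spec)


def make_chain(n_residues: int, spacing: float = 3.8, rng=None) -> Structure:
    """A straight Cα-only chain, optionally jittered, residues 1..n."""
    coords = np.zeros((n_residues, 3))
    coords[:, 0] = spacing * np.arange(n_residues)
    if rng is not None:
        coords = coords + rng.normal(scale=0.5, size=coords.shape)
    return Structure(
        atom_names=np.full(n_residues, "CA"),
        resids=np.arange(1, n_residues + 1),
        resnames=np.full(n_residues, "GLY"),
        chains=np.full(n_residues, "A"),
        elements=np.full(n_residues, "C"),
        coords=coords,
    )


def random_rotation(rng) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
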