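import numpy as np
import pytest

from rotoshear.core import Structure
from rotoshear.trajgen import (
    compose,
    make_breathing,
    make_rigid_rotor,
    make_toy_protein,
    make_twist,
)

#: prescribed rigid angular velocity about x3 (1/ps); 5 per ns
OMEGA3 = 0.005
OMEGA = np.array([0.0, 0.0, OMEGA3])
DT = 0.02  # ps

#: twist frequency chosen so 250 frames x 0.02 ps cover one full period
TWIST_FREQ = 0.2
N_FRAMES = 250


@pytest.fixture(scope="session")
def tetrahedron() -> Structure:
    verts = 0.2 * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return Structure(positions=verts, masses=np.ones(4))


@pytest.fixture(scope="session")
def toy_structure() -> Structure:
    return make_toy_protein(30, bond_length=0.35, seed=1)


@pytest.fixture(scope="session")
def mirror_structure() -> Structure:
    """Twist-balanced cloud: halves are z-mirror images and each half is
    C2-symmetric about z (so its xz/yz inertia products vanish); the angular
    momenta of counter-twisting halves then cancel exactly."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(-0.8, 0.8, size=(10, 3))
    pts[:, 2] = rng.uniform(0.15, 0.9, 10)
    upper = np.vstack([pts, pts * [-1, -1, 1]])
    pos = np.vstack([upper, upper * [1, 1, -1]])
    return Structure(positions=pos - pos.mean(axis=0), masses=np.ones(40))


@pytest.fixture(scope="session")
def rigid_traj(toy_structure):
    return make_rigid_rotor(toy_structure, OMEGA, 60, DT)


@pytest.fixture(scope="session")
def breathing_traj(toy_structure):
    return make_breathing(toy_structure, 0.1, 0.05, 60, DT)


@pytest.fixture(scope="session")
def twist_traj(toy_structure):
    return make_twist(toy_structure, 0.3, TWIST_FREQ, (0, 0, 1), 60, DT)


@pytest.fixture(scope="session")
def composite_traj(toy_structure):
    """rigid + twist over one full twist period (prescribed omega3 = OMEGA3)."""
    rigid = make_rigid_rotor(toy_structure, OMEGA, N_FRAMES, DT)
    twist = make_twist(toy_structure, 0.3, TWIST_FREQ, (0, 0, 1), N_FRAMES, DT)
    return compose([rigid, twist])


@pytest.fixture(scope="session")
def drift_traj(toy_structure):
    rigid = make_rigid_rotor(toy_structure, OMEGA, 20, DT)
    return compose([rigid], com_velocity=(0.01, -0.02, 0.005))


@pytest.fixture(
    params=["rigid", "breathing", "twist", "composite", "drift"],
    scope="session",
)
def any_fixture_traj(
    request, rigid_traj, breathing_traj, twist_traj, composite_traj, drift_traj
):
    return {
        "rigid": rigid_traj,
        "breathing": breathing_traj,
        "twist": twist_traj,
        "composite": composite_traj,
        "drift": drift_traj,
    }[request.param]
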