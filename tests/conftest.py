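import numpy as np
import pytest

from ambiflock.flock_sim import SimConfig, run_simulation


@pytest.fixture(scope="session")
def small_traj():
    """A small but dynamically equilibrated flock shared by analysis tests."""
    cfg = SimConfig(n_agents=60, v_max=8.0, repulsion_radius=1.0,
                    n_steps=600, burn_in=300, seed=7)
    return run_simulation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_cone_points(rng, n, width):
    """n unit vectors within angular distance `width` of a random axis."""
    axis = random_unit_vectors(rng, 1)[0]
    e1 = np.cross(axis, random_unit_vectors(rng, 1)[0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    th = np.arccos(1.0 - (1.0 - np.cos(width)) * rng.random(n))
    ph = rng.uniform(0, 2 * np.pi, n)
    return (
        np.cos(th)[:, None] * axis
        + np.sin(th)[:, None] * (np.cos(ph)[:, None] * e1 + np.sin(ph)[:, None] * e2)
    )
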