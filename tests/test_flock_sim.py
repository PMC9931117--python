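"""Simulator tests: topology, interaction caps, avoidance, update contract."""

import numpy as np
import pytest

from ambiflock import sphere_geometry as sg
from ambiflock.flock_sim import (
    FlockState,
    SimConfig,
    Trajectory,
    avoidance_direction,
    delaunay_neighbors,
    initial_state,
    interaction_sphere,
    next_velocity,
    quasi_alignment_cap,
    quasi_attraction_cap,
    run_simulation,
    step,
)
from conftest import random_unit_vectors


def make_state(positions, velocities, history_steps=1):
    """State whose position log extends straight back along the velocities."""
    pos = np.asarray(positions, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    hist = np.stack([pos - k * vel for k in range(history_steps, -1, -1)])
    return FlockState(history=hist, velocities=vel.copy())


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def test_delaunay_tetrahedron_is_complete_graph():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    nbrs = delaunay_neighbors(pts)
    for i, nb in enumerate(nbrs):
        assert set(nb) == set(range(4)) - {i}


def test_delaunay_bipyramid_apices_see_equator():
    pts = np.array(
        [
            [1, 0, 0],
            [-0.5, np.sqrt(3) / 2, 0],
            [-0.5, -np.sqrt(3) / 2, 0],
            [0, 0, 1.0],
            [0, 0, -1.0],
        ]
    )
    nbrs = delaunay_neighbors(pts)
    assert set(nbrs[3]) >= {0, 1, 2}
    assert set(nbrs[4]) >= {0, 1, 2}


def test_delaunay_symmetry_property(rng):
    for _ in range(30):
        pts = rng.random((rng.integers(8, 40), 3)) * 10
        nbrs = delaunay_neighbors(pts)
        for i, nb in enumerate(nbrs):
            assert len(nb) >= 1
            for j in nb:
                assert i in nbrs[j]


def test_delaunay_degenerate_coplanar_jitter_retry():
    pts = np.zeros((8, 3))
    pts[:, 0] = np.arange(8)
    pts[:, 1] = np.arange(8) % 3
    nbrs = delaunay_neighbors(pts)  # coplanar: must not raise
    assert all(len(nb) >= 1 for nb in nbrs)


# ---------------------------------------------------------------------------
# Interaction sphere and caps
# ---------------------------------------------------------------------------


def test_interaction_sphere_is_max_neighbor_distance(rng):
    pos = np.vstack([[0, 0, 0], [1, 0, 0], [0, 3, 0], [0, 0, 2]]).astype(float)
    state = make_state(pos, np.tile([1.0, 0, 0], (4, 1)))
    assert interaction_sphere(0, state, [1, 2, 3]) == pytest.approx(3.0)
    assert interaction_sphere(0, state, [3]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        interaction_sphere(0, state, [])


def test_quasi_attraction_cap_covers_all_exits(rng):
    for _ in range(30):
        n = 11
        pos = rng.normal(size=(n, 3)) * 3
        vel = 8.0 * random_unit_vectors(rng, n)
        state = make_state(pos, vel)
        nbrs = np.arange(1, n)
        r_max = interaction_sphere(0, state, nbrs)
        cap = quasi_attraction_cap(0, state, nbrs, r_max)
        # every neighbor exit and the focal agent's own heading are inside
        assert sg.cap_contains(cap, sg.normalize(vel[0]), tol=1e-7)
        for j in nbrs:
            exit_pt = sg.ray_sphere_exit(pos[j], sg.normalize(vel[j]), pos[0], r_max)
            assert sg.cap_contains(cap, sg.normalize(exit_pt - pos[0]), tol=1e-7)


def test_quasi_attraction_parallel_motion_centers_on_heading():
    """Symmetric neighbors moving parallel to the focal agent: the cap axis
    is the shared heading."""
    heading = np.array([1.0, 0.0, 0.0])
    offsets = np.array([[0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    pos = np.vstack([[0, 0, 0], offsets])
    vel = 8.0 * np.tile(heading, (5, 1))
    state = make_state(pos, vel)
    cap = quasi_attraction_cap(0, state, np.arange(1, 5), 1.0)
    assert np.allclose(cap.center, heading, atol=1e-9)


def test_quasi_attraction_neighbor_on_sphere_exits_at_itself():
    """A neighbor sitting on the interaction sphere moving outward contributes
    its own bearing (reaching time t = 0)."""
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 1, 0]])
    vel = np.array([[8.0, 0, 0], [8.0, 0, 0], [0.0, 8, 0]])
    state = make_state(pos, vel)
    r_max = interaction_sphere(0, state, [1, 2])  # = 2, neighbor 1 on the sphere
    cap = quasi_attraction_cap(0, state, [1, 2], r_max)
    assert sg.cap_contains(cap, np.array([1.0, 0, 0]), tol=1e-9)


def test_quasi_alignment_straight_tracks_give_tight_cap_on_heading():
    rng = np.random.default_rng(0)
    heading = np.array([1.0, 0.0, 0.0])
    pos = rng.normal(size=(8, 3)) * 2.0
    vel = 8.0 * np.tile(heading, (8, 1))
    state = make_state(pos, vel, history_steps=30)
    nbrs = np.arange(1, 8)
    r_max = interaction_sphere(0, state, nbrs)
    cap, dmin = quasi_alignment_cap(0, state, nbrs, r_max, v_max=8.0)
    assert dmin >= 1
    assert sg.angular_distance(cap.center, heading) < cap.theta + 1e-9
    assert cap.theta < np.pi / 3  # predictions cluster ahead


def test_quasi_alignment_delta_min_is_minimal():
    """At Delta_min all predicted points are outside the sphere; at
    Delta_min - 1 at least one is inside."""
    from ambiflock.flock_sim import alignment_predictions

    rng = np.random.default_rng(3)
    pos = rng.normal(size=(9, 3)) * 10.0
    vel = 8.0 * random_unit_vectors(rng, 9)
    state = make_state(pos, vel, history_steps=30)
    nbrs = np.arange(1, 9)
    r_max = interaction_sphere(0, state, nbrs)
    cap, dmin = quasi_alignment_cap(0, state, nbrs, r_max, v_max=8.0)
    if dmin >= 1:
        members = np.concatenate(([0], nbrs))
        pred = alignment_predictions(state, dmin, 8.0)
        assert np.all(np.linalg.norm(pred[members] - pos[0], axis=1) > r_max)
        if dmin > 1:
            pred_prev = alignment_predictions(state, dmin - 1, 8.0)
            assert np.any(
                np.linalg.norm(pred_prev[members] - pos[0], axis=1) <= r_max
            )


def test_quasi_alignment_tracks_circling_agent():
    """A neighbor on a circular path is extrapolated along its rotation."""
    from ambiflock.flock_sim import alignment_predictions

    omega = 0.1
    radius = 8.0 / omega  # speed ~ v_max
    tt = np.arange(-40, 1) * omega
    circle = np.column_stack([radius * np.cos(tt), radius * np.sin(tt), 0 * tt])
    # focal agent far away, straight
    focal = np.column_stack([np.full(41, 200.0), np.arange(-40, 1) * 8.0, np.zeros(41)])
    hist = np.stack([np.vstack([focal[k], circle[k]]) for k in range(41)])
    vel = np.vstack([focal[-1] - focal[-2], circle[-1] - circle[-2]])
    state = FlockState(history=hist, velocities=vel)
    for dt in (1, 3, 5):
        pred = alignment_predictions(state, dt, 8.0)
        # analytic continuation of the circle by dt more steps of arc omega*dt,
        # displaced chord-style at v_max*dt
        lag_dir = circle[-1] - circle[-1 - dt]
        lag_dir /= np.linalg.norm(lag_dir)
        rot = sg.rotation_from_pair(
            sg.normalize(circle[-1 - dt] - circle[-1 - 2 * dt]), lag_dir
        )
        expected = circle[-1] + 8.0 * dt * sg.predict_direction(rot, lag_dir, 1)
        assert np.allclose(pred[1], expected, atol=1e-8)


# ---------------------------------------------------------------------------
# Avoidance
# ---------------------------------------------------------------------------


def test_avoidance_direction_geodesic_projection():
    """The escape heading lies on the crowd-cap boundary along the geodesic
    from the focal agent's own exit."""
    pos = np.array([[0.0, 0, 0], [0.5, 0.1, 0]])
    vel = np.array([[8.0, 0, 0], [8.0, 0, 0]])
    state = make_state(pos, vel)
    d = avoidance_direction(0, state, repulsion_radius=1.0)
    # own exit is inside the cap -> result sits exactly on the boundary
    exit1 = sg.ray_sphere_exit(pos[1], np.array([1.0, 0, 0]), pos[0], 1.0)
    cap = sg.minimal_enclosing_cap(
        [np.array([1.0, 0, 0]), sg.normalize(exit1 - pos[0])], sphere_radius=1.0
    )
    assert sg.angular_distance(cap.center, d) == pytest.approx(cap.theta, abs=1e-9)
    assert np.linalg.norm(d) == pytest.approx(1.0)


def test_avoidance_symmetric_neighbors_keep_mirror_plane():
    pos = np.array([[0.0, 0, 0], [0.4, 0.3, 0.2], [0.4, 0.3, -0.2]])
    vel = np.array([[8.0, 0, 0], [8.0, 0, 0], [8.0, 0, 0]])
    state = make_state(pos, vel)
    d = avoidance_direction(0, state, repulsion_radius=1.0)
    assert d[2] == pytest.approx(0.0, abs=1e-9)  # stays in the z = 0 mirror plane


def test_avoidance_outside_cap_keeps_heading():
    # neighbor behind, moving away: its exit is far from the focal exit
    pos = np.array([[0.0, 0, 0], [-0.5, 0, 0]])
    vel = np.array([[8.0, 0, 0], [-8.0, 0, 0]])
    state = make_state(pos, vel)
    d = avoidance_direction(0, state, repulsion_radius=1.0)
    assert np.allclose(d, [1.0, 0, 0])


# ---------------------------------------------------------------------------
# Velocity rule
# ---------------------------------------------------------------------------


def test_next_velocity_speed_rule(rng):
    heading = np.array([1.0, 0.0, 0.0])
    # zero-spread cap aligned with the heading: straight flight at v_max
    cap = sg.SphericalCap(heading, 0.0)
    v = next_velocity(0, cap, heading, rng, v_max=8.0)
    assert np.allclose(v, [8.0, 0, 0])
    # zero-spread cap 90 degrees off: the realized turn is clamped at pi/2
    cap = sg.SphericalCap(np.array([0.0, 1.0, 0.0]), 0.0)
    v = next_velocity(0, cap, heading, rng, v_max=8.0, max_turn=np.pi / 2)
    assert np.linalg.norm(v) == pytest.approx(8.0 * np.cos(np.pi / 4))
    assert np.allclose(sg.normalize(v), [0, 1, 0], atol=1e-9)
    # turn clamping: a cap at 150 degrees only rotates the heading by max_turn
    far = sg.normalize([-np.sqrt(3) / 2, 0.5, 0.0])
    cap = sg.SphericalCap(far, 0.0)
    v = next_velocity(0, cap, heading, rng, v_max=8.0, max_turn=np.pi / 2)
    assert sg.angular_distance(sg.normalize(v), heading) == pytest.approx(np.pi / 2)


def test_speed_bound_holds_throughout_run(small_traj):
    speeds = np.linalg.norm(small_traj.velocities, axis=2)
    assert np.all(speeds <= small_traj.config.v_max + 1e-9)
    assert np.all(speeds > 0)


# ---------------------------------------------------------------------------
# Step and full-run contracts
# ---------------------------------------------------------------------------


def test_fixed_seed_runs_are_bit_identical():
    cfg = SimConfig(n_agents=25, n_steps=40, burn_in=10, seed=42)
    a = run_simulation(cfg)
    b = run_simulation(cfg)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_single_agent_is_ballistic():
    """With all interactions removed the motion is a straight line at v_max."""
    cfg = SimConfig(n_agents=1, n_steps=50, burn_in=0, seed=3)
    traj = run_simulation(cfg)
    d = np.diff(traj.positions[:, 0, :], axis=0)
    assert np.allclose(d, d[0], atol=1e-12)
    assert np.linalg.norm(d[0]) == pytest.approx(8.0)


def test_self_tuned_noise_shrinks_with_alignment():
    """A high-polarity neighborhood must produce a smaller next-direction cap
    than a matched isotropic-heading neighborhood."""
    from ambiflock.sphere_geometry import max_inscribed_cap

    rng = np.random.default_rng(11)
    pos = rng.normal(size=(12, 3)) * 3.0

    def combined_theta(vel):
        state = make_state(pos, vel, history_steps=30)
        nbrs = np.arange(1, 12)
        r_max = interaction_sphere(0, state, nbrs)
        catr = quasi_attraction_cap(0, state, nbrs, r_max)
        calg, _ = quasi_alignment_cap(0, state, nbrs, r_max, v_max=8.0)
        return max_inscribed_cap(catr, calg).theta

    aligned = 8.0 * np.tile([1.0, 0, 0], (12, 1))
    isotropic = 8.0 * random_unit_vectors(rng, 12)
    assert combined_theta(aligned) < combined_theta(isotropic)


def test_step_matches_run_simulation_orchestration():
    """The public step() reproduces the preallocated run loop exactly."""
    cfg = SimConfig(n_agents=20, n_steps=15, burn_in=0, seed=8)
    traj = run_simulation(cfg)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_agents + 1)
    state = initial_state(cfg, np.random.default_rng(children[0]))
    blocks = np.stack(
        [np.random.default_rng(children[i + 1]).random((cfg.n_steps, 2))
         for i in range(cfg.n_agents)],
        axis=1,
    )
    for t in range(cfg.n_steps):
        state = step(state, cfg, uniforms=blocks[t])
        assert np.allclose(state.positions, traj.positions[t], atol=1e-12)
        assert np.allclose(state.velocities, traj.velocities[t], atol=1e-12)


def test_flock_stays_cohesive(small_traj):
    """No agent escapes: the largest nearest-neighbor distance stays bounded
    relative to the flock scale."""
    from scipy.spatial import cKDTree

    for t in range(0, small_traj.n_steps, 50):
        pos = small_traj.positions[t]
        nn = cKDTree(pos).query(pos, k=2)[0][:, 1]
        assert nn.max() < 30 * small_traj.config.v_max


def test_center_of_mass_is_unconstrained(small_traj):
    """No boundary: the flock drifts freely, far from the origin."""
    com = small_traj.positions.mean(axis=1)
    assert np.linalg.norm(com[-1] - com[0]) > 10 * small_traj.config.v_max


# ---------------------------------------------------------------------------
# Config validation and I/O
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_agents": 3},
        {"v_max": 0.0},
        {"repulsion_radius": -1.0},
        {"max_turn": 0.0},
        {"max_turn": 4.0},
        {"n_steps": 0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_trajectory_hdf5_round_trip(tmp_path, small_traj):
    path = tmp_path / "traj.h5"
    small_traj.save_hdf5(path)
    back = Trajectory.load_hdf5(path)
    assert np.array_equal(back.positions, small_traj.positions)
    assert np.array_equal(back.velocities, small_traj.velocities)
    assert back.config == small_traj.config


def test_trajectory_csv_round_trip(tmp_path, small_traj):
    import pandas as pd

    path = tmp_path / "traj.csv"
    small_traj.save_csv(path)
    df = pd.read_csv(path)
    assert len(df) == small_traj.n_steps * small_traj.n_agents
    row = df[(df.t == 3) & (df.agent == 5)].iloc[0]
    assert row.x == pytest.approx(small_traj.positions[3, 5, 0])
    assert row.vz == pytest.approx(small_traj.velocities[3, 5, 2])


def test_kernel_caps_match_reference_operations():
    """The compiled per-step kernel and the readable per-agent operations
    compute identical interaction caps on the same state."""
    from ambiflock import _kernels as _k
    from ambiflock.flock_sim import _delaunay_csr
    from ambiflock.sphere_geometry import max_inscribed_cap

    rng = np.random.default_rng(19)
    n = 30
    pos = rng.normal(size=(n, 3)) * 6.0
    vel = 8.0 * random_unit_vectors(rng, n)
    state = make_state(pos, vel, history_steps=25)
    indptr, indices = _delaunay_csr(pos)

    new_vel = vel.copy()
    cap_theta = np.zeros(n)
    _k._phase2_kernel(
        np.ascontiguousarray(state.history),
        np.ascontiguousarray(pos),
        state.t,
        np.ascontiguousarray(vel),
        indptr,
        indices,
        8.0,
        np.pi / 2,
        12,
        2.0,
        12.0,
        rng.random((n, 2)),
        np.ones(n, dtype=bool),
        new_vel,
        cap_theta,
    )
    for i in range(n):
        nbrs = indices[indptr[i]:indptr[i + 1]]
        r_max = interaction_sphere(i, state, nbrs)
        catr = quasi_attraction_cap(i, state, nbrs, r_max)
        calg, _ = quasi_alignment_cap(i, state, nbrs, r_max, v_max=8.0, max_dt=12)
        expected = max_inscribed_cap(catr, calg).theta
        assert cap_theta[i] == pytest.approx(expected, abs=1e-9)
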