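"""The ambiguous-interaction flocking simulator.

Agents move in unbounded 3D space with a synchronous per-step update:

1. *Avoidance* (rare): any agent with a metric neighbor inside the repulsion
   radius ``R`` steers deterministically to the nearest edge of the cap of
   repulsion-sphere exit points, then moves.
2. *Quasi-attraction / quasi-alignment*: a Delaunay graph is built on the
   post-avoidance positions.  Each remaining agent forms its interaction
   sphere (radius = farthest Delaunay neighbor), covers the forward exits of
   neighbor velocities (quasi-attraction cap) and the radial projections of
   turning-rate-extrapolated future neighbor positions (quasi-alignment cap),
   intersects the two caps, and samples its next heading from a von
   Mises-Fisher distribution whose spread is the cap's own angular radius.
   Speed follows the turn-deceleration rule ``v = v_max * cos(dtheta / 2)``.

The model has three parameters - agent count ``N``, maximum speed ``v_max``
and repulsion radius ``R`` - and its noise is entirely self-tuned: tightly
aligned neighborhoods shrink the cap and make motion near-deterministic,
disordered ones widen it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from . import _kernels as _k
from .sphere_geometry import (
    SphericalCap,
    angular_distance,
    minimal_enclosing_cap,
    normalize,
    ray_sphere_exit,
    sample_vmf,
)

__all__ = [
    "SimConfig",
    "FlockState",
    "Trajectory",
    "initial_state",
    "delaunay_neighbors",
    "interaction_sphere",
    "quasi_attraction_cap",
    "quasi_alignment_cap",
    "avoidance_direction",
    "next_velocity",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """Run parameters.

    ``n_agents`` must be >= 4 (3D Delaunay) or exactly 1 (the interaction-free
    ballistic control).  ``max_turn`` caps the per-step heading change;
    ``history_depth`` bounds the quasi-alignment prediction-lag search;
    ``burn_in`` steps are simulated but dropped from the returned trajectory.
    The time step is fixed at 1.
    """

    n_agents: int = 300
    v_max: float = 8.0
    repulsion_radius: float = 1.0
    n_steps: int = 1000
    seed: int = 0
    max_turn: float = np.pi / 2
    history_depth: int = 50
    burn_in: int = 500
    kappa_power: float = 2.0
    kappa_scale: float = 12.0
    init_radius_factor: float = 1.0

    def __post_init__(self):
        if self.n_agents != 1 and self.n_agents < 4:
            raise ValueError("n_agents must be >= 4 (or 1 for the ballistic control)")
        if self.v_max <= 0 or self.repulsion_radius <= 0:
            raise ValueError("v_max and repulsion_radius must be positive")
        if not 0 < self.max_turn <= np.pi:
            raise ValueError("max_turn must lie in (0, pi]")
        if self.n_steps < 1 or self.burn_in < 0:
            raise ValueError("n_steps >= 1 and burn_in >= 0 required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FlockState:
    """Positions/velocities at a step plus the position log needed for
    turning-rate extrapolation.  ``history[k]`` is the position array at step
    ``k``; ``history[-1]`` is the current one."""

    history: np.ndarray  # (t+1, N, 3)
    velocities: np.ndarray  # (N, 3)

    @property
    def t(self) -> int:
        return self.history.shape[0] - 1

    @property
    def positions(self) -> np.ndarray:
        return self.history[-1]

    @property
    def n_agents(self) -> int:
        return self.history.shape[1]


@dataclass
class Trajectory:
    """Recorded run: ``positions``/``velocities`` of shape (steps, N, 3) and
    the generating config.  The interchange object for every analysis."""

    positions: np.ndarray
    velocities: np.ndarray
    config: SimConfig

    def __post_init__(self):
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share a shape")
        if not np.isfinite(self.positions).all() or not np.isfinite(self.velocities).all():
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("velocities", data=self.velocities)
            for key, val in self.config.to_dict().items():
                f.attrs[key] = val

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            pos = f["positions"][...]
            vel = f["velocities"][...]
            attrs = {k: f.attrs[k] for k in f.attrs}
        cfg_fields = {f.name for f in dataclasses.fields(SimConfig)}
        cfg = SimConfig(**{k: v for k, v in attrs.items() if k in cfg_fields})
        return cls(positions=pos, velocities=vel, config=cfg)

    def to_dataframe(self):
        import pandas as pd

        T, N, _ = self.positions.shape
        t = np.repeat(np.arange(T), N)
        agent = np.tile(np.arange(N), T)
        pos = self.positions.reshape(-1, 3)
        vel = self.velocities.reshape(-1, 3)
        return pd.DataFrame(
            {
                "t": t,
                "agent": agent,
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
                "vx": vel[:, 0],
                "vy": vel[:, 1],
                "vz": vel[:, 2],
            }
        )

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def _delaunay_csr(positions: np.ndarray, jitter_scale: float = 1e-9):
    """Symmetric Delaunay adjacency as CSR (indptr, indices); degenerate
    inputs (coplanar/duplicate) get one jitter-and-retry pass."""
    positions = np.asarray(positions, dtype=float)
    try:
        tri = Delaunay(positions)
    except QhullError:
        scale = max(np.ptp(positions), 1.0)
        rng = np.random.default_rng(0)
        jittered = positions + rng.normal(scale=jitter_scale * scale, size=positions.shape)
        tri = Delaunay(jittered)
    indptr, indices = tri.vertex_neighbor_vertices
    return indptr.astype(np.int64), indices.astype(np.int64)


def delaunay_neighbors(positions) -> list[np.ndarray]:
    """Per-agent Delaunay neighbor index sets (symmetric by construction)."""
    indptr, indices = _delaunay_csr(np.asarray(positions, dtype=float))
    return [indices[indptr[i] : indptr[i + 1]] for i in range(len(indptr) - 1)]


# ---------------------------------------------------------------------------
# Per-agent operations (readable reference forms; the simulator's inner loop
# uses the compiled equivalents in ``_kernels``)
# ---------------------------------------------------------------------------


def interaction_sphere(i: int, state: FlockState, nbrs) -> float:
    """Radius of the interaction sphere: farthest Delaunay-neighbor distance."""
    nbrs = np.asarray(nbrs, dtype=int)
    if nbrs.size == 0:
        raise ValueError("interaction_sphere requires a nonempty neighbor set")
    d = np.linalg.norm(state.positions[nbrs] - state.positions[i], axis=1)
    return float(d.max())


def quasi_attraction_cap(i: int, state: FlockState, nbrs, r_max: float) -> SphericalCap:
    """Minimal cap covering the forward exits of each neighbor's velocity ray
    (and the focal agent's own exit) on the interaction sphere."""
    center = state.positions[i]
    pts = [normalize(state.velocities[i])]  # own exit: the agent sits at the center
    for j in np.asarray(nbrs, dtype=int):
        vj = state.velocities[j]
        if np.linalg.norm(vj) < 1e-12:
            # stationary neighbor: treat its bearing from the focal agent as its exit
            pts.append(normalize(state.positions[j] - center))
            continue
        exit_pt = ray_sphere_exit(state.positions[j], normalize(vj), center, r_max)
        pts.append(normalize(exit_pt - center))
    cap = minimal_enclosing_cap(pts, sphere_radius=r_max)
    return cap


def alignment_predictions(state: FlockState, dt: int, v_max: float) -> np.ndarray:
    """Rotation-extrapolated positions of all agents ``dt`` steps ahead.

    The turning rotation over the lag ``dt`` is rebuilt from the pair of
    successive lag-``dt`` displacement directions and applied once to the
    current lag direction; the agent then travels ``v_max * dt`` along it.
    """
    traj = np.ascontiguousarray(state.history)
    cur = np.ascontiguousarray(state.positions)
    t = state.t
    out = np.empty_like(cur)
    for j in range(state.n_agents):
        out[j] = _k._turning_prediction(traj, cur, t, j, int(dt), float(v_max))
    return out


def quasi_alignment_cap(
    i: int,
    state: FlockState,
    nbrs,
    r_max: float,
    v_max: float,
    max_dt: int = 50,
) -> tuple[SphericalCap, int]:
    """Minimal cap covering the radial projections of predicted future
    positions onto the interaction sphere.

    The prediction lag is Delta_min: the smallest ``dt`` at which *every*
    predicted point (neighbors and the focal agent itself) lies outside the
    interaction sphere.  If no lag up to ``max_dt`` qualifies, straight-line
    extrapolation far enough to guarantee exit is used (reported as lag 0).
    Returns ``(cap, delta_min)``.
    """
    nbrs = np.asarray(nbrs, dtype=int)
    members = np.concatenate(([i], nbrs))
    center = state.positions[i]
    for dt in range(1, max_dt + 1):
        pred = alignment_predictions(state, dt, v_max)
        dist = np.linalg.norm(pred[members] - center, axis=1)
        if np.all(dist > r_max):
            pts = [(pred[j] - center) / np.linalg.norm(pred[j] - center) for j in members]
            return minimal_enclosing_cap(pts, sphere_radius=r_max), dt
    # straight-line fallback, guaranteed outside the sphere
    steps = 2.0 * r_max / v_max + 2.0
    pts = []
    for j in members:
        head = normalize(state.velocities[j])
        p = state.positions[j] + v_max * steps * head - center
        pts.append(normalize(p))
    return minimal_enclosing_cap(pts, sphere_radius=r_max), 0


def avoidance_direction(i: int, state: FlockState, repulsion_radius: float) -> np.ndarray:
    """Deterministic escape heading when metric neighbors intrude within the
    repulsion radius: the point on the boundary of the cap of repulsion-sphere
    exit points nearest (along a geodesic) to the agent's own exit."""
    center = state.positions[i]
    d = np.linalg.norm(state.positions - center, axis=1)
    metric = np.where((d > 0) & (d <= repulsion_radius))[0]
    if metric.size == 0:
        raise ValueError("avoidance requires at least one metric neighbor within R")
    own = normalize(state.velocities[i])
    pts = [own]
    for j in metric:
        vj = state.velocities[j]
        if np.linalg.norm(vj) < 1e-12:
            pts.append(normalize(state.positions[j] - center))
            continue
        exit_pt = ray_sphere_exit(state.positions[j], normalize(vj), center, repulsion_radius)
        pts.append(normalize(exit_pt - center))
    cap = minimal_enclosing_cap(pts, sphere_radius=repulsion_radius)
    sep = angular_distance(cap.center, own)
    if sep > cap.theta + 1e-12:
        return own  # own exit already clear of the crowd cap
    if sep < 1e-12:
        axis = _k._perp3(cap.center)
        return _k._rodrigues(axis, cap.theta, cap.center)
    # nearest boundary point: along the geodesic center -> own exit, at theta
    return _boundary_toward(cap, own)


def _boundary_toward(cap: SphericalCap, u: np.ndarray) -> np.ndarray:
    """Point of the cap boundary on the geodesic from the cap center through u."""
    c = np.asarray(cap.center, dtype=float)
    d = angular_distance(c, u)
    return _k._slerp(c, np.asarray(u, dtype=float), d, cap.theta)


def _clamped_turn(heading: np.ndarray, target: np.ndarray, max_turn: float):
    """Rotate ``heading`` toward ``target`` by at most ``max_turn``; returns
    (direction, realized turn angle)."""
    dth = angular_distance(heading, target)
    if dth <= max_turn:
        return np.asarray(target, dtype=float), dth
    axis = np.cross(heading, target)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        axis = _k._perp3(np.asarray(heading, dtype=float))
    else:
        axis = axis / s
    return _k._rodrigues(axis, max_turn, np.asarray(heading, dtype=float)), max_turn


def next_velocity(
    i: int,
    cap: SphericalCap,
    current_heading: np.ndarray,
    rng: np.random.Generator,
    v_max: float,
    max_turn: float = np.pi / 2,
    kappa_power: float = 2.0,
) -> np.ndarray:
    """Sample the next heading from the interaction cap's self-tuned vMF noise,
    clamp the turn, and decelerate with the turn angle:
    ``speed = v_max * cos(dtheta / 2)``."""
    d = sample_vmf(np.asarray(cap.center), cap.theta, rng, kappa_power=kappa_power)
    heading = normalize(current_heading)
    d, dth = _clamped_turn(heading, d, max_turn)
    return v_max * np.cos(0.5 * dth) * d


# ---------------------------------------------------------------------------
# Synchronous step and full run
# ---------------------------------------------------------------------------


def _avoidance_phase(state: FlockState, config: SimConfig):
    """Phase 1: move every agent that has a repulsion-zone intruder.

    Returns (cur_positions, cur_velocities, active_mask): avoidance agents are
    already advanced; ``active`` marks the agents still awaiting phase 2.
    """
    pos = state.positions
    n = state.n_agents
    cur = pos.copy()
    vel = state.velocities.copy()
    active = np.ones(n, dtype=bool)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(config.repulsion_radius, output_type="ndarray")
    if len(pairs):
        for i in np.unique(pairs):
            d = avoidance_direction(i, state, config.repulsion_radius)
            heading = normalize(state.velocities[i])
            d, dth = _clamped_turn(heading, d, config.max_turn)
            vel[i] = config.v_max * np.cos(0.5 * dth) * d
            cur[i] = pos[i] + vel[i]
            active[i] = False
    return cur, vel, active


def step(
    state: FlockState,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    uniforms: np.ndarray | None = None,
) -> FlockState:
    """One synchronous update.  ``uniforms`` (N, 2) may be supplied instead of
    ``rng`` to drive the vMF draws from externally managed per-agent streams."""
    n = state.n_agents
    if uniforms is None:
        if rng is None:
            raise ValueError("provide either rng or uniforms")
        uniforms = rng.random((n, 2))
    uniforms = np.ascontiguousarray(uniforms, dtype=float)

    if n == 1:  # interaction-free control: pure ballistic flight
        v = config.v_max * normalize(state.velocities[0])
        new_pos = state.positions + v
        history = np.concatenate([state.history, new_pos[None]], axis=0)
        return FlockState(history=history, velocities=v[None].copy())

    cur, vel, active = _avoidance_phase(state, config)
    indptr, indices = _delaunay_csr(cur)
    new_vel = vel.copy()
    cap_theta = np.zeros(n)
    _k._phase2_kernel(
        np.ascontiguousarray(state.history),
        np.ascontiguousarray(cur),
        state.t,
        np.ascontiguousarray(vel),
        indptr,
        indices,
        float(config.v_max),
        float(config.max_turn),
        int(config.history_depth),
        float(config.kappa_power),
        float(config.kappa_scale),
        uniforms,
        active,
        new_vel,
        cap_theta,
    )
    cur[active] += new_vel[active]
    if not np.isfinite(cur).all():
        raise FloatingPointError(f"non-finite positions at step {state.t + 1}")
    history = np.concatenate([state.history, cur[None]], axis=0)
    return FlockState(history=history, velocities=new_vel)


def initial_state(config: SimConfig, rng: np.random.Generator) -> FlockState:
    """Positions uniform in a ball of radius ``init_radius_factor * N^(1/3) * R``,
    headings uniform on the sphere, speeds at ``v_max``."""
    n = config.n_agents
    radius = config.init_radius_factor * n ** (1.0 / 3.0) * config.repulsion_radius
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    pos = u * r[:, None]
    head = rng.normal(size=(n, 3))
    head /= np.linalg.norm(head, axis=1, keepdims=True)
    vel = config.v_max * head
    return FlockState(history=pos[None].copy(), velocities=vel)


def run_simulation(config: SimConfig, record_burn_in: bool = False) -> Trajectory:
    """Simulate ``burn_in + n_steps`` synchronous steps and return the
    post-burn-in trajectory (positions and velocities per step).

    Randomness: the master seed spawns one stream for the initial condition
    plus one independent substream per agent, so agent updates are
    order-independent and runs are bit-reproducible.
    """
    n = config.n_agents
    total = config.burn_in + config.n_steps
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n + 1)
    state0 = initial_state(config, np.random.default_rng(children[0]))

    # pre-draw each agent's uniform block (2 variates per step)
    uniforms = np.empty((total, n, 2))
    for i in range(n):
        uniforms[:, i, :] = np.random.default_rng(children[i + 1]).random((total, 2))

    traj = np.empty((total + 1, n, 3))
    vels = np.empty((total + 1, n, 3))
    traj[0] = state0.positions
    vels[0] = state0.velocities

    velocities = state0.velocities.copy()
    for t in range(total):
        state = FlockState(history=traj[: t + 1], velocities=velocities)
        if n == 1:
            v = config.v_max * normalize(velocities[0])
            traj[t + 1] = traj[t] + v
            vels[t + 1] = v
            velocities = vels[t + 1].copy()
            continue
        cur, vel, active = _avoidance_phase(state, config)
        indptr, indices = _delaunay_csr(cur)
        new_vel = vel.copy()
        cap_theta = np.zeros(n)
        _k._phase2_kernel(
            traj[: t + 1],
            cur,
            t,
            vel,
            indptr,
            indices,
            float(config.v_max),
            float(config.max_turn),
            int(config.history_depth),
            float(config.kappa_power),
            float(config.kappa_scale),
            uniforms[t],
            active,
            new_vel,
            cap_theta,
        )
        cur[active] += new_vel[active]
        traj[t + 1] = cur
        vels[t + 1] = new_vel
        velocities = new_vel
        if not np.isfinite(cur).all():
            raise FloatingPointError(f"non-finite positions at step {t + 1}")

    start = 0 if record_burn_in else config.burn_in
    return Trajectory(
        positions=traj[start + 1 :].copy(),
        velocities=vels[start + 1 :].copy(),
        config=config,
    )
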