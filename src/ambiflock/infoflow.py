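"""Information flow between scale-free-induced subgroups and group turning.

Pipeline: the flock is split every step into two subgroups by consensus
2-means clustering of (position, unit fluctuation) features - the correlated
domains induced by scale-free correlation - and the groups are reindexed
into *leader* (front along the mean heading) and *follower*.  The flock's
future behavior is summarized by the curvature ``K(t)`` of its
center-of-mass trajectory; low-``K`` stretches are ballistic, high-``K``
stretches are group turns.  Mutual information between the per-group average
velocity (or fluctuation) vectors and ``K(t)`` is then decomposed with
two-input partial information decomposition (PID)

    I({X1, X2}; K) = R + U1 + U2 + S

into redundancy, two unique flows and synergy.  The default estimator is
Gaussian-copula MI with minimum-mutual-information (MMI) redundancy
``R = min(I(X1;K), I(X2;K))``, which keeps every component non-negative for
two sources; a discrete plug-in estimator (quantile-binned for continuous
data) with an optional common-change-in-surprisal redundancy is available
for cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "SubgroupLabeling",
    "CurvatureSeries",
    "PIDResult",
    "partition_subgroups",
    "reindex_leader_follower",
    "label_survival",
    "subgroup_averages",
    "curvature_series",
    "regime_mask",
    "mutual_information",
    "pid_decompose",
    "coupling_analysis",
    "turning_information_pipeline",
]


@dataclass(frozen=True)
class SubgroupLabeling:
    """Per-agent binary labels (1 = leader after reindexing) and per-agent
    consensus counts over the k-means restarts."""

    labels: np.ndarray
    consensus: np.ndarray


@dataclass(frozen=True)
class CurvatureSeries:
    K: np.ndarray
    window: int


@dataclass(frozen=True)
class PIDResult:
    """Two-input PID of I({X1, X2}; Z), in bits."""

    total: float
    redundancy: float
    unique1: float
    unique2: float
    synergy: float
    estimator: str

    def components(self) -> np.ndarray:
        return np.array([self.redundancy, self.unique1, self.unique2, self.synergy])


# ---------------------------------------------------------------------------
# Scale-free induced subgroups
# ---------------------------------------------------------------------------


def partition_subgroups(
    positions: np.ndarray,
    fluctuations: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int = 20,
    position_scale: float = 1.0,
) -> SubgroupLabeling:
    """Two-way consensus split of the flock from (position, unit fluctuation)
    features.

    Features are the centered positions in raw length units next to the
    unit-normalized fluctuations, exactly the input pair a stock k-means
    receives; with flocks much larger than 1 length unit the split is
    position-led and spatially coherent, with the fluctuation domains
    tipping the boundary.  ``position_scale`` divides the positions first
    (e.g. the flock size) to re-balance the two blocks.  Lloyd's 2-means is
    run ``n_restarts`` times with random initialization, restart labelings
    are aligned to the first by majority overlap, and each agent receives
    its majority label (the consensus count records how often it won).
    """
    pos = np.asarray(positions, dtype=float)
    u = np.asarray(fluctuations, dtype=float)
    n = pos.shape[0]
    if n < 10:
        raise ValueError("need at least 10 agents")
    un = np.linalg.norm(u, axis=1, keepdims=True)
    un[un == 0] = 1.0
    feats = np.hstack([(pos - pos.mean(0)) / position_scale, u / un])
    votes = np.zeros(n, dtype=int)
    ref = None
    done = 0
    attempts = 0
    while done < n_restarts and attempts < 4 * n_restarts:
        attempts += 1
        km = KMeans(
            n_clusters=2,
            n_init=1,
            init="random",
            random_state=int(rng.integers(2 ** 31 - 1)),
        ).fit(feats)
        lab = km.labels_.astype(int)
        if lab.min() == lab.max():
            continue  # empty cluster: discard restart
        if ref is None:
            ref = lab
        if np.mean(lab == ref) < 0.5:
            lab = 1 - lab
        votes += lab
        done += 1
    if done == 0:
        raise RuntimeError("2-means failed to produce a two-group split")
    labels = (votes * 2 >= done).astype(int)
    consensus = np.maximum(votes, done - votes)
    return SubgroupLabeling(labels=labels, consensus=consensus)


def reindex_leader_follower(
    positions: np.ndarray, velocities: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Relabel so that label 1 is the *leader* group: the one whose centroid
    projects furthest along the flock's mean heading."""
    pos = np.asarray(positions, dtype=float)
    mean_dir = np.asarray(velocities, dtype=float).mean(axis=0)
    nrm = np.linalg.norm(mean_dir)
    if nrm == 0:
        return np.asarray(labels, dtype=int)
    mean_dir = mean_dir / nrm
    labels = np.asarray(labels, dtype=int)
    proj0 = pos[labels == 0] @ mean_dir
    proj1 = pos[labels == 1] @ mean_dir
    if proj0.size == 0 or proj1.size == 0:
        return labels
    return labels if proj1.mean() >= proj0.mean() else 1 - labels


def label_survival(labels_over_time: np.ndarray, lag: int, match_labels: bool = True) -> float:
    """Fraction of agents still in the same subgroup after ``lag`` steps,
    averaged over all start times.

    With ``match_labels`` (default) the two partitions are compared under
    the best binary label matching, so the statistic measures persistence of
    the subgroups *as sets* and is immune to leader/follower identity flips
    while the flock turns; without it, raw per-agent label agreement is
    scored.
    """
    lab = np.asarray(labels_over_time, dtype=int)
    if lag < 1 or lag >= lab.shape[0]:
        raise ValueError("lag out of range")
    agree = np.mean(lab[lag:] == lab[:-lag], axis=1)
    if match_labels:
        agree = np.maximum(agree, 1.0 - agree)
    return float(np.mean(agree))


def subgroup_averages(
    velocities: np.ndarray, fluctuations: np.ndarray, labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-group mean velocity and fluctuation vectors."""
    v = np.asarray(velocities, dtype=float)
    u = np.asarray(fluctuations, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = {}
    for name, g in (("follower", 0), ("leader", 1)):
        mask = labels == g
        if not mask.any():
            raise ValueError(f"empty {name} group")
        out[f"V_{name}"] = v[mask].mean(axis=0)
        out[f"F_{name}"] = u[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Curvature of the center-of-mass trajectory
# ---------------------------------------------------------------------------


def _menger_curvature_vectors(path: np.ndarray) -> np.ndarray:
    """Per-point curvature vectors of a 3D path from consecutive triples:
    magnitude 1/circumradius (Menger curvature), direction from the middle
    point toward the circumcenter; collinear triples give the zero vector.
    Entry ``t`` corresponds to path point ``t + 1``."""
    p0, p1, p2 = path[:-2], path[1:-1], path[2:]
    a = p0 - p1
    b = p2 - p1
    c = p2 - p0
    cross = np.cross(a, b)
    cn = np.linalg.norm(cross, axis=1)
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    out = np.zeros_like(p1)
    ok = cn > 1e-12 * np.maximum(la * lb, 1e-300)
    if ok.any():
        kmag = 2.0 * cn[ok] / (la[ok] * lb[ok] * lc[ok])
        # circumcenter direction: in-plane, perpendicular bisector construction
        aa, bb = a[ok], b[ok]
        la2 = (aa * aa).sum(1)
        lb2 = (bb * bb).sum(1)
        cr = cross[ok]
        cr2 = (cr * cr).sum(1)
        center_off = (
            np.cross(la2[:, None] * aa - lb2[:, None] * bb, cr) / (2.0 * cr2)[:, None]
        )
        dirn = center_off / np.linalg.norm(center_off, axis=1, keepdims=True)
        out[ok] = kmag[:, None] * dirn
    return out


def curvature_series(com_path: np.ndarray, window: int = 5) -> CurvatureSeries:
    """Windowed curvature ``K(t) = |sum_{t..t+window} k(s)| / window`` of the
    center-of-mass path: local zig-zags with zero net turning cancel, real
    group turns accumulate.  ``K(t)`` aligns with path point ``t``."""
    path = np.asarray(com_path, dtype=float)
    if path.shape[0] < window + 2:
        raise ValueError("path too short for the curvature window")
    k = _menger_curvature_vectors(path)  # k[t] belongs to point t+1
    csum = np.cumsum(np.vstack([np.zeros(3), k]), axis=0)
    seg = csum[window:] - csum[:-window]  # sums of `window` consecutive k's
    K = np.linalg.norm(seg, axis=1) / window
    return CurvatureSeries(K=K, window=window)


def regime_mask(K: np.ndarray, k_low: float = 0.05, k_high: float = 0.10):
    """Pointwise regime labels: ballistic (``K < k_low``), turning
    (``K > k_high``); the band in between belongs to neither."""
    K = np.asarray(K, dtype=float)
    return {"ballistic": K < k_low, "turning": K > k_high}


# ---------------------------------------------------------------------------
# Mutual information and PID
# ---------------------------------------------------------------------------


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _copula_transform(x: np.ndarray) -> np.ndarray:
    """Marginal rank-normalization to standard-normal scores (the Gaussian
    copula); invariant to monotone transforms of each column."""
    x = _as_2d(x)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        r = stats.rankdata(x[:, j], method="average")
        out[:, j] = stats.norm.ppf(r / (n + 1.0))
    return out


def _gaussian_mi_bits(x: np.ndarray, z: np.ndarray) -> float:
    """MI of jointly Gaussian blocks from covariance determinants, in bits."""
    x = _as_2d(x)
    z = _as_2d(z)
    xz = np.hstack([x, z])

    def _ridged(c):
        c = np.atleast_2d(c)
        # tiny ridge keeps duplicated/collinear blocks finite; it cancels
        # between numerator and denominator to leading order
        return c + 1e-10 * np.trace(c) / c.shape[0] * np.eye(c.shape[0])

    (s_x, ld_x) = np.linalg.slogdet(_ridged(np.cov(x, rowvar=False)))
    (s_z, ld_z) = np.linalg.slogdet(_ridged(np.cov(z, rowvar=False)))
    (s_xz, ld_xz) = np.linalg.slogdet(_ridged(np.cov(xz, rowvar=False)))
    if min(s_x, s_z, s_xz) <= 0:
        raise ValueError("degenerate covariance in MI estimate")
    return float(0.5 * (ld_x + ld_z - ld_xz) / np.log(2.0))


def _discrete_mi_bits(x: np.ndarray, z: np.ndarray) -> float:
    """Plug-in MI between two discrete (integer-coded) variables, in bits."""
    xi, x_inv = np.unique(x, axis=0, return_inverse=True)
    zi, z_inv = np.unique(z, axis=0, return_inverse=True)
    joint = np.zeros((len(xi), len(zi)))
    np.add.at(joint, (x_inv, z_inv), 1.0)
    joint /= joint.sum()
    px = joint.sum(1, keepdims=True)
    pz = joint.sum(0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ pz)[nz])).sum())


def _quantile_bin(x: np.ndarray, bins: int) -> np.ndarray:
    x = _as_2d(x)
    out = np.empty(x.shape, dtype=int)
    n = x.shape[0]
    for j in range(x.shape[1]):
        r = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.minimum((r / (n + 1.0) * bins).astype(int), bins - 1)
    # combine columns into one discrete symbol
    sym = out[:, 0].copy()
    for j in range(1, x.shape[1]):
        sym = sym * bins + out[:, j]
    return sym


def mutual_information(
    x: np.ndarray,
    z: np.ndarray,
    estimator: str = "copula",
    bins: int = 8,
) -> float:
    """MI between a (possibly multivariate) input block and an output, bits.

    ``"copula"``: Gaussian-copula estimator (rank-normalize marginals, then
    Gaussian MI); robust for continuous data and invariant to monotone
    marginal transforms.  ``"discrete"``: plug-in estimator on integer codes
    (continuous inputs are quantile-binned into ``bins`` levels first).
    """
    x = _as_2d(x)
    z = _as_2d(z)
    if x.shape[0] != z.shape[0]:
        raise ValueError("series must be aligned")
    if np.ptp(z) == 0:
        warnings.warn("constant output: MI = 0")
        return 0.0
    if estimator == "copula":
        return max(_gaussian_mi_bits(_copula_transform(x), _copula_transform(z)), 0.0)
    if estimator == "discrete":
        xd = x if np.issubdtype(np.asarray(x).dtype, np.integer) else _quantile_bin(x, bins)
        zd = z if np.issubdtype(np.asarray(z).dtype, np.integer) else _quantile_bin(z, bins)
        return _discrete_mi_bits(np.asarray(xd).reshape(len(z), -1), np.asarray(zd).reshape(len(z), -1))
    raise ValueError(f"unknown estimator {estimator!r}")


def _ccs_redundancy_bits(x1: np.ndarray, x2: np.ndarray, z: np.ndarray) -> float:
    """Common-change-in-surprisal redundancy on discrete codes: pointwise
    co-information terms kept only where both single-source local informations
    and the co-information share one sign."""
    codes = [np.unique(v, axis=0, return_inverse=True)[1] for v in (x1, x2, z)]
    c1, c2, cz = codes
    n1, n2, nz = (c.max() + 1 for c in codes)
    p = np.zeros((n1, n2, nz))
    np.add.at(p, (c1, c2, cz), 1.0)
    p /= p.sum()
    p1z = p.sum(1)
    p2z = p.sum(0)
    pz = p.sum((0, 1))
    p1 = p.sum((1, 2))
    p2 = p.sum((0, 2))
    red = 0.0
    nz_idx = np.argwhere(p > 0)
    for i, j, k in nz_idx:
        i1 = np.log2(p1z[i, k] / (p1[i] * pz[k]))
        i2 = np.log2(p2z[j, k] / (p2[j] * pz[k]))
        i12 = np.log2(p[i, j, k] / (p[i, j, :].sum() * pz[k]))
        co = i1 + i2 - i12
        # a term counts as common change in surprisal only when the two
        # single-source informations, the joint information and the
        # co-information all move the same way
        if i1 > 0 and i2 > 0 and i12 > 0 and co > 0:
            red += p[i, j, k] * co
        elif i1 < 0 and i2 < 0 and i12 < 0 and co < 0:
            red += p[i, j, k] * co
    return float(red)


def pid_decompose(
    x1: np.ndarray,
    x2: np.ndarray,
    z: np.ndarray,
    estimator: str = "copula",
    redundancy: str = "mmi",
    bins: int = 8,
) -> PIDResult:
    """Two-input PID of ``I({x1, x2}; z)``.

    With the default MMI redundancy ``R = min(I(x1;z), I(x2;z))`` all four
    components are non-negative for two sources and the decomposition
    identity holds exactly by construction.  ``redundancy="ccs"`` (discrete
    estimator only) uses the common-change-in-surprisal measure instead.
    """
    x1 = _as_2d(x1)
    x2 = _as_2d(x2)
    z = _as_2d(z)
    i1 = mutual_information(x1, z, estimator=estimator, bins=bins)
    i2 = mutual_information(x2, z, estimator=estimator, bins=bins)
    i12 = mutual_information(np.hstack([x1, x2]), z, estimator=estimator, bins=bins)
    if redundancy == "mmi":
        r = min(i1, i2)
    elif redundancy == "ccs":
        if estimator != "discrete":
            raise ValueError("ccs redundancy requires the discrete estimator")
        d1 = _quantile_bin(x1, bins) if not np.issubdtype(x1.dtype, np.integer) else x1.ravel()
        d2 = _quantile_bin(x2, bins) if not np.issubdtype(x2.dtype, np.integer) else x2.ravel()
        dz = _quantile_bin(z, bins) if not np.issubdtype(z.dtype, np.integer) else z.ravel()
        r = _ccs_redundancy_bits(d1, d2, dz)
    else:
        raise ValueError(f"unknown redundancy measure {redundancy!r}")
    u1 = i1 - r
    u2 = i2 - r
    s = i12 - r - u1 - u2
    return PIDResult(
        total=i12,
        redundancy=r,
        unique1=u1,
        unique2=u2,
        synergy=s,
        estimator=f"{estimator}/{redundancy}",
    )


def coupling_analysis(
    velocity_pids: list[PIDResult], fluctuation_pids: list[PIDResult]
) -> pd.DataFrame:
    """Pearson correlations, across trials, between every velocity-input PID
    component and every fluctuation-input PID component.  Zero-variance
    components yield NaN entries."""
    if len(velocity_pids) != len(fluctuation_pids) or len(velocity_pids) < 3:
        raise ValueError("need matched per-trial PID lists (>= 3 trials)")
    names = ["R", "U1", "U2", "S"]
    v = np.array([p.components() for p in velocity_pids])
    f = np.array([p.components() for p in fluctuation_pids])
    out = np.full((4, 4), np.nan)
    for a in range(4):
        for b in range(4):
            if np.ptp(v[:, a]) == 0 or np.ptp(f[:, b]) == 0:
                continue
            out[a, b] = stats.pearsonr(v[:, a], f[:, b]).statistic
    return pd.DataFrame(out, index=[f"{n}_V" for n in names], columns=[f"{n}_F" for n in names])


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def turning_information_pipeline(
    traj,
    seed: int = 0,
    curvature_window: int = 5,
    k_low: float = 0.05,
    k_high: float = 0.10,
    n_restarts: int = 20,
    estimator: str = "copula",
    max_steps: int | None = None,
    fluct_lag: int = 5,
) -> dict:
    """Subgroups -> averages -> curvature -> regime MI -> turning-phase PID
    for one simulated trajectory.

    Returns per-step series (labels, K), regime mutual informations for the
    velocity and fluctuation inputs, and the turning-region PID of each.
    """
    from .macro_criticality import fluctuation_vectors
    from .micro_criticality import center_of_mass_frame

    rng = np.random.default_rng(seed)
    pos = traj.positions
    vel = traj.velocities
    internal = center_of_mass_frame(traj)
    T = pos.shape[0] - fluct_lag if max_steps is None else min(max_steps, pos.shape[0] - fluct_lag)
    labels = np.empty((T, pos.shape[1]), dtype=int)
    feats = {k: np.empty((T, 3)) for k in ("V_leader", "V_follower", "F_leader", "F_follower")}
    for t in range(T):
        # lag-smoothed displacement fluctuations cancel the per-step
        # sampling noise and expose the correlated domains
        u = fluctuation_vectors(internal[t + fluct_lag] - internal[t])
        part = partition_subgroups(pos[t], u, rng, n_restarts=n_restarts)
        lab = reindex_leader_follower(pos[t], vel[t], part.labels)
        labels[t] = lab
        means = subgroup_averages(vel[t], u, lab)
        for k in feats:
            feats[k][t] = means[k]

    com = pos[:T].mean(axis=1)
    K = curvature_series(com, window=curvature_window).K
    n = min(len(K), T)
    K = K[:n]
    masks = regime_mask(K, k_low=k_low, k_high=k_high)

    def mi_pair(a, b, mask):
        x = np.hstack([feats[a][:n][mask], feats[b][:n][mask]])
        return mutual_information(x, K[mask], estimator=estimator)

    result = {"labels": labels, "K": K, "masks": masks, "features": feats}
    for kind, (a, b) in {
        "V": ("V_leader", "V_follower"),
        "F": ("F_leader", "F_follower"),
    }.items():
        for regime, mask in masks.items():
            if mask.sum() >= 50:
                result[f"I_{kind}_{regime}"] = mi_pair(a, b, mask)
            else:
                result[f"I_{kind}_{regime}"] = np.nan
        if masks["turning"].sum() >= 50:
            m = masks["turning"]
            result[f"pid_{kind}"] = pid_decompose(
                feats[a][:n][m], feats[b][:n][m], K[m], estimator=estimator
            )
        else:
            result[f"pid_{kind}"] = None
    return result
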