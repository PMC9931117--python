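"""Group-level statistics: anomalous diffusion, scale-free correlation,
polarity and flock morphology.

* **Super diffusion**: the mean squared displacement of center-of-mass-frame
  positions, averaged over agents and all time origins,
  ``dr^2(t) = <[x_i(t0 + t) - x_i(t0)]^2>``, is fitted as ``D * t^alpha``;
  ``1 < alpha < 2`` is super-diffusive.
* **Scale-free correlation**: the spatial correlation function of velocity
  fluctuations ``u_i = v_i - <v>``,
  ``C(r) = sum_ij u_i.u_j delta(r - r_ij) / (c0 sum_ij delta(r - r_ij))``,
  crosses zero at the correlation length ``xi``; scale-freeness means
  ``xi = a * L`` with ``L`` the flock size (max pairwise distance).
* **Morphology**: polarity ``P = |sum v_hat_i| / N``, alpha-shape volume
  ``V_alpha`` and group skewness ``1 - V_alpha / V_conv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .flock_sim import Trajectory

__all__ = [
    "DiffusionFit",
    "CorrelationCurve",
    "FlockSnapshotMetrics",
    "msd",
    "fit_diffusion",
    "fluctuation_vectors",
    "correlation_length",
    "snapshot_metrics",
    "scale_free_regression",
    "polarity_series",
    "flock_size",
]


@dataclass(frozen=True)
class DiffusionFit:
    D: float
    alpha: float
    t_lo: int
    t_hi: int


@dataclass(frozen=True)
class CorrelationCurve:
    r: np.ndarray
    C: np.ndarray
    c0: float


@dataclass(frozen=True)
class FlockSnapshotMetrics:
    polarity: float
    flock_size: float
    v_alpha: float
    v_conv: float
    skewness: float


# ---------------------------------------------------------------------------
# Mean squared displacement and diffusion exponent
# ---------------------------------------------------------------------------


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """All-time-origin MSD of one (T, d) track in O(T log T) via FFT."""
    T = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    s2 = np.zeros(T)
    for dim in range(x.shape[1]):
        f = np.fft.rfft(x[:, dim], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:T]
        s2 += ac
    d = (x ** 2).sum(axis=1)
    q = 2.0 * d.sum()
    s1 = np.empty(T)
    s1[0] = q
    for m in range(1, T):
        q -= d[m - 1] + d[T - m]
        s1[m] = q
    counts = T - np.arange(T)
    return s1 / counts - 2.0 * s2 / counts


def msd(internal: np.ndarray) -> np.ndarray:
    """Mean squared displacement curve of center-of-mass-frame positions
    (T, N, 3), averaged over agents and over all time origins; entry ``t``
    is the MSD at lag ``t`` (entry 0 is 0)."""
    internal = np.asarray(internal, dtype=float)
    T, N, _ = internal.shape
    out = np.zeros(T)
    for i in range(N):
        out += _msd_fft_single(internal[:, i, :])
    return out / N


def fit_diffusion(curve: np.ndarray, t_lo: int = 10, t_hi: int | None = None) -> DiffusionFit:
    """Least squares of ``log dr^2`` on ``log t`` over ``[t_lo, t_hi]``
    (default upper end: a tenth of the curve, the intermediate-time window
    before finite-trajectory saturation)."""
    curve = np.asarray(curve, dtype=float)
    T = curve.size
    if t_hi is None:
        t_hi = max(T // 10, t_lo + 10)
    t_hi = min(t_hi, T - 1)
    if t_hi - t_lo < 9:
        raise ValueError("need at least 10 points in the fit window")
    t = np.arange(t_lo, t_hi + 1)
    y = curve[t_lo : t_hi + 1]
    if np.any(y <= 0):
        raise ValueError("nonpositive MSD values in fit window")
    slope, intercept = np.polyfit(np.log(t), np.log(y), 1)
    return DiffusionFit(D=float(np.exp(intercept)), alpha=float(slope), t_lo=t_lo, t_hi=t_hi)


# ---------------------------------------------------------------------------
# Scale-free correlation
# ---------------------------------------------------------------------------


def fluctuation_vectors(velocities: np.ndarray) -> np.ndarray:
    """Fluctuations about the instantaneous group mean, ``u_i = v_i - <v>``
    (they sum to zero by construction)."""
    v = np.asarray(velocities, dtype=float)
    return v - v.mean(axis=0, keepdims=True)


def flock_size(positions: np.ndarray) -> float:
    """Maximum pairwise distance between agents."""
    pos = np.asarray(positions, dtype=float)
    try:
        pts = pos[ConvexHull(pos).vertices]
    except QhullError:
        pts = pos
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return float(d.max())


def correlation_length(
    positions: np.ndarray,
    quantity: np.ndarray,
    n_bins: int = 50,
) -> tuple[CorrelationCurve, float]:
    """Spatial correlation function of per-agent fluctuations and its first
    zero crossing ``xi``.

    ``quantity`` is either (N, 3) vector fluctuations (orientation mode) or
    (N,) scalar fluctuations (speed mode).  The delta function is realized by
    distance binning (width = flock size / ``n_bins``), the first bin holds
    the self-pairs so ``C(0) = 1`` after normalization, and ``xi`` is found
    by linear interpolation between the bins bracketing the sign change.
    With no crossing (e.g. all fluctuations parallel), ``xi`` falls back to
    the flock size with a warning.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(quantity, dtype=float)
    n = pos.shape[0]
    if n < 10:
        raise ValueError("need at least 10 agents")
    L = flock_size(pos)
    edges = np.linspace(0.0, L * (1 + 1e-9), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    iu, ju = np.triu_indices(n, k=0)  # include self-pairs (bin 0)
    rij = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    if q.ndim == 1:
        prod = q[iu] * q[ju]
    else:
        prod = np.einsum("ij,ij->i", q[iu], q[ju])
    idx = np.clip(np.digitize(rij, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=prod, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        raw = sums / counts
    c0 = raw[0]
    if not np.isfinite(c0) or c0 == 0:
        raise ValueError("degenerate fluctuations: zero self-correlation")
    C = raw / c0
    curve = CorrelationCurve(r=centers, C=C, c0=float(c0))
    valid = counts > 0
    xi = None
    prev_r, prev_c = 0.0, 1.0
    for r, c in zip(centers[valid], C[valid]):
        if c < 0:
            xi = prev_r + (0.0 - prev_c) * (r - prev_r) / (c - prev_c)
            break
        prev_r, prev_c = r, c
    if xi is None:
        warnings.warn("correlation function has no zero crossing; using flock size")
        xi = L
    return curve, float(xi)


def lagged_velocities(internal: np.ndarray, t: int, dt: int) -> np.ndarray:
    """Lag-``dt`` displacement vectors ``x(t+dt) - x(t)`` of the
    center-of-mass-frame positions, the noise-robust velocity estimate used
    for correlation analysis."""
    return internal[t + dt] - internal[t]


def orientation_correlation_length(internal, t, dt=2, n_bins=50):
    """Correlation length of directional fluctuations at snapshot ``t``."""
    v = lagged_velocities(internal, t, dt)
    u = fluctuation_vectors(v)
    return correlation_length(internal[t], u, n_bins=n_bins)


def speed_correlation_length(internal, t, dt=2, n_bins=50):
    """Correlation length of scalar speed fluctuations at snapshot ``t``
    (the scalar analogue of the directional estimator)."""
    v = lagged_velocities(internal, t, dt)
    sp = np.linalg.norm(v, axis=1)
    return correlation_length(internal[t], sp - sp.mean(), n_bins=n_bins)


def scale_free_regression(L: np.ndarray, xi: np.ndarray) -> tuple[float, float]:
    """Through-origin slope of ``xi = a * L`` plus the Pearson correlation of
    the (L, xi) pairs."""
    L = np.asarray(L, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if L.size < 2 or np.ptp(L) == 0:
        raise ValueError("need variation in L")
    a = float((L * xi).sum() / (L * L).sum())
    r = float(stats.pearsonr(L, xi).statistic)
    return a, r


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------


def _tet_volume(p: np.ndarray) -> np.ndarray:
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def _circumradius(p: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (n, 4, 3), via the linear system for
    the circumcenter; degenerate tetrahedra get radius inf."""
    a = p[:, 0]
    rhs = np.empty((p.shape[0], 3))
    mat = np.empty((p.shape[0], 3, 3))
    for k in range(3):
        d = p[:, k + 1] - a
        mat[:, k, :] = 2.0 * d
        rhs[:, k] = np.einsum("ij,ij->i", d, d)
    out = np.full(p.shape[0], np.inf)
    det = np.linalg.det(mat)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(mat[ok], rhs[ok][..., None])[..., 0]
        out[ok] = np.linalg.norm(centers, axis=1)
    return out


def alpha_shape_volume(positions: np.ndarray, alpha: float | None = None) -> tuple[float, float]:
    """(V_alpha, alpha): volume of the 3D alpha-shape, computed as the union
    of Delaunay tetrahedra with circumradius below ``alpha``.

    ``alpha`` defaults to twice the median nearest-neighbor distance, which
    tracks the flock's local density.
    """
    pos = np.asarray(positions, dtype=float)
    if alpha is None:
        nn = cKDTree(pos).query(pos, k=2)[0][:, 1]
        alpha = 2.0 * float(np.median(nn))
    try:
        tri = Delaunay(pos)
    except QhullError:
        return 0.0, float(alpha)
    tets = pos[tri.simplices]
    keep = _circumradius(tets) < alpha
    return float(_tet_volume(tets[keep]).sum()), float(alpha)


def snapshot_metrics(
    positions: np.ndarray, velocities: np.ndarray, alpha: float | None = None
) -> FlockSnapshotMetrics:
    """Polarity, flock size, alpha-shape volume and skewness of one snapshot."""
    pos = np.asarray(positions, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    if pos.shape[0] < 4:
        raise ValueError("need at least 4 agents")
    vhat = vel / np.linalg.norm(vel, axis=1, keepdims=True)
    P = float(np.linalg.norm(vhat.mean(axis=0)))
    L = flock_size(pos)
    try:
        v_conv = float(ConvexHull(pos).volume)
    except QhullError:
        v_conv = 0.0
    v_alpha, _ = alpha_shape_volume(pos, alpha=alpha)
    v_alpha = min(v_alpha, v_conv)
    skew = 1.0 - v_alpha / v_conv if v_conv > 0 else 0.0
    return FlockSnapshotMetrics(
        polarity=P, flock_size=L, v_alpha=v_alpha, v_conv=v_conv, skewness=float(skew)
    )


def polarity_series(traj: Trajectory) -> np.ndarray:
    """Group polarity ``P(t) = |sum_i v_hat_i| / N`` for every recorded step."""
    sp = np.linalg.norm(traj.velocities, axis=2, keepdims=True)
    vhat = traj.velocities / sp
    return np.linalg.norm(vhat.mean(axis=1), axis=1)
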