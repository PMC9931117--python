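"""Individual-level criticality statistics in the center-of-mass frame.

Two micro-scale signatures are quantified for each agent's *internal*
trajectory ``x_i(t) = r_i(t) - r_CM(t)``:

* **Lévy-walk structure in space**: displacements below a pause threshold
  ``dr`` are treated as pauses; the path lengths of the runs between pauses
  ("steps") are fitted with a doubly truncated power law
  ``P(l) ~ l^-mu / (l_min^(1-mu) - l_max^(1-mu))`` by maximum likelihood,
  with a Kolmogorov-Smirnov goodness test and an Akaike weight against a
  truncated exponential.  ``mu ~ 2`` is the Lévy-optimal regime.
* **1/f structure in time**: the velocity-variation series
  ``||x_i(t) - x_i(t-1)||`` is summarized by the spectral exponent gamma of
  a ``f^-gamma`` fit to its Welch periodogram; ``gamma ~ 1`` is pink noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .flock_sim import Trajectory

__all__ = [
    "StepLengthFit",
    "SpectralFit",
    "center_of_mass_frame",
    "extract_step_lengths",
    "truncated_powerlaw_cdf",
    "sample_truncated_powerlaw",
    "fit_truncated_powerlaw",
    "spectral_exponent",
    "velocity_variation",
]


@dataclass(frozen=True)
class StepLengthFit:
    """Truncated-power-law fit of a step-length sample."""

    mu: float
    l_min: float
    l_max: float
    ks_p: float
    aic_weight: float
    n_steps: int


@dataclass(frozen=True)
class SpectralFit:
    """Power-law spectrum fit: power ~ f^-gamma over [f_lo, f_hi]."""

    gamma: float
    f_lo: float
    f_hi: float


def center_of_mass_frame(traj: Trajectory | np.ndarray) -> np.ndarray:
    """Internal trajectories ``x_i(t) = r_i(t) - r_CM(t)``, shape (T, N, 3).

    The agent-mean of the result is zero at every step by construction.
    """
    pos = traj.positions if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    return pos - pos.mean(axis=1, keepdims=True)


def velocity_variation(internal: np.ndarray) -> np.ndarray:
    """Per-agent series ``||x_i(t) - x_i(t-1)||``, shape (T-1, N)."""
    return np.linalg.norm(np.diff(internal, axis=0), axis=2)


def extract_step_lengths(track: np.ndarray, dr: float) -> np.ndarray:
    """Step lengths of one internal track (T, 3).

    A frame whose displacement is below ``dr`` is a pause; a step is the
    cumulative path length of a maximal run of non-pause frames.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    track = np.asarray(track, dtype=float)
    d = np.linalg.norm(np.diff(track, axis=0), axis=1)
    moving = d >= dr
    if not moving.any():
        return np.empty(0)
    # boundaries of maximal runs of moving frames
    padded = np.concatenate(([False], moving, [False]))
    starts = np.where(~padded[:-1] & padded[1:])[0]
    ends = np.where(padded[:-1] & ~padded[1:])[0]
    cum = np.concatenate(([0.0], np.cumsum(d)))
    return cum[ends] - cum[starts]


# ---------------------------------------------------------------------------
# Truncated power law: sampling, MLE, goodness of fit
# ---------------------------------------------------------------------------


def truncated_powerlaw_cdf(l, mu: float, l_min: float, l_max: float):
    """CDF of the doubly truncated power law on [l_min, l_max]."""
    l = np.asarray(l, dtype=float)
    if abs(mu - 1.0) < 1e-9:
        return np.log(l / l_min) / np.log(l_max / l_min)
    a = l_min ** (1.0 - mu)
    b = l_max ** (1.0 - mu)
    return (a - l ** (1.0 - mu)) / (a - b)


def sample_truncated_powerlaw(
    mu: float, l_min: float, l_max: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of the truncated power law."""
    u = rng.random(size)
    if abs(mu - 1.0) < 1e-9:
        return l_min * (l_max / l_min) ** u
    a = l_min ** (1.0 - mu)
    b = l_max ** (1.0 - mu)
    return (a - u * (a - b)) ** (1.0 / (1.0 - mu))


def _tpl_negloglik(mu: float, logs: np.ndarray, l_min: float, l_max: float) -> float:
    n = logs.size
    if abs(mu - 1.0) < 1e-9:
        logz = np.log(np.log(l_max / l_min))
    else:
        z = (l_min ** (1.0 - mu) - l_max ** (1.0 - mu)) / (mu - 1.0)
        if z <= 0:
            return np.inf
        logz = np.log(z)
    return n * logz + mu * logs.sum()


def _texp_negloglik(lam: float, x: np.ndarray, l_min: float, l_max: float) -> float:
    if lam <= 0:
        return np.inf
    z = (np.exp(-lam * l_min) - np.exp(-lam * l_max)) / lam
    if z <= 0:
        return np.inf
    return x.size * np.log(z) + lam * x.sum()


def fit_truncated_powerlaw(
    lengths,
    mu_bounds: tuple[float, float] = (1.000001, 10.0),
    min_steps: int = 50,
    ks_method: str = "asymptotic",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> StepLengthFit:
    """Maximum-likelihood truncated-power-law fit of a step-length sample.

    The truncation bounds are the sample extremes.  ``ks_method`` selects the
    goodness-of-fit p-value: ``"asymptotic"`` (one-sample KS against the
    fitted CDF; fast, mildly optimistic) or ``"bootstrap"`` (Clauset-style
    parametric bootstrap with ``n_bootstrap`` replicates).  The Akaike weight
    compares the power law against a truncated exponential on the same
    support.
    """
    x = np.sort(np.asarray(lengths, dtype=float))
    if x.size < min_steps:
        raise ValueError(f"need at least {min_steps} steps, got {x.size}")
    l_min, l_max = float(x[0]), float(x[-1])
    if l_max <= l_min * (1 + 1e-12):
        raise ValueError("degenerate sample: all step lengths identical")
    logs = np.log(x)

    res = optimize.minimize_scalar(
        _tpl_negloglik, bounds=mu_bounds, args=(logs, l_min, l_max), method="bounded"
    )
    mu = float(res.x)
    ll_pl = -res.fun

    # exponential competitor on the same support
    lam0 = 1.0 / max(x.mean() - l_min, 1e-12)
    res_e = optimize.minimize_scalar(
        _texp_negloglik,
        bounds=(lam0 * 1e-3, lam0 * 1e3),
        args=(x, l_min, l_max),
        method="bounded",
    )
    ll_exp = -res_e.fun
    # both models have one free shape parameter, so AIC differences reduce to
    # log-likelihood differences; w_pl = exp(-AIC_pl/2) / sum
    diff = np.clip(ll_pl - ll_exp, -700.0, 700.0)
    aic_weight = float(1.0 / (1.0 + np.exp(-diff)))

    ks_stat = stats.kstest(x, lambda v: truncated_powerlaw_cdf(v, mu, l_min, l_max)).statistic
    if ks_method == "bootstrap":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_bootstrap):
            xb = np.sort(sample_truncated_powerlaw(mu, l_min, l_max, x.size, rng))
            lb = np.log(xb)
            rb = optimize.minimize_scalar(
                _tpl_negloglik, bounds=mu_bounds, args=(lb, xb[0], xb[-1]), method="bounded"
            )
            sb = stats.kstest(
                xb, lambda v: truncated_powerlaw_cdf(v, float(rb.x), xb[0], xb[-1])
            ).statistic
            if sb >= ks_stat:
                count += 1
        ks_p = count / n_bootstrap
    else:
        ks_p = float(stats.kstest(x, lambda v: truncated_powerlaw_cdf(v, mu, l_min, l_max)).pvalue)

    return StepLengthFit(
        mu=mu, l_min=l_min, l_max=l_max, ks_p=float(ks_p), aic_weight=aic_weight, n_steps=int(x.size)
    )


def fit_agent_steps(
    traj: Trajectory, dr: float | None = None, min_steps: int = 50
) -> list[StepLengthFit]:
    """Per-agent truncated-power-law fits for a whole trajectory.

    ``dr`` defaults to ``0.1 * v_max``.  Agents with fewer than ``min_steps``
    extracted steps are skipped.
    """
    if dr is None:
        dr = 0.1 * traj.config.v_max
    internal = center_of_mass_frame(traj)
    fits = []
    for i in range(traj.n_agents):
        lengths = extract_step_lengths(internal[:, i, :], dr)
        if lengths.size < min_steps or lengths.max() <= lengths.min() * (1 + 1e-12):
            continue
        fits.append(fit_truncated_powerlaw(lengths, min_steps=min_steps))
    return fits


# ---------------------------------------------------------------------------
# Spectral exponent
# ---------------------------------------------------------------------------


def spectral_exponent(
    series,
    nperseg: int = 1024,
    skip_low: int = 3,
    high_fraction: float = 0.75,
) -> SpectralFit:
    """Spectral exponent gamma of ``power ~ f^-gamma``.

    Welch periodogram (50% overlap) regressed as log power versus log
    frequency, excluding the ``skip_low`` lowest frequencies (finite-size)
    and frequencies above ``high_fraction`` of Nyquist (aliasing).  The
    result is invariant to the series mean and overall scale.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 512:
        raise ValueError("series too short for a stable spectrum (need >= 512)")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no spectral slope")
    nperseg = min(nperseg, x.size)
    f, p = signal.welch(x - x.mean(), nperseg=nperseg, noverlap=nperseg // 2)
    keep = slice(1 + skip_low, None)
    f, p = f[keep], p[keep]
    band = f <= high_fraction * f[-1]
    f, p = f[band], p[band]
    good = p > 0
    slope, _ = np.polyfit(np.log(f[good]), np.log(p[good]), 1)
    return SpectralFit(gamma=float(-slope), f_lo=float(f[0]), f_hi=float(f[-1]))


def agent_spectral_exponents(traj: Trajectory, **kwargs) -> np.ndarray:
    """Gamma of each agent's velocity-variation series."""
    internal = center_of_mass_frame(traj)
    vv = velocity_variation(internal)
    out = np.empty(traj.n_agents)
    for i in range(traj.n_agents):
        out[i] = spectral_exponent(vv[:, i], **kwargs).gamma
    return out
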