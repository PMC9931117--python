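"""Deterministic synthetic generators with known ground truth.

Each generator emulates exactly one statistical feature the analysis modules
measure, so every estimator can be validated against its generating
parameter without running the simulator: a truncated-power-law Lévy walker
for the step-length fit, spectrally synthesized colored noise for the 1/f
exponent, a two-domain correlated fluctuation field for the correlation
length and the subgroup partition, and jointly Gaussian triples with
closed-form mutual informations for the PID estimators.
"""

from __future__ import annotations

import numpy as np

from .micro_criticality import sample_truncated_powerlaw

__all__ = [
    "gen_levy_walk",
    "gen_colored_noise",
    "gen_correlated_field",
    "gen_gaussian_pid",
    "gen_circle_track",
]


def gen_levy_walk(
    mu: float,
    l_min: float,
    l_max: float,
    n_steps: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """3D Lévy walker: step lengths from the truncated power law, isotropic
    headings, unit speed, one explicit pause frame between steps.

    Returns ``(track, drawn_lengths)`` where ``track`` is (>= n_steps, 3) and
    ``drawn_lengths`` are the generator's ground-truth step lengths.
    """
    if not mu > 1:
        raise ValueError("mu must exceed 1")
    if not 0 < l_min < l_max:
        raise ValueError("need 0 < l_min < l_max")
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    lengths = []
    while len(pts) < n_steps:
        l = float(sample_truncated_powerlaw(mu, l_min, l_max, 1, rng)[0])
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n_full = int(np.floor(l))
        pos = pts[-1]
        for _ in range(n_full):  # unit-speed interpolation
            pos = pos + d
            pts.append(pos)
        frac = l - n_full
        if frac > 0:
            pos = pos + frac * d
            pts.append(pos)
        pts.append(pos)  # explicit 1-frame pause
        lengths.append(l)
    return np.array(pts), np.array(lengths)


def gen_colored_noise(gamma: float, n: int, seed: int) -> np.ndarray:
    """Zero-mean series with power spectrum ~ f^-gamma, by spectral synthesis
    (amplitudes f^(-gamma/2), random phases)."""
    if not 0 <= gamma <= 3:
        raise ValueError("gamma out of supported range [0, 3]")
    if n % 2:
        raise ValueError("n must be even for the FFT grid")
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-gamma / 2.0)
    phases = np.exp(2j * np.pi * rng.random(len(f)))
    spec = amp * phases
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_correlated_field(
    n_agents: int,
    box: float = 10.0,
    interface_axis: int = 0,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions uniform in a cube plus fluctuation vectors forming two
    antiparallel spatial domains split at the box midplane, with small noise;
    the fluctuations are re-centered so they sum exactly to zero.

    Returns ``(positions, fluctuations)``.
    """
    if n_agents < 20:
        raise ValueError("need at least 20 agents")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n_agents, 3))
    w = np.zeros(3)
    w[(interface_axis + 1) % 3] = 1.0
    side = np.where(pos[:, interface_axis] < box / 2.0, 1.0, -1.0)
    u = side[:, None] * w[None, :] + noise * rng.normal(size=(n_agents, 3))
    u -= u.mean(axis=0, keepdims=True)
    return pos, u


def gen_gaussian_pid(
    rho1: float,
    rho2: float,
    rho12: float,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Jointly Gaussian scalars (x1, x2, z) with corr(x1, z) = rho1,
    corr(x2, z) = rho2, corr(x1, x2) = rho12, plus the closed-form mutual
    informations (bits) implied by the covariance.

    Returns ``(x1, x2, z, truth)`` with truth keys ``I1``, ``I2``, ``I12``.
    """
    cov = np.array(
        [
            [1.0, rho12, rho1],
            [rho12, 1.0, rho2],
            [rho1, rho2, 1.0],
        ]
    )
    if np.linalg.eigvalsh(cov).min() <= 1e-12:
        raise ValueError("correlation matrix is not positive definite")
    rng = np.random.default_rng(seed)
    sample = rng.multivariate_normal(np.zeros(3), cov, size=n)
    x1, x2, z = sample[:, 0], sample[:, 1], sample[:, 2]
    det_x = np.linalg.det(cov[:2, :2])
    det_full = np.linalg.det(cov)
    truth = {
        "I1": -0.5 * np.log2(1.0 - rho1 ** 2),
        "I2": -0.5 * np.log2(1.0 - rho2 ** 2),
        "I12": 0.5 * np.log2(det_x / det_full),
    }
    return x1, x2, z, truth


def gen_circle_track(radius: float, n: int, step_angle: float = 0.05) -> np.ndarray:
    """Planar circular path of ``n`` points, for curvature oracles
    (Menger curvature = 1/radius everywhere)."""
    t = step_angle * np.arange(n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
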