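"""Spherical-cap primitives for the ambiguous-interaction flocking model.

The interaction domains of the model are spherical caps living on a per-agent
"interaction sphere".  This module provides the exact geometric operations the
simulator is built from:

* rotations reconstructed from direction pairs (Rodrigues form) and their
  repeated application for turning-rate extrapolation,
* forward ray/sphere exit points,
* the *cover function*: the minimal enclosing cap of a set of points on the
  sphere,
* the maximal cap inscribed in the intersection of two caps,
* von Mises-Fisher (vMF) sampling, the spherical analogue of an isotropic
  Gaussian, used for the model's self-tuned noise.

All angles are radians; all vectors are Cartesian ``float64`` arrays.  A cap
is described by a unit ``center`` (its axis), an angular radius ``theta``
(polar half-angle, in ``[0, pi]``) and the carrier-sphere radius.  The solid
angle subtended by a cap is ``2*pi*(1 - cos(theta))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k

__all__ = [
    "SphericalCap",
    "RotationSpec",
    "normalize",
    "angular_distance",
    "rotation_from_pair",
    "predict_direction",
    "ray_sphere_exit",
    "minimal_enclosing_cap",
    "max_inscribed_cap",
    "cap_contains",
    "kappa_from_theta",
    "sample_vmf",
]

_UNIT_TOL = 1e-9


def normalize(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit norm (raises on zero vectors)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def _check_unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError(f"{name} must be unit-norm, got |v| = {np.linalg.norm(v)!r}")
    return v


def angular_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic angle between two unit vectors."""
    d = float(np.clip(np.dot(a, b), -1.0, 1.0))
    return float(np.arccos(d))


@dataclass(frozen=True)
class SphericalCap:
    """A spherical cap: unit axis ``center``, angular radius ``theta`` (rad),
    on a carrier sphere of radius ``sphere_radius``."""

    center: np.ndarray
    theta: float
    sphere_radius: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not -1e-12 <= self.theta <= np.pi + 1e-12:
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        _check_unit(self.center, "cap center")

    @property
    def solid_angle(self) -> float:
        """Solid angle subtended by the cap, ``2*pi*(1 - cos(theta))`` sr."""
        return float(2.0 * np.pi * (1.0 - np.cos(self.theta)))


@dataclass(frozen=True)
class RotationSpec:
    """An axis/angle rotation (Rodrigues form); ``angle`` in ``[0, pi]``."""

    axis: np.ndarray
    angle: float

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        _check_unit(self.axis, "rotation axis")
        if not -1e-12 <= self.angle <= np.pi + 1e-12:
            raise ValueError(f"angle must lie in [0, pi], got {self.angle}")

    def apply(self, v: np.ndarray) -> np.ndarray:
        return _k._rodrigues(self.axis, float(self.angle), np.asarray(v, dtype=float))


def rotation_from_pair(v_prev: np.ndarray, v_curr: np.ndarray) -> RotationSpec:
    """Rotation carrying ``v_prev`` onto ``v_curr``.

    The axis is the normalized cross product of the pair and the angle the
    angle between them.  Antiparallel inputs have no continuous axis; a
    deterministic perpendicular axis with angle pi is returned.
    """
    a = _check_unit(v_prev, "v_prev")
    b = _check_unit(v_curr, "v_curr")
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = float(np.clip(np.dot(a, b), -1.0, 1.0))
    if s < 1e-12:
        if c > 0.0:  # identical directions: identity (axis irrelevant)
            return RotationSpec(axis=_k._perp3(a), angle=0.0)
        return RotationSpec(axis=_k._perp3(a), angle=float(np.pi))
    return RotationSpec(axis=axis / s, angle=float(np.arctan2(s, c)))


def predict_direction(rot: RotationSpec, v: np.ndarray, n_applications: int) -> np.ndarray:
    """Apply ``rot`` to unit vector ``v`` ``n_applications`` times."""
    if n_applications < 0:
        raise ValueError("n_applications must be >= 0")
    out = _check_unit(v, "v").copy()
    # compose once: n applications about a fixed axis = one rotation by n*angle
    total = rot.angle * n_applications
    out = _k._rodrigues(rot.axis, float(total), out)
    return out / np.linalg.norm(out)


def ray_sphere_exit(
    origin: np.ndarray,
    direction: np.ndarray,
    sphere_center: np.ndarray,
    sphere_radius: float,
) -> np.ndarray:
    """Forward intersection of the ray ``origin + s*direction`` (s >= 0) with
    the sphere surface.  The origin must lie inside or on the sphere; an
    origin exactly on the surface moving outward exits at itself (s = 0)."""
    origin = np.asarray(origin, dtype=float)
    center = np.asarray(sphere_center, dtype=float)
    d = _check_unit(direction, "direction")
    if np.linalg.norm(origin - center) > sphere_radius * (1.0 + 1e-9):
        raise ValueError("ray origin lies outside the sphere")
    u = _k._ray_exit_unit(origin, d, center, float(sphere_radius))
    return center + sphere_radius * u


def minimal_enclosing_cap(points, sphere_radius: float = 1.0) -> SphericalCap:
    """The cover function: minimal spherical cap containing all unit vectors.

    Deterministic Welzl-style incremental construction with support sets of
    size <= 3 (ties broken by input order); point sets spreading beyond a
    hemisphere are handled by an exhaustive fallback, up to ``theta <= pi``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("minimal_enclosing_cap requires a nonempty point set")
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    norms = np.linalg.norm(pts, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("all points must be unit vectors")
    center, theta = _k._min_cap(np.ascontiguousarray(pts))
    return SphericalCap(center=center, theta=float(theta), sphere_radius=sphere_radius)


def max_inscribed_cap(a: SphericalCap, b: SphericalCap) -> SphericalCap:
    """Largest cap contained in the intersection of two caps (the model's
    next-direction domain ``C``).

    If one cap contains the other the smaller cap is returned.  For a proper
    lens intersection the result is centered on the geodesic between the two
    axes with ``theta = (theta_a + theta_b - d) / 2``.  An empty intersection
    degenerates to a zero-radius cap at the point minimizing the larger
    angular excess, giving a deterministic, noise-free direction.
    """
    if abs(a.sphere_radius - b.sphere_radius) > 1e-9 * max(a.sphere_radius, 1.0):
        raise ValueError("caps must live on the same carrier sphere")
    c, t = _k._max_inscribed(a.center, float(a.theta), b.center, float(b.theta))
    return SphericalCap(center=c, theta=float(t), sphere_radius=a.sphere_radius)


def cap_contains(cap: SphericalCap, p: np.ndarray, tol: float = 1e-12) -> bool:
    """True iff ``p`` lies within angular distance ``theta`` of the cap axis."""
    p = _check_unit(p, "p")
    return angular_distance(cap.center, p) <= cap.theta + tol


def kappa_from_theta(theta: float, power: float = 2.0, scale: float = 12.0) -> float:
    """Concentration of the self-tuned vMF noise for a cap of angular radius
    ``theta``: ``kappa = scale * theta**-power``.

    With ``power=2`` the angular standard deviation of the draw is
    ``theta / sqrt(scale)``: the cap is read as a ``sqrt(scale)``-sigma
    support region of the distribution.  Stability of an ordered flock
    requires roughly ``sqrt(scale) > sqrt(2 ln deg)`` (the next cap must
    cover ~deg draws of the noise it generates), i.e. scale above ~5-6 for
    typical Delaunay degrees; the default ``scale=12`` (cap ~ 3.5 sigma) is
    calibrated so that group polarity wanders through the 0.5-0.9 band
    instead of freezing or dissolving - the critical regime the model is
    built to exhibit.
    """
    if theta <= 0:
        return np.inf
    return float(scale * theta ** -power)


def sample_vmf(
    mean: np.ndarray,
    theta: float,
    rng: np.random.Generator,
    kappa_power: float = 2.0,
    kappa_scale: float = 12.0,
) -> np.ndarray:
    """Draw a unit vector from a von Mises-Fisher distribution whose mean
    direction is ``mean`` and whose concentration is ``kappa_from_theta``.

    ``theta = 0`` is the deterministic limit and returns ``mean`` exactly.
    Draws consume exactly two uniforms, so a seeded generator is
    bit-reproducible.
    """
    mean = _check_unit(mean, "mean")
    if theta < 1e-9:
        return mean.copy()
    kappa = kappa_from_theta(theta, power=kappa_power, scale=kappa_scale)
    u = rng.random(2)
    return _k._vmf_from_uniforms(mean, float(kappa), float(u[0]), float(u[1]))
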