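"""Rigid-body geometry: least-squares superposition and transforms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with a proper rotation (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis by ``angle`` radians (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("zero rotation axis")
    x, y, z = axis / norm
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Returns the proper rigid transform minimizing the RMSD of
    ``transform(moving)`` to ``fixed`` over the given 1:1 correspondence,
    together with that minimum RMSD in Å.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise GeometryError("superpose requires two equally shaped (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 corresponding atoms")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    # collinearity check: rank of the moving set
    if np.linalg.matrix_rank(a, tol=1e-6) < 2:
        raise GeometryError("superposition anchors are collinear")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transform = RigidTransform(rot, fc - rot @ mc)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(moving) - fixed) ** 2, axis=1))))
    return transform, rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations of the same atom list."""
    _, value = superpose(a, b)
    return value


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (>= 3).

    The sign follows the right-hand rule over the point order: the normal
    has positive dot product with the sum of cross products of consecutive
    centered points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered)
    normal = vt[2]
    rolled = np.roll(centered, -1, axis=0)
    handedness = np.cross(centered, rolled).sum(axis=0)
    if np.dot(normal, handedness) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)
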