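"""Rigid (rotation + translation) transforms in millimetre space.

Accuracy evaluation forbids scaling, so the only admissible map between a
test and a reference scan is a proper rigid motion; constructors enforce
orthonormality and det(+1) of the rotation block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch", "random_rigid_transform"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t`` (rotation in SO(3), mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    _TOL = 1e-9

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=100 * self._TOL):
            raise ValueError("rotation block is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-7:
            raise ValueError("rotation block must have determinant +1 (no reflection/scale)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def kabsch(source: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping ``source`` onto
    ``target`` (cross-covariance SVD with reflection correction).

    Minimizes sum of w_i * ||R s_i + t - g_i||^2 over proper rotations R and
    translations t.
    """
    P = np.asarray(source, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("source/target must be matching (n, 3) arrays")
    if weights is None:
        w = np.full(len(P), 1.0 / len(P))
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def random_rigid_transform(
    rng: np.random.Generator, max_rotation_deg: float, max_translation_mm: float
) -> RigidTransform:
    """Draw a uniform-axis rotation of magnitude U(0, max) and a translation
    of magnitude U(0, max) in a uniform direction."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    t = tdir * rng.uniform(0.0, max_translation_mm)
    return RigidTransform(R, t)
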