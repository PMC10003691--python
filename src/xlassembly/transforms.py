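"""Proper rigid-body transforms, the common currency of assemblies and poses.

Convention: rotation first, ``x' = R x + t``, coordinates in Angstrom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "ImproperRotationError"]


class ImproperRotationError(ValueError):
    """Raised when a transform's rotation part is not a proper rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x' = R x + t``.

    Parameters
    ----------
    rotation : (3, 3) array
        Orthonormal matrix with determinant +1.
    translation : (3,) array
        Translation in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float).reshape(3, 3)
        t = np.array(self.translation, dtype=float).reshape(3)
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_translation(t) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, dtype=float))

    def require_proper(self, det_tol: float = 1e-9, ortho_tol: float = 1e-8) -> "RigidTransform":
        """Validate orthonormality and det = +1; raise on reflections."""
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=ortho_tol):
            raise ImproperRotationError("rotation matrix is not orthonormal")
        det = float(np.linalg.det(R))
        if abs(det - 1.0) > det_tol:
            raise ImproperRotationError(
                f"rotation determinant is {det:.12f}, not +1 (reflections are not rigid motions)"
            )
        return self

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) or (3,) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ inner`` (apply *inner* first, then *self*)."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def to_flat(self) -> np.ndarray:
        """Row-major 3x3 rotation followed by the translation (12 numbers)."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        v = np.asarray(values, dtype=float).ravel()
        if v.size != 12:
            raise ValueError(f"expected 12 numbers (3x3 rotation + translation), got {v.size}")
        return cls(v[:9].reshape(3, 3), v[9:])
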