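"""Proper rigid-body transforms (rotation + translation) in Angstroms.

A :class:`RigidTransform` maps coordinates of the *second* interface into
the frame of the first: ``x' = R @ x + t``.  Only proper rotations
(det = +1) are ever constructed, so mirror superpositions are excluded by
construction throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1 (checked to 1e-8).
    translation : (3,) ndarray
        Translation vector in Angstroms.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        err = R.T @ R
        err[0, 0] -= 1.0
        err[1, 1] -= 1.0
        err[2, 2] -= 1.0
        if np.abs(err).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is improper (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def angle(self) -> float:
        """Rotation angle in radians, in [0, pi]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(self.angle))

    def distance_to(self, other: "RigidTransform") -> tuple[float, float]:
        """(relative rotation angle in degrees, translation difference in A).

        Computed from ``self ∘ other⁻¹``, the transform taking ``other``'s
        output frame onto ``self``'s.
        """
        rel = self.compose(other.inverse())
        return rel.angle_deg, float(np.linalg.norm(rel.translation))

    def is_close(self, other: "RigidTransform", rot_tol_deg: float, trans_tol: float) -> bool:
        ang, shift = self.distance_to(other)
        return ang <= rot_tol_deg and shift <= trans_tol
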