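"""2D rigid transforms (rotation + translation) in pixel coordinates.

The convention is origin-anchored: ``p' = R(angle) @ p + t`` with the
rotation about the coordinate origin. Helpers convert from the more
natural "rotate about the field centre, then shift" parameterisation used
when injecting inter-round drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]


def _rotation_matrix(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform:
    """Distance-preserving map ``p -> R(angle) p + translation``."""

    angle: float = 0.0  # radians, counter-clockwise in (x, y)
    translation: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0))

    @classmethod
    def from_center_rotation(
        cls, angle: float, shift: tuple[float, float], center: tuple[float, float]
    ) -> "RigidTransform":
        """Rotation by ``angle`` about ``center`` followed by ``shift``."""
        c = np.asarray(center, dtype=float)
        t = c - _rotation_matrix(angle) @ c + np.asarray(shift, dtype=float)
        return cls(angle, (float(t[0]), float(t[1])))

    @property
    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.angle)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + np.asarray(self.translation)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        t = -(_rotation_matrix(-self.angle) @ np.asarray(self.translation))
        return RigidTransform(-self.angle, (float(t[0]), float(t[1])))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        t = self.matrix @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform(self.angle + other.angle, (float(t[0]), float(t[1])))

    def displacement_at(self, point: tuple[float, float]) -> np.ndarray:
        """Displacement this transform induces at ``point`` (T(p) - p)."""
        p = np.asarray(point, dtype=float)
        return self.apply(p) - p

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.angle) < tol and float(np.hypot(*self.translation)) < tol
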