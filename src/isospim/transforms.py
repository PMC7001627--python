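"""Rigid/affine 3D transforms on physical (micrometre) coordinates.

Convention: image arrays are indexed ``(z, y, x)``; every coordinate
*array* in this package follows the same ``(z, y, x)`` component order.
Tuples crossing public APIs (voxel sizes, bead centres, displacements)
are ``(x, y, z)`` and are converted at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffineTransform3D",
    "rotation_about_y",
    "xyz_to_zyx",
    "zyx_to_xyz",
]


def xyz_to_zyx(t) -> np.ndarray:
    """Reverse an (x, y, z) triple into (z, y, x) array order."""
    t = np.asarray(t, dtype=float)
    return t[::-1].copy()


def zyx_to_xyz(t) -> tuple:
    a = np.asarray(t, dtype=float)
    return tuple(a[::-1])


@dataclass
class AffineTransform3D:
    """Affine map ``p -> linear @ p + translation`` on (z, y, x) µm points.

    ``linear`` must be invertible; rigid transforms additionally have an
    orthonormal linear part with determinant +1.
    """

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation_um = np.asarray(self.translation_um, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) <= 1e-9:
            raise ValueError("affine linear part is singular")

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (N, 3) stack of (z, y, x) points."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + self.translation_um

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the map ``self ∘ other`` (apply *other* first)."""
        return AffineTransform3D(
            self.linear @ other.linear,
            self.linear @ other.translation_um + self.translation_um,
        )

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform3D(inv, -inv @ self.translation_um)

    @property
    def is_rigid(self) -> bool:
        lin = self.linear
        return (
            np.allclose(lin @ lin.T, np.eye(3), atol=1e-8)
            and np.linalg.det(lin) > 0
        )

    @staticmethod
    def identity() -> "AffineTransform3D":
        return AffineTransform3D()

    def almost_equal(self, other: "AffineTransform3D", tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.linear, other.linear, atol=tol)
            and np.allclose(self.translation_um, other.translation_um, atol=tol)
        )

    # -- serialization ----------------------------------------------------
    def to_json_dict(self) -> dict:
        m = np.hstack([self.linear, self.translation_um[:, None]])
        return {"matrix_3x4_row_major": m.ravel().tolist(), "axes": "zyx", "units": "um"}

    @staticmethod
    def from_json_dict(d: dict) -> "AffineTransform3D":
        m = np.asarray(d["matrix_3x4_row_major"], dtype=float).reshape(3, 4)
        return AffineTransform3D(m[:, :3], m[:, 3])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "AffineTransform3D":
        with open(path) as fh:
            return AffineTransform3D.from_json_dict(json.load(fh))


def rotation_about_y(angle_deg: float, center_um=(0.0, 0.0, 0.0)) -> AffineTransform3D:
    """Right-handed rotation about the vertical (y) axis through ``center``.

    ``center`` is given in (z, y, x) µm. A positive angle rotates +x
    toward +z (right-hand rule about +y in the xyz frame).
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # In xyz: x' = c x + s z ; z' = -s x + c z.  Rows/cols ordered (z, y, x).
    lin = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    center = np.asarray(center_um, dtype=float)
    return AffineTransform3D(lin, center - lin @ center)
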