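"""Tilted continuous-scan geometry.

A light-sheet stage scan translates the sample along a direction S that
is deliberately tilted away from the detection (z) axis.  Each camera
frame therefore carries sub-voxel lateral *and* axial offsets relative
to its neighbours; decimating the oversampled frame stream into groups
yields mutually shifted low-resolution stacks that support super-
resolved reconstruction.

Tilt convention: the scan unit vector is ``R_y(θ2) · R_x(θ1) · ẑ`` with
the first rotation about the horizontal lateral axis (x) and the second
about the vertical axis (y).  With a 280 nm step and θ1 = θ2 = 10° this
yields per-step lateral components of ≈48 nm and an axial component of
≈272 nm.

Frames stacked by index live in a *sheared* ("scan") frame: plane k is
laterally displaced by ``k · (dx, dy)`` in sample space.  Within that
frame, decimated groups are offset purely axially; the oblique 3D
offset ``j·d`` is the sample-frame description of the same lattice.
:func:`shear_matrix` maps scan-frame to Cartesian sample coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .transforms import AffineTransform3D, rotation_about_y

__all__ = [
    "ScanGeometry",
    "Displacement3D",
    "GroupingPlan",
    "ViewPose",
    "step_displacement",
    "grouping_plan",
    "shear_matrix",
    "view_pose",
]


class InvalidGeometryError(ValueError):
    pass


class InsufficientOversamplingError(ValueError):
    pass


@dataclass(frozen=True)
class ScanGeometry:
    """Stage-scan and sampling geometry for one view.

    Parameters
    ----------
    step_nm : per-frame stage step along the scan direction (nm).
    tilt_first_deg : rotation θ1 about the horizontal lateral axis (x),
        applied first; in [0, 90).
    tilt_second_deg : rotation θ2 about the vertical axis (y), applied
        second; in [0, 90).
    n_frames : number of frames in the continuous scan.
    lr_voxel_um : native low-resolution voxel size (vx, vy, vz) µm.
    enhancement : integer resolution-enhancement factors (rx, ry, rz).
    """

    step_nm: float
    tilt_first_deg: float = 0.0
    tilt_second_deg: float = 0.0
    n_frames: int = 1
    lr_voxel_um: tuple = (1.625, 1.625, 4.5)
    enhancement: tuple = (1, 1, 1)

    def __post_init__(self):
        if self.step_nm <= 0:
            raise InvalidGeometryError("step_nm must be > 0")
        for t in (self.tilt_first_deg, self.tilt_second_deg):
            if not (0.0 <= t < 90.0):
                raise InvalidGeometryError("tilt angles must lie in [0, 90)")
        if self.n_frames < 1:
            raise InvalidGeometryError("n_frames must be >= 1")
        if any(v <= 0 for v in self.lr_voxel_um):
            raise InvalidGeometryError("voxel sizes must be > 0")
        if any(int(r) != r or r < 1 for r in self.enhancement):
            raise InvalidGeometryError("enhancement factors must be integers >= 1")

    @property
    def hr_voxel_um(self) -> tuple:
        """High-resolution voxel size (vx, vy, vz) = lr_voxel / enhancement."""
        return tuple(v / r for v, r in zip(self.lr_voxel_um, self.enhancement))

    def scan_direction(self) -> np.ndarray:
        """Unit scan vector, (x, y, z) components."""
        t1 = np.deg2rad(self.tilt_first_deg)
        t2 = np.deg2rad(self.tilt_second_deg)
        # R_y(t2) @ R_x(t1) @ [0, 0, 1]
        return np.array(
            [
                np.sin(t2) * np.cos(t1),
                -np.sin(t1),
                np.cos(t1) * np.cos(t2),
            ]
        )

    # -- JSON round trip ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "step_nm": self.step_nm,
            "tilt_first_deg": self.tilt_first_deg,
            "tilt_second_deg": self.tilt_second_deg,
            "n_frames": self.n_frames,
            "lr_voxel_um": list(self.lr_voxel_um),
            "enhancement": list(self.enhancement),
        }

    @staticmethod
    def from_json_dict(d: dict) -> "ScanGeometry":
        return ScanGeometry(
            step_nm=d["step_nm"],
            tilt_first_deg=d["tilt_first_deg"],
            tilt_second_deg=d["tilt_second_deg"],
            n_frames=d["n_frames"],
            lr_voxel_um=tuple(d["lr_voxel_um"]),
            enhancement=tuple(int(r) for r in d["enhancement"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "ScanGeometry":
        with open(path) as fh:
            return ScanGeometry.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class Displacement3D:
    """One scan step expressed in the detection frame, in nm."""

    dx: float
    dy: float
    dz: float

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(self.dx**2 + self.dy**2 + self.dz**2))

    def as_um_xyz(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz]) / 1000.0

    def as_um_zyx(self) -> np.ndarray:
        return np.array([self.dz, self.dy, self.dx]) / 1000.0


def step_displacement(geometry: ScanGeometry) -> Displacement3D:
    """Per-frame displacement ``d = s · R_y(θ2)·R_x(θ1)·ẑ`` in nm."""
    d = geometry.step_nm * geometry.scan_direction()
    return Displacement3D(dx=float(d[0]), dy=float(d[1]), dz=float(d[2]))


@dataclass(frozen=True)
class GroupingPlan:
    """Decimation plan turning the frame stream into shifted LR groups.

    ``offsets`` are the sample-frame offsets ``j·d`` of group j relative
    to group 0, in HR-voxel units and (x, y, z) order.  In the sheared
    scan frame, where the groups are actually stacked, the same offsets
    are purely axial; :meth:`scan_frame_offsets` returns that form.
    """

    decimation_M: int
    n_groups_G: int
    offsets: tuple  # of (ox, oy, oz) HR-voxel triples
    lr_axial_spacing_um: float
    step_um_xyz: tuple
    hr_voxel_um: tuple
    enhancement: tuple = (1, 1, 1)

    def scan_frame_offsets(self) -> np.ndarray:
        """(G, 3) array of (z, y, x) offsets in HR voxels, axial-only.

        On the reconstruction grid (axial voxel = M·dz/rz) group j sits
        exactly ``j · rz / M`` voxels along the scan axis.
        """
        rz = self.enhancement[2]
        out = np.zeros((self.n_groups_G, 3))
        out[:, 0] = np.arange(self.n_groups_G) * rz / self.decimation_M
        return out


def grouping_plan(
    geometry: ScanGeometry,
    target_axial_spacing_um: float,
    n_groups: int | None = None,
) -> GroupingPlan:
    """Plan the frame decimation for a target LR axial spacing.

    ``M = round(target_axial_spacing / dz)`` frames per LR axial sample;
    by default every decimation phase becomes a group (``G = M``).
    """
    d = step_displacement(geometry)
    dz_um = d.dz / 1000.0
    if dz_um <= 0:
        raise InvalidGeometryError("scan has no axial component")
    if target_axial_spacing_um < dz_um - 1e-12:
        raise InvalidGeometryError(
            "target axial spacing smaller than one scan step"
        )
    M = int(round(target_axial_spacing_um * 1000.0 / d.dz))
    rz = geometry.enhancement[2]
    if M < max(rz, 1):
        raise InsufficientOversamplingError(
            f"M={M} phases cannot support axial enhancement rz={rz}"
        )
    G = M if n_groups is None else int(n_groups)
    if G < 1 or G > M:
        raise InvalidGeometryError("n_groups must lie in [1, M]")
    hr = geometry.hr_voxel_um
    d_um = d.as_um_xyz()
    offsets = tuple(
        tuple(j * d_um[i] / hr[i] for i in range(3)) for j in range(G)
    )
    return GroupingPlan(
        decimation_M=M,
        n_groups_G=G,
        offsets=offsets,
        lr_axial_spacing_um=M * dz_um,
        step_um_xyz=tuple(d_um),
        hr_voxel_um=hr,
        enhancement=tuple(int(r) for r in geometry.enhancement),
    )


def shear_matrix(geometry: ScanGeometry) -> AffineTransform3D:
    """Scan-frame → Cartesian shear, on (z, y, x) µm coordinates.

    Treating the frame index as the axial coordinate, each axial plane
    at height z is laterally displaced by ``z · (dx, dy) / dz``; an
    untilted scan returns the identity.
    """
    d = step_displacement(geometry)
    if d.dz <= 0:
        raise InvalidGeometryError("scan has no axial component")
    gx = d.dx / d.dz
    gy = d.dy / d.dz
    lin = np.array(
        [
            [1.0, 0.0, 0.0],
            [gy, 1.0, 0.0],
            [gx, 0.0, 1.0],
        ]
    )
    return AffineTransform3D(lin, np.zeros(3))


@dataclass(frozen=True)
class ViewPose:
    """Rotation state of one acquisition view about the vertical axis."""

    view_index: int
    angle_deg: float
    rigid: AffineTransform3D
    center_um: tuple = (0.0, 0.0, 0.0)  # (z, y, x)


def view_pose(view_index: int, n_views: int, center_um=(0.0, 0.0, 0.0)) -> ViewPose:
    """Pose of view ``view_index`` out of ``n_views`` equiangular views."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if not (0 <= view_index < n_views):
        raise ValueError("view_index out of range")
    angle = view_index * 360.0 / n_views
    return ViewPose(
        view_index=view_index,
        angle_deg=angle,
        rigid=rotation_about_y(angle, center_um),
        center_um=tuple(center_um),
    )
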