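"""Volumetric containers and TIFF/JSON I/O.

Volumes are stored as (z, y, x) arrays with an explicit physical voxel
size and origin so that every stage of the pipeline can reason in
micrometres.  Multi-page TIFF carries the pixel data; a JSON sidecar
carries the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import ScanGeometry

__all__ = ["HRVolume", "RawSequence"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class HRVolume:
    """A 3D intensity volume with physical scale.

    Attributes
    ----------
    data : (Z, Y, X) non-negative intensity array.
    voxel_um : (vx, vy, vz) voxel size in µm.
    origin_um : (x0, y0, z0) physical position of voxel (0, 0, 0) centre.
    frame : "cartesian" or "scan" (sheared) coordinate frame tag.
    meta : free-form provenance dictionary.
    """

    data: np.ndarray
    voxel_um: tuple
    origin_um: tuple = (0.0, 0.0, 0.0)
    frame: str = "cartesian"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_zyx(self) -> np.ndarray:
        return np.asarray(self.voxel_um, dtype=float)[::-1]

    @property
    def origin_zyx(self) -> np.ndarray:
        return np.asarray(self.origin_um, dtype=float)[::-1]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_um))

    def physical_flux(self) -> float:
        """Integral of intensity over space (counts · µm³)."""
        return float(self.data.sum(dtype=np.float64) * self.voxel_volume_um3)

    def coords_zyx(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (z, y, x) µm positions."""
        idx = np.asarray(indices, dtype=float)
        return idx * self.voxel_zyx + self.origin_zyx

    def index_of(self, points_zyx: np.ndarray) -> np.ndarray:
        """Map (z, y, x) µm positions to fractional voxel indices."""
        p = np.asarray(points_zyx, dtype=float)
        return (p - self.origin_zyx) / self.voxel_zyx

    # -- I/O ---------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32))
        sidecar = {
            "voxel_um": list(self.voxel_um),
            "origin_um": list(self.origin_um),
            "frame": self.frame,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(path) -> "HRVolume":
        path = Path(path)
        data = tifffile.imread(path)
        sc = json.loads(path.with_suffix(".json").read_text())
        return HRVolume(
            data=data,
            voxel_um=tuple(sc["voxel_um"]),
            origin_um=tuple(sc["origin_um"]),
            frame=sc.get("frame", "cartesian"),
            meta=sc.get("meta", {}),
        )


@dataclass
class RawSequence:
    """Time-ordered frames from one continuous tilted scan of one view.

    ``frames`` has shape (T, Y, X); pixel (0, 0) of frame 0 sits at
    ``origin_um`` and frame i is displaced by ``i · d`` in sample space.
    """

    frames: np.ndarray
    geometry: ScanGeometry
    origin_um: tuple = (0.0, 0.0, 0.0)  # (x0, y0, z0) of frame-0 pixel (0,0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, Y, X)")
        if self.frames.shape[0] != self.geometry.n_frames:
            raise ValueError("frame count does not match geometry.n_frames")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")

    # -- I/O ---------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.frames, dtype=np.float32))
        sidecar = {
            "geometry": self.geometry.to_json_dict(),
            "origin_um": list(self.origin_um),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(path) -> "RawSequence":
        path = Path(path)
        frames = tifffile.imread(path)
        sc = json.loads(path.with_suffix(".json").read_text())
        return RawSequence(
            frames=frames,
            geometry=ScanGeometry.from_json_dict(sc["geometry"]),
            origin_um=tuple(sc["origin_um"]),
            meta=sc.get("meta", {}),
        )
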