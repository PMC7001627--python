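"""Ground-truth phantoms and light-sheet image-formation simulation.

The simulator emulates the acquisition chain of a tilted-scan,
multi-view light-sheet microscope: a separable Gaussian PSF (lateral
FWHM set by the detection optics, axial FWHM by the sheet thickness),
continuous stage scanning along a direction tilted from the detection
axis, sample rotation about the vertical axis for multiple views,
depth-dependent exponential attenuation along the illumination axis,
and Poisson + Gaussian read noise at the camera.

Intensities are carried as *densities* (counts per µm³ up to the camera
gain), so flux bookkeeping survives resampling: the physical flux of a
rendered primitive equals ``sum(data) × voxel_volume``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geometry import ScanGeometry, step_displacement, view_pose
from .kernels import FWHM_TO_SIGMA, gaussian_kernel
from .transforms import xyz_to_zyx
from .volume import HRVolume, RawSequence

__all__ = [
    "PSFModel",
    "Bead",
    "Filament",
    "Phantom",
    "AttenuationModel",
    "CameraModel",
    "make_bead_phantom",
    "make_filament_phantom",
    "render_volume",
    "simulate_scan",
    "simulate_multiview",
]

_SQRT2 = np.sqrt(2.0)


class PhantomCapacityError(RuntimeError):
    pass


class OversamplingError(ValueError):
    pass


@dataclass(frozen=True)
class PSFModel:
    """Separable Gaussian PSF: lateral width from the detection optics,
    axial width from the light-sheet thickness (both FWHM, µm)."""

    lateral_fwhm_um: float = 4.2
    axial_fwhm_um: float = 12.0

    def __post_init__(self):
        if self.lateral_fwhm_um <= 0 or self.axial_fwhm_um <= 0:
            raise ValueError("PSF FWHMs must be positive")

    @property
    def sigma_xyz_um(self) -> np.ndarray:
        s_lat = self.lateral_fwhm_um * FWHM_TO_SIGMA
        s_ax = self.axial_fwhm_um * FWHM_TO_SIGMA
        return np.array([s_lat, s_lat, s_ax])

    def covariance_zyx_um2(self) -> np.ndarray:
        return np.diag(self.sigma_xyz_um[::-1] ** 2)

    def render(self, voxel_um, truncate: float = 4.0) -> np.ndarray:
        """Normalized kernel sampled at (vx, vy, vz) µm voxels."""
        return gaussian_kernel(
            self.covariance_zyx_um2(), xyz_to_zyx(voxel_um), truncate
        )


@dataclass(frozen=True)
class Bead:
    """Sub-resolution fluorescent microbead, modelled as an isotropic
    Gaussian blob with FWHM equal to its nominal diameter."""

    center_um: tuple  # (x, y, z)
    peak: float = 1.0  # density amplitude before PSF blur
    diameter_um: float = 0.5

    @property
    def sigma_um(self) -> float:
        return self.diameter_um * FWHM_TO_SIGMA

    @property
    def flux(self) -> float:
        return float(self.peak * (2.0 * np.pi) ** 1.5 * self.sigma_um**3)


@dataclass(frozen=True)
class Filament:
    """Tube-like structure along a polyline; Gaussian cross-section with
    FWHM equal to the tube diameter (2 × radius)."""

    points_um: tuple  # of (x, y, z)
    radius_um: float = 0.5
    intensity: float = 1.0  # counts per µm of length


@dataclass
class Phantom:
    beads: list = field(default_factory=list)
    filaments: list = field(default_factory=list)
    bounds_um: tuple = (((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)))

    def is_empty(self) -> bool:
        return not self.beads and not self.filaments

    @property
    def center_um(self) -> tuple:
        return tuple((lo + hi) / 2.0 for lo, hi in self.bounds_um)

    def bead_centers_zyx(self) -> np.ndarray:
        if not self.beads:
            return np.zeros((0, 3))
        return np.array([xyz_to_zyx(b.center_um) for b in self.beads])

    def to_json_dict(self) -> dict:
        return {
            "bounds_um": [list(b) for b in self.bounds_um],
            "beads": [
                {"center_um": list(b.center_um), "peak": b.peak,
                 "diameter_um": b.diameter_um}
                for b in self.beads
            ],
            "filaments": [
                {"points_um": [list(p) for p in f.points_um],
                 "radius_um": f.radius_um, "intensity": f.intensity}
                for f in self.filaments
            ],
        }

    @staticmethod
    def from_json_dict(d: dict) -> "Phantom":
        return Phantom(
            beads=[
                Bead(tuple(b["center_um"]), b["peak"], b["diameter_um"])
                for b in d["beads"]
            ],
            filaments=[
                Filament(tuple(tuple(p) for p in f["points_um"]),
                         f["radius_um"], f["intensity"])
                for f in d["filaments"]
            ],
            bounds_um=tuple(tuple(b) for b in d["bounds_um"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @staticmethod
    def load(path) -> "Phantom":
        with open(path) as fh:
            return Phantom.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class AttenuationModel:
    """Exponential loss of illumination with depth into the sample.

    ``transmittance(depth) = max(exp(-depth / length_scale), floor)``,
    measured along the illumination axis (x) from the entry face.
    ``direction`` +1 means light enters from the low-x face.
    """

    length_scale_um: float
    direction: int = 1
    floor: float = 0.0

    def __post_init__(self):
        if self.length_scale_um <= 0:
            raise ValueError("attenuation length scale must be positive")
        if not (0.0 <= self.floor <= 1.0):
            raise ValueError("floor must lie in [0, 1]")

    def transmittance(self, depth_um) -> np.ndarray:
        d = np.maximum(np.asarray(depth_um, dtype=float), 0.0)
        return np.maximum(np.exp(-d / self.length_scale_um), self.floor)


@dataclass(frozen=True)
class CameraModel:
    """Detection and digitization: pixel pitch, shot noise, read noise."""

    pixel_um: float = 1.625
    read_noise_sd: float = 0.0
    poisson: bool = False
    seed: int = 0
    gain: float = 1.0  # counts per unit density


# ---------------------------------------------------------------------------
# phantom generators
# ---------------------------------------------------------------------------

def _bounds_array(bounds_um) -> np.ndarray:
    b = np.asarray(bounds_um, dtype=float).reshape(3, 2)
    if np.any(b[:, 1] <= b[:, 0]):
        raise ValueError("degenerate phantom bounds")
    return b


def _draw_position(rng, b, region: str) -> np.ndarray:
    """Uniform (x, y, z) draw inside a box, or inside the cylinder about
    the central vertical axis inscribed in the box (so that rotated
    views keep every primitive in the field)."""
    if region == "box":
        return rng.uniform(b[:, 0], b[:, 1])
    if region == "cylinder":
        cx = b[0].mean()
        cz = b[2].mean()
        r_max = min(b[0, 1] - b[0, 0], b[2, 1] - b[2, 0]) / 2.0
        r = r_max * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        y = rng.uniform(b[1, 0], b[1, 1])
        return np.array([cx + r * np.cos(phi), y, cz + r * np.sin(phi)])
    raise ValueError(f"unknown region {region!r}")


def make_bead_phantom(
    n_beads: int,
    bounds_um,
    diameter_um: float = 0.5,
    min_separation_um: float = 0.0,
    seed: int = 0,
    peak: float = 1.0,
    region: str = "box",
    edge_margin_um: float = 0.0,
    max_tries: int = 10_000,
) -> Phantom:
    """Place ``n_beads`` uniformly with a pairwise minimum separation.

    ``edge_margin_um`` keeps beads away from the bounds so their full
    profiles stay measurable.  Deterministic for a fixed seed; raises
    :class:`PhantomCapacityError` if the separation cannot be achieved
    after bounded retries.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    b_full = _bounds_array(bounds_um)
    b = b_full.copy()
    b[:, 0] += edge_margin_um
    b[:, 1] -= edge_margin_um
    if np.any(b[:, 1] <= b[:, 0]):
        raise ValueError("edge margin leaves no placement volume")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_beads:
        if tries >= max_tries:
            raise PhantomCapacityError(
                f"could not place {n_beads} beads with separation "
                f"{min_separation_um} µm after {max_tries} draws"
            )
        tries += 1
        cand = _draw_position(rng, b, region)
        if all(np.linalg.norm(cand - p) >= min_separation_um for p in placed):
            placed.append(cand)
    beads = [Bead(tuple(p), peak=peak, diameter_um=diameter_um) for p in placed]
    return Phantom(beads=beads, bounds_um=tuple(map(tuple, b_full)))


def make_filament_phantom(
    n_filaments: int,
    bounds_um,
    radius_um: float = 0.5,
    seed: int = 0,
    intensity: float = 1.0,
    step_um: float = 1.0,
    n_steps: int = 60,
    wobble_deg: float = 10.0,
) -> Phantom:
    """Smooth random-walk polylines clipped to the bounds."""
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    b = _bounds_array(bounds_um)
    rng = np.random.default_rng(seed)
    filaments = []
    for _ in range(n_filaments):
        p = rng.uniform(b[:, 0], b[:, 1])
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p.copy()]
        for _ in range(n_steps):
            # small random rotation of the heading
            perturb = rng.normal(scale=np.deg2rad(wobble_deg), size=3)
            d = d + np.cross(perturb, d)
            d /= np.linalg.norm(d)
            q = pts[-1] + step_um * d
            if np.any(q < b[:, 0]) or np.any(q > b[:, 1]):
                break
            pts.append(q)
        if len(pts) >= 2:
            filaments.append(
                Filament(tuple(map(tuple, pts)), radius_um, intensity)
            )
    return Phantom(filaments=filaments, bounds_um=tuple(map(tuple, b)))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _erf_profile(centers: np.ndarray, mu: float, sigma: float, v: float) -> np.ndarray:
    """Mean of a unit Gaussian density over voxels of width v at ``centers``."""
    a = (centers - v / 2.0 - mu) / (_SQRT2 * sigma)
    c = (centers + v / 2.0 - mu) / (_SQRT2 * sigma)
    return 0.5 * (erf(c) - erf(a)) / v


def _deposit_gaussian(
    data: np.ndarray,
    voxel_zyx: np.ndarray,
    origin_zyx: np.ndarray,
    center_zyx: np.ndarray,
    sigma_zyx: np.ndarray,
    flux: float,
    truncate: float = 5.0,
) -> None:
    """Accumulate an erf-integrated separable Gaussian blob in place."""
    los, his, axes = [], [], []
    for ax in range(3):
        idx_c = (center_zyx[ax] - origin_zyx[ax]) / voxel_zyx[ax]
        half = truncate * sigma_zyx[ax] / voxel_zyx[ax] + 1.0
        lo = max(int(np.floor(idx_c - half)), 0)
        hi = min(int(np.ceil(idx_c + half)) + 1, data.shape[ax])
        if hi <= lo:
            return
        centers = origin_zyx[ax] + np.arange(lo, hi) * voxel_zyx[ax]
        axes.append(
            _erf_profile(centers, center_zyx[ax], sigma_zyx[ax], voxel_zyx[ax])
        )
        los.append(lo)
        his.append(hi)
    block = flux * (
        axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    )
    data[los[0]: his[0], los[1]: his[1], los[2]: his[2]] += block


def render_volume(
    phantom: Phantom,
    voxel_um,
    psf: PSFModel | None = None,
    origin_um=None,
    shape=None,
    pad_um: float = 0.0,
) -> HRVolume:
    """Analytically rasterize a phantom, optionally PSF-blurred.

    Gaussian primitives are integrated over voxels with error functions,
    so the total flux of interior primitives is exact.  Blur is folded
    into the primitive widths (Gaussian ⊗ Gaussian), not applied as a
    separate discrete convolution.
    """
    voxel_xyz = np.asarray(voxel_um, dtype=float)
    b = _bounds_array(phantom.bounds_um)
    undersampled = False
    if psf is not None:
        min_fwhm = np.array([psf.lateral_fwhm_um, psf.lateral_fwhm_um,
                             psf.axial_fwhm_um])
        if np.any(voxel_xyz > min_fwhm / 2.0):
            undersampled = True
    if origin_um is None:
        origin_xyz = b[:, 0] - pad_um
    else:
        origin_xyz = np.asarray(origin_um, dtype=float)
    if shape is None:
        extent = b[:, 1] + pad_um - origin_xyz
        shape = tuple(
            int(np.ceil(e / v)) + 1 for e, v in zip(extent[::-1], voxel_xyz[::-1])
        )
    voxel_zyx = voxel_xyz[::-1]
    origin_zyx = origin_xyz[::-1]
    data = np.zeros(shape, dtype=np.float64)
    psf_var_zyx = (
        np.zeros(3) if psf is None else psf.sigma_xyz_um[::-1] ** 2
    )
    for bead in phantom.beads:
        sigma = np.sqrt(bead.sigma_um**2 + psf_var_zyx)
        _deposit_gaussian(
            data, voxel_zyx, origin_zyx, xyz_to_zyx(bead.center_um),
            sigma, bead.flux,
        )
    for fil in phantom.filaments:
        sigma_t = 2.0 * fil.radius_um * FWHM_TO_SIGMA
        sigma = np.sqrt(sigma_t**2 + psf_var_zyx)
        pts = np.array([xyz_to_zyx(p) for p in fil.points_um])
        ds_target = float(min(voxel_zyx)) / 2.0
        for p0, p1 in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(p1 - p0)
            n = max(int(np.ceil(seg / ds_target)), 1)
            for t in (np.arange(n) + 0.5) / n:
                _deposit_gaussian(
                    data, voxel_zyx, origin_zyx, p0 + t * (p1 - p0),
                    sigma, fil.intensity * seg / n,
                )
    # _erf_profile already yields per-axis mean densities, so data is in
    # counts/µm³ and flux = sum * voxel volume
    return HRVolume(
        data=data,
        voxel_um=tuple(voxel_xyz),
        origin_um=tuple(origin_xyz),
        meta={"psf_undersampled": undersampled, "rendered": True},
    )


# ---------------------------------------------------------------------------
# scanning simulation
# ---------------------------------------------------------------------------

def _scan_layout(phantom: Phantom, psf: PSFModel, geometry: ScanGeometry,
                 camera: CameraModel, margin_sigmas: float = 3.0):
    """Choose frame-0 origin, frame shape and frame count so that the
    scanned field covers the phantom plus blur margins and lateral
    scan drift."""
    b = _bounds_array(phantom.bounds_um)
    s = psf.sigma_xyz_um
    d_um = step_displacement(geometry).as_um_xyz()
    mx = margin_sigmas * s[0] + 1.0
    my = margin_sigmas * s[1] + 1.0
    mz = margin_sigmas * s[2] + 1.0
    z0 = b[2, 0] - mz
    n_frames = int(np.ceil((b[2, 1] + mz - z0) / d_um[2])) + 1
    drift_x = n_frames * d_um[0]
    drift_y = n_frames * d_um[1]
    x0 = b[0, 0] - mx - max(0.0, drift_x)
    x1 = b[0, 1] + mx - min(0.0, drift_x)
    y0 = b[1, 0] - my - max(0.0, drift_y)
    y1 = b[1, 1] + my - min(0.0, drift_y)
    nx = int(np.ceil((x1 - x0) / camera.pixel_um)) + 1
    ny = int(np.ceil((y1 - y0) / camera.pixel_um)) + 1
    return (x0, y0, z0), (ny, nx), n_frames


def _bead_frames(
    phantom, psf, geometry, camera, attenuation, origin, frame_shape, n_frames,
    x_entry_range,
) -> np.ndarray:
    """Analytic noise-free frames for a bead-only phantom."""
    d_um = step_displacement(geometry).as_um_xyz()
    ny, nx = frame_shape
    px_x = origin[0] + np.arange(nx) * camera.pixel_um
    px_y = origin[1] + np.arange(ny) * camera.pixel_um
    frames = np.zeros((n_frames, ny, nx), dtype=np.float64)
    i_idx = np.arange(n_frames)
    z_i = origin[2] + i_idx * d_um[2]
    for bead in phantom.beads:
        cx, cy, cz = bead.center_um
        svar = bead.sigma_um**2
        sx = np.sqrt(svar + psf.sigma_xyz_um[0] ** 2)
        sy = np.sqrt(svar + psf.sigma_xyz_um[1] ** 2)
        sz = np.sqrt(svar + psf.sigma_xyz_um[2] ** 2)
        if attenuation is not None:
            if attenuation.direction >= 0:
                depth = cx - x_entry_range[0]
            else:
                depth = x_entry_range[1] - cx
            trans = float(attenuation.transmittance(depth))
        else:
            trans = 1.0
        gz = np.exp(-0.5 * ((z_i - cz) / sz) ** 2) / (sz * np.sqrt(2 * np.pi))
        active = np.nonzero(gz > gz.max(initial=0.0) * 1e-8)[0]
        for i in active:
            # frame i samples the sample at pixel + i*d (lateral drift)
            fx = _erf_profile(px_x + i_idx[i] * d_um[0], cx, sx, camera.pixel_um)
            fy = _erf_profile(px_y + i_idx[i] * d_um[1], cy, sy, camera.pixel_um)
            frames[i] += bead.flux * trans * gz[i] * np.outer(fy, fx)
    return frames


def _general_frames(
    phantom, psf, geometry, camera, attenuation, origin, frame_shape, n_frames,
    x_entry_range,
) -> np.ndarray:
    """Frames via a finely rendered blurred volume and interpolation
    (path for filament or mixed phantoms)."""
    d_um = step_displacement(geometry).as_um_xyz()
    fine_lat = min(camera.pixel_um / 2.0, psf.lateral_fwhm_um / 6.0)
    fine_ax = psf.axial_fwhm_um / 8.0
    vol = render_volume(
        phantom, (fine_lat, fine_lat, fine_ax), psf=psf,
        pad_um=2.0 * psf.axial_fwhm_um,
    )
    ny, nx = frame_shape
    px_x = origin[0] + np.arange(nx) * camera.pixel_um
    px_y = origin[1] + np.arange(ny) * camera.pixel_um
    frames = np.zeros((n_frames, ny, nx), dtype=np.float64)
    for i in range(n_frames):
        X = px_x + i * d_um[0]
        Y = px_y + i * d_um[1]
        Z = origin[2] + i * d_um[2]
        pts_z = np.full((ny, nx), Z)
        pts_y = np.broadcast_to(Y[:, None], (ny, nx))
        pts_x = np.broadcast_to(X[None, :], (ny, nx))
        idx = vol.index_of(
            np.stack([pts_z.ravel(), pts_y.ravel(), pts_x.ravel()], axis=1)
        )
        vals = ndimage.map_coordinates(
            vol.data, idx.T, order=1, mode="constant", cval=0.0
        ).reshape(ny, nx)
        if attenuation is not None:
            if attenuation.direction >= 0:
                depth = pts_x - x_entry_range[0]
            else:
                depth = x_entry_range[1] - pts_x
            vals = vals * attenuation.transmittance(depth)
        frames[i] = vals
    return frames


def simulate_scan(
    phantom: Phantom,
    psf: PSFModel,
    geometry: ScanGeometry,
    camera: CameraModel,
    attenuation: AttenuationModel | None = None,
    force: bool = False,
    meta: dict | None = None,
) -> RawSequence:
    """Simulate one continuous tilted scan of a phantom.

    Frame i is the detection-plane section of the PSF-blurred phantom at
    scan position ``i·d``, integrated over camera pixels, attenuated
    along the illumination axis, with seeded Poisson and read noise.
    The oversampling precondition (step ≪ sheet thickness) is enforced
    unless ``force``.
    """
    if geometry.step_nm >= psf.axial_fwhm_um * 1000.0 and not force:
        raise OversamplingError(
            "scan step must be smaller than the light-sheet FWHM "
            "(pass force=True to override)"
        )
    origin, frame_shape, n_frames = _scan_layout(phantom, psf, geometry, camera)
    geometry = dataclasses.replace(geometry, n_frames=n_frames)
    # illumination attenuates from the sample (phantom bounds) surface on
    b = _bounds_array(phantom.bounds_um)
    x_entry = (float(b[0, 0]), float(b[0, 1]))
    if phantom.is_empty():
        frames = np.zeros((n_frames, *frame_shape), dtype=np.float64)
    elif not phantom.filaments:
        frames = _bead_frames(
            phantom, psf, geometry, camera, attenuation, origin, frame_shape,
            n_frames, x_entry,
        )
    else:
        frames = _general_frames(
            phantom, psf, geometry, camera, attenuation, origin, frame_shape,
            n_frames, x_entry,
        )
    frames = frames * camera.gain
    rng = np.random.default_rng(camera.seed)
    if camera.poisson:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(np.float64)
    if camera.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, camera.read_noise_sd, frames.shape)
    frames = np.maximum(frames, 0.0).astype(np.float32)
    md = {
        "camera": dataclasses.asdict(camera),
        "attenuation": None if attenuation is None
        else dataclasses.asdict(attenuation),
    }
    if meta:
        md.update(meta)
    return RawSequence(frames=frames, geometry=geometry,
                       origin_um=tuple(origin), meta=md)


def rotate_phantom(phantom: Phantom, angle_deg: float,
                   center_um=None) -> Phantom:
    """Phantom as seen after rotating the sample by ``angle_deg`` about
    the vertical axis through ``center`` ((x, y, z) µm)."""
    if center_um is None:
        center_um = phantom.center_um
    from .transforms import rotation_about_y

    rot = rotation_about_y(angle_deg, xyz_to_zyx(center_um))
    beads = []
    for b in phantom.beads:
        q = rot.apply(xyz_to_zyx(b.center_um))
        beads.append(Bead(tuple(q[::-1]), b.peak, b.diameter_um))
    filaments = []
    for f in phantom.filaments:
        pts = [tuple(rot.apply(xyz_to_zyx(p))[::-1]) for p in f.points_um]
        filaments.append(Filament(tuple(pts), f.radius_um, f.intensity))
    return Phantom(beads=beads, filaments=filaments,
                   bounds_um=phantom.bounds_um)


def simulate_multiview(
    phantom: Phantom,
    psf: PSFModel,
    geometry: ScanGeometry,
    camera: CameraModel,
    attenuation: AttenuationModel | None = None,
    n_views: int = 8,
) -> list[RawSequence]:
    """Simulate ``n_views`` equiangular acquisitions of one phantom.

    View v images the phantom rotated by ``view_pose(v, n_views)`` about
    the phantom centre; attenuation acts in each view's own frame, so
    opposing views darken opposite sides of the sample.  Each view gets
    an independent, seed-derived noise stream; ground-truth poses are
    recorded in the sequence metadata.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    center = phantom.center_um
    out = []
    for v in range(n_views):
        pose = view_pose(v, n_views, center_um=xyz_to_zyx(center))
        rotated = rotate_phantom(phantom, pose.angle_deg, center)
        cam_v = dataclasses.replace(camera, seed=camera.seed + 1000 * v)
        seq = simulate_scan(
            rotated, psf, geometry, cam_v, attenuation,
            meta={
                "view_index": v,
                "n_views": n_views,
                "pose_angle_deg": pose.angle_deg,
                "pose_center_um": list(center),
                "true_bead_centers_um": [list(b.center_um)
                                         for b in rotated.beads],
            },
        )
        out.append(seq)
    return out
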