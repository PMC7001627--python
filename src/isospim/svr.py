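"""Subvoxel-resolving (SVR) reconstruction of one tilted-scan view.

The oversampled frame stream is decimated into G low-resolution groups
(every M-th frame at a fixed phase).  In the stacked ("scan") frame the
groups are mutually offset by sub-voxel amounts along the scan axis;
each group is modelled as

    y_j = D( S_j( H x ) )

with ``x`` the high-resolution volume on the scan-frame grid, ``H`` the
optics PSF sheared into the scan frame, ``S_j`` the sub-voxel group
shift (trilinear) and ``D`` area-preserving block-average downsampling
by the enhancement factors.  The Poisson maximum-likelihood estimate is
iterated with the multiplicative (Richardson–Lucy-type) multi-frame
update

    x ← x · [ Σ_j A_jᵀ (y_j / A_j x) ] / [ Σ_j A_jᵀ 1 ]

which preserves non-negativity.  A final voxel realignment shears the
estimate back to Cartesian sample coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GroupingPlan, ScanGeometry, shear_matrix, step_displacement
from .kernels import (
    FFTConvolver,
    block_mean,
    block_mean_adjoint,
    gaussian_kernel,
    shift_trilinear,
)
from .synth import PSFModel
from .volume import HRVolume, RawSequence

__all__ = [
    "LRGroup",
    "SVRConfig",
    "extract_lr_groups",
    "estimate_offsets",
    "initial_guess",
    "forward_project",
    "run_svr",
    "realign",
]


class TooFewFramesError(ValueError):
    pass


@dataclass
class LRGroup:
    """One decimated low-resolution stack with its known offsets.

    ``offset_hr_voxels`` is the oblique sample-frame offset ``j·d``
    ((x, y, z), HR-voxel units); ``scan_offset_hr_voxels`` is the same
    offset expressed in the scan frame where the stack actually lives
    ((z, y, x), axial component only).
    """

    stack: np.ndarray
    offset_hr_voxels: tuple
    scan_offset_hr_voxels: np.ndarray
    provenance: tuple
    lr_voxel_um: tuple  # (vx, vy, vz) with vz = actual group axial spacing
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError("group stack must be 3D")


@dataclass
class SVRConfig:
    max_iterations: int = 200
    rel_tolerance: float = 1e-4
    update: str = "poisson"  # or "leastsq"
    exponent: float = 1.0  # >1 accelerates the multiplicative update
    epsilon_scale: float = 1e-6
    init_group: int = 0
    dtype: str = "float64"  # "float32" halves time/memory for large runs

    def __post_init__(self):
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be > 0")
        if self.update not in ("poisson", "leastsq"):
            raise ValueError("update must be 'poisson' or 'leastsq'")
        if not (1.0 <= self.exponent <= 2.0):
            raise ValueError("exponent must lie in [1, 2]")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")


def extract_lr_groups(raw: RawSequence, plan: GroupingPlan) -> list[LRGroup]:
    """Decimate a raw sequence into ``G`` phase-shifted LR groups.

    Group j holds frames {j, j+M, j+2M, ...}; group provenances are
    disjoint and (for G = M) cover every frame.
    """
    T = raw.frames.shape[0]
    M = plan.decimation_M
    G = plan.n_groups_G
    if T < M:
        raise TooFewFramesError(f"{T} frames cannot fill a decimation of {M}")
    n_slices = (T - G) // M + 1
    if n_slices < 1:
        raise TooFewFramesError("not enough frames for the requested groups")
    pixel = raw.geometry.lr_voxel_um[0]
    scan_offsets = plan.scan_frame_offsets()
    groups = []
    for j in range(G):
        idx = tuple(range(j, j + n_slices * M, M))
        stack = np.ascontiguousarray(raw.frames[list(idx)], dtype=np.float64)
        groups.append(
            LRGroup(
                stack=stack,
                offset_hr_voxels=plan.offsets[j],
                scan_offset_hr_voxels=scan_offsets[j],
                provenance=idx,
                lr_voxel_um=(pixel, pixel, plan.lr_axial_spacing_um),
                origin_um=raw.origin_um,
            )
        )
    return groups


def estimate_offsets(
    groups: list[LRGroup],
    enhancement,
    upsample_factor: int = 20,
    min_confidence: float = 0.2,
) -> list[np.ndarray]:
    """Refine scan-frame group offsets by subvoxel phase correlation.

    Each group is correlated against group 0; the measured LR-voxel
    shift is converted to HR-voxel units.  Groups whose aligned
    correlation falls below ``min_confidence`` fall back to their
    nominal geometric offsets with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to correlate")
    from skimage.registration import phase_cross_correlation

    rz, ry, rx = int(enhancement[2]), int(enhancement[1]), int(enhancement[0])
    scale = np.array([rz, ry, rx], dtype=float)
    ref = groups[0].stack
    out = [np.zeros(3)]
    for g in groups[1:]:
        shift, _, _ = phase_cross_correlation(
            ref, g.stack, upsample_factor=upsample_factor, normalization=None
        )
        aligned = ndimage.shift(g.stack, shift, order=1, mode="constant")
        denom = ref.std() * aligned.std()
        conf = 0.0
        if denom > 0:
            conf = float(
                ((ref - ref.mean()) * (aligned - aligned.mean())).mean() / denom
            )
        if conf < min_confidence:
            warnings.warn(
                "phase correlation confidence "
                f"{conf:.3f} < {min_confidence}; falling back to nominal "
                "geometric offset",
                stacklevel=2,
            )
            out.append(np.asarray(g.scan_offset_hr_voxels, dtype=float))
        else:
            out.append(shift * scale)
    return out


def initial_guess(
    group: LRGroup, enhancement, epsilon_scale: float = 1e-6
) -> HRVolume:
    """Trilinear interpolation of one LR group onto the HR grid, with a
    strictly positive floor."""
    rz, ry, rx = int(enhancement[2]), int(enhancement[1]), int(enhancement[0])
    data = ndimage.zoom(
        group.stack, (rz, ry, rx), order=1, mode="nearest", grid_mode=True
    )
    eps = epsilon_scale * max(float(data.mean()), 1e-30)
    data = np.maximum(data, eps)
    hv = tuple(v / r for v, r in zip(group.lr_voxel_um, (rx, ry, rz)))
    origin = tuple(
        o - (r - 1) / 2.0 * h
        for o, r, h in zip(group.origin_um, (rx, ry, rz), hv)
    )
    return HRVolume(data=data, voxel_um=hv, origin_um=origin, frame="scan")


def _scan_frame_kernel(
    psf: PSFModel, geometry: ScanGeometry, hr_voxel_zyx
) -> np.ndarray:
    """Optics PSF expressed in the sheared scan frame."""
    shear_inv = shear_matrix(geometry).inverse().linear
    cov = shear_inv @ psf.covariance_zyx_um2() @ shear_inv.T
    return gaussian_kernel(cov, hr_voxel_zyx)


def forward_project(
    hr: HRVolume,
    offset_scan_hr_voxels,
    psf: PSFModel | None,
    enhancement,
    geometry: ScanGeometry | None = None,
) -> np.ndarray:
    """Predict one LR group from an HR scan-frame estimate:
    shift → blur → block-average downsample (all linear in the input).

    A ``None`` PSF means a delta (no blur); if ``geometry`` is given the
    PSF is sheared into the scan frame first.
    """
    rz, ry, rx = int(enhancement[2]), int(enhancement[1]), int(enhancement[0])
    x = np.asarray(hr.data, dtype=np.float64)
    x = shift_trilinear(x, offset_scan_hr_voxels)
    if psf is not None:
        voxel_zyx = np.asarray(hr.voxel_um, dtype=float)[::-1]
        if geometry is not None:
            kernel = _scan_frame_kernel(psf, geometry, voxel_zyx)
        else:
            kernel = gaussian_kernel(psf.covariance_zyx_um2(), voxel_zyx)
        x = FFTConvolver(kernel, x.shape, dtype=np.float64).convolve(x)
    return block_mean(x, (rz, ry, rx))


class _SVRProblem:
    """Cached operators for the iterative update (blur applied once per
    iteration, shift/downsample per group; exact adjoint pairing)."""

    def __init__(self, groups, psf, geometry, enhancement, offsets=None,
                 dtype=np.float64):
        self.rzyx = (int(enhancement[2]), int(enhancement[1]), int(enhancement[0]))
        z, y, x = groups[0].stack.shape
        self.lr_shape = (z, y, x)
        self.hr_shape = (z * self.rzyx[0], y * self.rzyx[1], x * self.rzyx[2])
        hv = np.array(
            [
                groups[0].lr_voxel_um[2] / self.rzyx[0],
                groups[0].lr_voxel_um[1] / self.rzyx[1],
                groups[0].lr_voxel_um[0] / self.rzyx[2],
            ]
        )
        self.hr_voxel_zyx = hv
        if psf is not None:
            kernel = _scan_frame_kernel(psf, geometry, hv)
            self.conv = FFTConvolver(kernel, self.hr_shape, dtype=dtype)
        else:
            self.conv = None
        if offsets is None:
            offsets = [np.asarray(g.scan_offset_hr_voxels, float) for g in groups]
        self.offsets = offsets
        self.dtype = dtype
        self.data = [np.asarray(g.stack, dtype=dtype) for g in groups]
        # scan-frame offsets are usually axial-only; then the lateral
        # binning commutes with every group shift and can be hoisted out
        # of the per-group loop (identical result, ~(ry·rx)× cheaper)
        self.lateral_only = all(
            abs(o[1]) < 1e-12 and abs(o[2]) < 1e-12 for o in offsets
        )
        self.small_shape = (self.hr_shape[0], self.lr_shape[1],
                            self.lr_shape[2])

    def blur(self, x):
        return self.conv.convolve(x) if self.conv is not None else x

    def blur_adj(self, x):
        return self.conv.correlate(x) if self.conv is not None else x

    def lateral_down(self, x):
        return block_mean(x, (1, self.rzyx[1], self.rzyx[2]))

    def lateral_up(self, x):
        return block_mean_adjoint(x, (1, self.rzyx[1], self.rzyx[2]),
                                  self.hr_shape)

    def project_small(self, x_lat, j):
        shifted = shift_trilinear(x_lat, (self.offsets[j][0], 0.0, 0.0))
        return block_mean(shifted, (self.rzyx[0], 1, 1))

    def backproject_small(self, lr, j):
        up = block_mean_adjoint(lr, (self.rzyx[0], 1, 1), self.small_shape)
        return shift_trilinear(up, (-self.offsets[j][0], 0.0, 0.0))

    def project_group(self, blurred, j):
        return block_mean(shift_trilinear(blurred, self.offsets[j]), self.rzyx)

    def backproject_group(self, lr, j):
        up = block_mean_adjoint(lr, self.rzyx, self.hr_shape)
        return shift_trilinear(up, -self.offsets[j])


def run_svr(
    groups: list[LRGroup],
    psf: PSFModel | None,
    geometry: ScanGeometry,
    config: SVRConfig | None = None,
    offsets: list[np.ndarray] | None = None,
) -> tuple[HRVolume, pd.DataFrame]:
    """Iterate the multi-frame maximum-likelihood update to convergence.

    Returns the scan-frame HR estimate and a per-iteration log with the
    data-fit KL divergence and the relative L2 change of the estimate.
    Pass ``offsets`` (scan-frame, HR voxels) to override the nominal
    geometric offsets, e.g. with :func:`estimate_offsets` output.
    """
    if not groups:
        raise ValueError("need at least one LR group")
    config = config or SVRConfig()
    enhancement = geometry.enhancement
    prob = _SVRProblem(groups, psf, geometry, enhancement, offsets,
                       dtype=np.dtype(config.dtype).type)
    total = sum(d.sum() for d in prob.data)
    hv_xyz = tuple(prob.hr_voxel_zyx[::-1])
    origin = tuple(
        o - (r - 1) / 2.0 * h
        for o, r, h in zip(groups[0].origin_um, enhancement, hv_xyz)
    )
    meta = {"shear_anchor_z_um": groups[0].origin_um[2]}
    if total <= 0:
        warnings.warn("all-zero LR data; returning zero volume", stacklevel=2)
        vol = HRVolume(
            np.zeros(prob.hr_shape), hv_xyz, origin, frame="scan", meta=meta
        )
        return vol, pd.DataFrame(columns=["iteration", "kl", "rel_change"])

    x = np.asarray(
        initial_guess(groups[config.init_group], enhancement,
                      config.epsilon_scale).data,
        dtype=prob.dtype,
    )
    eps = config.epsilon_scale * float(x.mean())
    ones_lr = np.ones(prob.lr_shape, dtype=prob.dtype)
    n_groups = len(groups)
    if prob.lateral_only:
        denom = prob.blur_adj(
            prob.lateral_up(
                sum(prob.backproject_small(ones_lr, j)
                    for j in range(n_groups))
            )
        )
    else:
        denom = prob.blur_adj(
            sum(prob.backproject_group(ones_lr, j) for j in range(n_groups))
        )
    denom = np.maximum(denom, eps)
    log = []
    for it in range(1, config.max_iterations + 1):
        blurred = prob.blur(x)
        kl = 0.0
        if prob.lateral_only:
            x_lat = prob.lateral_down(blurred)
            acc_small = np.zeros(prob.small_shape, dtype=prob.dtype)
            for j, y in enumerate(prob.data):
                pred = np.maximum(prob.project_small(x_lat, j), eps)
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(y > 0, y * np.log(y / pred), 0.0)
                kl += float((term - y + pred).sum(dtype=np.float64))
                r = y / pred if config.update == "poisson" else y - pred
                acc_small += prob.backproject_small(r, j)
            acc = prob.lateral_up(acc_small)
        else:
            acc = np.zeros(prob.hr_shape, dtype=prob.dtype)
            for j, y in enumerate(prob.data):
                pred = np.maximum(prob.project_group(blurred, j), eps)
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(y > 0, y * np.log(y / pred), 0.0)
                kl += float((term - y + pred).sum(dtype=np.float64))
                r = y / pred if config.update == "poisson" else y - pred
                acc += prob.backproject_group(r, j)
        if config.update == "poisson":
            corr = prob.blur_adj(acc) / denom
            corr = np.maximum(corr, 0.0)
            if config.exponent != 1.0:
                corr = corr**config.exponent
            x_new = x * corr
        else:
            grad = prob.blur_adj(acc)
            step = 1.0 / float(denom.max())
            x_new = np.maximum(x + step * grad, 0.0)
        if not np.all(np.isfinite(x_new)):
            raise FloatingPointError(f"non-finite estimate at iteration {it}")
        nrm = float(np.linalg.norm(x))
        rel = float(np.linalg.norm(x_new - x)) / max(nrm, 1e-30)
        log.append({"iteration": it, "kl": kl, "rel_change": rel})
        x = x_new
        if rel < config.rel_tolerance:
            break
    vol = HRVolume(np.asarray(x, dtype=np.float64), hv_xyz, origin,
                   frame="scan", meta=meta)
    return vol, pd.DataFrame(log)


def realign(
    hr: HRVolume, geometry: ScanGeometry, mode: str = "linear"
) -> HRVolume:
    """Apply the inverse shear, mapping the scan-frame estimate to
    Cartesian sample coordinates (flux-preserving resampling)."""
    d = step_displacement(geometry)
    gx = d.dx / d.dz
    gy = d.dy / d.dz
    order = {"linear": 1, "nearest": 0}[mode]
    if gx == 0.0 and gy == 0.0:
        out = HRVolume(
            hr.data.copy(), hr.voxel_um, hr.origin_um, frame="cartesian",
            meta=dict(hr.meta),
        )
        return out
    vz, vy, vx = hr.voxel_zyx
    oz, oy, ox = hr.origin_zyx
    z0 = float(hr.meta.get("shear_anchor_z_um", oz))
    nz, ny, nx = hr.data.shape
    z_lo = oz - z0
    z_hi = oz + (nz - 1) * vz - z0
    # cartesian lateral range = scan range + shear excursion
    def _range(g, o, n, v):
        lo = o + min(0.0, g * z_lo, g * z_hi)
        hi = o + (n - 1) * v + max(0.0, g * z_lo, g * z_hi)
        return lo, int(np.ceil((hi - lo) / v)) + 1

    oy_c, ny_c = _range(gy, oy, ny, vy)
    ox_c, nx_c = _range(gx, ox, nx, vx)
    # scan coords of an output point p:  q_lat = p_lat - g*(p_z - z0); q_z = p_z
    # index map: idx_scan = Minv (idx_cart * v + origin_cart_shift) ...
    lin = np.array(
        [
            [1.0, 0.0, 0.0],
            [-gy * vz / vy, 1.0, 0.0],
            [-gx * vz / vx, 0.0, 1.0],
        ]
    )
    origin_cart = np.array([oz, oy_c, ox_c])
    origin_scan = np.array([oz, oy, ox])
    voxel = np.array([vz, vy, vx])
    # q_um = L_um p_um + t_um with L_um rows as in shear inverse
    L_um = np.array([[1.0, 0.0, 0.0], [-gy, 1.0, 0.0], [-gx, 0.0, 1.0]])
    t_um = np.array([0.0, gy * z0, gx * z0])
    # idx_scan = (L_um (origin_cart + idx*voxel) + t_um - origin_scan)/voxel
    mat = L_um * voxel[None, :] / voxel[:, None]
    off = (L_um @ origin_cart + t_um - origin_scan) / voxel
    data = ndimage.affine_transform(
        np.asarray(hr.data, dtype=np.float64),
        mat,
        offset=off,
        output_shape=(nz, ny_c, nx_c),
        order=order,
        mode="constant",
        cval=0.0,
    )
    meta = dict(hr.meta)
    meta["realigned"] = True
    return HRVolume(
        data=np.maximum(data, 0.0),
        voxel_um=hr.voxel_um,
        origin_um=(ox_c, oy_c, oz),
        frame="cartesian",
        meta=meta,
    )
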