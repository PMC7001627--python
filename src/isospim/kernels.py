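"""Shared numerical primitives: Gaussian kernels, FFT convolution,
sub-voxel shifts and block resampling.

All operators here are linear, and the pairs used inside the iterative
reconstructions are exact numerical adjoints of each other (verified
against dense matrices in the test suite), which the multiplicative
maximum-likelihood updates rely on.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

__all__ = [
    "gaussian_kernel",
    "FFTConvolver",
    "shift_trilinear",
    "block_mean",
    "block_mean_adjoint",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # σ = FWHM · this


def gaussian_kernel(
    cov_zyx_um2: np.ndarray,
    voxel_zyx_um,
    truncate: float = 4.0,
) -> np.ndarray:
    """Render a normalized 3D Gaussian with covariance ``cov`` (µm²).

    The kernel is sampled on the voxel grid, centred on the middle voxel
    of an odd-sized array and normalized to sum 1.  General (including
    rotated or sheared) covariances are supported.
    """
    cov = np.asarray(cov_zyx_um2, dtype=float).reshape(3, 3)
    voxel = np.asarray(voxel_zyx_um, dtype=float)
    sd = np.sqrt(np.diag(cov))
    half = np.maximum(np.ceil(truncate * sd / voxel).astype(int), 1)
    grids = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    prec = np.linalg.inv(cov)
    quad = np.einsum("...i,ij,...j->...", pts, prec, pts)
    k = np.exp(-0.5 * quad)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate Gaussian kernel")
    return (k / s).astype(np.float64)


class FFTConvolver:
    """Cached-OTF linear convolution with a fixed, centred kernel.

    Inputs are zero-padded to the full linear-convolution size (rounded
    up to FFT-friendly lengths), so there is no circular wrap-around.
    For point-symmetric kernels (all Gaussians used here) the operator
    is self-adjoint; ``correlate`` applies the mirrored kernel and is
    exact in general.
    """

    def __init__(self, kernel: np.ndarray, shape, dtype=np.float32):
        kernel = np.asarray(kernel, dtype=np.float64)
        self.shape = tuple(shape)
        self.kshape = kernel.shape
        if any(k % 2 == 0 for k in kernel.shape):
            raise ValueError("kernel must have odd dimensions")
        full = [s + k - 1 for s, k in zip(self.shape, kernel.shape)]
        self.fshape = [sfft.next_fast_len(n, real=True) for n in full]
        self.dtype = dtype
        self._otf = sfft.rfftn(kernel, self.fshape)
        # mirrored kernel about its centre (NOT a circular conjugate,
        # which would misplace the crop window)
        self._otf_mirror = sfft.rfftn(kernel[::-1, ::-1, ::-1], self.fshape)
        if np.dtype(dtype) == np.float32:
            self._otf = self._otf.astype(np.complex64)
            self._otf_mirror = self._otf_mirror.astype(np.complex64)
        self._half = [k // 2 for k in kernel.shape]

    def _apply(self, x: np.ndarray, otf) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.shape != self.shape:
            raise ValueError("input shape does not match convolver")
        spec = sfft.rfftn(x, self.fshape)
        full = sfft.irfftn(spec * otf, self.fshape)
        sl = tuple(
            slice(h, h + s) for h, s in zip(self._half, self.shape)
        )
        return np.ascontiguousarray(full[sl]).astype(self.dtype, copy=False)

    def convolve(self, x: np.ndarray) -> np.ndarray:
        return self._apply(x, self._otf)

    def correlate(self, x: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`convolve` (mirrored-kernel convolution)."""
        return self._apply(x, self._otf_mirror)


def _shift_axis_linear(x: np.ndarray, shift: float, axis: int) -> np.ndarray:
    """Sample ``x`` at coordinate + shift along one axis (linear interp,
    zero outside).  Positive shift moves content toward lower indices."""
    n = x.shape[axis]
    k = int(np.floor(shift))
    f = shift - k
    out = np.zeros_like(x)

    def take(offset: int) -> tuple[slice, slice] | None:
        # out[i] += w * x[i + offset], valid where 0 <= i + offset < n
        lo = max(0, -offset)
        hi = min(n, n - offset)
        if hi <= lo:
            return None
        src = [slice(None)] * x.ndim
        dst = [slice(None)] * x.ndim
        dst[axis] = slice(lo, hi)
        src[axis] = slice(lo + offset, hi + offset)
        return tuple(dst), tuple(src)

    for offset, w in ((k, 1.0 - f), (k + 1, f)):
        if w == 0.0:
            continue
        spans = take(offset)
        if spans is not None:
            dst, src = spans
            out[dst] += w * x[src]
    return out


def shift_trilinear(x: np.ndarray, offset_zyx) -> np.ndarray:
    """Evaluate ``x`` at ``p + offset`` (voxel units) by trilinear
    interpolation with zero boundary.

    The adjoint of ``shift_trilinear(·, o)`` is ``shift_trilinear(·, -o)``
    because the interpolation kernel is symmetric.
    """
    out = np.asarray(x)
    for axis, s in enumerate(np.asarray(offset_zyx, dtype=float)):
        if s != 0.0:
            out = _shift_axis_linear(out, s, axis)
    return out if out is not x else out.copy()


def block_mean(x: np.ndarray, factors_zyx) -> np.ndarray:
    """Area-preserving downsampling: mean over (fz, fy, fx) blocks.

    Trailing samples that do not fill a block are discarded.
    """
    fz, fy, fx = (int(f) for f in factors_zyx)
    z, y, w = (n // f for n, f in zip(x.shape, (fz, fy, fx)))
    v = x[: z * fz, : y * fy, : w * fx]
    return v.reshape(z, fz, y, fy, w, fx).mean(axis=(1, 3, 5))


def block_mean_adjoint(y: np.ndarray, factors_zyx, out_shape) -> np.ndarray:
    """Adjoint of :func:`block_mean`: replicate each LR value over its
    block, scaled by 1/block-size."""
    fz, fy, fx = (int(f) for f in factors_zyx)
    b = fz * fy * fx
    rep = np.repeat(np.repeat(np.repeat(y, fz, axis=0), fy, axis=1), fx, axis=2)
    out = np.zeros(out_shape, dtype=rep.dtype)
    out[: rep.shape[0], : rep.shape[1], : rep.shape[2]] = rep / b
    return out
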