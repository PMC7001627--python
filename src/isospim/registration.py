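"""Feature-based multiview registration.

Point features (fluorescent beads, or cell bodies in tissue) are
detected as multi-scale difference-of-Gaussians maxima with subvoxel
quadratic localization, matched across views with rotation-invariant
constellation descriptors (sorted distances to the k nearest
neighbours) followed by random-sample consensus on a rigid fit, and the
resulting transform is used to pull every view onto the reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .transforms import AffineTransform3D
from .volume import HRVolume

__all__ = [
    "FeaturePoint",
    "CorrespondenceSet",
    "detect_features",
    "match_features",
    "fit_affine",
    "resample",
]


class NoConsensusError(RuntimeError):
    pass


class DegenerateConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FeaturePoint:
    """A detected blob feature (position in µm, volume-origin frame)."""

    position_um: tuple  # (x, y, z)
    scale_um: float
    intensity: float

    def zyx(self) -> np.ndarray:
        return np.asarray(self.position_um, dtype=float)[::-1]


@dataclass
class CorrespondenceSet:
    pairs: list  # of (index_a, index_b)
    inliers: list = field(default_factory=list)  # parallel bool flags
    residual_um: list = field(default_factory=list)

    def inlier_pairs(self) -> list:
        if not self.inliers:
            return list(self.pairs)
        return [p for p, ok in zip(self.pairs, self.inliers) if ok]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index_a": [p[0] for p in self.pairs],
                "index_b": [p[1] for p in self.pairs],
                "inlier": self.inliers or [True] * len(self.pairs),
                "residual_um": self.residual_um or [np.nan] * len(self.pairs),
            }
        )


def _quadratic_refine(arr: np.ndarray, idx: tuple) -> np.ndarray:
    """Per-axis parabolic refinement of a local maximum (≤ ±0.5 voxel)."""
    out = np.array(idx, dtype=float)
    for ax in range(3):
        i = idx[ax]
        if i <= 0 or i >= arr.shape[ax] - 1:
            continue
        sl = list(idx)
        sl[ax] = slice(i - 1, i + 2)
        f = arr[tuple(sl)].astype(float)
        denom = f[0] - 2.0 * f[1] + f[2]
        if denom < 0:
            out[ax] = i + 0.5 * (f[0] - f[2]) / denom
    return out


def detect_features(
    volume: HRVolume,
    scales_um,
    threshold: float,
    relative: bool = False,
    anisotropy: float = 1.0,
) -> list[FeaturePoint]:
    """Multi-scale DoG blob detection with subvoxel localization.

    ``scales_um`` are approximate feature FWHMs; for each, a
    difference-of-Gaussians response (σ, 1.6σ) is computed and local
    maxima above ``threshold`` are kept (if ``relative``, the threshold
    is a fraction of the global maximum response).  Within each scale,
    detections closer than one scale radius are merged, keeping the
    strongest.
    """
    scales = list(scales_um)
    if not scales:
        raise ValueError("need at least one detection scale")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    data = np.asarray(volume.data, dtype=np.float64)
    if data.max() <= 0:
        return []
    voxel = volume.voxel_zyx
    found: list[FeaturePoint] = []
    for scale in scales:
        sigma_um = np.array([scale * anisotropy, scale, scale]) / 2.3548
        s1 = sigma_um / voxel
        dog = ndimage.gaussian_filter(data, s1) - ndimage.gaussian_filter(
            data, 1.6 * s1
        )
        thr = threshold * dog.max() if relative else threshold
        if thr <= 0:
            continue
        mx = ndimage.maximum_filter(dog, size=3, mode="constant")
        peaks = np.argwhere((dog == mx) & (dog > thr))
        cands = []
        for p in peaks:
            refined = _quadratic_refine(dog, tuple(p))
            pos_zyx = refined * voxel + volume.origin_zyx
            cands.append((float(dog[tuple(p)]), pos_zyx))
        # suppress duplicates within one scale radius, keep strongest
        cands.sort(key=lambda c: -c[0])
        kept: list[tuple[float, np.ndarray]] = []
        for strength, pos in cands:
            if all(np.linalg.norm(pos - k[1]) >= scale / 2.0 for k in kept):
                kept.append((strength, pos))
        for strength, pos in kept:
            found.append(
                FeaturePoint(
                    position_um=tuple(pos[::-1]),
                    scale_um=float(scale),
                    intensity=strength,
                )
            )
    # merge across scales: keep strongest within the smaller scale radius
    found.sort(key=lambda f: -f.intensity)
    merged: list[FeaturePoint] = []
    for f in found:
        r = min(f.scale_um, *(g.scale_um for g in merged)) / 2.0 if merged else 0.0
        if all(np.linalg.norm(f.zyx() - g.zyx()) >= r for g in merged):
            merged.append(f)
    return merged


def _descriptors(points: np.ndarray, k: int) -> np.ndarray:
    """Sorted distances to the k nearest neighbours (rotation and
    translation invariant)."""
    tree = cKDTree(points)
    kq = min(k + 1, len(points))
    d, _ = tree.query(points, k=kq)
    desc = np.sort(d[:, 1:], axis=1)
    if desc.shape[1] < k:  # pad when fewer neighbours exist
        pad = np.full((len(points), k - desc.shape[1]), np.inf)
        desc = np.hstack([desc, pad])
    return desc


def _kabsch(src: np.ndarray, dst: np.ndarray) -> AffineTransform3D:
    """Least-squares rigid transform mapping src points onto dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return AffineTransform3D(R, mu_d - R @ mu_s)


def fit_affine(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    model: str = "rigid",
) -> AffineTransform3D:
    """Least-squares transform mapping points ``b`` onto points ``a``.

    Points are (N, 3) in (z, y, x) µm.  The rigid model solves the
    orthogonal alignment problem in closed form; the affine model uses
    linear least squares and needs ≥4 non-coplanar pairs.
    """
    a = np.asarray(pairs_a, dtype=float).reshape(-1, 3)
    b = np.asarray(pairs_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(a)
    if model == "rigid":
        if n < 3:
            raise ValueError("rigid fit needs >= 3 pairs")
        centered = b - b.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise DegenerateConfigurationError("points are collinear")
        return _kabsch(b, a)
    if model == "affine":
        if n < 4:
            raise ValueError("affine fit needs >= 4 pairs")
        X = np.hstack([b, np.ones((n, 1))])
        if np.linalg.matrix_rank(X, tol=1e-9) < 4:
            raise DegenerateConfigurationError(
                "points are coplanar/collinear; affine fit is rank-deficient"
            )
        sol, *_ = np.linalg.lstsq(X, a, rcond=None)
        return AffineTransform3D(sol[:3].T, sol[3])
    raise ValueError("model must be 'rigid' or 'affine'")


def match_features(
    a: list[FeaturePoint],
    b: list[FeaturePoint],
    init: AffineTransform3D | None = None,
    k_neighbors: int = 4,
    ratio: float = 0.8,
    inlier_radius_um: float = 1.0,
    n_draws: int = 1000,
    min_inlier_fraction: float = 0.25,
    seed: int = 0,
) -> CorrespondenceSet:
    """Match features of view B to view A.

    Candidate pairs come from nearest constellation descriptors with a
    ratio test; a seeded random-sample rigid consensus prunes them to a
    geometrically consistent inlier set.  If ``init`` is given it seeds
    the consensus directly.  Raises :class:`NoConsensusError` when the
    inlier fraction stays below ``min_inlier_fraction``.
    """
    if len(a) < 4 or len(b) < 4:
        raise ValueError("need >= 4 features in each view")
    pa = np.array([f.zyx() for f in a])
    pb = np.array([f.zyx() for f in b])
    da = _descriptors(pa, k_neighbors)
    db = _descriptors(pb, k_neighbors)
    # nearest descriptor with ratio test
    cand: list[tuple[int, int]] = []
    for i in range(len(a)):
        dist = np.linalg.norm(db - da[i], axis=1)
        order = np.argsort(dist)
        if len(order) > 1 and dist[order[0]] > ratio * dist[order[1]]:
            continue
        cand.append((i, int(order[0])))
    if len(cand) < 3 and init is None:
        raise NoConsensusError("too few descriptor matches for consensus")

    def _inliers(tf: AffineTransform3D):
        mapped = tf.apply(pb)
        tree = cKDTree(mapped)
        d, idx = tree.query(pa, k=1)
        pairs, used = [], set()
        for i in np.argsort(d):
            j = int(idx[i])
            if d[i] <= inlier_radius_um and j not in used:
                pairs.append(((int(i), j), float(d[i])))
                used.add(j)
        return pairs

    rng = np.random.default_rng(seed)
    best_pairs: list = []
    if init is not None:
        best_pairs = _inliers(init)
    ci = np.array([c[0] for c in cand])
    cj = np.array([c[1] for c in cand])
    for _ in range(n_draws):
        if len(cand) < 3:
            break
        sel = rng.choice(len(cand), size=3, replace=False)
        src = pb[cj[sel]]
        dst = pa[ci[sel]]
        if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9) < 2:
            continue
        tf = _kabsch(src, dst)
        trial = _inliers(tf)
        if len(trial) > len(best_pairs):
            best_pairs = trial
    n_min = max(3, int(np.ceil(min_inlier_fraction * min(len(a), len(b)))))
    if len(best_pairs) < n_min:
        raise NoConsensusError(
            f"consensus found only {len(best_pairs)} inliers (< {n_min})"
        )
    # refine once on the consensus set and recompute residuals
    idx_a = [p[0][0] for p in best_pairs]
    idx_b = [p[0][1] for p in best_pairs]
    tf = _kabsch(pb[idx_b], pa[idx_a])
    res = np.linalg.norm(tf.apply(pb[idx_b]) - pa[idx_a], axis=1)
    return CorrespondenceSet(
        pairs=[(int(i), int(j)) for i, j in zip(idx_a, idx_b)],
        inliers=[bool(r <= inlier_radius_um) for r in res],
        residual_um=[float(r) for r in res],
    )


def fit_from_correspondences(
    corr: CorrespondenceSet,
    a: list[FeaturePoint],
    b: list[FeaturePoint],
    model: str = "rigid",
) -> AffineTransform3D:
    pairs = corr.inlier_pairs()
    pa = np.array([a[i].zyx() for i, _ in pairs])
    pb = np.array([b[j].zyx() for _, j in pairs])
    return fit_affine(pa, pb, model=model)


def resample(
    volume: HRVolume,
    transform: AffineTransform3D,
    target_grid: HRVolume | dict,
    mode: str = "linear",
) -> HRVolume:
    """Pull a view onto the reference grid.

    ``transform`` maps the view's physical coordinates into the
    reference frame; the target grid is given either by an existing
    volume or a dict with ``shape``, ``voxel_um`` and ``origin_um``.
    Voxels sampled from outside the view are zero and flagged in the
    validity mask stored at ``meta['validity']``.
    """
    if isinstance(target_grid, HRVolume):
        shape = target_grid.data.shape
        voxel_um = target_grid.voxel_um
        origin_um = target_grid.origin_um
    else:
        shape = tuple(target_grid["shape"])
        voxel_um = tuple(target_grid["voxel_um"])
        origin_um = tuple(target_grid["origin_um"])
    order = {"linear": 1, "nearest": 0}[mode]
    inv = transform.inverse()
    voxel_t = np.asarray(voxel_um, dtype=float)[::-1]
    origin_t = np.asarray(origin_um, dtype=float)[::-1]
    voxel_s = volume.voxel_zyx
    origin_s = volume.origin_zyx
    # idx_src = (inv.linear @ (origin_t + idx*voxel_t) + inv.t - origin_s)/voxel_s
    mat = inv.linear * voxel_t[None, :] / voxel_s[:, None]
    off = (inv.linear @ origin_t + inv.translation_um - origin_s) / voxel_s
    src = np.asarray(volume.data, dtype=np.float64)
    data = ndimage.affine_transform(
        src, mat, offset=off, output_shape=shape, order=order,
        mode="constant", cval=0.0,
    )
    validity = ndimage.affine_transform(
        np.ones_like(src), mat, offset=off, output_shape=shape, order=order,
        mode="constant", cval=0.0,
    )
    return HRVolume(
        data=np.maximum(data, 0.0),
        voxel_um=voxel_um,
        origin_um=origin_um,
        frame="cartesian",
        meta={"validity": validity > 0.999, "source_meta": dict(volume.meta)},
    )
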