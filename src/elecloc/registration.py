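"""Rigid CT→MRI coregistration by normalized mutual information.

The cost is the normalized mutual information

    NMI(A, B) = (H(A) + H(B)) / H(A, B)

computed from a joint intensity histogram of the fixed (T1) and moving
(CT) volumes.  NMI lies in [1, 2]: 1 for independent intensities, 2 when
either image determines the other exactly, and is invariant to any
bijective relabeling of intensity bins — which is what makes it suitable
for cross-modal registration (bone is bright in CT and dark in T1, yet the
dependence between the two is maximal when the skulls line up).

Optimization is derivative-free (Powell) over the 6 rigid parameters
(translation mm, intrinsic x-y-z Euler angles in degrees, rotation about
the fixed-volume center), run coarse→fine over a Gaussian resolution
pyramid with each level warm-started from the previous one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core_io import RigidTransform, Volume, voxel_to_world, world_to_voxel

logger = logging.getLogger(__name__)

__all__ = ["RegOptions", "joint_histogram", "nmi", "register_rigid", "resample", "mip_slab"]


@dataclass
class RegOptions:
    """Knobs of the NMI registration.

    n_bins : histogram bins per intensity axis (>= 8).
    hist_sigma_bins : Gaussian smoothing of the joint histogram, in bins
        (Parzen-like regularization; 0 disables).
    interpolation : how the moving volume is sampled ("trilinear"/"nearest").
    xtol, ftol : Powell tolerances on parameters / cost.
    pyramid : downsampling factors, strictly decreasing to 1.
    max_samples : cap on fixed-voxel samples per level at coarse levels
        (the finest level uses the full grid).
    clip_percentiles : intensity clipping before min–max binning; CT metal
        artifacts otherwise compress the histogram into a few bins.
    seed : seed for the voxel subsampling.
    """

    n_bins: int = 32
    hist_sigma_bins: float = 1.0
    interpolation: str = "trilinear"
    xtol: float = 1e-4
    ftol: float = 1e-4
    pyramid: tuple = (4, 2, 1)
    max_samples: int = 200_000
    clip_percentiles: tuple = (1.0, 99.0)
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        p = tuple(self.pyramid)
        if p[-1] != 1 or any(a <= b for a, b in zip(p, p[1:])):
            raise ValueError("pyramid factors must strictly decrease to 1")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be 'trilinear' or 'nearest'")


def _bin_volume(data: np.ndarray, n_bins: int, clip_percentiles) -> np.ndarray:
    """Min–max rescale to [0, n_bins) after percentile clipping; int bins."""
    lo, hi = np.percentile(data, clip_percentiles)
    if hi <= lo:
        lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        hi = lo + 1.0
    scaled = (np.clip(data, lo, hi) - lo) / (hi - lo) * (n_bins - 1e-6)
    return np.clip(scaled.astype(np.int32), 0, n_bins - 1)


def _scale_params(data: np.ndarray, clip_percentiles) -> tuple:
    lo, hi = np.percentile(data, clip_percentiles)
    if hi <= lo:
        lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def joint_histogram(
    fixed: Volume,
    moving: Volume,
    t: RigidTransform | None = None,
    opts: RegOptions | None = None,
    sample_ijk: np.ndarray | None = None,
) -> np.ndarray:
    """Joint intensity histogram of ``fixed`` and ``moving`` under ``t``.

    The moving volume is sampled at ``t⁻¹(world(fixed voxel))`` — i.e. ``t``
    maps moving-space world coordinates onto fixed-space world coordinates,
    the same convention :func:`resample` uses.  Intensities of each volume
    are min–max rescaled to ``[0, n_bins)`` (after percentile clipping)
    before binning.  Raises if fewer than 10% of the sampled fixed voxels
    land inside the moving volume.
    """
    opts = opts or RegOptions()
    t = t or RigidTransform.identity()
    if sample_ijk is None:
        grid = np.indices(fixed.shape).reshape(3, -1).T
    else:
        grid = np.asarray(sample_ijk)
    fixed_bins_all = _bin_volume(fixed.data, opts.n_bins, opts.clip_percentiles)
    fb = fixed_bins_all[grid[:, 0], grid[:, 1], grid[:, 2]]
    world = voxel_to_world(fixed, grid)
    mov_lo, mov_hi = _scale_params(moving.data, opts.clip_percentiles)
    hist, n_overlap = _histogram_at(
        fb, world, moving, t, opts, (mov_lo, mov_hi)
    )
    if n_overlap < 0.10 * len(grid):
        raise ValueError("no overlap under transform")
    if opts.hist_sigma_bins > 0:
        total = hist.sum()
        hist = ndimage.gaussian_filter(hist, opts.hist_sigma_bins, mode="constant")
        s = hist.sum()
        if s > 0:
            hist *= total / s
    return hist


def _histogram_at(fixed_bins, fixed_world, moving, t, opts, mov_range):
    """Raw (unsmoothed) joint histogram; returns (hist, n_overlap)."""
    mov_world = t.inverse().apply(fixed_world)
    ijk = world_to_voxel(moving, mov_world)
    shape = np.asarray(moving.shape)
    inside = np.all((ijk >= 0) & (ijk <= shape - 1), axis=1)
    n_overlap = int(inside.sum())
    if n_overlap == 0:
        return np.zeros((opts.n_bins, opts.n_bins)), 0
    order = 1 if opts.interpolation == "trilinear" else 0
    vals = ndimage.map_coordinates(
        moving.data.astype(np.float32), ijk[inside].T, order=order, mode="nearest"
    )
    lo, hi = mov_range
    mb = ((np.clip(vals, lo, hi) - lo) / (hi - lo) * (opts.n_bins - 1e-6)).astype(np.int32)
    mb = np.clip(mb, 0, opts.n_bins - 1)  # float32 rounding at the range edge
    joint = np.bincount(
        fixed_bins[inside].astype(np.int64) * opts.n_bins + mb,
        minlength=opts.n_bins * opts.n_bins,
    ).reshape(opts.n_bins, opts.n_bins).astype(float)
    return joint, n_overlap


def nmi(hist: np.ndarray) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) of a joint histogram.

    Entropies are Shannon entropies in nats of the normalized histogram.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise ValueError("all-zero histogram")
    p = hist / total
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _H(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = _H(p.ravel())
    if h_ab == 0.0:
        return 2.0  # single occupied cell: degenerate, perfectly dependent
    return (_H(pa) + _H(pb)) / h_ab


def register_rigid(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    opts: RegOptions | None = None,
) -> RigidTransform:
    """Recover the rigid moving→fixed transform maximizing NMI.

    Runs Powell minimization of −NMI over a coarse→fine Gaussian pyramid;
    each level is warm-started from the previous.  Rotation is about the
    fixed volume's world center.  On non-convergence a warning is issued
    and the best transform found so far is returned with
    ``result.converged = False`` attached (attribute ``converged``, and
    per-level NMI in ``level_log``).
    """
    opts = opts or RegOptions()
    center = voxel_to_world(fixed, (np.asarray(fixed.shape, float) - 1) / 2)
    if init is None:
        init = RigidTransform(center=center)
    params = np.concatenate([init.translation, init.rotation])
    rng = np.random.default_rng(opts.seed)

    level_log = []
    converged = True
    for level, factor in enumerate(opts.pyramid):
        fdata, mdata = fixed.data.astype(np.float32), moving.data.astype(np.float32)
        # factor/2 matches the sampling stride; the floor of 0.5 voxel at the
        # finest level suppresses trilinear-interpolation artifacts in the
        # NMI landscape that otherwise bias sub-degree rotations
        sigma = max(factor / 2.0, 0.5)
        fdata = ndimage.gaussian_filter(fdata, sigma)
        mdata = ndimage.gaussian_filter(mdata, sigma)
        fvol = Volume(fdata, fixed.affine, frame=fixed.frame)
        mvol = Volume(mdata, moving.affine, frame=moving.frame)

        idx = np.indices(fixed.shape)[:, ::factor, ::factor, ::factor].reshape(3, -1).T
        if factor > 1 and len(idx) > opts.max_samples:
            sel = rng.choice(len(idx), size=opts.max_samples, replace=False)
            idx = idx[sel]
        fixed_bins = _bin_volume(fvol.data, opts.n_bins, opts.clip_percentiles)
        fb = fixed_bins[idx[:, 0], idx[:, 1], idx[:, 2]]
        fworld = voxel_to_world(fvol, idx)
        mov_range = _scale_params(mvol.data, opts.clip_percentiles)

        def cost(p):
            t = RigidTransform(translation=p[:3], rotation=p[3:], center=center)
            hist, n_ov = _histogram_at(fb, fworld, mvol, t, opts, mov_range)
            if n_ov < max(100, 0.10 * len(fb)):
                return 0.0  # −NMI lower bound: discourage leaving the overlap
            if opts.hist_sigma_bins > 0:
                hist = ndimage.gaussian_filter(hist, opts.hist_sigma_bins, mode="constant")
            return -nmi(hist)

        nmi0 = -cost(params)
        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options=dict(xtol=opts.xtol, ftol=opts.ftol, maxiter=opts.max_iter),
        )
        params = res.x
        level_log.append(
            dict(level=level, factor=factor, n_samples=len(fb), nmi_start=nmi0,
                 nmi_end=-res.fun, params=params.copy())
        )
        logger.info(
            "pyramid level %d (factor %d): NMI %.4f -> %.4f", level, factor, nmi0, -res.fun
        )
        converged = converged and bool(res.success)
    if not converged:
        warnings.warn(
            "rigid registration did not converge; returning best transform so far "
            "(poor initial conditions are the usual cause — supply a rough manual init)",
            RuntimeWarning,
        )
    out = RigidTransform(translation=params[:3], rotation=params[3:], center=center)
    out.converged = converged
    out.level_log = level_log
    return out


def resample(
    moving: Volume,
    t: RigidTransform,
    like: Volume,
    interpolation: str = "trilinear",
) -> Volume:
    """Pull-resample ``moving`` through ``t`` onto ``like``'s grid.

    Out-of-field voxels are zero.  ``t`` maps moving world → fixed world,
    so each output voxel center is pulled from ``t⁻¹`` of its world
    position.
    """
    grid = np.indices(like.shape).reshape(3, -1).T
    world = voxel_to_world(like, grid)
    src = world_to_voxel(moving, t.inverse().apply(world))
    order = 1 if interpolation == "trilinear" else 0
    vals = ndimage.map_coordinates(
        moving.data.astype(np.float64), src.T, order=order, mode="constant", cval=0.0
    )
    return Volume(vals.reshape(like.shape), like.affine, frame=like.frame)


def mip_slab(vol: Volume, axis: int, slice_index: int, half_width: int = 15) -> np.ndarray:
    """Maximum intensity projection over ``slice_index ± half_width`` slices.

    The slab is clipped to the volume bounds; ``half_width=0`` returns the
    plain slice.  A 15-slice half-width makes CT electrode artifacts
    conspicuous while keeping local context.
    """
    n = vol.shape[axis]
    if not (0 <= slice_index < n):
        raise IndexError(f"slice {slice_index} outside axis of length {n}")
    lo = max(0, slice_index - half_width)
    hi = min(n, slice_index + half_width + 1)
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    return np.asarray(vol.data[tuple(sl)]).max(axis=axis)
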