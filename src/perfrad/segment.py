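"""Semi-automatic 3D tumor segmentation from an approximate bounding box.

The method has three stages:

1. **Preprocessing** — Gaussian smoothing, gradient-based anisotropic
   diffusion, central-difference gradient magnitude in HU/mm, and a rank
   transform of the gradient magnitude to [0, 1].  The rank transform makes
   the edge map invariant to any monotone intensity remapping.
2. **Initial segmentation** — voxels in the bounding box are kept when their
   HU falls within three standard deviations of the mean of a central sample
   of the lesion, floored at -400 HU, i.e. the interval
   ``[max(mu - 3*sigma, -400), mu + 3*sigma]``; morphological dilation, 3D
   flood filling (hole filling + retention of the connected component that
   contains the box centre) and erosion then produce a clean initial mask.
3. **Level-set refinement** — the initial mask seeds a signed distance
   function evolved under a geodesic active-contour flow whose speed combines
   curvature regularisation and advection toward edges through the
   edge-stopping function ``g = 1 - rank-transformed gradient``; a per-slice
   2D pass smooths the final contour.

Everything is deterministic: there is no randomness anywhere in this module.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.stats import rankdata

from .imaging import BinaryMask, BoundingBox, CTVolume

HU_FLOOR = -400.0  # lesions are soft tissue; anything below is air/fat boundary


class SegmentationError(RuntimeError):
    pass


class EmptySegmentationError(SegmentationError):
    pass


class DegenerateSeedError(SegmentationError):
    pass


class CollapseError(SegmentationError):
    """Level-set evolution emptied the contour; carries the last nonempty mask."""

    def __init__(self, message: str, last_mask: np.ndarray):
        super().__init__(message)
        self.last_mask = last_mask


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma_mm: float = 1.0
    diffusion_iters: int = 5
    diffusion_conductance: float = 2.0
    diffusion_timestep: float = 0.06  # stability bound for 3D is 0.0625
    morph_radius_mm: float | None = None  # default: one voxel (max spacing)
    levelset_max_iters: int = 300
    curvature_weight: float = 1.0
    advection_weight: float = 2.0
    balloon_weight: float = 0.0
    convergence_tol: float = 0.001  # fraction of voxels changing sign per iteration
    reinit_every: int = 25
    slice_iters: int = 20
    box_margin_voxels: int = 5
    center_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.diffusion_iters < 1 or self.levelset_max_iters < 1 or self.slice_iters < 0:
            raise ValueError("iteration counts must be >= 1")
        if min(self.curvature_weight, self.advection_weight) < 0:
            raise ValueError("level-set weights must be >= 0")
        if not 0.0 < self.convergence_tol < 1.0:
            raise ValueError("convergence tolerance must be in (0, 1)")
        if not 0.0 < self.center_fraction <= 1.0:
            raise ValueError("center fraction must be in (0, 1]")


@dataclasses.dataclass
class PreprocessedVolume:
    """Outputs of the preprocessing stage, all on the source grid."""

    smoothed: np.ndarray  # HU after smoothing + anisotropic diffusion
    gradient_magnitude: np.ndarray  # HU/mm, central differences
    rank_gradient: np.ndarray  # gradient magnitude rank-transformed to [0, 1]
    spacing: tuple[float, float, float]


@dataclasses.dataclass
class SegmentationResult:
    mask: BinaryMask
    initial_mask: BinaryMask
    diagnostics: dict


def rank_transform(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Rank-transform values to [0, 1] with average ranks for ties.

    With ``mask`` given, only masked entries are ranked; the rest are 0.
    Invariant under any strictly increasing remapping of ``values``.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape)
    flat = values[mask] if mask is not None else values.ravel()
    n = flat.size
    if n == 0:
        return out
    ranks = rankdata(flat, method="average")
    scaled = (ranks - 1.0) / (n - 1.0) if n > 1 else np.full(n, 0.5)
    if mask is not None:
        out[mask] = scaled
    else:
        out = scaled.reshape(values.shape)
    return out


def _anisotropic_diffusion(arr: np.ndarray, spacing, params: SegmentationParams) -> np.ndarray:
    img = sitk.GetImageFromArray(arr.astype(np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))  # sitk wants (x,y,z)
    f = sitk.GradientAnisotropicDiffusionImageFilter()
    f.SetNumberOfIterations(int(params.diffusion_iters))
    f.SetConductanceParameter(float(params.diffusion_conductance))
    f.SetTimeStep(float(params.diffusion_timestep))
    return sitk.GetArrayFromImage(f.Execute(img))


def preprocess(vol: CTVolume, params: SegmentationParams | None = None) -> PreprocessedVolume:
    """Stage 1: smooth, diffuse, take the physical gradient magnitude, rank it."""
    params = params or SegmentationParams()
    if min(vol.shape) < 2:
        raise SegmentationError("gradient undefined on a single-voxel axis")
    sig_vox = [params.smoothing_sigma_mm / h for h in vol.spacing]
    smoothed = ndimage.gaussian_filter(vol.voxels.astype(np.float64), sigma=sig_vox)
    smoothed = _anisotropic_diffusion(smoothed, vol.spacing, params)
    grads = np.gradient(smoothed, *vol.spacing)
    gmag = np.sqrt(sum(g * g for g in grads))
    return PreprocessedVolume(smoothed, gmag, rank_transform(gmag), vol.spacing)


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Anisotropy-aware ball: offsets whose physical distance is <= radius."""
    r_vox = [max(1, int(np.floor(radius_mm / h + 1e-9))) for h in spacing]
    grids = np.meshgrid(*[np.arange(-r, r + 1) * h for r, h in zip(r_vox, spacing)], indexing="ij")
    return (sum(g * g for g in grids) <= radius_mm**2 + 1e-9).astype(np.uint8)


def threshold_interval(mu: float, sigma: float) -> tuple[float, float]:
    """HU interval [max(mu - 3*sigma, -400), mu + 3*sigma] for the initial stage."""
    return (max(mu - 3.0 * sigma, HU_FLOOR), mu + 3.0 * sigma)


def _center_sample_slices(box: BoundingBox, fraction: float) -> tuple[slice, ...]:
    out = []
    for lo, hi in zip(box.lo, box.hi):
        n = hi - lo
        w = max(1, int(round(n * fraction)))
        start = lo + (n - w) // 2
        out.append(slice(start, start + w))
    return tuple(out)


def initial_segmentation(
    pre: PreprocessedVolume,
    vol: CTVolume,
    box: BoundingBox,
    params: SegmentationParams | None = None,
) -> tuple[BinaryMask, dict]:
    """Stage 2: statistical thresholding + morphological cleanup.

    Sample statistics come from the central ``center_fraction`` of the box per
    axis, computed on the raw HU voxels (the smoothed grids only drive the
    level-set stage).  Returns the mask and a diagnostics dict with mu, sigma
    and the threshold interval.
    """
    params = params or SegmentationParams()
    box.validate_within(vol.shape)
    sample = vol.voxels[_center_sample_slices(box, params.center_fraction)]
    if sample.size == 0:
        raise SegmentationError("empty centre sample")
    mu, sigma = float(sample.mean()), float(sample.std())
    if np.all(sample < HU_FLOOR):
        raise DegenerateSeedError(f"centre sample entirely below {HU_FLOOR} HU (mu={mu:.1f})")
    lo, hi = threshold_interval(mu, sigma)
    keep = np.zeros(vol.shape, dtype=bool)
    sl = box.slices
    region = vol.voxels[sl]
    keep[sl] = (region >= lo) & (region <= hi)
    if not keep.any():
        raise EmptySegmentationError(
            f"threshold interval [{lo:.1f}, {hi:.1f}] HU excludes every voxel in the box"
        )
    radius = params.morph_radius_mm if params.morph_radius_mm is not None else max(vol.spacing)
    ball = _ball_footprint(radius, vol.spacing)
    work = ndimage.binary_dilation(keep, structure=ball)
    work = ndimage.binary_fill_holes(work)
    labels, _ = ndimage.label(work)
    centre = box.center
    lab = labels[centre]
    if lab == 0:
        # centre fell outside the thresholded set: take the component nearest it
        fg = labels > 0
        if not fg.any():
            raise EmptySegmentationError("morphology produced an empty mask")
        idx = np.argwhere(fg)
        d2 = ((idx - np.array(centre)) * np.array(vol.spacing)) ** 2
        lab = labels[tuple(idx[np.argmin(d2.sum(axis=1))])]
    work = labels == lab
    work = ndimage.binary_erosion(work, structure=ball)
    # locality: confine to the dilated box
    allowed = np.zeros(vol.shape, dtype=bool)
    allowed[box.dilate(params.box_margin_voxels, vol.shape).slices] = True
    work &= allowed
    if not work.any():
        raise EmptySegmentationError("initial segmentation empty after erosion")
    diag = {"center_mean_hu": mu, "center_sd_hu": sigma, "threshold_lo": lo, "threshold_hi": hi}
    return BinaryMask(work.astype(np.uint8), vol.spacing, vol.origin), diag


# ---------------------------------------------------------------------------
# Level-set evolution
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance, negative inside the mask, in mm."""
    inside = mask.astype(bool)
    if not inside.any():
        return np.full(mask.shape, max(s * n for s, n in zip(spacing, mask.shape)))
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    return np.where(inside, -d_in, d_out)


def _curvature_times_gradnorm(phi: np.ndarray, spacing) -> np.ndarray:
    """kappa * |grad phi| = laplacian(phi) - (grad phi . H . grad phi)/|grad phi|^2."""
    grads = np.gradient(phi, *spacing)
    gnorm2 = sum(g * g for g in grads)
    lap = 0.0
    quad = 0.0
    for i, gi in enumerate(grads):
        hrow = np.gradient(gi, *spacing)
        lap = lap + hrow[i]
        for j, hij in enumerate(hrow):
            quad = quad + grads[i] * grads[j] * hij
    return lap - quad / np.maximum(gnorm2, 1e-12)


def _upwind_advection(phi: np.ndarray, vel: list[np.ndarray], spacing) -> np.ndarray:
    """Upwind approximation of  sum_i v_i * dphi/dx_i  for phi_t = v . grad phi."""
    total = np.zeros(phi.shape)
    for ax, (v, h) in enumerate(zip(vel, spacing)):
        fwd = (np.roll(phi, -1, axis=ax) - phi) / h
        bwd = (phi - np.roll(phi, 1, axis=ax)) / h
        # one-sided copies at the borders
        sl_last = [slice(None)] * phi.ndim
        sl_last[ax] = -1
        fwd[tuple(sl_last)] = bwd[tuple(sl_last)]
        sl_first = [slice(None)] * phi.ndim
        sl_first[ax] = 0
        bwd[tuple(sl_first)] = fwd[tuple(sl_first)]
        total += np.where(v > 0, fwd, bwd) * v
    return total


def _evolve(
    phi: np.ndarray,
    g: np.ndarray,
    spacing,
    params: SegmentationParams,
    max_iters: int,
    curvature: float,
    advection: float,
    balloon: float,
) -> tuple[np.ndarray, int]:
    """Run the geodesic flow  phi_t = a*g*kappa|grad phi| + b*grad g . grad phi
    + c*g*|grad phi|  until the changed-voxel fraction stays below tolerance."""
    grad_g = [w * advection for w in np.gradient(g, *spacing)]
    inv_h2 = sum(1.0 / h**2 for h in spacing)
    v_over_h = sum(np.abs(v).max() / h for v, h in zip(grad_g, spacing))
    dt = 0.8 / (2.0 * max(curvature, 1e-12) * inv_h2 + v_over_h + abs(balloon) * inv_h2 + 1e-12)
    prev_inside = phi < 0
    last_nonempty = prev_inside
    stable = 0
    it = 0
    # per-iteration interface displacement is O(h^2) for curvature flow, so a
    # voxel flip can take tens of iterations to build up: before any flip has
    # happened a longer quiet period is required than after the contour has
    # demonstrably locked in place
    min_quiet_after_flip = min(30, max_iters)
    min_quiet_no_flip = min(80, max_iters)
    any_flip = False
    flipped_since_reinit = False
    for it in range(1, max_iters + 1):
        force = np.zeros(phi.shape)
        if curvature > 0:
            force += curvature * g * _curvature_times_gradnorm(phi, spacing)
        if advection > 0:
            force += _upwind_advection(phi, grad_g, spacing)
        if balloon != 0.0:
            grads = np.gradient(phi, *spacing)
            force += balloon * g * np.sqrt(sum(gr * gr for gr in grads))
        phi = phi + dt * force
        inside = phi < 0
        changed = np.count_nonzero(inside != prev_inside) / phi.size
        prev_inside = inside
        if not inside.any():
            raise CollapseError("level-set evolution emptied the contour", last_nonempty)
        last_nonempty = inside
        if changed > 0:
            any_flip = True
            flipped_since_reinit = True
        min_iters = min_quiet_after_flip if any_flip else min_quiet_no_flip
        if changed < params.convergence_tol and it >= min_iters:
            stable += 1
            if stable >= 5:
                break
        else:
            stable = 0
        # re-anchor phi to a signed distance, but only once the interface has
        # actually moved — otherwise sub-voxel progress would be wiped out
        if it % params.reinit_every == 0 and flipped_since_reinit:
            phi = _signed_distance(inside, spacing)
            flipped_since_reinit = False
    return phi, it


def levelset_refine(
    init: BinaryMask,
    pre: PreprocessedVolume,
    params: SegmentationParams | None = None,
) -> tuple[BinaryMask, dict]:
    """Stage 3: 3D geodesic level-set refinement, then a per-slice 2D pass.

    The edge-stopping function is ``g = 1 - rank_gradient``: near zero on the
    strongest edges, so the contour halts there; curvature smooths the surface
    and advection pulls it into the gradient valleys.
    """
    params = params or SegmentationParams()
    if not init.voxels.any():
        raise EmptySegmentationError("level-set refinement needs a nonempty initial mask")
    g = 1.0 - pre.rank_gradient
    spacing = pre.spacing
    # crop to the init neighbourhood for speed; evolution is local
    idx = np.argwhere(init.voxels > 0)
    lo = np.maximum(idx.min(axis=0) - params.box_margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + params.box_margin_voxels + 1, init.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub_mask = init.voxels[sl].astype(bool)
    sub_g = g[sl]

    phi = _signed_distance(sub_mask, spacing)
    try:
        phi, iters3d = _evolve(
            phi, sub_g, spacing, params, params.levelset_max_iters,
            params.curvature_weight, params.advection_weight, params.balloon_weight,
        )
        inside = phi < 0
    except CollapseError as err:
        raise CollapseError(str(err), _embed(err.last_mask, sl, init.shape)) from None

    # per-slice 2D smoothing pass
    iters2d = 0
    if params.slice_iters > 0:
        out = inside.copy()
        for k in range(inside.shape[0]):
            if not inside[k].any():
                continue
            phi2 = _signed_distance(inside[k], spacing[1:])
            try:
                phi2, it2 = _evolve(
                    phi2, sub_g[k], spacing[1:], params, params.slice_iters,
                    params.curvature_weight, params.advection_weight, 0.0,
                )
                out[k] = phi2 < 0
                iters2d = max(iters2d, it2)
            except CollapseError:
                out[k] = inside[k]  # keep the 3D result where 2D smoothing collapses
        inside = out
    if not inside.any():
        raise CollapseError("refinement emptied the mask", init.voxels.copy())
    full = _embed(inside, sl, init.shape)
    diag = {"levelset_iters_3d": iters3d, "levelset_iters_2d_max": iters2d}
    return BinaryMask(full, spacing, init.origin), diag


def _embed(sub: np.ndarray, sl, shape) -> np.ndarray:
    full = np.zeros(shape, dtype=np.uint8)
    full[sl] = sub.astype(np.uint8)
    return full


def segment_tumor(
    vol: CTVolume,
    box: BoundingBox,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Run all three stages and return the final mask with diagnostics."""
    params = params or SegmentationParams()
    box.validate_within(vol.shape)
    pre = preprocess(vol, params)
    init, diag = initial_segmentation(pre, vol, box, params)
    refined, ls_diag = levelset_refine(init, pre, params)
    # locality contract: the final mask stays inside the dilated box
    allowed = np.zeros(vol.shape, dtype=bool)
    allowed[box.dilate(params.box_margin_voxels, vol.shape).slices] = True
    final = BinaryMask((refined.voxels.astype(bool) & allowed).astype(np.uint8), vol.spacing, vol.origin)
    if not final.voxels.any():
        raise EmptySegmentationError("refined mask empty after locality clipping")
    diag.update(ls_diag)
    return SegmentationResult(mask=final, initial_mask=init, diagnostics=diag)
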