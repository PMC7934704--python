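"""Radiomic and perfusion feature extraction.

Exactly 26 radiomic features are computed per (volume, mask) pair, in three
categories.  The list is fixed and versioned: consumers can rely on the names
and ordering of :data:`FEATURE_NAMES`.

**Volume / size (10)** — voxel count; volume (mm^3); surface area (mm^2) of
the 0.5-level marching-cubes mesh; equivalent-sphere diameter; bounding-box
volume; extent (volume / bbox volume); major, minor and least principal axis
lengths (4*sqrt of the coordinate-covariance eigenvalues, in mm); maximum 3D
diameter (largest pairwise distance between surface voxel centres).

**Shape (8)** — sphericity ``pi^(1/3) (6V)^(2/3) / A``; compactness
``V / (sqrt(pi) A^(3/2))``; spherical disproportion (1/sphericity);
surface-to-volume ratio; elongation ``sqrt(l2/l1)`` and flatness
``sqrt(l3/l1)`` of the covariance eigenvalues ``l1 >= l2 >= l3``; fractional
anisotropy of those eigenvalues; normalised radial SD (SD/mean of surface
voxel distances to the centroid).

**Gray level (8)** — mean, SD, skewness and excess kurtosis of HU inside the
mask; histogram entropy (bits) and energy with fixed 25-HU bins over
[-200, 300] (values clipped into range); border-core contrast (mean HU of the
eroded core minus mean HU of the one-voxel border shell); mean
gradient magnitude on the border shell, where gradients use **only in-mask
neighbours** (one-sided at the margin) so every intensity feature is exactly
invariant to voxel edits outside the mask.

Degenerate inputs (single voxel, zero intensity variance, empty core) yield
NaN for the features whose formula is undefined; the rest are still computed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .imaging import PERFUSION_PARAMS, BinaryMask, CTVolume, PerfusionMapSet

HIST_RANGE = (-200.0, 300.0)
HIST_BIN_WIDTH = 25.0

VOLUME_FEATURES = (
    "voxel_count",
    "volume_mm3",
    "surface_area_mm2",
    "equiv_sphere_diameter_mm",
    "bbox_volume_mm3",
    "extent",
    "major_axis_mm",
    "minor_axis_mm",
    "least_axis_mm",
    "max_diameter_3d_mm",
)
SHAPE_FEATURES = (
    "sphericity",
    "compactness",
    "spherical_disproportion",
    "surface_to_volume_ratio",
    "elongation",
    "flatness",
    "fractional_anisotropy",
    "radial_sd_norm",
)
GRAY_FEATURES = (
    "hu_mean",
    "hu_sd",
    "hu_skewness",
    "hu_kurtosis",
    "hu_entropy",
    "hu_energy",
    "border_core_contrast",
    "margin_gradient_mean",
)
FEATURE_NAMES: tuple[str, ...] = VOLUME_FEATURES + SHAPE_FEATURES + GRAY_FEATURES
assert len(FEATURE_NAMES) == 26

FEATURE_CATEGORIES = {
    **{f: "volume" for f in VOLUME_FEATURES},
    **{f: "shape" for f in SHAPE_FEATURES},
    **{f: "gray" for f in GRAY_FEATURES},
}


@dataclasses.dataclass(frozen=True)
class RadiomicFeatureVector:
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 26 named features in order")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[f] for f in FEATURE_NAMES])


@dataclasses.dataclass(frozen=True)
class PerfusionFeatureVector:
    """ROI means of the five perfusion parameters plus the voxel counts used."""

    values: dict[str, float]
    roi_voxels: dict[str, int]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_volume(mask: BinaryMask) -> float:
    """Tumor volume: 1-voxel count times the physical voxel volume (mm^3)."""
    n = int(mask.voxels.sum())
    if n == 0:
        warnings.warn("empty mask: volume is 0")
    return n * mask.voxel_volume


def _voxel_coords_mm(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask > 0)
    return idx * np.asarray(spacing)


MESH_SMOOTH_SIGMA_VOX = 1.0  # mollification before meshing, in voxels


def surface_mesh_area(mask: np.ndarray, spacing) -> float:
    """Area of the 0.5-level marching-cubes mesh of the mollified mask.

    The binary indicator is smoothed with a 1-voxel Gaussian before meshing:
    the raw staircase surface of a voxelised smooth body is ~8% larger than
    the body's true surface and does not converge with resolution, whereas
    the mollified 0.5-level surface does.  Masks too small to reach the 0.5
    level after mollification (e.g. a single voxel) have no surface: NaN.
    """
    from scipy.ndimage import gaussian_filter

    padded = np.pad(mask.astype(np.float64), 2)
    smooth = gaussian_filter(padded, sigma=MESH_SMOOTH_SIGMA_VOX)
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask."""
    m = mask.astype(bool)
    core = np.ones_like(m)
    for ax in range(3):
        for shift in (1, -1):
            rolled = np.roll(m, shift, axis=ax)
            edge = [slice(None)] * 3
            edge[ax] = 0 if shift == 1 else -1
            rolled[tuple(edge)] = False
            core &= rolled
    return m & ~core


def masked_gradient_magnitude(vol: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """Gradient magnitude using only in-mask neighbours.

    Per axis: central difference when both neighbours are inside the mask,
    one-sided when only one is, zero when neither is.  Exactly invariant to
    edits outside the mask.
    """
    m = mask.astype(bool)
    total = np.zeros(vol.shape)
    for ax, h in enumerate(spacing):
        plus = np.roll(vol, -1, axis=ax)
        minus = np.roll(vol, 1, axis=ax)
        m_plus = np.roll(m, -1, axis=ax)
        m_minus = np.roll(m, 1, axis=ax)
        hi = [slice(None)] * 3
        hi[ax] = -1
        m_plus[tuple(hi)] = False
        lo = [slice(None)] * 3
        lo[ax] = 0
        m_minus[tuple(lo)] = False
        d = np.zeros(vol.shape)
        both = m_plus & m_minus
        d[both] = (plus[both] - minus[both]) / (2.0 * h)
        only_p = m_plus & ~m_minus
        d[only_p] = (plus[only_p] - vol[only_p]) / h
        only_m = m_minus & ~m_plus
        d[only_m] = (vol[only_m] - minus[only_m]) / h
        total += d * d
    out = np.sqrt(total)
    out[~m] = 0.0
    return out


def extract_radiomics(vol: CTVolume, mask: BinaryMask) -> RadiomicFeatureVector:
    """Compute the 26 radiomic features for one (volume, mask) pair."""
    if not vol.same_grid(mask):
        raise ValueError("volume and mask grids differ")
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(vol.spacing)
    hu = vol.voxels[m].astype(np.float64)
    n = int(m.sum())
    vol_mm3 = n * mask.voxel_volume

    feats: dict[str, float] = {}
    feats["voxel_count"] = float(n)
    feats["volume_mm3"] = vol_mm3
    try:
        area = surface_mesh_area(m, spacing)
    except (RuntimeError, ValueError):
        area = float("nan")
    feats["surface_area_mm2"] = area
    feats["equiv_sphere_diameter_mm"] = float((6.0 * vol_mm3 / np.pi) ** (1.0 / 3.0))
    idx = np.argwhere(m)
    extent_vox = idx.max(axis=0) - idx.min(axis=0) + 1
    bbox_vol = float(np.prod(extent_vox * spacing))
    feats["bbox_volume_mm3"] = bbox_vol
    feats["extent"] = vol_mm3 / bbox_vol

    coords = idx * spacing
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / n  # population covariance of voxel centres
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    axis_len = 4.0 * np.sqrt(eig)
    feats["major_axis_mm"], feats["minor_axis_mm"], feats["least_axis_mm"] = map(float, axis_len)

    surf = _surface_voxels(m)
    surf_coords = np.argwhere(surf) * spacing
    if len(surf_coords) >= 2:
        if len(surf_coords) > 4:
            try:
                hull = ConvexHull(surf_coords)
                pts = surf_coords[hull.vertices]
            except Exception:
                pts = surf_coords
        else:
            pts = surf_coords
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        feats["max_diameter_3d_mm"] = float(np.sqrt(d2.max()))
    else:
        feats["max_diameter_3d_mm"] = 0.0

    # shape
    if np.isfinite(area) and area > 0:
        # capped at 1: the mollified mesh can under-measure a near-perfect
        # sphere's area by ~1%, and 1 is the theoretical supremum
        feats["sphericity"] = float(
            min(np.pi ** (1.0 / 3.0) * (6.0 * vol_mm3) ** (2.0 / 3.0) / area, 1.0)
        )
        feats["compactness"] = float(vol_mm3 / (np.sqrt(np.pi) * area**1.5))
        feats["spherical_disproportion"] = 1.0 / feats["sphericity"]
        feats["surface_to_volume_ratio"] = area / vol_mm3
    else:
        for f in ("sphericity", "compactness", "spherical_disproportion", "surface_to_volume_ratio"):
            feats[f] = float("nan")
    if eig[0] > 0:
        feats["elongation"] = float(np.sqrt(eig[1] / eig[0]))
        feats["flatness"] = float(np.sqrt(eig[2] / eig[0]))
    else:
        feats["elongation"] = float("nan")
        feats["flatness"] = float("nan")
    ssq = float((eig**2).sum())
    if ssq > 0:
        lbar = eig.mean()
        feats["fractional_anisotropy"] = float(np.sqrt(1.5 * ((eig - lbar) ** 2).sum() / ssq))
    else:
        feats["fractional_anisotropy"] = float("nan")
    r = np.sqrt(((surf_coords - centroid) ** 2).sum(axis=1)) if len(surf_coords) else np.array([])
    if r.size and r.mean() > 0:
        feats["radial_sd_norm"] = float(r.std() / r.mean())
    else:
        feats["radial_sd_norm"] = float("nan")

    # gray level
    mean = float(hu.mean())
    sd = float(hu.std())
    feats["hu_mean"] = mean
    feats["hu_sd"] = sd
    if sd > 0:
        z = (hu - mean) / sd
        feats["hu_skewness"] = float((z**3).mean())
        feats["hu_kurtosis"] = float((z**4).mean() - 3.0)
    else:
        feats["hu_skewness"] = float("nan")
        feats["hu_kurtosis"] = float("nan")
    nbins = int(round((HIST_RANGE[1] - HIST_RANGE[0]) / HIST_BIN_WIDTH))
    clipped = np.clip(hu, HIST_RANGE[0], HIST_RANGE[1])
    counts, _ = np.histogram(clipped, bins=nbins, range=HIST_RANGE)
    p = counts / counts.sum()
    nz = p[p > 0]
    feats["hu_entropy"] = float(-(nz * np.log2(nz)).sum())
    feats["hu_energy"] = float((p**2).sum())

    from scipy import ndimage

    core = ndimage.binary_erosion(m)
    border = m & ~core
    if core.any() and border.any():
        feats["border_core_contrast"] = float(vol.voxels[core].mean() - vol.voxels[border].mean())
    else:
        feats["border_core_contrast"] = float("nan")
    gmag = masked_gradient_magnitude(vol.voxels.astype(np.float64), m, spacing)
    feats["margin_gradient_mean"] = float(gmag[border].mean()) if border.any() else float("nan")

    return RadiomicFeatureVector({f: feats[f] for f in FEATURE_NAMES})


def perfusion_roi_stats(maps: PerfusionMapSet, mask: BinaryMask) -> PerfusionFeatureVector:
    """Mean of each perfusion map over the tumor ROI, missing voxels excluded.

    The mask must already live on the perfusion grid (see
    :func:`perfrad.imaging.resample_mask_to_grid`).
    """
    grid = maps.grid
    if not grid.same_grid(mask):
        raise ValueError("mask is not on the perfusion grid; resample it first")
    roi = mask.voxels.astype(bool)
    if not roi.any():
        raise ValueError(
            "ROI empty on the perfusion grid: the thin-slice mask did not survive "
            "the coverage-threshold transfer (resample_mask_to_grid)"
        )
    values, counts = {}, {}
    for p in PERFUSION_PARAMS:
        vals = maps[p].voxels[roi]
        vals = vals[np.isfinite(vals)]
        counts[p] = int(vals.size)
        values[p] = float(vals.mean()) if vals.size else float("nan")
    return PerfusionFeatureVector(values, counts)


def percent_change(pre_value: float, post_value: float) -> float:
    """100 * (post - pre) / pre; shrinkage is negative."""
    if pre_value == 0:
        raise ValueError("percent change undefined for a zero baseline value")
    return 100.0 * (post_value - pre_value) / pre_value


def classify_responder(volume_percent_change: float) -> bool:
    """Responder iff the tumor shrank by at least 50% (boundary inclusive)."""
    if not np.isfinite(volume_percent_change):
        raise ValueError("volume percent change must be finite")
    return volume_percent_change <= -50.0


@dataclasses.dataclass
class CaseRecord:
    """One patient's pre/post features, change features and labels."""

    case_id: str
    pre_radiomics: RadiomicFeatureVector
    post_radiomics: RadiomicFeatureVector
    pre_perfusion: PerfusionFeatureVector | None = None
    post_perfusion: PerfusionFeatureVector | None = None
    laryngoscopy_pct_change: float | None = None
    dfs_label: str | None = None

    def change_features(self) -> dict[str, float]:
        """Pre-to-post change features.

        Volume enters as percent change (the clinical convention for
        response); every other feature gets both an absolute change
        (``chg_<name>``) and a percent change (``pct_<name>``) where the
        baseline is nonzero.
        """
        out: dict[str, float] = {}
        out["volume_pct"] = percent_change(
            self.pre_radiomics["volume_mm3"], self.post_radiomics["volume_mm3"]
        )
        for name in FEATURE_NAMES:
            pre_v, post_v = self.pre_radiomics[name], self.post_radiomics[name]
            if name == "volume_mm3":
                continue
            out[f"chg_{name}"] = post_v - pre_v
            if np.isfinite(pre_v) and pre_v != 0 and np.isfinite(post_v):
                out[f"pct_{name}"] = percent_change(pre_v, post_v)
            else:
                out[f"pct_{name}"] = float("nan")
        if self.pre_perfusion is not None and self.post_perfusion is not None:
            for p in PERFUSION_PARAMS:
                pre_v, post_v = self.pre_perfusion[p], self.post_perfusion[p]
                out[f"chg_{p}"] = post_v - pre_v
                out[f"pct_{p}"] = percent_change(pre_v, post_v) if pre_v != 0 else float("nan")
        return out

    @property
    def responder(self) -> bool:
        return classify_responder(self.change_features()["volume_pct"])
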