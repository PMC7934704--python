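"""Volumetric image containers and I/O.

All grids in this package are axis-aligned with a fixed internal axis order
``(z, y, x)``: index ``voxels[k, j, i]`` sits at physical position
``origin + (k*dz, j*dy, i*dx)`` in millimetres.  Voxel index ranges are
0-based and half-open.  Hounsfield values are clamped to ``[-1024, 3071]``
when a volume is read from disk.

NIfTI files are read and written with :mod:`nibabel`; DICOM series with
:mod:`pydicom`.  On disk NIfTI data are stored in the conventional
``(x, y, z)`` layout and transposed on the way in and out.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom

HU_MIN = -1024.0
HU_MAX = 3071.0

#: sentinel for undefined voxels in perfusion maps
MISSING = np.nan

PERFUSION_PARAMS = ("PS", "BF", "BV", "MTT", "Tmax")
PERFUSION_UNITS = {
    "PS": "mL/100g/min",
    "BF": "mL/100g/min",
    "BV": "mL/100g",
    "MTT": "s",
    "Tmax": "s",
}


class FormatError(ValueError):
    """Raised for malformed or inconsistent image files."""


@dataclasses.dataclass(frozen=True)
class CTVolume:
    """A CT volume in Hounsfield units on a regular axis-aligned grid.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values, axis order (z, y, x).
    spacing : tuple of float
        Physical voxel size per axis in mm, order (z, y, x); all > 0.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm, order (z, y, x).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be 3D with >=1 voxel per axis, got shape {vox.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive components, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "CTVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask living on the grid of a parent :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError("mask must be 3D")
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    same_grid = CTVolume.same_grid

    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Per-axis half-open voxel index ranges [lo, hi), order (z, y, x)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if any(l < 0 for l in lo) or any(l >= h for l, h in zip(lo, hi)):
            raise ValueError(f"invalid bounding box lo={lo} hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    def validate_within(self, shape: Sequence[int]) -> None:
        if any(h > n for h, n in zip(self.hi, shape)):
            raise ValueError(f"bounding box {self} exceeds grid shape {tuple(shape)}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple((l + h) // 2 for l, h in zip(self.lo, self.hi))

    def dilate(self, margin: int, shape: Sequence[int]) -> "BoundingBox":
        lo = tuple(max(0, l - margin) for l in self.lo)
        hi = tuple(min(n, h + margin) for h, n in zip(self.hi, shape))
        return BoundingBox(lo, hi)


@dataclasses.dataclass(frozen=True)
class PerfusionMapSet:
    """The five deconvolution-derived perfusion parameter maps on one grid.

    PS and BF in mL/100g/min, BV in mL/100g, MTT and Tmax in seconds.
    Undefined voxels carry NaN.
    """

    maps: dict[str, CTVolume]

    def __post_init__(self) -> None:
        missing = set(PERFUSION_PARAMS) - set(self.maps)
        if missing:
            raise ValueError(f"perfusion map set missing parameters: {sorted(missing)}")
        ref = self.maps[PERFUSION_PARAMS[0]]
        for name in PERFUSION_PARAMS:
            m = self.maps[name]
            if not ref.same_grid(m):
                raise ValueError(f"perfusion map {name} not on the shared grid")
            if name != "PS":  # PS may legitimately be reported negative by some software
                vals = m.voxels[np.isfinite(m.voxels)]
                if vals.size and vals.min() < -1e-9:
                    raise ValueError(f"perfusion map {name} has negative values")

    def __getitem__(self, name: str) -> CTVolume:
        return self.maps[name]

    @property
    def grid(self) -> CTVolume:
        return self.maps[PERFUSION_PARAMS[0]]


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------


def _affine_from_grid(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    # grid order is (z,y,x); NIfTI stores (x,y,z)
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = [origin[2], origin[1], origin[0]]
    return aff


def write_volume(vol: CTVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1. Masks are stored as uint8, 1 = tumor."""
    data = vol.voxels
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine_from_grid(vol.spacing, vol.origin))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj).astype(np.float64), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    return data, spacing, origin


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM images under {path}")
    # order by projection of ImagePositionPatient onto the slice normal,
    # robust to renumbered InstanceNumber exports
    orient = np.array(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    slices.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal)))
    pos = np.array([np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal) for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(pos)
        dz = float(np.median(gaps))
        if dz <= 0 or np.any(np.abs(gaps - dz) > 0.01 * abs(dz)):
            raise FormatError("inconsistent DICOM slice spacing beyond 1% tolerance")
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    data = np.stack(
        [
            ds.pixel_array.astype(np.float64) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ]
    )
    ipp = np.array(slices[0].ImagePositionPatient, dtype=float)
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return data, (dz, dy, dx), origin


def read_volume(path: str | Path, clamp: bool = True) -> CTVolume:
    """Read a CT volume from a NIfTI file or a directory holding one DICOM series.

    HU values are clamped to [-1024, 3071]; axis order is normalised to (z,y,x).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        data, spacing, origin = _read_dicom_series(path)
    else:
        data, spacing, origin = _read_nifti(path)
    if clamp:
        data = np.clip(data, HU_MIN, HU_MAX)
    return CTVolume(data, spacing, origin)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask (uint8 NIfTI, 1 = tumor)."""
    data, spacing, origin = _read_nifti(Path(path))
    return BinaryMask((data > 0.5).astype(np.uint8), spacing, origin)


def read_perfusion_maps(directory: str | Path) -> PerfusionMapSet:
    """Read the five perfusion maps from ``<directory>/<PARAM>.nii.gz`` files."""
    directory = Path(directory)
    maps = {}
    for name in PERFUSION_PARAMS:
        candidates = list(directory.glob(f"{name}.nii*"))
        if not candidates:
            raise FileNotFoundError(f"missing perfusion map {name} under {directory}")
        maps[name] = read_volume(candidates[0], clamp=False)
    return PerfusionMapSet(maps)


def write_perfusion_maps(maps: PerfusionMapSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in PERFUSION_PARAMS:
        write_volume(maps[name], directory / f"{name}.nii.gz")


# ---------------------------------------------------------------------------
# Mask resampling between grids
# ---------------------------------------------------------------------------


def _axis_overlap(n_t: int, h_t: float, o_t: float, n_s: int, h_s: float, o_s: float) -> np.ndarray:
    """Overlap length matrix between target and source voxel intervals on one axis.

    Voxel ``i`` occupies the physical interval centred on ``o + i*h`` with
    width ``h``.  Returns an (n_t, n_s) matrix of interval-intersection
    lengths in mm.
    """
    t_lo = o_t + (np.arange(n_t) - 0.5) * h_t
    t_hi = t_lo + h_t
    s_lo = o_s + (np.arange(n_s) - 0.5) * h_s
    s_hi = s_lo + h_s
    lo = np.maximum(t_lo[:, None], s_lo[None, :])
    hi = np.minimum(t_hi[:, None], s_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def coverage_fraction(mask: BinaryMask, target: CTVolume | BinaryMask) -> np.ndarray:
    """Fraction of each target voxel's physical footprint covered by mask-1 voxels.

    Exact for axis-aligned grids: the footprint intersection factorises per
    axis, so the coverage is a separable tensor contraction of the mask with
    three interval-overlap matrices.
    """
    ov = [
        _axis_overlap(target.shape[ax], target.spacing[ax], target.origin[ax],
                      mask.shape[ax], mask.spacing[ax], mask.origin[ax])
        for ax in range(3)
    ]
    cov = np.einsum(
        "zs,yt,xu,stu->zyx", ov[0], ov[1], ov[2], mask.voxels.astype(np.float64),
        optimize=True,
    )
    return cov / float(np.prod(target.spacing))


def resample_mask_to_grid(mask: BinaryMask, target: CTVolume, threshold: float = 0.5) -> BinaryMask:
    """Transfer a mask to another grid by the >=50% footprint-coverage rule.

    A target voxel is set iff at least ``threshold`` of its physical volume is
    covered by source voxels equal to 1.  This is how a thin-slice (1.25 mm)
    contour is carried onto a thick-slice (5 mm) perfusion grid, where each
    perfusion slice is a composite of four thin slices.
    """
    if mask.same_grid(target):
        return BinaryMask(mask.voxels.copy(), mask.spacing, mask.origin)
    cov = coverage_fraction(mask, target)
    out = (cov >= threshold).astype(np.uint8)
    if mask.voxels.any() and not out.any():
        if cov.max() == 0.0:
            warnings.warn("mask and target grid have zero physical overlap; returning empty mask")
        else:
            warnings.warn("no target voxel reached the coverage threshold; returning empty mask")
    return BinaryMask(out, target.spacing, target.origin)
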