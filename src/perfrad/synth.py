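"""Synthetic phantoms and cohorts.

The study this package supports used paired pre/post-induction neck CT of 36
patients whose images cannot be shared.  This module generates stand-ins with
the statistical structure the analysis assumes:

* ellipsoidal tumor phantoms with a smoothed HU boundary and Gaussian noise,
  on a thin-slice "conventional" grid (default 1.25 mm slices) and matching
  thick-slice (5 mm) perfusion parameter maps;
* paired pre/post cases whose true volume ratio is set exactly by a shrink
  factor, with per-group perfusion truths;
* feature-level cohorts (default 36 cases, 10 without one-year disease-free
  survival) with multivariate-normal change features and simulated rater
  columns (two radiologist volume readings with multiplicative lognormal
  noise, one laryngoscopic percent-change estimate).

Everything is deterministic given the seed; label counts are exact rather
than binomial.  None of these distributions are claims about real tumors —
they are the package's own modelling assumptions (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import PERFUSION_PARAMS, BinaryMask, CTVolume, PerfusionMapSet

#: effect sizes (standardised mean difference nonDFS - DFS) calibrated so the
#: informative features sit at the AUC scale the analysis is designed for:
#: population AUC = Phi(d/sqrt(2)) -> 0.68 for the blood-flow change and 0.64
#: for the percent volume change.
DEFAULT_EFFECT_SIZES = {
    "d_BF_pct": 0.6612,
    "d_volume_pct": 0.5073,
}

#: typical head-and-neck tumor perfusion values used as generator means
PERFUSION_TRUTH_MEANS = {"PS": 15.0, "BF": 80.0, "BV": 5.0, "MTT": 8.0, "Tmax": 4.0}
PERFUSION_TRUTH_SDS = {"PS": 4.0, "BF": 20.0, "BV": 1.5, "MTT": 2.0, "Tmax": 1.0}


class SpecError(ValueError):
    """Raised when a phantom or cohort specification is invalid."""


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream: hashing (seed, stage) keeps one
    stage's draws independent of every other stage's."""
    import zlib

    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Specification of one ellipsoidal tumor phantom."""

    shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (1.25, 1.0, 1.0)
    center_mm: tuple[float, float, float] | None = None  # default: grid centre
    radii_mm: tuple[float, float, float] = (12.0, 10.0, 8.0)
    tumor_hu: float = 80.0
    background_hu: float = -100.0
    noise_sd: float = 8.0
    edge_width_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise SpecError("ellipsoid radii must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be >= 0")
        c = self.resolved_center()
        for ax in range(3):
            extent = (self.shape[ax] - 1) * self.spacing[ax]
            if c[ax] - self.radii_mm[ax] < 0 or c[ax] + self.radii_mm[ax] > extent:
                raise SpecError(
                    f"tumor extends beyond grid on axis {ax}: "
                    f"centre {c[ax]} mm, radius {self.radii_mm[ax]} mm, extent {extent} mm"
                )

    def resolved_center(self) -> tuple[float, float, float]:
        if self.center_mm is not None:
            return self.center_mm
        return tuple((n - 1) * h / 2.0 for n, h in zip(self.shape, self.spacing))

    def analytic_volume_mm3(self) -> float:
        rz, ry, rx = self.radii_mm
        return 4.0 / 3.0 * math.pi * rz * ry * rx


def _ellipsoid_occupancy_mask(spec: PhantomSpec, subdiv: int = 5) -> np.ndarray:
    """>=50%-occupancy discretisation of the ellipsoid via subvoxel sampling."""
    c = spec.resolved_center()
    offs = (np.arange(subdiv) + 0.5) / subdiv - 0.5  # subcell centres in voxel units
    frac = np.zeros(spec.shape)
    coords = [np.arange(n) * h for n, h in zip(spec.shape, spec.spacing)]
    for oz in offs:
        for oy in offs:
            for ox in offs:
                z = (coords[0] + oz * spec.spacing[0] - c[0]) / spec.radii_mm[0]
                y = (coords[1] + oy * spec.spacing[1] - c[1]) / spec.radii_mm[1]
                x = (coords[2] + ox * spec.spacing[2] - c[2]) / spec.radii_mm[2]
                inside = (
                    z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
                ) <= 1.0
                frac += inside
    frac /= subdiv**3
    return (frac >= 0.5).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, BinaryMask]:
    """Build one phantom volume and its noiseless ground-truth mask.

    The tumor boundary is smoothed with a linear HU ramp over
    ``edge_width_mm`` (measured by signed Euclidean distance to the mask
    surface), then additive Gaussian noise is applied.  The mask is the
    noiseless >=50%-occupancy ellipsoid discretisation.
    """
    mask = _ellipsoid_occupancy_mask(spec)
    inside = mask.astype(bool)
    # signed distance: positive outside the tumor, negative inside
    d_out = ndimage.distance_transform_edt(~inside, sampling=spec.spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spec.spacing)
    signed = np.where(inside, -d_in, d_out)
    if spec.edge_width_mm > 0:
        t = np.clip(0.5 - signed / spec.edge_width_mm, 0.0, 1.0)
    else:
        t = inside.astype(float)
    vox = spec.background_hu + (spec.tumor_hu - spec.background_hu) * t
    if spec.noise_sd > 0:
        rng = rng_for(spec.seed, "phantom-noise")
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape)
    vol = CTVolume(vox, spec.spacing)
    return vol, BinaryMask(mask, spec.spacing)


@dataclasses.dataclass
class SyntheticCase:
    """One simulated patient: paired scans, truth, labels and rater columns."""

    case_id: str
    pre_volume: CTVolume
    post_volume: CTVolume
    pre_mask: BinaryMask
    post_mask: BinaryMask
    true_pre_volume_mm3: float
    true_post_volume_mm3: float
    true_perfusion_pre: dict[str, float]
    true_perfusion_post: dict[str, float]
    label: str  # "DFS" or "nonDFS"
    rater_volumes: dict[str, tuple[float, float]]  # rater -> (pre, post) mm^3
    laryngoscopy_pct_change: float

    @property
    def true_pct_volume_change(self) -> float:
        return 100.0 * (self.true_post_volume_mm3 - self.true_pre_volume_mm3) / self.true_pre_volume_mm3

    @property
    def responder(self) -> bool:
        # >=50% decrease, boundary inclusive
        return self.true_pct_volume_change <= -50.0


def generate_case_pair(
    spec: PhantomSpec,
    shrink_factor: float,
    label: str = "DFS",
    case_id: str = "case",
    perfusion_pre: dict[str, float] | None = None,
    perfusion_post: dict[str, float] | None = None,
    rater_log_sd: float = 0.0,
    laryngoscopy_sd: float = 0.0,
) -> SyntheticCase:
    """Generate a paired pre/post case.

    Post-scan ellipsoid radii are scaled by ``shrink_factor**(1/3)`` so that
    the true volume ratio equals ``shrink_factor`` exactly.
    """
    if not 0.0 < shrink_factor <= 1.5:
        raise SpecError(f"shrink_factor must be in (0, 1.5], got {shrink_factor}")
    scale = shrink_factor ** (1.0 / 3.0)
    post_radii = tuple(r * scale for r in spec.radii_mm)
    if min(post_radii) < max(spec.spacing):
        raise SpecError("shrunk tumor smaller than one voxel")
    post_spec = dataclasses.replace(spec, radii_mm=post_radii, seed=spec.seed + 1)
    pre_vol, pre_mask = generate_phantom(spec)
    post_vol, post_mask = generate_phantom(post_spec)
    v_pre = spec.analytic_volume_mm3()
    v_post = post_spec.analytic_volume_mm3()

    rng = rng_for(spec.seed, "case-truths")
    if perfusion_pre is None:
        perfusion_pre = {
            p: max(0.1, rng.normal(PERFUSION_TRUTH_MEANS[p], PERFUSION_TRUTH_SDS[p]))
            for p in PERFUSION_PARAMS
        }
    if perfusion_post is None:
        perfusion_post = {
            p: max(0.1, perfusion_pre[p] * rng.lognormal(-0.1, 0.2)) for p in PERFUSION_PARAMS
        }
    raters = {}
    for rater in ("rad1", "rad2"):
        noise = rng.normal(0.0, rater_log_sd, size=2) if rater_log_sd > 0 else np.zeros(2)
        raters[rater] = (v_pre * math.exp(noise[0]), v_post * math.exp(noise[1]))
    true_pc = 100.0 * (v_post - v_pre) / v_pre
    lar_pc = true_pc + (rng.normal(0.0, laryngoscopy_sd) if laryngoscopy_sd > 0 else 0.0)
    return SyntheticCase(
        case_id=case_id,
        pre_volume=pre_vol,
        post_volume=post_vol,
        pre_mask=pre_mask,
        post_mask=post_mask,
        true_pre_volume_mm3=v_pre,
        true_post_volume_mm3=v_post,
        true_perfusion_pre=perfusion_pre,
        true_perfusion_post=perfusion_post,
        label=label,
        rater_volumes=raters,
        laryngoscopy_pct_change=float(lar_pc),
    )


def generate_perfusion_maps(
    case: SyntheticCase,
    timepoint: str = "pre",
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0),
    background: dict[str, float] | None = None,
    noise_frac: float = 0.05,
    seed: int | None = None,
) -> PerfusionMapSet:
    """Thick-slice perfusion maps consistent with a case's true values.

    Each map is the tumor truth inside the (downsampled) tumor region, a
    muscle-like background outside, plus proportional Gaussian noise.  Emulates
    the 5 mm cine composite grid; it does not simulate deconvolution.
    """
    vol = case.pre_volume if timepoint == "pre" else case.post_volume
    mask = case.pre_mask if timepoint == "pre" else case.post_mask
    truth = case.true_perfusion_pre if timepoint == "pre" else case.true_perfusion_post
    shape = tuple(
        max(1, int(round(n * h / ht))) for n, h, ht in zip(vol.shape, vol.spacing, spacing)
    )
    target = CTVolume(np.zeros(shape), spacing, vol.origin)
    from .imaging import resample_mask_to_grid

    roi = resample_mask_to_grid(mask, target).voxels.astype(bool)
    if background is None:
        background = {p: 0.35 * PERFUSION_TRUTH_MEANS[p] for p in PERFUSION_PARAMS}
    rng = rng_for(seed if seed is not None else 0, f"perfusion-maps-{timepoint}")
    maps = {}
    for p in PERFUSION_PARAMS:
        vals = np.where(roi, truth[p], background[p]).astype(float)
        if noise_frac > 0:
            vals = vals * (1.0 + rng.normal(0.0, noise_frac, size=vals.shape))
        maps[p] = CTVolume(np.clip(vals, 0.0, None), spacing, vol.origin)
    return PerfusionMapSet(maps)


# ---------------------------------------------------------------------------
# Feature-level cohorts
# ---------------------------------------------------------------------------


def rater_log_sd_for_icc(target_icc: float, case_log_sd: float) -> float:
    """Per-scan rater lognormal SD giving a target percent-change ICC.

    With case log volume ratio L ~ N(mu, s^2) and rater log noise
    delta ~ N(0, 2*sigma_r^2) per percent-change reading, the population ICC
    of percent change between two raters has the closed form

        ICC = (1 - e^{-s^2}) / ((1 - e^{-s^2}) + (e^{2 sigma_r^2} - 1)),

    solved here for sigma_r.
    """
    if not 0.0 < target_icc < 1.0:
        raise SpecError("target ICC must be in (0, 1)")
    b = 1.0 - math.exp(-(case_log_sd**2))
    return math.sqrt(0.5 * math.log(1.0 + b * (1.0 - target_icc) / target_icc))


#: names of the 26 change features the default cohort carries: the six
#: perfusion/volume changes plus 20 uninformative radiomic-change columns
def default_feature_names() -> list[str]:
    names = ["volume_pct", "BF_pct", "PS_pct", "BV_pct", "MTT_pct", "Tmax_pct"]
    names += [f"radiomic_chg_{i:02d}" for i in range(1, 21)]
    return names


@dataclasses.dataclass
class CohortConfig:
    """Configuration of a feature-level synthetic cohort.

    ``effect_sizes`` maps feature name to the standardised mean difference of
    the nonDFS group relative to the DFS group (feature SD 1 by default, so
    the per-feature population AUC is Phi(d / sqrt(2))).
    """

    n_cases: int = 36
    n_nondfs: int = 10
    responder_fraction: float = 33.0 / 44.0
    feature_names: list[str] = dataclasses.field(default_factory=default_feature_names)
    effect_sizes: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "BF_pct": DEFAULT_EFFECT_SIZES["d_BF_pct"],
            "volume_pct": DEFAULT_EFFECT_SIZES["d_volume_pct"],
        }
    )
    feature_sds: dict[str, float] = dataclasses.field(default_factory=dict)
    correlation: np.ndarray | None = None  # inter-feature correlation, default identity
    case_log_sd: float = 0.5  # SD of case-to-case log volume ratio
    target_icc: float = 0.75  # calibration target for the radiologist raters
    laryngoscopy_icc: float = 0.55  # much noisier external rater
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_nondfs < self.n_cases:
            raise SpecError("need 0 < n_nondfs < n_cases")
        for sd in self.feature_sds.values():
            if sd <= 0:
                raise SpecError("feature SDs must be positive")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (len(self.feature_names),) * 2:
                raise SpecError("correlation matrix shape must match feature count")
            if not np.allclose(c, c.T):
                raise SpecError("correlation matrix must be symmetric")
            eig = np.linalg.eigvalsh(c)
            if eig.min() < -1e-10:
                raise SpecError("correlation matrix must be positive semi-definite")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table: one row per case, exact label counts.

    Columns: case_id, label, dfs (0/1 with 1 = did NOT achieve DFS, the
    positive class of the prediction task), responder, true/rater volumes and
    percent changes, the laryngoscopic percent change, and one column per
    change feature.
    """
    rng = rng_for(config.seed, "cohort")
    n, p = config.n_cases, len(config.feature_names)
    labels = np.array([1] * config.n_nondfs + [0] * (n - config.n_nondfs))
    rng.shuffle(labels)

    sds = np.array([config.feature_sds.get(f, 1.0) for f in config.feature_names])
    means = np.zeros((n, p))
    for j, f in enumerate(config.feature_names):
        d = config.effect_sizes.get(f, 0.0)
        means[:, j] = labels * d * sds[j]
    corr = config.correlation if config.correlation is not None else np.eye(p)
    cov = corr * np.outer(sds, sds)
    feats = means + rng.multivariate_normal(np.zeros(p), cov, size=n, method="svd")

    # ground-truth volumes: lognormal pre volume, log ratio tied loosely to the
    # volume_pct feature's group structure
    v_pre = np.exp(rng.normal(math.log(8000.0), 0.4, size=n))
    log_ratio = rng.normal(math.log(0.45), config.case_log_sd, size=n)
    v_post = v_pre * np.exp(log_ratio)
    true_pc = 100.0 * (v_post - v_pre) / v_pre

    sig_r = rater_log_sd_for_icc(config.target_icc, config.case_log_sd)
    sig_l = rater_log_sd_for_icc(config.laryngoscopy_icc, config.case_log_sd)
    rows = {}
    for rater, sig in (("rad1", sig_r), ("rad2", sig_r)):
        pre = v_pre * np.exp(rng.normal(0.0, sig, size=n))
        post = v_post * np.exp(rng.normal(0.0, sig, size=n))
        rows[f"{rater}_pre_volume"] = pre
        rows[f"{rater}_post_volume"] = post
        rows[f"{rater}_pct_change"] = 100.0 * (post - pre) / pre
    lar_ratio = np.exp(log_ratio + rng.normal(0.0, sig_l * math.sqrt(2.0), size=n))
    rows["laryngoscopy_pct_change"] = 100.0 * (lar_ratio - 1.0)

    df = pd.DataFrame(
        {
            "case_id": [f"case{i:03d}" for i in range(n)],
            "label": np.where(labels == 1, "nonDFS", "DFS"),
            "dfs_fail": labels,
            "true_pre_volume": v_pre,
            "true_post_volume": v_post,
            "true_pct_change": true_pc,
            "responder": (true_pc <= -50.0).astype(int),
            **rows,
        }
    )
    for j, f in enumerate(config.feature_names):
        df[f] = feats[:, j]
    return df
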