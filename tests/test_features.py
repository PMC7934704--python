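"""Feature extraction: brute-force oracles, invariances, change rules."""

import math

import numpy as np
import pytest

from perfrad import features, imaging, synth


# ---------------------------------------------------------------------------
# independent brute-force implementation of every radiomic feature
# ---------------------------------------------------------------------------


def brute_force_radiomics(vol: imaging.CTVolume, mask: imaging.BinaryMask) -> dict:
    """Loop-based reference implementation, coded independently of the package."""
    m = mask.voxels.astype(bool)
    hz, hy, hx = vol.spacing
    voxvol = hz * hy * hx
    idx = [tuple(i) for i in np.argwhere(m)]
    n = len(idx)
    out = {}
    out["voxel_count"] = float(n)
    out["volume_mm3"] = n * voxvol
    V = out["volume_mm3"]

    # surface area: same mesh definition (mollified marching cubes), area summed
    # triangle by triangle with the explicit Heron-style cross-product loop
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    padded = np.pad(m.astype(float), 2)
    smooth = gaussian_filter(padded, sigma=features.MESH_SMOOTH_SIGMA_VOX)
    try:
        verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=vol.spacing)
        area = 0.0
        for f in faces:
            p0, p1, p2 = verts[f[0]], verts[f[1]], verts[f[2]]
            u, v = p1 - p0, p2 - p0
            cx = u[1] * v[2] - u[2] * v[1]
            cy = u[2] * v[0] - u[0] * v[2]
            cz = u[0] * v[1] - u[1] * v[0]
            area += 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)
    except (RuntimeError, ValueError):
        area = float("nan")
    out["surface_area_mm2"] = area
    out["equiv_sphere_diameter_mm"] = (6.0 * V / math.pi) ** (1.0 / 3.0)

    zs = [i[0] for i in idx]
    ys = [i[1] for i in idx]
    xs = [i[2] for i in idx]
    bbox = (max(zs) - min(zs) + 1) * hz * (max(ys) - min(ys) + 1) * hy * (max(xs) - min(xs) + 1) * hx
    out["bbox_volume_mm3"] = bbox
    out["extent"] = V / bbox

    coords = [(i[0] * hz, i[1] * hy, i[2] * hx) for i in idx]
    cz = sum(c[0] for c in coords) / n
    cy = sum(c[1] for c in coords) / n
    cx = sum(c[2] for c in coords) / n
    cov = np.zeros((3, 3))
    for c in coords:
        d = np.array([c[0] - cz, c[1] - cy, c[2] - cx])
        cov += np.outer(d, d)
    cov /= n
    eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
    eig = [max(e, 0.0) for e in eig]
    out["major_axis_mm"], out["minor_axis_mm"], out["least_axis_mm"] = (
        4.0 * math.sqrt(e) for e in eig
    )

    # surface voxels: any 6-neighbour outside
    def is_surface(i):
        for ax in range(3):
            for d in (-1, 1):
                j = list(i)
                j[ax] += d
                if not (0 <= j[ax] < m.shape[ax]) or not m[tuple(j)]:
                    return True
        return False

    surf = [i for i in idx if is_surface(i)]
    surf_mm = [(i[0] * hz, i[1] * hy, i[2] * hx) for i in surf]
    dmax = 0.0
    for i in range(len(surf_mm)):
        for j in range(i + 1, len(surf_mm)):
            d = math.dist(surf_mm[i], surf_mm[j])
            dmax = max(dmax, d)
    out["max_diameter_3d_mm"] = dmax

    if math.isfinite(area) and area > 0:
        out["sphericity"] = min(math.pi ** (1 / 3) * (6 * V) ** (2 / 3) / area, 1.0)
        out["compactness"] = V / (math.sqrt(math.pi) * area**1.5)
        out["spherical_disproportion"] = 1.0 / out["sphericity"]
        out["surface_to_volume_ratio"] = area / V
    else:
        for k in ("sphericity", "compactness", "spherical_disproportion", "surface_to_volume_ratio"):
            out[k] = float("nan")
    out["elongation"] = math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else float("nan")
    out["flatness"] = math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else float("nan")
    ssq = sum(e * e for e in eig)
    lbar = sum(eig) / 3.0
    out["fractional_anisotropy"] = (
        math.sqrt(1.5 * sum((e - lbar) ** 2 for e in eig) / ssq) if ssq > 0 else float("nan")
    )
    radii = [math.dist(p, (cz, cy, cx)) for p in surf_mm]
    if radii and sum(radii) > 0:
        rmean = sum(radii) / len(radii)
        rsd = math.sqrt(sum((r - rmean) ** 2 for r in radii) / len(radii))
        out["radial_sd_norm"] = rsd / rmean
    else:
        out["radial_sd_norm"] = float("nan")

    hu = [float(vol.voxels[i]) for i in idx]
    mean = sum(hu) / n
    var = sum((h - mean) ** 2 for h in hu) / n
    sd = math.sqrt(var)
    out["hu_mean"] = mean
    out["hu_sd"] = sd
    if sd > 0:
        out["hu_skewness"] = sum(((h - mean) / sd) ** 3 for h in hu) / n
        out["hu_kurtosis"] = sum(((h - mean) / sd) ** 4 for h in hu) / n - 3.0
    else:
        out["hu_skewness"] = out["hu_kurtosis"] = float("nan")
    nbins = int(round((features.HIST_RANGE[1] - features.HIST_RANGE[0]) / features.HIST_BIN_WIDTH))
    counts = [0] * nbins
    for h in hu:
        h = min(max(h, features.HIST_RANGE[0]), features.HIST_RANGE[1])
        b = int((h - features.HIST_RANGE[0]) / features.HIST_BIN_WIDTH)
        counts[min(b, nbins - 1)] += 1
    ps = [c / n for c in counts if c > 0]
    out["hu_entropy"] = -sum(p * math.log2(p) for p in ps)
    out["hu_energy"] = sum((c / n) ** 2 for c in counts)

    # core via 6-connected erosion (scipy default structuring element)
    core = [i for i in idx if not is_surface(i)]
    border = [i for i in idx if is_surface(i)]
    if core and border:
        out["border_core_contrast"] = (
            sum(float(vol.voxels[i]) for i in core) / len(core)
            - sum(float(vol.voxels[i]) for i in border) / len(border)
        )
    else:
        out["border_core_contrast"] = float("nan")

    def masked_grad(i):
        total = 0.0
        for ax, h in enumerate(vol.spacing):
            jp = list(i); jp[ax] += 1
            jm = list(i); jm[ax] -= 1
            p_in = 0 <= jp[ax] < m.shape[ax] and m[tuple(jp)]
            m_in = 0 <= jm[ax] < m.shape[ax] and m[tuple(jm)]
            if p_in and m_in:
                d = (float(vol.voxels[tuple(jp)]) - float(vol.voxels[tuple(jm)])) / (2 * h)
            elif p_in:
                d = (float(vol.voxels[tuple(jp)]) - float(vol.voxels[i])) / h
            elif m_in:
                d = (float(vol.voxels[i]) - float(vol.voxels[tuple(jm)])) / h
            else:
                d = 0.0
            total += d * d
        return math.sqrt(total)

    out["margin_gradient_mean"] = (
        sum(masked_grad(i) for i in border) / len(border) if border else float("nan")
    )
    return out


def assert_feature_vectors_match(fv, oracle, rtol=1e-9):
    for name in features.FEATURE_NAMES:
        a, b = fv[name], oracle[name]
        if math.isnan(b):
            assert math.isnan(a), name
        else:
            assert a == pytest.approx(b, rel=rtol, abs=1e-12), name


class TestComputeVolume:
    def test_counting(self):
        vox = np.zeros((10, 10, 10), dtype=np.uint8)
        vox.ravel()[:1000] = 1
        assert features.compute_volume(imaging.BinaryMask(vox, (1, 1, 1))) == 1000.0

    def test_ellipsoid_volume_fine_voxelization(self):
        spec = synth.PhantomSpec(
            shape=(50, 42, 34), spacing=(0.5, 0.5, 0.5),
            radii_mm=(10.0, 8.0, 6.0), noise_sd=0.0,
        )
        _, mask = synth.generate_phantom(spec)
        analytic = 4.0 / 3.0 * math.pi * 480.0
        assert features.compute_volume(mask) == pytest.approx(analytic, rel=0.02)

    def test_empty_mask_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            v = features.compute_volume(imaging.BinaryMask(np.zeros((3, 3, 3)), (1, 1, 1)))
        assert v == 0.0


class TestExtractRadiomics:
    def test_matches_brute_force_on_random_fixtures(self, random_volume_mask):
        vol, mask = random_volume_mask
        fv = features.extract_radiomics(vol, mask)
        assert_feature_vectors_match(fv, brute_force_radiomics(vol, mask))

    def test_matches_brute_force_on_second_fixture(self):
        rng = np.random.default_rng(999)
        vox = rng.normal(-20, 120, size=(14, 16, 15))
        blob = rng.random((14, 16, 15)) < 0.25
        blob[6:10, 6:11, 6:10] = True
        vol = imaging.CTVolume(vox, (2.0, 0.7, 1.1))
        mask = imaging.BinaryMask(blob.astype(np.uint8), (2.0, 0.7, 1.1))
        fv = features.extract_radiomics(vol, mask)
        assert_feature_vectors_match(fv, brute_force_radiomics(vol, mask))

    def test_sphere_sphericity_near_one(self):
        spec = synth.PhantomSpec(
            shape=(34, 34, 34), spacing=(1.0, 1.0, 1.0), radii_mm=(10.0, 10.0, 10.0), noise_sd=0.0
        )
        vol, mask = synth.generate_phantom(spec)
        fv = features.extract_radiomics(vol, mask)
        assert fv["sphericity"] >= 0.95
        assert fv["sphericity"] <= 1.0

    def test_constant_intensity_degenerate_histogram(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[2:6, 2:6, 2:6] = 1
        vol = imaging.CTVolume(np.full((8, 8, 8), 50.0), (1, 1, 1))
        fv = features.extract_radiomics(vol, imaging.BinaryMask(m, (1, 1, 1)))
        assert fv["hu_mean"] == 50.0
        assert fv["hu_sd"] == 0.0
        assert fv["hu_entropy"] == 0.0
        assert fv["hu_energy"] == 1.0

    def test_single_voxel_surface_features_undefined(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[2, 2, 2] = 1
        vol = imaging.CTVolume(np.full((5, 5, 5), 10.0), (1, 1, 1))
        fv = features.extract_radiomics(vol, imaging.BinaryMask(m, (1, 1, 1)))
        assert math.isnan(fv["sphericity"])
        assert fv["volume_mm3"] == 1.0
        assert fv["hu_mean"] == 10.0

    def test_exactly_26_features(self):
        assert len(features.FEATURE_NAMES) == 26
        counts = {"volume": 0, "shape": 0, "gray": 0}
        for f in features.FEATURE_NAMES:
            counts[features.FEATURE_CATEGORIES[f]] += 1
        assert counts == {"volume": 10, "shape": 8, "gray": 8}

    def test_translation_invariance(self, random_volume_mask):
        vol, mask = random_volume_mask
        moved_vol = imaging.CTVolume(vol.voxels, vol.spacing, origin=(50.0, -20.0, 13.0))
        moved_mask = imaging.BinaryMask(mask.voxels, mask.spacing, origin=(50.0, -20.0, 13.0))
        a = features.extract_radiomics(vol, mask).as_array()
        b = features.extract_radiomics(moved_vol, moved_mask).as_array()
        np.testing.assert_array_equal(a, b)

    def test_intensity_features_ignore_mask_external_edits(self, random_volume_mask):
        vol, mask = random_volume_mask
        outside = ~mask.voxels.astype(bool)
        edited = vol.voxels.copy()
        edited[outside] = 2222.0
        a = features.extract_radiomics(vol, mask)
        b = features.extract_radiomics(imaging.CTVolume(edited, vol.spacing), mask)
        for name in features.GRAY_FEATURES:
            assert a[name] == b[name] or (math.isnan(a[name]) and math.isnan(b[name])), name

    def test_scaling_laws_under_isotropic_spacing(self):
        spec1 = synth.PhantomSpec(
            shape=(36, 36, 36), spacing=(1.0, 1.0, 1.0), radii_mm=(11.0, 9.0, 8.0), noise_sd=0.0
        )
        vol1, mask1 = synth.generate_phantom(spec1)
        s = 2.0
        vol2 = imaging.CTVolume(vol1.voxels, tuple(h * s for h in vol1.spacing))
        mask2 = imaging.BinaryMask(mask1.voxels, vol2.spacing)
        f1 = features.extract_radiomics(vol1, mask1)
        f2 = features.extract_radiomics(vol2, mask2)
        assert f2["volume_mm3"] == pytest.approx(f1["volume_mm3"] * s**3, rel=1e-12)
        # mesh vertices are float32 inside marching cubes: 1e-6 relative
        assert f2["surface_area_mm2"] == pytest.approx(f1["surface_area_mm2"] * s**2, rel=1e-6)
        assert f2["sphericity"] == pytest.approx(f1["sphericity"], rel=1e-6)


class TestPerfusionROIStats:
    def _maps(self, arrs):
        return imaging.PerfusionMapSet(
            {p: imaging.CTVolume(arrs[p], (5, 1, 1)) for p in imaging.PERFUSION_PARAMS}
        )

    def test_constant_field(self):
        arrs = {p: np.full((2, 4, 4), 50.0) for p in imaging.PERFUSION_PARAMS}
        roi = np.zeros((2, 4, 4), dtype=np.uint8)
        roi[0, 1:3, 1:3] = 1
        pf = features.perfusion_roi_stats(self._maps(arrs), imaging.BinaryMask(roi, (5, 1, 1)))
        assert pf["BF"] == 50.0

    def test_half_and_half_mean(self):
        arr = np.full((1, 2, 2), 40.0)
        arr[0, 1] = 60.0
        arrs = {p: arr.copy() for p in imaging.PERFUSION_PARAMS}
        roi = np.ones((1, 2, 2), dtype=np.uint8)
        pf = features.perfusion_roi_stats(self._maps(arrs), imaging.BinaryMask(roi, (5, 1, 1)))
        assert pf["MTT"] == 50.0

    def test_missing_voxels_excluded_and_counted(self):
        arr = np.full((1, 2, 5), 70.0)
        arr[0, 0, :3] = np.nan
        arrs = {p: arr.copy() for p in imaging.PERFUSION_PARAMS}
        roi = np.ones((1, 2, 5), dtype=np.uint8)
        pf = features.perfusion_roi_stats(self._maps(arrs), imaging.BinaryMask(roi, (5, 1, 1)))
        assert pf["BV"] == 70.0
        assert pf.roi_voxels["BV"] == 7

    def test_empty_roi_names_transfer_step(self):
        arrs = {p: np.zeros((1, 2, 2)) for p in imaging.PERFUSION_PARAMS}
        roi = np.zeros((1, 2, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match="resample_mask_to_grid"):
            features.perfusion_roi_stats(self._maps(arrs), imaging.BinaryMask(roi, (5, 1, 1)))


class TestChangeRules:
    def test_percent_change_arithmetic(self):
        assert features.percent_change(10000.0, 4000.0) == pytest.approx(-60.0)
        assert features.percent_change(123.0, 123.0) == 0.0
        with pytest.raises(ValueError):
            features.percent_change(0.0, 5.0)

    @pytest.mark.parametrize(
        "pct,expected",
        [(-60.0, True), (-49.9, False), (-50.0, True), (0.0, False), (25.0, False)],
    )
    def test_responder_boundary(self, pct, expected):
        assert features.classify_responder(pct) is expected

    def test_case_record_change_features(self, random_volume_mask):
        vol, mask = random_volume_mask
        fv = features.extract_radiomics(vol, mask)
        # post scan: same case, intensities shifted, mask shrunk
        shrunk = mask.voxels.copy()
        shrunk[:, :, :9] = 0
        post_mask = imaging.BinaryMask(shrunk, mask.spacing)
        post_fv = features.extract_radiomics(vol, post_mask)
        rec = features.CaseRecord("c1", fv, post_fv)
        chg = rec.change_features()
        expected_pct = 100.0 * (post_fv["volume_mm3"] - fv["volume_mm3"]) / fv["volume_mm3"]
        assert chg["volume_pct"] == pytest.approx(expected_pct)
        assert chg["chg_hu_mean"] == pytest.approx(post_fv["hu_mean"] - fv["hu_mean"])
        assert rec.responder is features.classify_responder(chg["volume_pct"])
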