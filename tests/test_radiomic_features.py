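"""Feature catalogue: discretization, per-family values and matrix oracles.

Each texture family is checked against an independent brute-force counter
(triple loops / BFS flood fill) on small random ROIs — exact integer
agreement on the raw count matrices — plus the hand-enumerable examples.
"""

import numpy as np
import pytest

import radstab as rs
from radstab.radiomic_features import (
    DIRECTIONS_13,
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    SHAPE_NAMES,
    _rlm_style_features,
    discretize,
    first_order_features,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    shape_features,
)
from conftest import random_roi

_OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _roi_from_levels(levels, spacing=(1, 1, 1)):
    """VolumeGrid/MaskVolume whose discretization reproduces given levels."""
    levels = np.asarray(levels)
    mask = levels > 0
    vals = np.where(mask, (levels - 1) * 25.0, 0.0).astype(float)
    v = rs.VolumeGrid(vals, spacing, (0, 0, 0))
    m = rs.MaskVolume(mask, spacing, (0, 0, 0))
    d = discretize(v, m, 25.0)
    assert np.array_equal(d.levels, levels)
    return d


# --------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementations)
# --------------------------------------------------------------------------


def glcm_oracle(lv, ng, direction):
    dx, dy, dz = direction
    out = np.zeros((ng, ng))
    sx, sy, sz = lv.shape
    for x in range(sx):
        for y in range(sy):
            for z in range(sz):
                if lv[x, y, z] == 0:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if 0 <= x2 < sx and 0 <= y2 < sy and 0 <= z2 < sz and lv[x2, y2, z2] > 0:
                    out[lv[x, y, z] - 1, lv[x2, y2, z2] - 1] += 1
    return out + out.T


def glrlm_oracle(lv, ng, direction, max_len):
    out = np.zeros((ng, max_len))
    shape = lv.shape
    dvec = np.asarray(direction)
    for start in np.ndindex(shape):
        prev = np.asarray(start) - dvec
        if all(0 <= prev[a] < shape[a] for a in range(3)):
            continue  # not a line start
        run_lv, run_len = 0, 0
        q = np.asarray(start)
        while all(0 <= q[a] < shape[a] for a in range(3)):
            level = lv[tuple(q)]
            if level == run_lv and level > 0:
                run_len += 1
            else:
                if run_lv > 0:
                    out[run_lv - 1, run_len - 1] += 1
                run_lv, run_len = level, 1
            q = q + dvec
        if run_lv > 0:
            out[run_lv - 1, run_len - 1] += 1
    return out


def glszm_oracle(lv, ng, n_voxels):
    out = np.zeros((ng, n_voxels))
    visited = np.zeros(lv.shape, bool)
    shape = lv.shape
    for start in np.ndindex(shape):
        if lv[start] == 0 or visited[start]:
            continue
        g = lv[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            cx, cy, cz = stack.pop()
            size += 1
            for a, b, c in _OFFSETS_26:
                nxt = (cx + a, cy + b, cz + c)
                if (
                    all(0 <= nxt[i] < shape[i] for i in range(3))
                    and not visited[nxt]
                    and lv[nxt] == g
                ):
                    visited[nxt] = True
                    stack.append(nxt)
        out[g - 1, size - 1] += 1
    return out


def gldm_oracle(lv, ng, alpha=0):
    shape = lv.shape
    deps = []
    for x, y, z in np.ndindex(shape):
        if lv[x, y, z] == 0:
            continue
        dep = 0
        for a, b, c in _OFFSETS_26:
            nxt = (x + a, y + b, z + c)
            if (
                all(0 <= nxt[i] < shape[i] for i in range(3))
                and lv[nxt] > 0
                and abs(int(lv[nxt]) - int(lv[x, y, z])) <= alpha
            ):
                dep += 1
        deps.append((lv[x, y, z], dep))
    out = np.zeros((ng, max(d for _, d in deps) + 1))
    for g, dep in deps:
        out[g - 1, dep] += 1
    return out


# --------------------------------------------------------------------------
# discretization and first-order
# --------------------------------------------------------------------------


class TestDiscretize:
    def test_definition_example(self):
        v = rs.VolumeGrid(np.array([0, 24.9, 25, 60]).reshape(4, 1, 1), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((4, 1, 1), bool), (1, 1, 1), (0, 0, 0))
        d = discretize(v, m, 25.0)
        assert list(d.levels.ravel()) == [1, 1, 2, 3]
        assert d.Ng == 3

    def test_constant_roi_single_level(self):
        v = rs.VolumeGrid(np.full((3, 3, 3), -500.0), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((3, 3, 3), bool), (1, 1, 1), (0, 0, 0))
        d = discretize(v, m, 25.0)
        assert d.Ng == 1 and np.all(d.in_mask_levels == 1)

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            vals = rng.normal(0, 100, size=(6, 6, 6))
            mask = rng.random((6, 6, 6)) < 0.6
            mask.flat[0] = True
            v = rs.VolumeGrid(vals, (1, 1, 1), (0, 0, 0))
            m = rs.MaskVolume(mask, (1, 1, 1), (0, 0, 0))
            d = discretize(v, m, 40.0)
            lo = vals[mask].min()
            expect = np.floor((vals[mask] - lo) / 40.0).astype(int) + 1
            assert np.array_equal(d.in_mask_levels, expect)

    def test_nonpositive_bin_width_rejected(self):
        v = rs.VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((2, 2, 2), bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="bin_width"):
            discretize(v, m, 0.0)


class TestFirstOrder:
    def test_three_value_example(self):
        v = rs.VolumeGrid(np.array([1.0, 2, 3]).reshape(3, 1, 1), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((3, 1, 1), bool), (1, 1, 1), (0, 0, 0))
        fo = first_order_features(v, m)
        assert fo["Mean"] == 2.0
        assert fo["Range"] == 2.0
        assert fo["Variance"] == pytest.approx(2.0 / 3.0)  # population convention

    def test_constant_roi(self):
        v = rs.VolumeGrid(np.full((3, 3, 3), 42.0), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((3, 3, 3), bool), (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning, match="Skewness"):
            fo = first_order_features(v, m)
        assert fo["Variance"] == 0.0
        assert fo["Uniformity"] == 1.0
        assert fo["Entropy"] == 0.0

    def test_single_voxel_nan_moments_warn_not_raise(self):
        v = rs.VolumeGrid(np.full((1, 1, 1), 5.0), (1, 1, 1), (0, 0, 0))
        m = rs.MaskVolume(np.ones((1, 1, 1), bool), (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning):
            fo = first_order_features(v, m)
        assert np.isnan(fo["Skewness"]) and np.isnan(fo["Kurtosis"])
        assert fo["Mean"] == 5.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(-300, 150, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.4
        v = rs.VolumeGrid(vals, (0.5, 0.5, 1.0), (0, 0, 0))
        m = rs.MaskVolume(mask, (0.5, 0.5, 1.0), (0, 0, 0))
        fo = first_order_features(v, m, bin_width=25.0)
        x = np.sort(vals[mask])
        n = x.size
        mean = x.sum() / n
        var = ((x - mean) ** 2).sum() / n
        p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
        sub = x[(x >= p10) & (x <= p90)]
        lev = np.floor((x - x.min()) / 25.0).astype(int)
        p = np.bincount(lev) / n
        p = p[p > 0]
        expect = {
            "Energy": (x**2).sum(),
            "TotalEnergy": (x**2).sum() * 0.25,
            "Entropy": -(p * np.log2(p)).sum(),
            "Minimum": x[0],
            "Maximum": x[-1],
            "Mean": mean,
            "Median": np.median(x),
            "InterquartileRange": p75 - p25,
            "Range": x[-1] - x[0],
            "MeanAbsoluteDeviation": np.abs(x - mean).sum() / n,
            "RobustMeanAbsoluteDeviation": np.abs(sub - sub.mean()).sum() / sub.size,
            "RootMeanSquared": np.sqrt((x**2).sum() / n),
            "Skewness": ((x - mean) ** 3).sum() / n / var**1.5,
            "Kurtosis": ((x - mean) ** 4).sum() / n / var**2,
            "Variance": var,
            "Uniformity": (p**2).sum(),
        }
        for name, val in expect.items():
            assert fo[name] == pytest.approx(val, abs=1e-9), name

    def test_permutation_invariance(self):
        """First-order features see an unordered bag of intensities."""
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(4, 4, 4))
        m = rs.MaskVolume(np.ones((4, 4, 4), bool), (1, 1, 1), (0, 0, 0))
        a = first_order_features(rs.VolumeGrid(vals, (1, 1, 1), (0, 0, 0)), m)
        shuffled = rng.permutation(vals.ravel()).reshape(4, 4, 4)
        b = first_order_features(rs.VolumeGrid(shuffled, (1, 1, 1), (0, 0, 0)), m)
        for k in FIRST_ORDER_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-12), k


class TestShape:
    def test_single_voxel_volume(self):
        m = rs.MaskVolume(
            np.pad(np.ones((1, 1, 1), bool), 2), (1, 1, 1), (0, 0, 0)
        )
        sh = shape_features(m)
        assert sh["VoxelVolume"] == pytest.approx(1.0)

    def test_digitized_sphere(self):
        spec = rs.PhantomSpec(
            nodule_type="SN", diameter_mm=10, center_mm=(15.75, 15.75, 15.75),
            grid_shape=(64, 64, 64), spacing_mm=(0.5, 0.5, 0.5), noise_sd_hu=0,
        )
        _, m = rs.generate_phantom(spec)
        sh = shape_features(m)
        assert 0.97 <= sh["Sphericity"] <= 1.0
        assert sh["MeshVolume"] == pytest.approx(np.pi * 1000 / 6, rel=0.03)
        assert sh["Maximum3DDiameter"] == pytest.approx(10.0, rel=0.08)

    def test_prolate_ellipsoid_axis_ratios(self):
        x, y, z = np.meshgrid(
            np.arange(48) - 23.5, np.arange(24) - 11.5, np.arange(24) - 11.5,
            indexing="ij",
        )
        ell = (x / 20) ** 2 + (y / 10) ** 2 + (z / 10) ** 2 <= 1
        sh = shape_features(rs.MaskVolume(ell, (1, 1, 1), (0, 0, 0)))
        assert sh["Elongation"] == pytest.approx(0.5, rel=0.05)
        assert sh["Flatness"] == pytest.approx(0.5, rel=0.05)
        assert sh["MajorAxisLength"] > sh["MinorAxisLength"] >= sh["LeastAxisLength"]

    def test_all_names_present(self, sphere_10mm):
        _, m = sphere_10mm
        assert set(shape_features(m)) == set(SHAPE_NAMES)


# --------------------------------------------------------------------------
# texture families
# --------------------------------------------------------------------------


class TestGLCM:
    def test_constant_roi_trivials(self):
        d = _roi_from_levels(np.ones((3, 3, 3), int))
        f = rs.glcm_features(d)
        assert f["Contrast"] == 0.0
        assert f["JointEnergy"] == 1.0
        assert f["MaximumProbability"] == 1.0

    def test_checkerboard_axis_vs_diagonal_contrast(self):
        """In-plane checkerboard: axis steps always change level, in-plane
        diagonal steps never do."""
        xx, yy = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        levels = ((xx + yy) % 2 + 1)[:, :, None]  # 4x4x1
        d = _roi_from_levels(levels)
        mats = rs.glcm_matrix(d)
        for k, (dx, dy, dz) in enumerate(DIRECTIONS_13):
            P = mats[k]
            if P.sum() == 0:
                continue
            P = P / P.sum()
            i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
            contrast = (P * (i - j) ** 2).sum()
            if (dx, dy, dz) in ((1, 0, 0), (0, 1, 0)):
                assert contrast == pytest.approx(1.0)
            elif (dx, dy, dz) in ((1, 1, 0), (1, -1, 0)):
                assert contrast == pytest.approx(0.0)

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            v, m = random_roi(rng)
            d = discretize(v, m, 25.0)
            mats = rs.glcm_matrix(d)
            for k, direction in enumerate(DIRECTIONS_13):
                assert np.array_equal(mats[k], glcm_oracle(d.levels, d.Ng, direction))

    def test_normalized_probabilities_and_nonnegative_contrast(self):
        rng = np.random.default_rng(22)
        v, m = random_roi(rng, shape=(6, 6, 6))
        d = discretize(v, m, 25.0)
        mats = rs.glcm_matrix(d)
        for k in range(len(DIRECTIONS_13)):
            if mats[k].sum() > 0:
                P = mats[k] / mats[k].sum()
                assert P.sum() == pytest.approx(1.0)
                assert np.allclose(P, P.T)
        f = rs.glcm_features(d)
        assert f["Contrast"] >= 0.0
        assert set(f) == set(GLCM_NAMES)

    def test_single_level_degenerate_fallbacks(self):
        d = _roi_from_levels(np.ones((3, 3, 3), int))
        f = rs.glcm_features(d)
        assert f["Correlation"] == 1.0
        assert f["Imc1"] == 0.0 and f["Imc2"] == 0.0
        assert f["MCC"] == 1.0


class TestGLRLM:
    def test_single_line_run(self):
        """A 1x1x4 constant ROI is one run of length 4 along the z axis;
        that direction's LongRunEmphasis is 16."""
        d = _roi_from_levels(np.ones((1, 1, 4), int))
        mats = rs.glrlm_matrix(d)
        k = [tuple(v) for v in DIRECTIONS_13].index((0, 0, 1))
        P = mats[k]
        assert P.sum() == 1 and P[0, 3] == 1
        f = _rlm_style_features(P, 4, GLRLM_NAMES, "run")
        assert f["LongRunEmphasis"] == pytest.approx(16.0)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0 / 16.0)

    def test_all_distinct_levels(self):
        levels = np.arange(1, 28).reshape(3, 3, 3)
        d = _roi_from_levels(levels)
        f = rs.glrlm_features(d)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)
        assert f["RunPercentage"] == pytest.approx(1.0)

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            v, m = random_roi(rng)
            d = discretize(v, m, 25.0)
            mats = glrlm_matrix(d)
            max_len = mats.shape[2]
            for k, direction in enumerate(DIRECTIONS_13):
                oracle = glrlm_oracle(d.levels, d.Ng, direction, max_len)
                assert np.array_equal(mats[k], oracle)

    def test_run_lengths_conserve_voxels(self):
        """Per direction, sum(run length x count) equals the in-mask count."""
        rng = np.random.default_rng(24)
        v, m = random_roi(rng, shape=(7, 6, 5))
        d = discretize(v, m, 25.0)
        mats = glrlm_matrix(d)
        lengths = np.arange(1, mats.shape[2] + 1)
        for k in range(len(DIRECTIONS_13)):
            assert (mats[k] * lengths).sum() == m.n_foreground


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        d = _roi_from_levels(np.ones((3, 3, 3), int))
        f = rs.glszm_features(d)
        assert f["ZonePercentage"] == pytest.approx(1.0 / 27.0)

    def test_two_disjoint_blobs_two_zones(self):
        levels = np.zeros((7, 3, 3), int)
        levels[0:2] = 1
        levels[5:7] = 1
        d = _roi_from_levels(levels)
        P = glszm_matrix(d)
        assert P.sum() == 2 and P[0, 17] == 2  # two zones of 18 voxels

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(25)
        for _ in range(8):
            v, m = random_roi(rng)
            d = discretize(v, m, 25.0)
            n_vox = int((d.levels > 0).sum())
            assert np.array_equal(
                glszm_matrix(d), glszm_oracle(d.levels, d.Ng, n_vox)
            )

    def test_feature_names(self):
        rng = np.random.default_rng(26)
        v, m = random_roi(rng, shape=(5, 5, 5))
        assert set(rs.glszm_features(discretize(v, m, 25.0))) == set(GLSZM_NAMES)


class TestGLDM:
    def test_full_cube_center_dependence(self):
        d = _roi_from_levels(np.ones((3, 3, 3), int))
        P = gldm_matrix(d)
        assert P[0, 26] == 1.0  # the center voxel has all 26 neighbors

    def test_single_voxel(self):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        d = _roi_from_levels(levels)
        P = gldm_matrix(d)
        assert P.shape == (1, 1) and P[0, 0] == 1.0

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(27)
        for _ in range(8):
            v, m = random_roi(rng)
            d = discretize(v, m, 25.0)
            assert np.array_equal(gldm_matrix(d, 0.0), gldm_oracle(d.levels, d.Ng, 0))

    def test_alpha_relaxes_dependence(self):
        rng = np.random.default_rng(28)
        v, m = random_roi(rng, shape=(5, 5, 5))
        d = discretize(v, m, 25.0)
        strict = rs.gldm_features(d, alpha=0.0)["LargeDependenceEmphasis"]
        loose = rs.gldm_features(d, alpha=10.0)["LargeDependenceEmphasis"]
        assert loose >= strict
        assert set(rs.gldm_features(d)) == set(GLDM_NAMES)


# --------------------------------------------------------------------------
# catalogue assembly
# --------------------------------------------------------------------------


class TestExtractAll:
    def test_deterministic(self, noisy_sphere_10mm):
        v, m = noisy_sphere_10mm
        a = rs.extract_all(v, m)
        b = rs.extract_all(v, m)
        assert list(a) == list(b)
        va, vb = np.array(list(a.values())), np.array(list(b.values()))
        assert np.array_equal(va, vb)

    def test_all_finite_on_wellformed_nodule(self, noisy_sphere_10mm):
        v, m = noisy_sphere_10mm
        values = rs.extract_all(v, m)
        bad = [k for k, x in values.items() if not np.isfinite(x)]
        assert bad == []

    def test_degenerate_image_yields_nan_not_abort(self):
        """A constant volume breaks moment features but the vector survives."""
        v = rs.VolumeGrid(np.zeros((16, 16, 16)), (1, 1, 1), (0, 0, 0))
        mask = np.zeros((16, 16, 16), bool)
        mask[6:10, 6:10, 6:10] = True
        m = rs.MaskVolume(mask, (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning):
            values = rs.extract_all(v, m)
        assert len(values) == 1246
        assert np.isnan(values["original_firstorder_Skewness"])
        assert values["original_firstorder_Mean"] == 0.0
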