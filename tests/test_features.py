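"""Radiomic feature panel: discretization, matrices, and oracle equivalence."""

import json
from pathlib import Path

import numpy as np
import pytest

from orgpet.features import (
    FEATURE_NAMES,
    build_glcm,
    build_glrlm,
    build_glszm,
    discretize,
    extract_all,
    first_order_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    standard_params,
)
from orgpet.phantom import PhantomImage
from orgpet.segmentation import VOIMask

import oracles

SPACING = (4.07, 4.07, 4.07)
FIXTURES = Path(__file__).parent / "fixtures"


def make_pair(values, mask=None):
    values = np.asarray(values, dtype=float)
    img = PhantomImage(values, SPACING)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    voi = VOIMask(
        mask=mask,
        threshold_suv=float(values[mask].min()),
        suvmax_ref=float(values[mask].max()),
        n_voxels=int(mask.sum()),
    )
    return img, voi


def random_pair(rng, shape=(5, 5, 5), n_bins=8):
    vals = rng.random(shape) * 10.0
    mask = rng.random(shape) < 0.8
    mask.flat[0] = True  # never empty
    return make_pair(vals, mask), n_bins


class TestStandardParams:
    def test_simple_arithmetic(self):
        vals = np.ones((2, 2, 2))
        vals[0, 0, :] = [4.0, 6.0]
        vals[0, 1, 0] = 10.0
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, 0, :] = True
        mask[0, 1, 0] = True
        img, voi = make_pair(vals, mask)
        p = standard_params(img, voi)
        assert p["SUVmax"] == 10.0 and p["SUVmin"] == 4.0
        assert p["SUVmean"] == pytest.approx(20.0 / 3.0)
        assert p["SUVdiff"] == 6.0
        assert p["MTV"] == pytest.approx(3 * 4.07**3 / 1000.0)

    def test_constant_voi_degenerate(self):
        img, voi = make_pair(np.full((3, 3, 3), 2.5))
        p = standard_params(img, voi)
        assert p["SUVdiff"] == 0.0
        assert p["SUVmean"] == p["SUVmax"] == p["SUVmin"] == 2.5


class TestDiscretize:
    def test_constant_voi_all_level_one(self):
        img, voi = make_pair(np.full((3, 3, 3), 7.0))
        d = discretize(img, voi, 255)
        assert set(d.levels[d.mask].tolist()) == {1}

    def test_two_values_two_bins(self):
        vals = np.zeros((1, 1, 2))
        vals[0, 0, 1] = 1.0
        img, voi = make_pair(vals)
        d = discretize(img, voi, 2)
        assert d.levels[0, 0, 0] == 1 and d.levels[0, 0, 1] == 2

    def test_matches_flat_oracle(self, rng):
        (img, voi), _ = random_pair(rng)
        d = discretize(img, voi, 255)
        got = d.levels[voi.mask].tolist()
        exp = oracles.discretize_oracle(img.values[voi.mask].tolist(), 255)
        assert got == exp

    def test_uniform_input_fills_levels_uniformly(self, rng):
        from scipy import stats

        vals = rng.random((16, 16, 16))
        img, voi = make_pair(vals)
        d = discretize(img, voi, 255)
        counts = np.bincount(d.levels[d.mask], minlength=256)[1:]
        assert stats.chisquare(counts).pvalue > 1e-3


class TestFirstOrder:
    def test_symmetric_values_zero_skewness(self):
        img, voi = make_pair(np.array([[[1.0, 2.0, 3.0]]]))
        f = first_order_features(img, voi)
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_voi_degenerate_values(self):
        img, voi = make_pair(np.full((2, 2, 2), 4.0))
        f = first_order_features(img, voi)
        assert f["Entropy.image"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_normal_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(99)
        vals = rng.standard_normal(10_000).reshape(10, 10, 100) + 10.0
        img, voi = make_pair(vals)
        f = first_order_features(img, voi)
        assert f["Kurtosis"] == pytest.approx(3.0, abs=0.15)

    def test_matches_literal_oracle(self, rng):
        (img, voi), _ = random_pair(rng)
        got = first_order_features(img, voi, 255)
        exp = oracles.first_order_oracle(img.values[voi.mask].tolist(), 255)
        for k, v in exp.items():
            assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k


class TestGLCM:
    def test_two_voxel_voi(self):
        vals = np.array([[[1.0, 2.0]]])
        img, voi = make_pair(vals)
        d = discretize(img, voi, 2)
        glcm = build_glcm(d)
        m = glcm[(0, 0, 1)]
        assert m[0, 1] == 1 and m[1, 0] == 1 and m.sum() == 2
        for off, mat in glcm.items():
            if off != (0, 0, 1):
                assert mat.sum() == 0

    def test_constant_cube_pair_counts(self):
        img, voi = make_pair(np.full((3, 3, 3), 2.0))
        d = discretize(img, voi, 255)
        glcm = build_glcm(d)
        for off, m in glcm.items():
            n_pairs = 1
            for n, o in zip((3, 3, 3), off):
                n_pairs *= n - abs(o)
            assert m[0, 0] == 2 * n_pairs  # symmetrized
            assert m.sum() == m[0, 0]

    def test_checkerboard_axis_contrast_is_one(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        vals = 1.0 + (idx % 2)
        img, voi = make_pair(vals)
        d = discretize(img, voi, 2)
        glcm = build_glcm(d)
        for off in ((0, 0, 1), (0, 1, 0), (1, 0, 0)):
            f = glcm_features({off: glcm[off]})
            assert f["Contrast"] == pytest.approx(1.0)
            assert f["Dissimilarity"] == pytest.approx(1.0)

    def test_constant_voi_feature_limits(self):
        img, voi = make_pair(np.full((3, 3, 3), 1.0))
        f = glcm_features(build_glcm(discretize(img, voi, 255)))
        assert f["Contrast"] == 0.0
        assert f["Dissimilarity"] == 0.0
        assert f["Homogeneity.1"] == pytest.approx(1.0)
        assert f["Joint Entropy.2"] == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            (img, voi), n_bins = random_pair(rng, shape=(4, 4, 4))
            d = discretize(img, voi, n_bins)
            glcm = build_glcm(d)
            for off in oracles.OFFSETS_13:
                exp_pairs = oracles.glcm_pairs(d.levels, off)
                m = glcm[off]
                for (i, j), c in exp_pairs.items():
                    assert m[i - 1, j - 1] == c
                assert m.sum() == sum(exp_pairs.values())
            got = glcm_features(glcm)
            exp = oracles.glcm_features_oracle(d.levels)
            mapping = {
                "Contrast": "contrast",
                "Dissimilarity": "dissimilarity",
                "Homogeneity.1": "hom1",
                "Homogeneity.2": "hom2",
                "Correlation": "correlation",
                "Joint Entropy.2": "joint_entropy",
                "Sum Entropy.3": "sum_entropy",
                "Difference Entropy.1": "diff_entropy",
            }
            for k, ok in mapping.items():
                assert got[k] == pytest.approx(exp[ok], rel=1e-9, abs=1e-12), k


class TestGLRLM:
    def test_single_run_arithmetic(self):
        img, voi = make_pair(np.full((1, 1, 4), 3.0))
        d = discretize(img, voi, 255)
        r = build_glrlm(d)[(0, 0, 1)]
        assert r[0, 3] == 1 and r.sum() == 1
        f = glrlm_features({(0, 0, 1): r}, n_voxels=4)
        assert f["Long.Run.Emphasis"] == pytest.approx(16.0)
        assert f["Short.Run.Emphasis"] == pytest.approx(1.0 / 16.0)
        assert f["Run.Percentage"] == pytest.approx(0.25)

    def test_all_distinct_levels_unit_runs(self):
        vals = np.arange(27.0).reshape(3, 3, 3)
        img, voi = make_pair(vals)
        d = discretize(img, voi, 27)
        f = glrlm_features(build_glrlm(d), n_voxels=27)
        assert f["Short.Run.Emphasis"] == pytest.approx(1.0)
        assert f["Long.Run.Emphasis"] == pytest.approx(1.0)
        assert f["Run.Percentage"] == pytest.approx(1.0)

    def test_matches_run_enumeration_oracle(self, rng):
        for _ in range(5):
            (img, voi), n_bins = random_pair(rng, shape=(4, 4, 4), n_bins=4)
            d = discretize(img, voi, n_bins)
            got = glrlm_features(build_glrlm(d), d.n_voxels)
            exp = oracles.glrlm_features_oracle(d.levels, d.n_voxels)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-9), k


class TestGLSZM:
    def test_single_zone_arithmetic(self):
        img, voi = make_pair(np.full((3, 3, 3), 5.0))
        d = discretize(img, voi, 255)
        f = glszm_features(build_glszm(d), n_voxels=27)
        assert f["ZonePercentage"] == pytest.approx(1.0 / 27.0)
        assert f["LargeAreaEmphasis"] == pytest.approx(729.0)

    def test_all_distinct_levels_unit_zones(self):
        vals = np.arange(27.0).reshape(3, 3, 3)
        img, voi = make_pair(vals)
        d = discretize(img, voi, 27)
        f = glszm_features(build_glszm(d), n_voxels=27)
        assert f["ZonePercentage"] == pytest.approx(1.0)
        assert f["LargeAreaEmphasis"] == pytest.approx(1.0)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            (img, voi), n_bins = random_pair(rng, shape=(4, 4, 4), n_bins=4)
            d = discretize(img, voi, n_bins)
            got = glszm_features(build_glszm(d), d.n_voxels)
            exp = oracles.glszm_features_oracle(d.levels, d.n_voxels)
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, rel=1e-9), k


class TestExtractAll:
    def test_exactly_35_named_features(self, rng):
        (img, voi), _ = random_pair(rng)
        fv = extract_all(img, voi)
        assert tuple(fv.keys()) == FEATURE_NAMES
        assert len(fv) == 35

    def test_constant_voi_degenerate_vector(self):
        img, voi = make_pair(np.full((3, 3, 3), 2.0))
        fv = extract_all(img, voi)
        assert fv["Entropy.image"] == 0.0
        assert fv["Joint Entropy.2"] == 0.0
        assert fv["Sum Entropy.3"] == 0.0
        assert fv["Difference Entropy.1"] == 0.0
        assert fv["SUVdiff"] == 0.0
        assert fv["Run.Percentage"] <= 1.0 and fv["Zone" + "Percentage"] > 0.0

    def test_first_order_permutation_invariant_texture_not(self, rng):
        vals = np.sort(rng.random((4, 4, 4)), axis=None).reshape(4, 4, 4) + 1.0
        img, voi = make_pair(vals)
        fv = extract_all(img, voi)
        flat = img.values[voi.mask]
        perm = rng.permutation(flat)
        vals2 = np.array(img.values)
        vals2[voi.mask] = perm
        img2, voi2 = make_pair(vals2)
        fv2 = extract_all(img2, voi2)
        for k in ("Variance", "Skewness", "Kurtosis", "Entropy.image", "Energy", "STD"):
            assert fv2[k] == pytest.approx(fv[k], rel=1e-12), k
        assert fv2["Contrast"] != pytest.approx(fv["Contrast"], rel=1e-6)

    def test_texture_invariant_under_intensity_shift(self, rng):
        (img, voi), _ = random_pair(rng)
        shifted = np.array(img.values) + 5.0
        img2, voi2 = make_pair(shifted, voi.mask)
        fv = extract_all(img, voi)
        fv2 = extract_all(img2, voi2)
        shift_dependent = {"SUVmax", "SUVmin", "SUVmean", "MTV"}
        for k in FEATURE_NAMES:
            if k in shift_dependent:
                continue
            assert fv2[k] == pytest.approx(fv[k], rel=1e-9, abs=1e-12), k

    def test_matches_frozen_snapshot(self):
        with open(FIXTURES / "feature_snapshot.json") as fh:
            snap = json.load(fh)
        rng = np.random.default_rng(snap["rng_seed"])
        vals = 1.0 + rng.random((5, 5, 5)) * 9.0
        img, voi = make_pair(vals)
        fv = extract_all(img, voi, n_bins=snap["n_bins"])
        for k, v in snap["features"].items():
            assert fv[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_gating_sharpens_uptake_across_cohort(self, motion_cohort_features):
        """Gated scans show higher peak/mean uptake and dispersion, smaller MTV."""
        n = len(motion_cohort_features)
        up = {"SUVmax": 0, "SUVmean": 0, "STD": 0}
        down = {"MTV": 0}
        for f in motion_cohort_features:
            for k in up:
                up[k] += f["ORG"][k] > f["nonORG"][k]
            for k in down:
                down[k] += f["ORG"][k] < f["nonORG"][k]
        for k, c in {**up, **down}.items():
            assert c >= int(0.9 * n), (k, c, n)
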