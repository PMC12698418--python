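"""Feature schema, closed-form values, oracle equivalence and invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from collagensig.features import (FEATURE_NAMES, GABOR_NAMES, GLCM_NAMES,
                                  INTENSITY_NAMES, MORPH_NAMES, FeatureVector,
                                  aggregate_patient, extract_feature_vector,
                                  gabor_features, glcm_features,
                                  intensity_features, morphological_features)
from collagensig.segmentation import (CollagenMask, ROIImage, extract_fibers,
                                      segment_collagen)
from collagensig.simulate import FiberFieldParams, simulate_fiber_image

from conftest import make_line_image
from oracles import glcm_stats_oracle


class TestSchema:
    def test_partition_8_6_80_48(self):
        assert len(FEATURE_NAMES) == 142
        assert len(MORPH_NAMES) == 8
        assert len(INTENSITY_NAMES) == 6
        assert len(GLCM_NAMES) == 80
        assert len(GABOR_NAMES) == 48
        assert len(set(FEATURE_NAMES)) == 142

    def test_any_simulated_image_yields_full_finite_vector(self):
        params = FiberFieldParams(image_size_px=96, n_fibers=8, length_mean=100)
        for seed in (0, 1):
            img, _ = simulate_fiber_image(params, seed)
            fv = extract_feature_vector(img)
            assert fv.names == FEATURE_NAMES
            assert np.all(np.isfinite(fv.values))

    def test_different_seeds_same_schema_different_values(self):
        params = FiberFieldParams(image_size_px=96, n_fibers=8, length_mean=100)
        a = extract_feature_vector(simulate_fiber_image(params, 0)[0])
        b = extract_feature_vector(simulate_fiber_image(params, 1)[0])
        assert a.names == b.names
        assert not np.array_equal(a.values, b.values)

    def test_all_zero_image_gives_convention_vector_with_flags(self):
        fv = extract_feature_vector(ROIImage(np.zeros((64, 64), np.uint8), 1.0))
        assert {"no_collagen", "no_fibers", "constant_image"} <= fv.flags
        assert fv["morph.number"] == 0.0
        assert fv["int.mean"] == 0.0
        assert fv["glcm.energy.d1.a0"] == 1.0


class TestMorphology:
    def test_parallel_fibers_are_aligned(self):
        img = make_line_image([((r, 4), (r, 60)) for r in (10, 22, 34, 46)])
        fibers = extract_fibers(segment_collagen(img), img)
        morph, _ = morphological_features(fibers, segment_collagen(img))
        assert morph["morph.arrangement"] <= 0.05

    def test_isotropic_orientations_are_disordered(self):
        params = FiberFieldParams(n_fibers=100, orientation_kappa=0.0,
                                  image_size_px=256, background_noise_sd=0.0,
                                  crosslink_rate=0.0)
        img, _ = simulate_fiber_image(params, seed=4)
        mask = segment_collagen(img)
        morph, _ = morphological_features(extract_fibers(mask, img), mask)
        assert morph["morph.arrangement"] >= 0.8

    def test_crosslink_density_matches_hand_formula(self):
        img = make_line_image([((8, 8), (56, 56)), ((8, 56), (56, 8))],
                              pixel_size_um=2.0)
        mask = segment_collagen(img)
        fibers = extract_fibers(mask, img)
        morph, _ = morphological_features(fibers, mask)
        area_mm2 = mask.mask.sum() * 2.0 ** 2 / 1e6
        assert morph["morph.crosslink_density"] == pytest.approx(1.0 / area_mm2)

    def test_no_fibers_convention(self):
        empty = CollagenMask(np.zeros((16, 16), bool), 1.0, degenerate=True)
        from collagensig.segmentation import FiberSet
        morph, flags = morphological_features(FiberSet(), empty)
        assert "no_fibers" in flags
        assert all(morph[k] == 0.0 for k in morph)

    def test_monotone_response_to_generator_knobs(self):
        """Mean crosslink density rises with crosslink_rate; arrangement
        falls with orientation concentration (Spearman rho > 0.8)."""
        from scipy.stats import spearmanr

        def mean_feature(name, **kw):
            out = []
            for seed in range(20):
                p = FiberFieldParams(image_size_px=96, n_fibers=10,
                                     length_mean=100, length_sd=30, **kw)
                img, _ = simulate_fiber_image(p, seed)
                mask = segment_collagen(img)
                morph, _ = morphological_features(extract_fibers(mask, img), mask)
                out.append(morph[name])
            return float(np.mean(out))

        rates = [0.1, 0.4, 0.8, 1.5, 2.5]
        dens = [mean_feature("morph.crosslink_density", crosslink_rate=r)
                for r in rates]
        assert spearmanr(rates, dens).statistic > 0.8
        kappas = [0.0, 0.5, 1.5, 4.0, 10.0]
        arr = [mean_feature("morph.arrangement", orientation_kappa=k)
               for k in kappas]
        assert spearmanr(kappas, arr).statistic < -0.8


class TestIntensity:
    def _masked(self, values):
        arr = np.zeros((4, len(values)), dtype=np.uint8)
        arr[0] = values
        mask = np.zeros_like(arr, dtype=bool)
        mask[0] = True
        return ROIImage(arr, 1.0), CollagenMask(mask, 1.0)

    def test_constant_region(self):
        img, mask = self._masked([100] * 8)
        feats, flags = intensity_features(img, mask)
        assert feats["int.mean"] == 100.0
        assert feats["int.variance"] == 0.0
        assert feats["int.energy"] == 1.0
        assert feats["int.entropy"] == 0.0
        assert "zero_intensity_variance" in flags

    def test_two_equiprobable_levels(self):
        img, mask = self._masked([10] * 4 + [200] * 4)
        feats, _ = intensity_features(img, mask)
        assert feats["int.entropy"] == pytest.approx(1.0)
        assert feats["int.energy"] == pytest.approx(0.5)
        assert feats["int.skewness"] == pytest.approx(0.0, abs=1e-12)
        assert feats["int.mean"] == pytest.approx(105.0)

    def test_kurtosis_is_non_excess(self):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.normal(128, 20, 4000), 0, 255).astype(np.uint8)
        img = ROIImage(vals.reshape(40, 100), 1.0)
        mask = CollagenMask(np.ones((40, 100), bool), 1.0)
        feats, _ = intensity_features(img, mask)
        assert feats["int.kurtosis"] == pytest.approx(3.0, abs=0.3)


class TestGLCM:
    def test_constant_image_conventions(self):
        roi = ROIImage(np.full((16, 16), 9, np.uint8), 1.0)
        feats, flags = glcm_features(roi)
        for d in (1, 2, 3, 4, 5):
            for a in (0, 45, 90, 135):
                assert feats[f"glcm.contrast.d{d}.a{a}"] == 0.0
                assert feats[f"glcm.energy.d{d}.a{a}"] == 1.0
                assert feats[f"glcm.uniformity.d{d}.a{a}"] == 1.0
                assert feats[f"glcm.correlation.d{d}.a{a}"] == 0.0
        assert "glcm_zero_variance" in flags

    def test_checkerboard_contrast_matches_pair_enumeration(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2 * 255).astype(np.uint8)
        feats, _ = glcm_features(ROIImage(board, 1.0))
        oracle = glcm_stats_oracle(board, 32, d=1, angle_deg=0)
        assert feats["glcm.contrast.d1.a0"] == pytest.approx(oracle["contrast"])
        # every horizontal neighbor pair differs by the full gray range
        assert oracle["contrast"] == pytest.approx(31 ** 2)

    def test_vertical_stripes_are_anisotropic(self):
        stripes = np.zeros((16, 16), dtype=np.uint8)
        stripes[:, ::2] = 200
        feats, _ = glcm_features(ROIImage(stripes, 1.0))
        assert feats["glcm.contrast.d1.a90"] == 0.0
        assert feats["glcm.contrast.d1.a0"] > 0.0

    @given(st.integers(0, 511), st.integers(1, 3),
           st.sampled_from([0, 45, 90, 135]))
    def test_binary_3x3_oracle_equivalence(self, code, d, angle):
        bits = [(code >> k) & 1 for k in range(9)]
        img = (np.array(bits).reshape(3, 3) * 255).astype(np.uint8)
        feats, _ = glcm_features(ROIImage(img, 1.0))
        oracle = glcm_stats_oracle(img, 32, d=d, angle_deg=angle)
        for stat in ("contrast", "correlation", "energy", "uniformity"):
            assert feats[f"glcm.{stat}.d{d}.a{angle}"] == \
                pytest.approx(oracle[stat], abs=1e-12)


class TestGabor:
    def test_constant_image_has_flat_response(self):
        roi = ROIImage(np.full((64, 64), 55, np.uint8), 1.0)
        feats, _ = gabor_features(roi)
        for s in (1, 2, 3, 4):
            for o in range(1, 7):
                assert feats[f"gabor.variance.s{s}.o{o}"] <= 1e-6

    def test_grating_peaks_at_matched_scale_and_orientation(self):
        x = np.arange(64)
        grating = (127.5 + 127.5 * np.sin(2 * np.pi * x / 8.0))
        img = np.tile(grating, (64, 1)).astype(np.uint8)
        feats, _ = gabor_features(ROIImage(img, 1.0))
        means = {(s, o): feats[f"gabor.mean.s{s}.o{o}"]
                 for s in (1, 2, 3, 4) for o in range(1, 7)}
        # wavelength 8 px = scale 3; modulation along x = orientation 1 (0 deg)
        assert max(means, key=means.get) == (3, 1)

    def test_determinism(self):
        img, _ = simulate_fiber_image(
            FiberFieldParams(image_size_px=96, n_fibers=6, length_mean=80), 0)
        a, _ = gabor_features(img)
        b, _ = gabor_features(img)
        assert a == b

    def test_small_image_warns_when_kernel_clipped(self):
        roi = ROIImage((np.random.default_rng(0).random((24, 24)) * 255)
                       .astype(np.uint8), 1.0)
        with pytest.warns(UserWarning, match="kernel"):
            _, flags = gabor_features(roi)
        assert "gabor_kernel_clipped" in flags


@pytest.fixture(scope="module")
def pair():
    img, _ = simulate_fiber_image(
        FiberFieldParams(image_size_px=96, n_fibers=8, length_mean=100), 1)
    rot = ROIImage(np.rot90(img.pixels), img.pixel_size_um)
    return img, rot


class TestRotationInvariance:
    amap = {0: 90, 90: 0, 45: 135, 135: 45}
    omap = {1: 4, 2: 5, 3: 6, 4: 1, 5: 2, 6: 3}

    def test_glcm_angles_permute_under_rot90(self, pair):
        img, rot = pair
        f0, _ = glcm_features(img)
        f1, _ = glcm_features(rot)
        for stat in ("contrast", "correlation", "energy", "uniformity"):
            for d in (1, 2, 3, 4, 5):
                for a in (0, 45, 90, 135):
                    assert abs(f1[f"glcm.{stat}.d{d}.a{self.amap[a]}"]
                               - f0[f"glcm.{stat}.d{d}.a{a}"]) <= 1e-9

    def test_gabor_orientations_permute_under_rot90(self, pair):
        img, rot = pair
        f0, _ = gabor_features(img)
        f1, _ = gabor_features(rot)
        for stat in ("mean", "variance"):
            for s in (1, 2, 3, 4):
                for o in range(1, 7):
                    ref = f0[f"gabor.{stat}.s{s}.o{o}"]
                    got = f1[f"gabor.{stat}.s{s}.o{self.omap[o]}"]
                    assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_intensity_features_unchanged_under_rot90(self, pair):
        img, rot = pair
        m0, m1 = segment_collagen(img), segment_collagen(rot)
        f0, _ = intensity_features(img, m0)
        f1, _ = intensity_features(rot, m1)
        for k in f0:
            assert f1[k] == pytest.approx(f0[k], abs=1e-9)


class TestAggregation:
    def test_mean_is_idempotent_on_identical_vectors(self):
        fv = FeatureVector(np.linspace(0, 1, 142))
        agg = aggregate_patient([fv] * 5)
        assert np.allclose(agg.values, fv.values)

    def test_elementwise_mean(self):
        vecs = [FeatureVector(np.full(142, v)) for v in (0, 0, 0, 0, 10)]
        agg = aggregate_patient(vecs)
        assert np.allclose(agg.values, 2.0)

    def test_wrong_roi_count_warns(self):
        fv = FeatureVector(np.zeros(142))
        with pytest.warns(UserWarning, match="expected 5"):
            aggregate_patient([fv, fv])

    def test_mismatched_schema_rejected(self):
        fv = FeatureVector(np.zeros(142))
        other = FeatureVector(np.zeros(3), names=("a", "b", "c"))
        with pytest.raises(ValueError, match="schema"):
            aggregate_patient([fv] * 4 + [other])

    def test_non_finite_vector_rejected(self):
        vals = np.zeros(142)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            FeatureVector(vals)
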