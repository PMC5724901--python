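import numpy as np
import pandas as pd
import pytest
from _oracles import glcm_oracle, glrlm_oracle
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from retinaseg import features as ft
from retinaseg.features import (
    FEATURE_NAMES,
    GaborParams,
    GlcmParams,
    TABLE_RANKING,
    compute_glcm,
    compute_glrlm,
    extract_pixel_features,
    gabor_kernel,
    glcm_features,
    glrlm_features,
    intensity_moments,
)


class TestIntensityMoments:
    def test_constant_window(self):
        m = intensity_moments(np.full((3, 3), 0.3))
        assert m["mean"] == pytest.approx(0.3)
        assert m["variance"] == m["skewness"] == m["kurtosis"] == 0.0

    def test_alternating_window_direct_sums(self):
        w = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], float)
        m = intensity_moments(w)
        assert m["mean"] == pytest.approx(5 / 9)
        assert m["variance"] == pytest.approx(((w - 5 / 9) ** 2).sum() / 9)
        assert m["kurtosis"] == pytest.approx(((w - 5 / 9) ** 4).sum() / 9)

    def test_symmetric_window_zero_skew(self):
        w = np.array([[0.2, 0.8], [0.8, 0.2]])
        assert intensity_moments(w)["skewness"] == pytest.approx(0.0)


class TestGlcm:
    def test_two_by_two_matches_enumeration(self):
        w = np.array([[0, 0], [1, 1]])
        p = GlcmParams(distance=1, levels=2)
        assert np.allclose(compute_glcm(w, p), glcm_oracle(w, 1, 2))

    def test_constant_patch_single_cell(self):
        p = compute_glcm(np.full((3, 3), 5, int), GlcmParams(levels=8))
        assert p[5, 5] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_default_distance_is_one(self):
        assert GlcmParams().distance == 1

    def test_oracle_equivalence_random_patches(self, rng):
        p = GlcmParams(distance=1, levels=8)
        for _ in range(100):
            w = rng.integers(0, 8, size=(5, 5))
            assert np.allclose(compute_glcm(w, p), glcm_oracle(w, 1, 8))

    def test_degenerate_window_all_zero_table(self):
        table = compute_glcm(np.array([[3]]), GlcmParams(levels=8))
        assert table.sum() == 0.0
        assert all(v == 0.0 for v in glcm_features(table).values())


class TestGlcmFeatures:
    def test_constant_patch_values(self):
        f = glcm_features(compute_glcm(np.full((3, 3), 2, int), GlcmParams(levels=8)))
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["maximum_probability"] == pytest.approx(1.0)
        assert f["homogeneity_i"] == pytest.approx(1.0)

    def test_stripe_table_contrast_and_energy(self):
        table = np.zeros((2, 2))
        table[0, 1] = table[1, 0] = 0.5
        f = glcm_features(table)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)

    def test_zero_variance_correlation_guard(self):
        table = np.zeros((4, 4))
        table[1, 1] = 1.0
        f = glcm_features(table)
        assert f["correlation_i"] == 0.0
        assert f["correlation_ii"] == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hnp.arrays(np.int64, (5, 5), elements=st.integers(0, 7)))
    def test_entropy_energy_ranges(self, window):
        f = glcm_features(compute_glcm(window, GlcmParams(levels=8)))
        for name in ("entropy", "sum_entropy", "difference_entropy"):
            assert f[name] >= -1e-12
        assert 0.0 < f["energy"] <= 1.0
        assert 0.0 < f["maximum_probability"] <= 1.0


class TestGlrlm:
    def test_single_row_single_run(self):
        r = compute_glrlm(np.array([[3, 3, 3, 3]]), levels=8)
        # 1x4 patch: one horizontal run of 4, four vertical runs of 1,
        # and eight diagonal runs of 1 (four per diagonal direction)
        assert r.counts[3, 3] == 1
        assert r.counts[3, 0] == 12
        assert r.n_pixels == 4

    def test_all_distinct_runs_of_one(self):
        w = np.arange(4).reshape(2, 2)
        r = compute_glrlm(w, levels=4)
        assert r.counts[:, 1:].sum() == 0
        assert r.counts[:, 0].sum() == r.n_runs

    def test_constant_three_by_three(self):
        r = compute_glrlm(np.full((3, 3), 1, int), levels=8)
        # 3 horizontal + 3 vertical runs of length 3; diagonals give runs
        # of lengths 1,2,3,2,1 in each of the two diagonal directions
        assert r.counts[1, 2] == 3 + 3 + 1 + 1
        assert r.counts[1, 1] == 4
        assert r.counts[1, 0] == 4
        assert r.n_runs == 16

    def test_oracle_equivalence_random_patches(self, rng):
        for _ in range(100):
            w = rng.integers(0, 8, size=(5, 5))
            counts, n_runs = glrlm_oracle(w, 8)
            r = compute_glrlm(w, levels=8)
            assert np.array_equal(r.counts, counts)
            assert r.n_runs == n_runs


class TestGlrlmFeatures:
    def test_single_run_of_four(self):
        counts = np.zeros((8, 4))
        counts[0, 3] = 1  # level index 1 (1-based), length 4
        f = glrlm_features(ft.Glrlm(counts, n_runs=1, n_pixels=4))
        assert f["short_run_emphasis"] == pytest.approx(1 / 16)
        assert f["long_run_emphasis"] == pytest.approx(16.0)
        assert f["run_percentage"] == pytest.approx(0.25)

    def test_unit_runs_give_unit_emphasis(self):
        counts = np.zeros((4, 3))
        counts[[0, 2], 0] = [3, 2]
        f = glrlm_features(ft.Glrlm(counts, n_runs=5, n_pixels=5))
        assert f["short_run_emphasis"] == pytest.approx(1.0)
        assert f["long_run_emphasis"] == pytest.approx(1.0)

    def test_single_gray_level_nonuniformity_collapses(self):
        counts = np.zeros((4, 4))
        counts[2, [0, 1, 3]] = [2, 1, 1]
        nr = 4
        f = glrlm_features(ft.Glrlm(counts, n_runs=nr, n_pixels=16))
        assert f["gray_level_nonuniformity"] == pytest.approx(nr)

    def test_empty_table_all_zero(self):
        f = glrlm_features(ft.Glrlm(np.zeros((4, 4)), 0, 9))
        assert all(v == 0.0 for v in f.values())


class TestGabor:
    def test_even_kernel_symmetry(self):
        k = gabor_kernel(4.0, theta=0.7, phase=0.0)
        assert np.allclose(k, k[::-1, ::-1])

    def test_constant_image_zero_energy(self):
        maps = ft.gabor_features(np.full((20, 20), 0.5), GaborParams(), window=3)
        for per_scale in maps.values():
            assert np.allclose(per_scale["energy"], 0.0, atol=1e-12)

    def test_grating_amplitude_orientation_selectivity(self):
        lam = 6.0
        xx = np.arange(48)
        img = 0.5 + 0.4 * np.sin(2 * np.pi * xx / lam)[None, :] * np.ones((48, 1))
        params = GaborParams(wavelengths=(lam,), n_orientations=2)
        aligned = ft.gabor_features(img, GaborParams(wavelengths=(lam,), n_orientations=1))
        # orientation 0 (stripes vertical: variation along x) vs pi/2
        from scipy import ndimage as ndi

        k0e = gabor_kernel(lam, 0.0, 0.0)
        k0o = gabor_kernel(lam, 0.0, np.pi / 2)
        k9e = gabor_kernel(lam, np.pi / 2, 0.0)
        k9o = gabor_kernel(lam, np.pi / 2, np.pi / 2)
        amp0 = np.hypot(
            ndi.convolve(img, k0e, mode="reflect"), ndi.convolve(img, k0o, mode="reflect")
        )
        amp9 = np.hypot(
            ndi.convolve(img, k9e, mode="reflect"), ndi.convolve(img, k9o, mode="reflect")
        )
        interior = np.s_[12:36, 12:36]
        assert amp0[interior].mean() > 2 * amp9[interior].mean()
        assert aligned[lam]["amplitude"][interior].mean() > 0

    def test_wavelength_validation(self):
        with pytest.raises(ValueError):
            GaborParams(wavelengths=(2.0,))


class TestExtractPixelFeatures:
    def test_registry_has_35_unique_names(self):
        assert len(FEATURE_NAMES) == 35
        assert len(set(FEATURE_NAMES)) == 35
        assert sorted(TABLE_RANKING) == sorted(FEATURE_NAMES)

    def test_constant_image_constant_features(self):
        img = np.full((16, 16), 0.5)
        fov = np.ones((16, 16), bool)
        table = extract_pixel_features(img, fov, pixels=np.array([[4, 4], [9, 11]]))
        a, b = table.iloc[0][list(FEATURE_NAMES)], table.iloc[1][list(FEATURE_NAMES)]
        assert np.allclose(a.to_numpy(float), b.to_numpy(float))

    def test_rows_match_single_window_recompute(self, rng):
        img = rng.random((64, 64))
        fov = np.ones((64, 64), bool)
        gp, gb = GlcmParams(), GaborParams()
        pixels = np.array([[20, 30], [41, 12]])
        table = extract_pixel_features(img, fov, 3, gp, gb, pixels=pixels)
        q = ft.quantize(img, gp.levels, fov)
        maps = ft.gabor_features(img, gb, 3)[gb.wavelengths[0]]
        for _, row in table.iterrows():
            r, c = int(row["row"]), int(row["col"])
            wi = img[r - 1 : r + 2, c - 1 : c + 2]
            wq = q[r - 1 : r + 2, c - 1 : c + 2]
            expected = intensity_moments(wi)
            expected.update(glcm_features(compute_glcm(wq, gp)))
            expected.update(glrlm_features(compute_glrlm(wq, gp.levels)))
            expected["gabor_energy"] = maps["energy"][r, c]
            expected["gabor_mean_amplitude"] = maps["amplitude"][r, c]
            for name in FEATURE_NAMES:
                assert row[name] == pytest.approx(expected[name])

    def test_translation_equivariance(self, rng):
        img = rng.random((40, 40))
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        fov = np.ones((40, 40), bool)
        a = extract_pixel_features(img, fov, pixels=np.array([[20, 20]]))
        b = extract_pixel_features(shifted, fov, pixels=np.array([[23, 25]]))
        assert np.allclose(
            a[list(FEATURE_NAMES)].to_numpy(), b[list(FEATURE_NAMES)].to_numpy()
        )

    def test_pixel_outside_fov_skipped_with_warning(self, rng):
        img = rng.random((16, 16))
        fov = np.zeros((16, 16), bool)
        fov[4:12, 4:12] = True
        with pytest.warns(UserWarning, match="outside the FOV"):
            table = extract_pixel_features(
                img, fov, pixels=np.array([[8, 8], [0, 0]])
            )
        assert len(table) == 1

    def test_labels_read_from_truth_mask(self, rng):
        img = rng.random((16, 16))
        fov = np.ones((16, 16), bool)
        truth = np.zeros((16, 16), bool)
        truth[5, 5] = True
        table = extract_pixel_features(
            img, fov, pixels=np.array([[5, 5], [10, 10]]), labels=truth
        )
        assert list(table["label"]) == [1, -1]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            extract_pixel_features(np.zeros((8, 8)), np.ones((8, 8), bool), window=4)
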