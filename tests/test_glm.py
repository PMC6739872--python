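"""Design-matrix construction, percent signal change, AR(2) GLM and group
statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scalegrad import (NoiseSpec, build_design_matrix,
                       build_modulation_regressor, contrast, fit_glm_ar2,
                       generate_paradigm, generate_ratings,
                       generate_tuning_field, group_random_effects,
                       hrf_kernel, percent_signal_change, simulate_bold)
from scalegrad.glm import CONV_DT, modulation_weights_from_ratings
from scalegrad.synthetic import Block, Paradigm


class TestHrf:
    def test_peak_near_five_seconds(self):
        h = hrf_kernel(0.1)
        assert np.argmax(h) * 0.1 == pytest.approx(5.0, abs=0.2)
        assert h.sum() > 0

    def test_coarse_sampling_subsamples_fine_kernel(self):
        fine = hrf_kernel(0.1)
        coarse = hrf_kernel(2.5)
        np.testing.assert_allclose(coarse, fine[::25], rtol=1e-12)

    def test_no_undershoot_is_nonnegative(self):
        h = hrf_kernel(0.1, {"ratio": 0.0})
        assert (h >= 0).all()

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hrf_kernel(0.0)


def _single_block_paradigm(onset=10.0, duration=12.5, scale=2, n_volumes=40):
    block = Block(run=0, onset=onset, duration=duration, scale=scale,
                  location=1, task="spatial")
    return Paradigm(n_runs=1, tr=2.5, volumes_per_run=n_volumes,
                    blocks=[block])


class TestDesignMatrix:
    def test_absent_scale_gives_zero_column(self, small_paradigm):
        par = _single_block_paradigm(scale=2)
        d = build_design_matrix(par)
        assert np.all(d.column("scale_4") == 0)
        assert np.any(d.column("scale_2") != 0)

    def test_column_matches_direct_convolution_oracle(self):
        # independent oracle: explicit convolution sum on the fine grid
        par = _single_block_paradigm(onset=10.0, duration=12.5)
        d = build_design_matrix(par)
        col = d.column("scale_2")

        h = hrf_kernel(CONV_DT)
        n_fine = int(40 * 2.5 / CONV_DT) + 1
        u = np.array([1.0 if 10.0 <= i * CONV_DT < 22.5 else 0.0
                      for i in range(n_fine)])
        oracle = np.array([
            sum(u[i - k] * h[k] for k in range(min(i + 1, len(h))))
            for i in range(n_fine)])
        vols = np.round(np.arange(40) * 2.5 / CONV_DT).astype(int)
        np.testing.assert_allclose(col, oracle[vols], atol=1e-8)
        assert np.argmax(col) == np.argmax(oracle[vols])

    def test_two_blocks_sum_of_single_blocks(self):
        b1 = Block(0, 10.0, 12.5, 3, 1, "spatial")
        b2 = Block(0, 50.0, 12.5, 3, 1, "spatial")
        both = Paradigm(1, 2.5, 40, [b1, b2])
        single1 = Paradigm(1, 2.5, 40, [b1])
        single2 = Paradigm(1, 2.5, 40, [b2])
        col = build_design_matrix(both).column("scale_3")
        expected = (build_design_matrix(single1).column("scale_3")
                    + build_design_matrix(single2).column("scale_3"))
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_block_outside_run_rejected(self):
        par = _single_block_paradigm(onset=95.0, duration=12.5)
        with pytest.raises(ValueError, match="outside"):
            build_design_matrix(par)

    def test_one_intercept_per_run(self):
        par = generate_paradigm(3, 6, 2.5, seed=0)
        d = build_design_matrix(par)
        icols = [n for n in d.names if n.startswith("intercept")]
        assert len(icols) == 3
        total = sum(d.column(n) for n in icols)
        assert np.all(total == 1.0)


class TestPercentSignalChange:
    def test_constant_series_maps_to_zero(self):
        scaled, valid = percent_signal_change(np.full((3, 10), 200.0))
        assert np.all(scaled == 0)
        assert valid.all()

    def test_simple_arithmetic(self):
        scaled, _ = percent_signal_change(np.array([[90.0, 110.0]]))
        np.testing.assert_allclose(scaled[0], [-10.0, 10.0])

    def test_zero_mean_voxel_excluded_without_exception(self):
        scaled, valid = percent_signal_change(
            np.array([[1.0, -1.0], [100.0, 102.0]]))
        assert not valid[0] and valid[1]
        assert np.all(scaled[0] == 0)


class TestFitGlmAr2:
    def test_noise_free_betas_recover_injected_responses(self, tuned_grid):
        paradigm, field, bold = tuned_grid
        series = bold[0].reshape(-1, bold[0].shape[-1])
        scaled, _ = percent_signal_change(series)
        fit = fit_glm_ar2(scaled, build_design_matrix(paradigm))
        betas = fit.betas_named("scale_")
        true = field.response()
        tuned = field.amplitude.ravel() > 0
        rel = np.abs(betas[tuned] - true[tuned]) / np.abs(true[tuned])
        assert rel.max() < 1e-6

    def test_ar_coefficients_recovered(self):
        # signal-free AR(2) series; Yule-Walker estimates near truth
        a1, a2 = 0.3, 0.2
        rng = np.random.default_rng(11)
        from scipy.signal import lfilter
        Y = lfilter([1.0], [1.0, -a1, -a2],
                    rng.normal(size=(100, 10_000)), axis=1)
        X = np.column_stack([np.ones(10_000)])
        from scalegrad.glm import DesignMatrix
        design = DesignMatrix(matrix=X, names=["intercept_run0"],
                              runs=np.zeros(10_000, dtype=int))
        fit = fit_glm_ar2(Y, design)
        assert np.abs(fit.ar_coefs[:, 0].mean() - a1) < 0.05
        assert np.abs(fit.ar_coefs[:, 1].mean() - a2) < 0.05

    def test_betas_invariant_to_series_offset(self, tuned_grid):
        paradigm, field, bold = tuned_grid
        series = bold[0].reshape(-1, bold[0].shape[-1])[:5]
        design = build_design_matrix(paradigm)
        f1 = fit_glm_ar2(series, design)
        f2 = fit_glm_ar2(series + 5.0, design)
        task = [i for i, n in enumerate(design.names)
                if n.startswith("scale_")]
        np.testing.assert_allclose(f1.beta[:, task], f2.beta[:, task],
                                   atol=1e-6)

    def test_rank_deficient_design_rejected(self, small_paradigm):
        d = build_design_matrix(small_paradigm)
        dup = pd.DataFrame({"dup": d.column("scale_1")})
        bad = build_design_matrix(small_paradigm, nuisance=dup)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm_ar2(np.random.default_rng(0).normal(
                size=(2, bad.matrix.shape[0])), bad)

    def test_estimator_unbiased_over_simulations(self):
        # mean beta error per condition < 2 SE of the mean over 200 sims
        par = generate_paradigm(1, 12, 2.5, seed=0)
        shape = (1, 1, 1)
        field = generate_tuning_field(shape, np.ones(shape, bool), slope=0.0,
                                      jitter_sd=0.0, seed=0, intercept=3.0)
        true = field.response()[0]
        design = build_design_matrix(par)
        errs = []
        for i in range(200):
            bold = simulate_bold(par, field,
                                 NoiseSpec(innovation_sd=0.5), seed=100 + i)
            scaled, _ = percent_signal_change(
                bold[0].reshape(1, -1))
            fit = fit_glm_ar2(scaled, design)
            errs.append(fit.betas_named("scale_")[0] - true)
        errs = np.array(errs)
        mean_err = errs.mean(axis=0)
        sem = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(mean_err) < 2 * sem + 1e-3)

    def test_whitening_improves_type_i_calibration(self):
        # under AR(2) noise the whitened t-test is closer to nominal alpha
        a1, a2 = 0.5, 0.25
        rng = np.random.default_rng(21)
        from scipy.signal import lfilter
        par = generate_paradigm(1, 12, 2.5, seed=1)
        design = build_design_matrix(par)
        n_sim, T = 500, design.matrix.shape[0]
        X = design.matrix
        from scalegrad.glm import DesignMatrix
        d = DesignMatrix(matrix=X, names=design.names,
                         runs=np.zeros(T, dtype=int))
        noise = lfilter([1.0], [1.0, -a1, -a2],
                        rng.normal(size=(n_sim, T)), axis=1)
        rates = {}
        for whiten in (True, False):
            fit = fit_glm_ar2(noise, d, whiten=whiten)
            j = d.names.index("scale_1")
            t = fit.beta[:, j] / fit.se[:, j]
            p = 2 * stats.t.sf(np.abs(t), fit.df)
            rates[whiten] = (p < 0.05).mean()
        assert abs(rates[True] - 0.05) < abs(rates[False] - 0.05)


class TestGroupStats:
    def test_hand_computed_group_t(self):
        g = group_random_effects([np.array([[1.0]]), np.array([[2.0]]),
                                  np.array([[3.0]])])
        assert g.mean[0, 0] == pytest.approx(2.0)
        assert g.se[0, 0] == pytest.approx(0.5774, abs=1e-4)
        assert g.t[0, 0] == pytest.approx(3.4641, abs=1e-4)

    def test_identical_subjects_give_missing_t(self):
        g = group_random_effects([np.array([[1.0]])] * 4)
        assert np.isnan(g.t[0, 0])

    def test_subject_order_exchangeable(self):
        rng = np.random.default_rng(0)
        subs = [rng.normal(size=(5, 6)) for _ in range(4)]
        a = group_random_effects(subs)
        b = group_random_effects(subs[::-1])
        np.testing.assert_allclose(a.t, b.t)

    def test_contrast_hand_computation(self):
        # subject differences 0.5, 1.0, 1.5, 2.0 -> t = 1.25/0.3227 = 3.873
        betas = np.array([[0.5, 0.0], [1.0, 0.0], [1.5, 0.0], [2.0, 0.0]])
        res = contrast(betas, [1.0, -1.0])
        assert res["t"] == pytest.approx(3.873, abs=1e-3)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            contrast(np.ones((3, 2)), [0.0, 0.0])

    def test_degenerate_se_reported_missing(self):
        betas = np.array([[2.0, 1.0], [3.0, 2.0], [4.0, 3.0]])
        res = contrast(betas, [1.0, -1.0])
        assert np.isnan(res["t"]) and np.isnan(res["p"])


class TestModulation:
    def test_equal_ratings_give_zero_regressor(self, small_paradigm):
        weights = np.zeros(len(small_paradigm.blocks))
        col = build_modulation_regressor(small_paradigm, weights)
        assert np.all(col == 0)

    def test_linearity_of_block_weights(self, small_paradigm):
        w = np.zeros(len(small_paradigm.blocks))
        w[0], w[3] = 1.0, -1.0
        col = build_modulation_regressor(small_paradigm, w,
                                         mean_center=False)
        w1 = np.zeros_like(w)
        w1[0] = 1.0
        w2 = np.zeros_like(w)
        w2[3] = 1.0
        c1 = build_modulation_regressor(small_paradigm, w1, mean_center=False)
        c2 = build_modulation_regressor(small_paradigm, w2, mean_center=False)
        np.testing.assert_allclose(col, c1 - c2, atol=1e-12)

    def test_weights_from_ratings_z_scored_by_location(self, small_paradigm):
        ratings = generate_ratings(n_subjects=2, seed=0)
        w = modulation_weights_from_ratings(small_paradigm, ratings, 0,
                                            "familiarity")
        z = ratings.z_scored(0, "familiarity")
        for weight, block in zip(w, small_paradigm.blocks):
            assert weight == z[block.location]

    def test_missing_rating_names_block(self, small_paradigm):
        ratings = generate_ratings(n_subjects=1, seed=0)
        trimmed = ratings.location_ratings[
            ratings.location_ratings["location"] != 1]
        ratings.location_ratings = trimmed
        with pytest.raises(ValueError, match="location 1"):
            modulation_weights_from_ratings(small_paradigm, ratings, 0,
                                            "familiarity")
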