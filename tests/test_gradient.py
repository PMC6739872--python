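"""Axis profiles and permutation slope tests of the scale gradient."""

import numpy as np
import pandas as pd
import pytest

from scalegrad import (axis_profile, fdr_across_regions,
                       permutation_test_slope, subject_level_gradient)
from scalegrad.gradient import AxisProfile
from .conftest import gaussian_betas


def make_profile(values, coords=None):
    values = np.asarray(values, dtype=float)
    coords = np.arange(len(values), dtype=float) if coords is None \
        else np.asarray(coords, dtype=float)
    return AxisProfile(region="r", axis=1, method="peak", coords=coords,
                       mean_scale=values, counts=np.ones(len(values), int))


class TestAxisProfile:
    def test_constant_slices(self):
        peak = np.full((2, 3, 2), np.nan)
        peak[:, 0], peak[:, 1], peak[:, 2] = 2.0, 3.0, 4.0
        prof = axis_profile(peak, np.ones((2, 3, 2), bool), axis=1)
        np.testing.assert_allclose(prof.mean_scale, [2, 3, 4])
        np.testing.assert_array_equal(prof.counts, [4, 4, 4])

    def test_empty_slice_omitted_not_zero_filled(self):
        peak = np.full((1, 3, 1), np.nan)
        peak[0, 0, 0], peak[0, 2, 0] = 2.0, 4.0
        prof = axis_profile(peak, np.ones((1, 3, 1), bool), axis=1)
        np.testing.assert_allclose(prof.coords, [0, 2])
        np.testing.assert_allclose(prof.mean_scale, [2, 4])

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        shape = (4, 6, 3)
        peak = rng.uniform(1, 6, shape)
        peak[rng.random(shape) < 0.3] = np.nan
        region = rng.random(shape) < 0.7
        prof = axis_profile(peak, region, axis=1)
        vals = np.where(region, peak, np.nan)
        frame = pd.DataFrame({
            "y": np.indices(shape)[1].ravel(), "v": vals.ravel()}).dropna()
        oracle = frame.groupby("y")["v"].mean()
        np.testing.assert_allclose(prof.mean_scale, oracle.to_numpy())
        np.testing.assert_allclose(prof.coords, oracle.index.to_numpy())

    def test_no_gated_voxels_rejected(self):
        with pytest.raises(ValueError, match="no gated voxels"):
            axis_profile(np.full((2, 2, 2), np.nan),
                         np.ones((2, 2, 2), bool))


class TestPermutationSlope:
    def test_exact_enumeration_of_monotone_profile(self):
        res = permutation_test_slope(make_profile([1, 2, 3, 4, 5, 6]),
                                     exact=True)
        assert res.p == pytest.approx(1 / 720)
        assert res.slope == pytest.approx(1.0)

    def test_sampled_p_near_exact(self):
        res = permutation_test_slope(make_profile([1, 2, 3, 4, 5, 6]),
                                     n_perm=1000, seed=2)
        # add-one estimate of 1/720 from 1000 draws: binomial 3-sigma band
        p_true = 1 / 720
        sd = np.sqrt(p_true * (1 - p_true) / 1000)
        assert 1 / 1001 <= res.p <= p_true + 3 * sd + 1 / 1001

    def test_reversed_profile_one_sided_p_near_one(self):
        res = permutation_test_slope(make_profile([6, 5, 4, 3, 2, 1]),
                                     n_perm=500, seed=0)
        assert res.p > 0.99

    def test_constant_profile_reports_zero_slope_p_one(self):
        res = permutation_test_slope(make_profile([3, 3, 3, 3]))
        assert res.slope == 0.0 and res.p == 1.0
        assert "constant-profile" in res.flags

    def test_seed_reproducibility(self):
        prof = make_profile([1.2, 3.1, 2.2, 4.5, 3.9, 5.0])
        a = permutation_test_slope(prof, n_perm=1000, seed=7)
        b = permutation_test_slope(prof, n_perm=1000, seed=7)
        assert a.p == b.p and a.slope == b.slope

    def test_too_few_coordinates_rejected(self):
        with pytest.raises(ValueError, match="3 coordinates"):
            permutation_test_slope(make_profile([1, 2]))

    def test_null_calibration(self):
        # shuffled-null profiles: rejection rate at alpha=0.05 near nominal
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 500
        for i in range(n_sim):
            prof = make_profile(rng.normal(3.5, 0.3, size=20))
            res = permutation_test_slope(prof, n_perm=500, seed=1000 + i)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_monotone_in_slope(self):
        rng = np.random.default_rng(9)
        power = []
        for slope in (0.0, 0.05, 0.1, 0.2):
            rej = 0
            for i in range(200):
                y = 2.0 + slope * np.arange(20) + rng.normal(0, 0.3, 20)
                res = permutation_test_slope(make_profile(y), n_perm=300,
                                             seed=i)
                rej += res.p < 0.05
            power.append(rej / 200)
        assert all(b >= a - 0.02 for a, b in zip(power, power[1:]))
        assert power[-1] > power[0]


class TestFdrAcrossRegions:
    def test_single_region_q_equals_p(self):
        res = [permutation_test_slope(make_profile([1, 3, 2, 4, 5, 6]),
                                      n_perm=200, seed=0)]
        fdr_across_regions(res)
        assert res[0].q == res[0].p

    def test_bh_by_hand_four_regions(self):
        results = []
        for p in (0.001, 0.001, 0.001, 0.2):
            r = permutation_test_slope(make_profile([1, 2, 3, 4, 5, 6]),
                                       n_perm=100, seed=0)
            r.p = p
            results.append(r)
        fdr_across_regions(results, q=0.05)
        assert [r.significant for r in results] == [True, True, True, False]

    def test_all_null_none_significant(self):
        results = []
        for _ in range(3):
            r = permutation_test_slope(make_profile([1, 2, 3, 4, 5, 6]),
                                       n_perm=100, seed=0)
            r.p = 1.0
            results.append(r)
        fdr_across_regions(results)
        assert not any(r.significant for r in results)


def _subject_beta_maps(n_subjects, slope_per_coord, noise_sd, seed,
                       shape=(3, 20, 1)):
    """Beta maps whose tuning centers follow a linear axis progression."""
    rng = np.random.default_rng(seed)
    maps = []
    y = np.indices(shape)[1]
    for _ in range(n_subjects):
        centers = 1.0 + slope_per_coord * y \
            + rng.normal(0, 0.2, size=shape)
        betas = np.stack([
            gaussian_betas(c) + rng.normal(0, noise_sd, 6)
            for c in centers.ravel()]).reshape(shape + (6,))
        maps.append(betas)
    return maps


class TestSubjectLevel:
    def test_strong_gradients_all_significant(self):
        maps = _subject_beta_maps(10, slope_per_coord=5.0 / 19,
                                  noise_sd=0.1, seed=1)
        region = np.ones((3, 20, 1), bool)
        results, n_sig = subject_level_gradient(maps, region, axis=1,
                                                n_perm=500, seed=3)
        assert n_sig == 10

    def test_null_slope_rarely_significant(self):
        maps = _subject_beta_maps(10, slope_per_coord=0.0, noise_sd=0.1,
                                  seed=2)
        region = np.ones((3, 20, 1), bool)
        _, n_sig = subject_level_gradient(maps, region, axis=1, n_perm=500,
                                          seed=4)
        assert n_sig <= 3

    def test_deterministic(self):
        maps = _subject_beta_maps(3, slope_per_coord=0.1, noise_sd=0.1,
                                  seed=5)
        region = np.ones((3, 20, 1), bool)
        r1, _ = subject_level_gradient(maps, region, n_perm=300, seed=6)
        r2, _ = subject_level_gradient(maps, region, n_perm=300, seed=6)
        assert [r.p for r in r1] == [r.p for r in r2]

    def test_subject_without_gated_voxels_flagged(self):
        maps = _subject_beta_maps(3, slope_per_coord=0.1, noise_sd=0.05,
                                  seed=7)
        maps[1] = np.zeros_like(maps[1])      # flat betas never pass the gate
        region = np.ones((3, 20, 1), bool)
        results, _ = subject_level_gradient(maps, region, n_perm=200, seed=8)
        assert "no-gated-voxels" in results[1].flags
        assert not results[1].significant


class TestSlopeRecovery:
    def test_recovered_slope_within_15_percent_median(self):
        true_slope = 0.15
        rng = np.random.default_rng(10)
        errors = []
        for i in range(100):
            y = 1.0 + true_slope * np.arange(25) + rng.normal(0, 0.3, 25)
            res = permutation_test_slope(make_profile(y), n_perm=10, seed=i)
            errors.append(abs(res.slope - true_slope) / true_slope)
        assert np.median(errors) < 0.15
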