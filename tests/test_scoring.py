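import dataclasses

import numpy as np
import pytest

from petsim.phantom import REFERENCE_AGE, PhantomParams, simulate_scan
from petsim.scoring import (
    NormalDatabase,
    ScoringConfig,
    ad_tsum,
    compute_tmap,
    fit_age_regression,
    intensity_normalize,
    pet_score,
    score_subject,
    smooth_gaussian,
)
from petsim.volumes import BrainVolume, Cohort, SubjectScan, VolumeMask

# ---------------------------------------------------------------------------
# Brute-force oracles (scalar loops, independent of the vectorized paths)
# ---------------------------------------------------------------------------


def ols_oracle(ages, values):
    """Closed-form OLS of values (n,) on ages (n,), residual SD with n-2 df."""
    n = len(ages)
    abar = sum(ages) / n
    sxx = sum((a - abar) ** 2 for a in ages)
    sxy = sum((a - abar) * v for a, v in zip(ages, values))
    slope = sxy / sxx
    ybar = sum(values) / n
    intercept = ybar - slope * abar
    rss = sum((v - intercept - slope * a) ** 2 for a, v in zip(ages, values))
    return intercept, slope, (rss / (n - 2)) ** 0.5


def tmap_oracle(data, db, brain, age):
    c = (1.0 + 1.0 / db.n_controls + (age - db.mean_age) ** 2 / db.age_ssq) ** 0.5
    t = np.zeros_like(data)
    for idx in np.ndindex(data.shape):
        if brain[idx]:
            expected = db.intercept[idx] + db.slope[idx] * age
            t[idx] = (expected - data[idx]) / (db.resid_sd[idx] * c)
    return t


def _tiny_masks(shape=(4, 4, 4)):
    brain = np.ones(shape, dtype=bool)
    preserved = np.zeros(shape, dtype=bool)
    preserved[0, 0, :2] = True
    ad = np.zeros(shape, dtype=bool)
    ad[-1, -1, -2:] = True
    return (
        VolumeMask(brain, "brain"),
        VolumeMask(preserved, "preserved_uptake"),
        VolumeMask(ad, "ad_pattern"),
    )


def _random_db(rng, shape, brain):
    return NormalDatabase(
        intercept=rng.uniform(0.5, 1.5, shape),
        slope=rng.uniform(-0.02, 0.02, shape),
        resid_sd=rng.uniform(0.05, 0.3, shape),
        n_controls=int(rng.integers(3, 30)),
        mean_age=float(rng.uniform(60, 80)),
        age_ssq=float(rng.uniform(50, 500)),
        brain=brain,
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        v = BrainVolume(rng.random((10, 10, 10)))
        out = smooth_gaussian(v, (0, 0, 0))
        np.testing.assert_array_equal(out.data, v.data)

    def test_constant_conserved_in_interior(self):
        v = BrainVolume(np.full((40, 40, 40), 3.5))
        out = smooth_gaussian(v, (12, 12, 12))
        assert out.data[20, 20, 20] == pytest.approx(3.5, rel=1e-6)

    def test_impulse_center_matches_analytic_kernel(self):
        """Center of a smoothed unit impulse = product of the per-axis central
        weights of the truncated sampled-Gaussian kernel."""
        fwhm, voxel = 12.0, 2.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4.0 * sigma + 0.5)  # truncation at 4 sigma
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        expected = kernel[radius] ** 3

        data = np.zeros((31, 31, 31))
        data[15, 15, 15] = 1.0
        out = smooth_gaussian(BrainVolume(data), (fwhm,) * 3)
        assert out.data[15, 15, 15] == pytest.approx(expected, rel=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            smooth_gaussian(BrainVolume(np.zeros((4, 4, 4))), (-1, 0, 0))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class TestIntensityNormalization:
    def test_mask_mean_is_one(self):
        rng = np.random.default_rng(1)
        brain, preserved, _ = _tiny_masks((6, 6, 6))
        v = BrainVolume(rng.uniform(0.5, 2.0, (6, 6, 6)))
        out, factor = intensity_normalize(v, preserved)
        assert out.data[preserved.data].mean() == pytest.approx(1.0, abs=1e-12)
        assert factor == pytest.approx(v.data[preserved.data].mean())

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        _, preserved, _ = _tiny_masks((6, 6, 6))
        v = BrainVolume(rng.uniform(0.5, 2.0, (6, 6, 6)))
        a, _ = intensity_normalize(v, preserved)
        b, _ = intensity_normalize(v.with_data(3.7 * v.data), preserved)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_degenerate_input_rejected(self):
        _, preserved, _ = _tiny_masks((6, 6, 6))
        with pytest.raises(ValueError, match="degenerate"):
            intensity_normalize(BrainVolume(np.zeros((6, 6, 6))), preserved)


# ---------------------------------------------------------------------------
# Age regression
# ---------------------------------------------------------------------------


class TestAgeRegression:
    def test_matches_scalar_ols_oracle(self):
        """Voxelwise fit equals the closed-form OLS oracle voxel by voxel,
        after per-subject preserved-mask normalization, on 100 random cases."""
        rng = np.random.default_rng(3)
        masks = _tiny_masks((4, 4, 4))
        cfg = ScoringConfig(pre_normalized=True, s_floor=1e-12)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            ages = rng.uniform(55, 90, n)
            vols = rng.uniform(0.5, 2.0, (n, 4, 4, 4))
            cohort = Cohort(
                [
                    SubjectScan(BrainVolume(vols[i]), ages[i], "NC", f"s{i}")
                    for i in range(n)
                ]
            )
            db = fit_age_regression(cohort, masks, cfg)
            norm = vols / vols[:, masks[1].data].mean(axis=1)[:, None, None, None]
            for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
                a, b, s = ols_oracle(list(ages), [norm[i][idx] for i in range(n)])
                assert db.intercept[idx] == pytest.approx(a, abs=1e-9)
                assert db.slope[idx] == pytest.approx(b, abs=1e-10)
                assert db.resid_sd[idx] == pytest.approx(max(s, 1e-12), abs=1e-9)

    def test_noise_free_phantom_slope_recovered(self, masks):
        """Noise-free controls recover the (normalized) age slope exactly and
        hit the residual-SD floor."""
        p = PhantomParams(grid_shape=masks[0].grid_shape, subject_noise_sd=0.0)
        ages = [60.0, 65.0, 70.0, 75.0, 80.0]
        cohort = Cohort(
            [simulate_scan(p, masks, a, "NC", 0, subject_id=f"c{i}") for i, a in enumerate(ages)]
        )
        db = fit_age_regression(cohort, masks, ScoringConfig(pre_normalized=True))
        region = (masks[0].data & ~masks[1].data)
        expected_slope = p.age_slope_per_year / p.base_uptake  # preserved mean = base
        np.testing.assert_allclose(db.slope[region], expected_slope, atol=1e-10)
        np.testing.assert_allclose(db.slope[masks[1].data], 0.0, atol=1e-10)
        # noise-free fit hits the residual-SD floor (still strictly positive)
        assert np.all(db.resid_sd[masks[0].data] > 0)
        assert db.resid_sd[masks[0].data].max() < 1e-4

    def test_degenerate_ages_rejected(self, masks):
        p = PhantomParams(grid_shape=masks[0].grid_shape, subject_noise_sd=0.0)
        cohort = Cohort(
            [simulate_scan(p, masks, 70.0, "NC", i, subject_id=f"c{i}") for i in range(4)]
        )
        with pytest.raises(ValueError, match="degenerate age"):
            fit_age_regression(cohort, masks, ScoringConfig(pre_normalized=True))

    def test_too_few_controls_rejected(self, masks):
        p = PhantomParams(grid_shape=masks[0].grid_shape)
        cohort = Cohort([simulate_scan(p, masks, 70.0, "NC", 0, subject_id="c0")])
        with pytest.raises(ValueError, match=">= 3"):
            fit_age_regression(cohort, masks, ScoringConfig(pre_normalized=True))


# ---------------------------------------------------------------------------
# t-map, t-sum, PET score
# ---------------------------------------------------------------------------


class TestTMap:
    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            shape = tuple(rng.integers(2, 9, 3))
            brain = rng.random(shape) > 0.3
            if not brain.any():
                brain[0, 0, 0] = True
            bm = VolumeMask(brain, "brain")
            db = _random_db(rng, shape, bm)
            age = float(rng.uniform(55, 90))
            subj = SubjectScan(BrainVolume(rng.uniform(0.2, 2.0, shape)), age, "NC", "s")
            t = compute_tmap(subj, db, bm)
            np.testing.assert_allclose(
                t.data, tmap_oracle(subj.volume.data, db, brain, age), atol=1e-10
            )

    def test_subject_equal_to_prediction_gives_zero(self):
        rng = np.random.default_rng(5)
        shape = (5, 5, 5)
        bm = VolumeMask(np.ones(shape, bool), "brain")
        db = _random_db(rng, shape, bm)
        age = 70.0
        subj = SubjectScan(BrainVolume(db.predicted(age)), age, "NC", "s")
        np.testing.assert_array_equal(compute_tmap(subj, db, bm).data, 0.0)

    def test_one_prediction_se_below_gives_t_one(self):
        rng = np.random.default_rng(6)
        shape = (3, 3, 3)
        bm = VolumeMask(np.ones(shape, bool), "brain")
        db = _random_db(rng, shape, bm)
        age = 66.0
        data = db.predicted(age)
        data[1, 1, 1] -= db.resid_sd[1, 1, 1] * db.prediction_se_factor(age)
        t = compute_tmap(SubjectScan(BrainVolume(data), age, "NC", "s"), db, bm)
        assert t.data[1, 1, 1] == pytest.approx(1.0, abs=1e-12)


class TestTsumAndScore:
    def test_tsum_matches_naive_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = tuple(rng.integers(2, 9, 3))
            mask = rng.random(shape) > 0.5
            if not mask.any():
                mask[0, 0, 0] = True
            t = rng.normal(size=shape)
            expected = sum(t[idx] for idx in np.ndindex(shape) if mask[idx])
            got = ad_tsum(BrainVolume(t), VolumeMask(mask, "ad_pattern"))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_uniform_t_over_known_mask(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.flat[:100] = True
        t = BrainVolume(np.full((10, 10, 10), 2.0))
        assert ad_tsum(t, VolumeMask(mask, "ad_pattern")) == pytest.approx(200.0)

    @pytest.mark.parametrize(
        "tsum,expected",
        [(11089.0, 1.0), (0.0, 0.0), (3 * 11089.0, 2.0), (11089.0 * 15, 4.0)],
    )
    def test_pet_score_values(self, tsum, expected):
        assert pet_score(tsum) == pytest.approx(expected, abs=1e-14)

    def test_pet_score_strictly_increasing(self):
        ts = np.linspace(-5000, 50000, 200)
        scores = [pet_score(t) for t in ts]
        assert np.all(np.diff(scores) > 0)

    def test_pathological_tsum_rejected(self):
        with pytest.raises(ValueError, match="pathological"):
            pet_score(-2 * 11089.0)


# ---------------------------------------------------------------------------
# Composed scoring
# ---------------------------------------------------------------------------


class TestScoreSubject:
    def test_noise_free_nc_scores_zero(self, masks):
        p = PhantomParams(grid_shape=masks[0].grid_shape, subject_noise_sd=0.0)
        ages = [60.0, 65.0, 70.0, 75.0, 80.0]
        cohort = Cohort(
            [simulate_scan(p, masks, a, "NC", 0, subject_id=f"c{i}") for i, a in enumerate(ages)]
        )
        cfg = ScoringConfig(pre_normalized=True)
        db = fit_age_regression(cohort, masks, cfg)
        subj = simulate_scan(p, masks, 67.0, "NC", 0, subject_id="probe")
        res = score_subject(subj, db, masks, cfg)
        assert res.pet_score == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance(self, normal_db, masks, test_cohort, scoring_config):
        s = test_cohort.subjects[0]
        base = score_subject(s, normal_db, masks, scoring_config)
        for c in (0.1, 3.7, 1000.0):
            scaled = SubjectScan(s.volume.with_data(c * s.volume.data), s.age, s.diagnosis, s.subject_id)
            res = score_subject(scaled, normal_db, masks, scoring_config)
            assert res.pet_score == pytest.approx(base.pet_score, abs=1e-10)

    def test_determinism(self, normal_db, masks, test_cohort, scoring_config):
        s = test_cohort.subjects[1]
        a = score_subject(s, normal_db, masks, scoring_config)
        b = score_subject(s, normal_db, masks, scoring_config)
        assert a.pet_score == b.pet_score and a.ad_tsum == b.ad_tsum

    def test_severity_monotonicity(self, masks, normal_db, scoring_config):
        """More hypometabolism -> strictly larger AD t-sum (noise-free)."""
        tsums = []
        for sev in (0.0, 0.05, 0.10, 0.20, 0.30):
            p = PhantomParams(grid_shape=masks[0].grid_shape, subject_noise_sd=0.0, ad_severity=sev)
            subj = simulate_scan(p, masks, 70.0, "AD", 0, subject_id="probe")
            tsums.append(score_subject(subj, normal_db, masks, scoring_config).ad_tsum)
        assert np.all(np.diff(tsums) > 0)

    def test_ad_scores_above_paired_nc(self, masks, normal_db, phantom_params, scoring_config):
        """Same seed and age: AD phantom scores strictly above its NC twin."""
        for seed in range(5):
            nc = simulate_scan(phantom_params, masks, 72.0, "NC", seed, subject_id="nc")
            ad = simulate_scan(phantom_params, masks, 72.0, "AD", seed, subject_id="ad")
            s_nc = score_subject(nc, normal_db, masks, scoring_config).pet_score
            s_ad = score_subject(ad, normal_db, masks, scoring_config).pet_score
            assert s_ad > s_nc
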