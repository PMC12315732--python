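"""ICC(A,1), CVws, Bland-Altman, CV trimming, and masked smoothing."""

import numpy as np
import pytest

from mdmri.reliability import (
    icc_a1, classify_icc, cv_ws, bland_altman, trim_cv_distribution,
    gaussian_smooth_masked, fwhm_to_sigma, icc_fwhm_sweep,
)


def _anova_icc_oracle(t):
    """Explicit sums-of-squares two-way ANOVA, written independently."""
    t = np.asarray(t, float)
    n, k = t.shape
    grand = t.sum() / t.size
    ss_rows = sum(k * (t[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (t[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x - grand) ** 2 for x in t.ravel())
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIccA1:
    def test_perfect_agreement_gives_one(self):
        t = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_a1(t) == pytest.approx(1.0)

    def test_hand_anova_example(self):
        """(1,2,3) vs (2,3,4): MSR=2, MSC=1.5, MSE=0 -> ICC = 2/3."""
        t = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        assert icc_a1(t) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_explicit_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 5))
            t = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            assert icc_a1(t) == pytest.approx(_anova_icc_oracle(t), abs=1e-10)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(1)
        t = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 1.5
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 2),
            "rater": np.tile(np.arange(2), 8),
            "score": t.ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        ref = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_a1(t) == pytest.approx(ref, abs=1e-8)

    def test_negative_values_clamped_when_requested(self):
        t = np.array([[1.0, 5.0], [5.0, 1.0], [3.0, 3.1]])
        assert icc_a1(t) < 0
        assert icc_a1(t, clamp=True) == 0.0

    def test_no_variance_is_undefined(self):
        assert np.isnan(icc_a1(np.full((3, 2), 2.0)))

    @pytest.mark.parametrize("value,category", [
        (0.3, "poor"), (0.5, "moderate"), (0.74, "moderate"),
        (0.8, "good"), (0.75, "good"), (0.95, "excellent"), (0.9, "excellent"),
    ])
    def test_classification_thresholds(self, value, category):
        assert classify_icc(value) == category

    def test_calibration_against_variance_ratio(self):
        """Mean estimated ICC tracks rho = sp^2/(sp^2+se^2) over replicates."""
        rng = np.random.default_rng(42)
        for rho in (0.5, 0.8, 0.95):
            sp = np.sqrt(rho)
            se = np.sqrt(1 - rho)
            vals = []
            for _ in range(200):
                t = rng.normal(0, sp, (10, 1)) + rng.normal(0, se, (10, 2))
                vals.append(icc_a1(t))
            assert np.mean(vals) == pytest.approx(rho, abs=0.05)


class TestCvWs:
    def test_identical_sessions_give_zero(self):
        t = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert cv_ws(t) == 0.0

    def test_hand_example(self):
        """MSws = 0.5, grand mean 2.5 -> CVws = sqrt(0.5)/2.5."""
        t = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        assert cv_ws(t) == pytest.approx(np.sqrt(0.5) / 2.5, abs=1e-12)

    def test_sign_flip_invariance(self, rng):
        t = rng.normal(2.0, 0.5, size=(6, 2))
        assert cv_ws(-t) == pytest.approx(cv_ws(t), rel=1e-12)

    def test_scales_inversely_with_mean(self, rng):
        base = rng.normal(0.0, 0.3, size=(6, 2))
        a = cv_ws(base + 2.0)
        b = cv_ws(base + 4.0)
        # same within-subject scatter, doubled mean -> roughly halved CV
        assert b < a

    def test_zero_mean_raises(self):
        t = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="mean"):
            cv_ws(t)


class TestBlandAltman:
    def test_identical_vectors(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.mean_difference == 0.0
        assert (s.ci_low, s.ci_high) == (0.0, 0.0)
        assert s.relative_mean_difference_pct == 0.0

    def test_hand_example(self):
        """(1,2) vs (2,3): bias -1, zero-width CI, grand mean 2 -> -50%."""
        s = bland_altman([1.0, 2.0], [2.0, 3.0])
        assert s.mean_difference == pytest.approx(-1.0)
        assert s.ci_low == pytest.approx(-1.0)
        assert s.ci_high == pytest.approx(-1.0)
        assert s.relative_mean_difference_pct == pytest.approx(-50.0)

    def test_shift_changes_relative_but_not_bias(self, rng):
        a = rng.normal(5, 1, 20)
        b = a + rng.normal(0, 0.1, 20)
        s0 = bland_altman(a, b)
        s1 = bland_altman(a + 10, b + 10)
        assert s1.mean_difference == pytest.approx(s0.mean_difference)
        assert s1.relative_mean_difference_pct \
            != pytest.approx(s0.relative_mean_difference_pct)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestTrimCvDistribution:
    def test_values_below_one_untouched(self, rng):
        v = rng.uniform(0, 0.9, 1000)
        out, removed = trim_cv_distribution(v)
        assert removed == 0
        assert len(out) == 1000

    def test_dense_uniform_sample_unchanged(self, rng):
        v = np.concatenate([rng.uniform(0.5, 1.5, 20000)])
        out, removed = trim_cv_distribution(v)
        assert removed == 0

    def test_isolated_outlier_removed(self, rng):
        v = np.concatenate([rng.normal(0.05, 0.005, 10_000), [50.0]])
        out, removed = trim_cv_distribution(v)
        assert removed >= 1
        assert out.max() < 50.0


class TestFwhmSweep:
    def test_smoothing_raises_icc_for_global_subject_differences(self):
        """When subject effects are global and session noise voxel-wise,
        smoothing suppresses the noise term and median ICC increases."""
        rng = np.random.default_rng(7)
        shape = (12, 12, 4)
        mask = np.ones(shape, dtype=bool)
        maps = {}
        for s in range(6):
            offset = rng.normal(0, 0.5)  # global subject effect
            for r in range(2):
                maps[(s, r)] = 1.0 + offset + rng.normal(0, 1.0, shape)
        sweep = icc_fwhm_sweep(maps, mask, fwhms_mm=[0.0, 4.0, 8.0],
                               voxel_size_mm=2.0)
        assert sweep[0.0] < sweep[4.0] < sweep[8.0]


class TestMaskedSmoothing:
    def test_fwhm_sigma_conversion(self):
        assert fwhm_to_sigma(4.0) == pytest.approx(1.6986, abs=1e-4)

    def test_constant_preserved_inside_arbitrary_mask(self, rng):
        mask = rng.random((12, 12, 6)) > 0.4
        vol = np.full(mask.shape, 3.7)
        out = gaussian_smooth_masked(vol, mask, fwhm_mm=4.0, voxel_size_mm=2.0)
        assert np.allclose(out[mask], 3.7)

    def test_outside_mask_intensity_has_no_influence(self):
        mask = np.zeros((11, 11, 5), dtype=bool)
        mask[2:7, 2:7, 1:4] = True
        vol = np.zeros(mask.shape)
        vol[~mask] = 1e6  # huge out-of-mask intensity
        out = gaussian_smooth_masked(vol, mask, fwhm_mm=6.0, voxel_size_mm=2.0)
        assert np.allclose(out[mask], 0.0)

    def test_smoothing_reduces_in_mask_variance(self, rng):
        mask = np.ones((16, 16, 8), dtype=bool)
        vol = rng.normal(size=mask.shape)
        out = gaussian_smooth_masked(vol, mask, fwhm_mm=4.0, voxel_size_mm=2.0)
        assert out[mask].std() < vol[mask].std()

    def test_nonpositive_fwhm_raises(self):
        with pytest.raises(ValueError):
            gaussian_smooth_masked(np.ones((4, 4, 4)),
                                   np.ones((4, 4, 4)), 0.0)
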