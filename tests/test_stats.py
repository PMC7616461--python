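"""Agreement statistics against brute-force oracles."""

import numpy as np
import pytest

from bhcal.stats import (
    PairedMeasurements,
    between_measure_cv,
    bland_altman,
    coupling_ratio,
    icc_absolute_agreement,
    paired_permutation_test,
)


def icc_bruteforce(a, b):
    """Independent ANOVA-sums oracle for ICC(A,1), written from the
    definition with explicit loops."""
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_columns(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        icc, lo, hi = icc_absolute_agreement(a, a.copy())
        assert icc == pytest.approx(1.0)

    def test_offset_penalised_vs_consistency(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 2, 20)
        b = a + 5.0  # large systematic offset
        icc, _, _ = icc_absolute_agreement(a, b)
        assert icc < 0.5  # absolute agreement punishes the offset

    def test_worked_table_matches_bruteforce(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.1, 2.1, 2.9, 4.2])
        icc, lo, hi = icc_absolute_agreement(a, b)
        assert icc == pytest.approx(icc_bruteforce(a, b), abs=1e-12)
        assert lo < icc < hi

    def test_random_tables_match_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(3, 11)
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.5, size=n)
            icc, _, _ = icc_absolute_agreement(a, b)
            assert icc == pytest.approx(icc_bruteforce(a, b), abs=1e-10)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 15)
        b = a + rng.normal(0.5, 1.0, 15)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["A", "B"], 15),
            "score": np.column_stack([a, b]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
        ref = float(row["ICC"].iloc[0])
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        ref_ci = row[ci_col].iloc[0]  # rounded to 2 dp by pingouin
        icc, lo, hi = icc_absolute_agreement(a, b)
        assert icc == pytest.approx(ref, abs=1e-8)
        assert lo == pytest.approx(ref_ci[0], abs=0.011)
        assert hi == pytest.approx(ref_ci[1], abs=0.011)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones(5), np.ones(5))


class TestBlandAltman:
    def test_identical_pairs(self):
        a = np.array([1.0, 2.0, 3.0])
        assert bland_altman(a, a.copy()) == (0.0, 0.0, 0.0)

    def test_constant_difference(self):
        bias, lo, hi = bland_altman(np.array([2.0, 3.0]),
                                    np.array([1.0, 2.0]))
        assert (bias, lo, hi) == (1.0, 1.0, 1.0)

    def test_two_point_arithmetic(self):
        bias, lo, hi = bland_altman(np.array([0.0, 2.0]),
                                    np.array([0.0, 0.0]))
        assert bias == 1.0
        assert lo == pytest.approx(1 - 1.96 * np.sqrt(2.0))
        assert hi == pytest.approx(1 + 1.96 * np.sqrt(2.0))

    def test_median_variant(self):
        d = np.array([0.0, 0.0, 0.0, 10.0, 0.0])
        bias, lo, hi = bland_altman(d, np.zeros(5), central="median")
        assert bias == 0.0
        assert hi <= 10.0

    def test_loa_coverage_gaussian(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = a + rng.normal(scale=0.3, size=200)
        bias, lo, hi = bland_altman(a, b, central="mean")
        d = a - b
        inside = np.mean((d >= lo) & (d <= hi))
        assert inside >= 0.93


class TestCv:
    def test_identical(self):
        a = np.array([1.0, 2.0, 3.0])
        assert between_measure_cv(a, a.copy())[0] == 0.0

    def test_two_point_arithmetic(self):
        mean_cv, _ = between_measure_cv(np.array([0.37, 0.37, 0.37]),
                                        np.array([0.39, 0.39, 0.39]))
        assert mean_cv == pytest.approx(
            0.02 / (np.sqrt(2.0) * 0.38) * 100.0, abs=1e-10)
        assert mean_cv == pytest.approx(3.72, abs=0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(1, 2, 10)
        b = a * rng.uniform(0.9, 1.1, 10)
        cv1 = between_measure_cv(a, b)
        cv2 = between_measure_cv(7.3 * a, 7.3 * b)
        assert cv1[0] == pytest.approx(cv2[0])


class TestPermutation:
    def test_all_zero_differences(self):
        assert paired_permutation_test(np.zeros(8)) == 1.0

    def test_all_same_sign_exhaustive(self):
        d = np.array([1, 2, 1, 3, 1, 2, 1, 1, 2, 1, 3, 2], dtype=float)
        assert paired_permutation_test(d) == pytest.approx(2 / 4096)

    def test_exhaustive_matches_direct_enumeration(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, 9)
        # direct enumeration oracle
        obs = abs(d.mean())
        count = 0
        for m in range(2 ** 9):
            signs = [1 if (m >> i) & 1 else -1 for i in range(9)]
            if abs(np.mean(signs * d)) >= obs - 1e-12:
                count += 1
        assert paired_permutation_test(d) == pytest.approx(count / 2 ** 9)

    def test_monte_carlo_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.2, 1.0, 20)
        p1 = paired_permutation_test(d, seed=9)
        p2 = paired_permutation_test(d, seed=9)
        assert p1 == p2

    def test_type_one_error_near_alpha(self):
        """Null simulations: the exhaustive sign-flip test rejects at
        ~5% when alpha = 0.05."""
        rng = np.random.default_rng(7)
        n_sim = 500
        rejections = 0
        for _ in range(n_sim):
            d = rng.normal(0.0, 1.0, 12)
            if paired_permutation_test(d) < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.03


class TestCoupling:
    def test_printed_roi_means(self):
        assert coupling_ratio(16.0, 12.0) == pytest.approx(4.0 / 3.0)

    def test_equal_inputs(self):
        assert coupling_ratio(5.0, 5.0) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            coupling_ratio(10.0, 0.0)


class TestPairedMeasurements:
    def test_validation(self):
        with pytest.raises(ValueError):
            PairedMeasurements(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            PairedMeasurements(np.array([1.0, 2.0, np.nan]),
                               np.array([1.0, 2.0, 3.0]))
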