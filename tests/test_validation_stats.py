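"""Agreement statistics: error rates, Bland–Altman, ICC(2,1)."""

import numpy as np
import pytest

from walkdist.errors import ValidationError
from walkdist.validation_stats import (
    PairedDistances,
    agreement_report,
    average_absolute_error_rate,
    bland_altman,
    fixed_distance_error_pct,
    icc_2_1,
)


def icc21_bruteforce(x):
    """Independent ANOVA-from-sums oracle for ICC(2,1)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssr = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ssc = n * np.sum((x.mean(axis=0) - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestFixedDistanceError:
    def test_symmetric_cohort_rates(self):
        abs_rate, signed = fixed_distance_error_pct([390.0, 410.0], 400.0)
        assert abs_rate == pytest.approx(2.5)
        assert signed == pytest.approx(0.0)

    def test_perfect_estimates_zero(self):
        abs_rate, signed = fixed_distance_error_pct([400.0] * 5, 400.0)
        assert abs_rate == 0.0 and signed == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            fixed_distance_error_pct([], 400.0)


class TestAverageAbsoluteErrorRate:
    def test_identity_is_zero(self):
        pd_ = PairedDistances(np.array([500.0, 450.0]), np.array([500.0, 450.0]))
        assert average_absolute_error_rate(pd_) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        manual = rng.uniform(300, 700, 20)
        digital = manual + rng.normal(0, 15, 20)
        pd1 = PairedDistances(manual, digital)
        pd2 = PairedDistances(3.7 * manual, 3.7 * digital)
        assert average_absolute_error_rate(pd1) == pytest.approx(
            average_absolute_error_rate(pd2)
        )


class TestBlandAltman:
    def test_identity_collapses_to_zero(self):
        x = np.array([400.0, 450.0, 500.0])
        with pytest.warns(UserWarning, match="zero variance"):
            ba = bland_altman(PairedDistances(x, x))
        assert ba.bias == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_hand_computed_unit_sd(self):
        manual = np.array([400.0, 400.0, 400.0])
        digital = manual + np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(PairedDistances(manual, digital))
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_upper == pytest.approx(1.96)
        assert ba.loa_lower == pytest.approx(-1.96)

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(24)
        manual = rng.uniform(350, 650, 24)
        digital = manual + rng.normal(-8, 20, 24)
        ba = bland_altman(PairedDistances(manual, digital))
        d = digital - manual
        bias = d.mean()
        sd = d.std(ddof=1)
        assert ba.bias == pytest.approx(bias)
        assert ba.loa_upper == pytest.approx(bias + 1.96 * sd)
        assert ba.loa_lower == pytest.approx(bias - 1.96 * sd)
        from scipy import stats

        tcrit = stats.t.ppf(0.975, 23)
        assert ba.bias_ci[0] == pytest.approx(bias - tcrit * sd / np.sqrt(24))
        assert ba.loa_upper_ci[1] == pytest.approx(
            bias + 1.96 * sd + tcrit * np.sqrt(3) * sd / np.sqrt(24)
        )

    def test_loa_midpoint_identity(self):
        rng = np.random.default_rng(5)
        manual = rng.uniform(300, 700, 15)
        digital = manual * rng.uniform(0.9, 1.1, 15)
        ba = bland_altman(PairedDistances(manual, digital))
        assert 0.5 * (ba.loa_upper + ba.loa_lower) == pytest.approx(ba.bias, abs=1e-9)

    def test_single_subject_raises(self):
        with pytest.raises(ValidationError):
            bland_altman(PairedDistances(np.array([400.0]), np.array([410.0])))


class TestIcc:
    def test_perfect_agreement_is_one(self):
        x = np.column_stack([np.arange(1.0, 9.0), np.arange(1.0, 9.0)])
        res = icc_2_1(x)
        assert res.icc == pytest.approx(1.0)

    def test_matches_bruteforce_anova_on_hand_table(self):
        table = np.array(
            [[9, 2], [1, 10], [8, 4], [2, 6], [7, 8], [8, 6]], dtype=float
        )
        res = icc_2_1(table)
        assert res.icc == pytest.approx(icc21_bruteforce(table), abs=1e-9)

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(77)
        subj = rng.normal(500, 90, 30)
        x = np.column_stack([subj + rng.normal(0, 20, 30), subj + rng.normal(5, 20, 30)])
        res = icc_2_1(x)
        assert res.icc == pytest.approx(icc21_bruteforce(x), abs=1e-9)
        assert res.ci[0] <= res.icc <= res.ci[1]

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(200)
        x = rng.normal(0, 1, (200, 2))
        res = icc_2_1(x)
        assert abs(res.icc) < 0.15

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        subj = rng.normal(100, 10, 12)
        x = np.column_stack([subj + rng.normal(0, 3, 12), subj + rng.normal(0, 3, 12)])
        assert icc_2_1(x + 1234.5).icc == pytest.approx(icc_2_1(x).icc, abs=1e-9)

    def test_decreases_with_noise_on_one_rater(self):
        rng = np.random.default_rng(13)
        subj = rng.normal(500, 80, 60)
        base = np.column_stack([subj, subj])
        iccs = []
        for sd in (5.0, 30.0, 120.0):
            noisy = base.copy()
            noisy[:, 1] += rng.normal(0, sd, 60)
            iccs.append(icc_2_1(noisy).icc)
        assert iccs[0] > iccs[1] > iccs[2]

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            icc_2_1(np.full((6, 2), 3.0))


def test_agreement_report_wires_all_components():
    rng = np.random.default_rng(31)
    manual = rng.uniform(350, 650, 24)
    digital = manual + rng.normal(-5, 18, 24)
    pd_ = PairedDistances(manual, digital)
    rep = agreement_report(pd_)
    assert rep.error_rate_pct == pytest.approx(average_absolute_error_rate(pd_))
    assert rep.bland_altman.bias == pytest.approx(bland_altman(pd_).bias)
    assert rep.icc.icc == pytest.approx(icc_2_1(np.column_stack([manual, digital])).icc)
    assert rep.bland_altman.loa_lower <= rep.bland_altman.bias <= rep.bland_altman.loa_upper
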