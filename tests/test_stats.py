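"""t-tests, Pearson correlation, post-hoc power, report assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retphys import (
    build_report,
    pearson_correlation,
    power_correlation,
    power_two_sample_t,
    two_sample_ttest,
)


class TestTwoSampleTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, rel=1e-12)

    def test_textbook_example(self):
        # means 2 and 5, pooled variance 1: t = -3/sqrt(2/3), df = 4
        res = two_sample_ttest([1, 2, 3], [4, 5, 6])
        assert abs(res.t) == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        assert abs(res.t) == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4

    def test_zero_variance_cases(self):
        res = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0
        with pytest.raises(ValueError):
            two_sample_ttest([2.0, 2.0], [3.0, 3.0])

    def test_p_value_matches_permutation_reference(self):
        # moderate effect: t and permutation nulls agree well away from the
        # extreme tail, where the discrete permutation distribution departs
        rng = np.random.default_rng(8)
        a = np.array([4.1, 5.2, 3.9, 4.8, 5.5, 4.3])
        b = np.array([5.4, 6.3, 4.2, 6.8, 4.7, 5.2])
        res = two_sample_ttest(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm = two_sample_ttest(perm[: a.size], perm[a.size:]).t
            if abs(t_perm) >= abs(res.t):
                count += 1
        p_perm = count / n_perm
        se = math.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        # the Student reference and the exact permutation distribution differ
        # by O(1/n) at n=6/6; allow that approximation gap beyond MC error
        assert abs(res.p - p_perm) < 2 * se + 0.015


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0, rel=1e-12)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_matches_permutation_reference(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(scale=0.8, size=10)
        r, p = pearson_correlation(x, y)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            r_perm, _ = pearson_correlation(x, rng.permutation(y))
            if abs(r_perm) >= abs(r):
                count += 1
        p_perm = count / n_perm
        se = math.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 2 * se + 2 / n_perm


class TestPowerTwoSampleT:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample_t(5, 1, 13, 5, 1, 13, alpha=0.05) == pytest.approx(
            0.05, rel=1e-6
        )

    def test_reference_velocity_contrast(self):
        # venous velocity groups 10.5±3.1 vs 6.6±1.4 at n=13/13
        power = power_two_sample_t(10.5, 3.1, 13, 6.6, 1.4, 13)
        assert round(100 * power) == 98

    def test_monotone_in_effect_and_n(self):
        p_small = power_two_sample_t(5.0, 1.0, 10, 5.5, 1.0, 10)
        p_large = power_two_sample_t(5.0, 1.0, 10, 6.0, 1.0, 10)
        p_more_n = power_two_sample_t(5.0, 1.0, 30, 5.5, 1.0, 30)
        assert p_large > p_small
        assert p_more_n > p_small

    def test_matches_monte_carlo_rejection_rate(self):
        rng = np.random.default_rng(21)
        reps, n1, n2 = 20_000, 12, 12
        m2, sd = 0.8, 1.0
        a = rng.normal(0.0, sd, size=(reps, n1))
        b = rng.normal(m2, sd, size=(reps, n2))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * math.sqrt(1 / n1 + 1 / n2))
        from scipy import stats as ss

        t_crit = ss.t.ppf(0.975, n1 + n2 - 2)
        rate = np.mean(np.abs(t) > t_crit)
        se = math.sqrt(rate * (1 - rate) / reps)
        assert abs(power_two_sample_t(0.0, sd, n1, m2, sd, n2) - rate) < 3 * se


class TestPowerCorrelation:
    def test_null_effect_gives_alpha(self):
        assert power_correlation(0.0, 26) == pytest.approx(0.05, abs=1e-4)
        assert power_correlation(0.0, 26, method="fisher-z") == pytest.approx(0.05)

    def test_reference_correlation_powers(self):
        # |r| = 0.57 at n = 26 and |r| = 0.53 at n = 19
        assert round(100 * power_correlation(0.57, 26)) == 89
        assert round(100 * power_correlation(0.53, 19)) == 68
        # sign of the association does not change detectability
        assert power_correlation(-0.57, 26) == power_correlation(0.57, 26)

    def test_fisher_z_close_to_exact(self):
        for rho, n in ((0.57, 26), (0.53, 19), (0.3, 40)):
            exact = power_correlation(rho, n, method="exact")
            fz = power_correlation(rho, n, method="fisher-z")
            assert fz == pytest.approx(exact, abs=0.01)

    def test_monotone_in_effect_and_n(self):
        assert power_correlation(0.6, 20) > power_correlation(0.4, 20)
        assert power_correlation(0.4, 60) > power_correlation(0.4, 20)

    def test_matches_monte_carlo_rejection_rate(self):
        rng = np.random.default_rng(22)
        reps, n, rho = 20_000, 20, 0.5
        z = rng.standard_normal((reps, n, 2))
        x = z[:, :, 0]
        y = rho * x + math.sqrt(1 - rho**2) * z[:, :, 1]
        xm = x - x.mean(axis=1, keepdims=True)
        ym = y - y.mean(axis=1, keepdims=True)
        r = (xm * ym).sum(axis=1) / np.sqrt(
            (xm**2).sum(axis=1) * (ym**2).sum(axis=1)
        )
        from scipy import stats as ss

        t_crit = ss.t.ppf(0.975, n - 2)
        r_crit = t_crit / math.sqrt(n - 2 + t_crit**2)
        rate = np.mean(np.abs(r) > r_crit)
        se = math.sqrt(rate * (1 - rate) / reps)
        assert abs(power_correlation(rho, n) - rate) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_correlation(1.0, 26)
        with pytest.raises(ValueError):
            power_correlation(0.5, 3)


class TestBuildReport:
    @staticmethod
    def toy_cohort(n_per_group=6, seed=0, groups=("WT", "5XFAD")):
        rng = np.random.default_rng(seed)
        rows = []
        for g in groups:
            shift = 0.0 if g == "WT" else 1.0
            for i in range(n_per_group):
                rows.append(
                    {
                        "animal_id": f"{g}_{i}",
                        "group": g,
                        "o2a_ml_dl": 6.5 + shift + rng.normal(0, 1),
                        "v_v_mm_s": 10.5 - 3 * shift + rng.normal(0, 2),
                        "nfl_rgcl": 16.0 - shift + rng.normal(0, 2),
                        "d_v_um": 30 + 3 * shift + rng.normal(0, 3),
                        "o2v_ml_dl": 2.8 + shift + rng.normal(0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_single_group_degenerate(self):
        df = self.toy_cohort(groups=("WT",))
        report = build_report(df)
        assert report.tests == []
        assert all(s.group == "WT" for s in report.summaries)

    def test_schema_and_power_entries(self):
        report = build_report(self.toy_cohort(n_per_group=13))
        tested = {t.metric for t in report.tests}
        assert {"o2a_ml_dl", "o2v_ml_dl", "d_v_um", "v_v_mm_s", "nfl_rgcl"} <= tested
        power_labels = {p.label for p in report.powers}
        assert {"o2a_ml_dl", "o2v_ml_dl", "d_v_um", "v_v_mm_s"} <= power_labels
        labels = {c["label"] for c in report.correlations}
        assert labels == {"O2A vs V_V", "O2A vs NFL/RGCL"}
        assert report.n_tests == len(report.tests) + len(report.correlations)

    def test_deterministic_given_table(self):
        df = self.toy_cohort(seed=4)
        assert build_report(df).to_json() == build_report(df).to_json()
        assert "power" in build_report(df).to_text()


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=20, deadline=None)
def test_power_bounds_property(seed):
    rng = np.random.default_rng(seed)
    rho = float(rng.uniform(-0.95, 0.95))
    n = int(rng.integers(5, 80))
    p = power_correlation(rho, n)
    assert 0.0 < p <= 1.0
    m2 = float(rng.uniform(0, 3))
    pt = power_two_sample_t(0.0, 1.0, 10, m2, 1.0, 10)
    assert 0.0 < pt <= 1.0
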