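"""Correlation/regression/t-test primitives and the full battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metstop.errors import DegenerateInputError, ValidationError
from metstop.registry import DomainRecord
from metstop.stats import (
    ols_simple,
    paired_t,
    pearson,
    run_battery,
    summarize_classes,
)
from metstop.synth import SynthConfig, gen_feature_table


def oracle_pearson(x, y):
    """Textbook covariance formula, written independently of scipy."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return sxy / (sx * sy)


def oracle_ols(y, x):
    """Normal equations solved by hand: slope = Sxy/Sxx."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx


class TestPearson:
    def test_identity_gives_r_one(self):
        assert pearson([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)

    def test_hand_evaluated_three_points(self):
        res = pearson([1, 2, 3], [2, 4, 7])
        assert res.r == pytest.approx(oracle_pearson([1, 2, 3], [2, 4, 7]), abs=1e-12)
        assert res.n == 3

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_oracle_equivalence_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert pearson(x, y).r == pytest.approx(oracle_pearson(x, y), abs=1e-10)

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = pearson(x, y)
        from scipy import stats as sps

        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = pearson(x, y).r
        assert pearson(3.2 * x - 7, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.1 * y + 2).r == pytest.approx(base, abs=1e-12)

    def test_pairwise_deletion_of_missing_entries(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        assert pearson(x, y).n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError):
            pearson([1, 2], [1, 2])


class TestOLS:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        res = ols_simple(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_four_point_toy_against_normal_equations(self):
        x, y = [0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 3.0, 3.0]
        res = ols_simple(y, x)
        slope, intercept = oracle_ols(y, x)
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.df_residual == 2

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_oracle_equivalence_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = ols_simple(y, x)
        slope, intercept = oracle_ols(y, x)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        # R^2 equals the squared correlation, F ties to R^2 and df
        assert res.r_squared == pytest.approx(oracle_pearson(x, y) ** 2, abs=1e-10)
        assert res.F == pytest.approx(res.r_squared / ((1 - res.r_squared) / (n - 2)), abs=1e-10)

    def test_slope_scales_with_x_rescaling(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert ols_simple(y, 2 * x).slope == pytest.approx(ols_simple(y, x).slope / 2, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            ols_simple([1, 2, 3], [5, 5, 5])


class TestPairedT:
    def test_two_point_hand_evaluation(self):
        # d = (1, 3): mean 2, sd sqrt(2), t = 2 / (sqrt(2)/sqrt(2)) = 2
        res = paired_t([2, 5], [1, 2])
        assert res.t == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1

    def test_formula_oracle(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = paired_t(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == 29

    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1, 2, 3], [1, 2, 3])


class TestSummarizeClasses:
    def test_packaged_table_counts(self, domain_records):
        counts = summarize_classes(domain_records)
        assert counts.selectivity == {
            "absolute": 20, "high": 11, "medium": 13, "low": 2, "none": 3,
        }
        assert counts.mai == {"S": 31, "W": 15, "N": 3}

    def test_empty_input_gives_all_zero(self):
        counts = summarize_classes([])
        assert all(v == 0 for v in counts.selectivity.values())
        assert all(v == 0 for v in counts.mai.values())


class TestBattery:
    def test_df_pattern_follows_pairwise_deletion(self, domain_records):
        report = run_battery(domain_records)
        assert report.regressions["pss~mss"].n == 50
        assert report.regressions["pss~mss"].df_residual == 48
        # undetermined-LSI row drops only from LSI-dependent analyses
        assert report.regressions["pss~lsi"].n == 49
        assert report.regressions["pss~lsi"].df_residual == 47
        assert report.regressions["expression~pss"].n == 50
        assert any("pss~lsi" in note for note in report.notes)

    def test_r_squared_equals_squared_correlation(self, domain_records):
        report = run_battery(domain_records)
        for name, reg in report.regressions.items():
            assert reg.r_squared == pytest.approx(report.correlations[name].r ** 2, abs=1e-10)

    def test_degenerate_table_fails_informatively(self):
        records = [
            DomainRecord(f"D{i}", frozenset({"3"}), 10, 2, 2, "S", 1.0)
            for i in range(5)
        ]
        with pytest.raises(DegenerateInputError, match="pss~mss"):
            run_battery(records)

    def test_report_serializes(self, domain_records):
        import json

        report = run_battery(domain_records)
        payload = json.loads(json.dumps(report.to_dict()))
        assert payload["regressions"]["pss~mss"]["df"] == [1, 48]
        assert "counts" in payload


class TestParameterRecovery:
    def test_estimated_r_within_standard_error_band(self):
        """Latent correlation is recovered (up to discretization attenuation)
        across many synthetic feature tables."""
        target = 0.4
        config = SynthConfig(
            n_domains=60,
            feature_correlations={("mss", "pss"): target},
        )
        rs = []
        for seed in range(200):
            records, _ = gen_feature_table(config, seed=seed)
            rs.append(pearson([r.mss for r in records], [r.pss for r in records]).r)
        mean_r = np.mean(rs)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        # discretization attenuates toward zero, so allow a one-sided bias of
        # up to 0.1 while requiring the estimate to track the target
        assert target - 0.1 - 3 * se < mean_r < target + 3 * se
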