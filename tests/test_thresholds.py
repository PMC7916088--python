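import math

import numpy as np
import pytest

from nutriprofile.core import Nutrient, ThresholdSet
from nutriprofile.thresholds import (
    TooFewProductsError,
    clamp_and_rerun,
    common_percentile_thresholds,
    derive_thresholds,
    threshold_report,
)

from conftest import make_products, oracle_common_percentile

SF, NA, PR = Nutrient.SATURATED_FAT, Nutrient.TOTAL_SODIUM, Nutrient.PROTEIN


def random_category(rng, n, nutrients, tie_grid=None):
    cols = {}
    for nut in nutrients:
        v = rng.lognormal(mean=1.0, sigma=0.6, size=n) + 2.0
        if tie_grid:
            v = np.round(v * tie_grid) / tie_grid
        cols[nut.value] = v
    return make_products(**cols)


class TestSearch:
    def test_one_dimensional_median_at_fifty_percent(self):
        values = list(range(1, 21))  # 20 distinct values
        df = make_products(saturated_fat=values)
        ts = common_percentile_thresholds(df, [SF], 50.0)
        assert ts.p == 50.0
        assert ts.thresholds[SF] == 10  # nearest-rank median
        assert ts.coverage == 0.5

    def test_one_dimensional_threshold_is_the_empirical_quantile(self):
        rng = np.random.default_rng(5)
        v = np.sort(rng.lognormal(size=100))
        df = make_products(saturated_fat=v)
        for x in (10, 25, 50, 65, 90, 100):
            ts = common_percentile_thresholds(df, [SF], float(x))
            assert ts.thresholds[SF] == v[math.ceil(x) - 1]
            assert ts.p == float(x)

    def test_two_independent_uniforms_need_sqrt_level(self):
        # P(U1 <= q, U2 <= q) = q^2 = 0.5 => p = 100*sqrt(0.5) ~ 70.7
        rng = np.random.default_rng(42)
        n = 20_000
        df = make_products(
            saturated_fat=rng.random(n), total_sodium=rng.random(n)
        )
        ts = common_percentile_thresholds(df, [SF, NA], 50.0)
        assert ts.p == pytest.approx(100 * math.sqrt(0.5), abs=1.0)
        assert 0.5 <= ts.coverage < 0.51

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize(
        "nutrients", [[SF], [SF, NA], [SF, NA, PR], [SF, PR]]
    )
    def test_bisection_equals_exhaustive_scan(self, seed, nutrients):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        # grid-round half of the fixtures to force ties
        df = random_category(rng, n, nutrients, tie_grid=4 if seed % 2 else None)
        x = float(rng.integers(5, 100))
        ts = common_percentile_thresholds(df, nutrients, x)
        p_oracle, thr_oracle, cov_oracle = oracle_common_percentile(df, nutrients, x)
        assert ts.p == p_oracle
        assert ts.coverage == cov_oracle
        for nut in nutrients:
            assert ts.thresholds[nut] == thr_oracle[nut]

    @pytest.mark.parametrize("seed", range(5))
    def test_minimality_and_coverage_count(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 150
        df = random_category(rng, n, [SF, NA])
        x = 40.0
        ts = common_percentile_thresholds(df, [SF, NA], x)
        assert ts.coverage >= x / 100
        # one grid step below the found level, coverage drops under target
        i_star = round(ts.p * n / 100)
        if i_star > 1:
            srt = {nut: np.sort(df[nut.value].to_numpy()) for nut in (SF, NA)}
            thr = {nut: srt[nut][i_star - 2] for nut in (SF, NA)}
            ok = np.ones(n, dtype=bool)
            for nut, t in thr.items():
                ok &= df[nut.value].to_numpy() <= t
            assert ok.mean() < x / 100
        assert (ts.coverage * n) >= math.ceil(x / 100 * n) - 1e-9

    def test_monotone_strictness_in_target_fraction(self):
        rng = np.random.default_rng(3)
        df = random_category(rng, 120, [SF, NA, PR])
        prev = None
        for x in range(5, 101, 5):
            ts = common_percentile_thresholds(df, [SF, NA, PR], float(x))
            if prev is not None:
                assert prev.thresholds[SF] <= ts.thresholds[SF]
                assert prev.thresholds[NA] <= ts.thresholds[NA]
                assert prev.thresholds[PR] >= ts.thresholds[PR]
            prev = ts

    def test_refuses_small_categories(self):
        df = make_products(saturated_fat=list(range(19)))
        with pytest.raises(TooFewProductsError):
            common_percentile_thresholds(df, [SF], 50.0)

    def test_linear_interpolation_configurable(self):
        df = make_products(saturated_fat=[float(i) for i in range(1, 22)])
        ts = common_percentile_thresholds(
            df, [SF], 50.0, quantile_method="linear"
        )
        assert ts.coverage >= 0.5


class TestClamping:
    def test_identity_when_no_threshold_beyond_limit(self):
        rng = np.random.default_rng(8)
        df = random_category(rng, 50, [SF])  # values ~ 3-10, limit 1.5
        ts = common_percentile_thresholds(df, [SF], 50.0)
        out = clamp_and_rerun(df, ts)
        assert out.thresholds == ts.thresholds and out.clamped == frozenset()

    def test_disqualifying_threshold_below_low_in_clamps_up(self):
        # sodium mostly below the 0.120 limit: derived cut < limit
        rng = np.random.default_rng(9)
        sodium = rng.uniform(0.01, 0.11, size=40)
        satfat = rng.uniform(2.0, 30.0, size=40)
        df = make_products(saturated_fat=satfat, total_sodium=sodium)
        ts = common_percentile_thresholds(df, [SF, NA], 50.0)
        assert ts.thresholds[NA] < 0.120
        out = clamp_and_rerun(df, ts)
        assert out.thresholds[NA] == 0.120
        assert NA in out.clamped
        assert out.coverage >= 0.5
        # rerun equals the oracle with the sodium coordinate fixed
        p_oracle, thr_oracle, cov_oracle = oracle_common_percentile(
            df, [SF, NA], 50.0, fixed={NA: 0.120}
        )
        assert out.p == p_oracle
        assert out.thresholds[SF] == thr_oracle[SF]
        assert out.coverage == cov_oracle

    def test_qualifying_threshold_below_source_of_raised_by_default(self):
        rng = np.random.default_rng(10)
        protein = np.linspace(2.0, 15.0, 60)  # lower tail below the 5.0 limit
        satfat = rng.uniform(2.0, 30.0, size=60)
        df = make_products(saturated_fat=satfat, protein=protein)
        ts = common_percentile_thresholds(df, [SF, PR], 95.0)
        assert ts.thresholds[PR] < 5.0  # weak cut at a permissive target
        out = clamp_and_rerun(df, ts)
        assert out.thresholds[PR] == 5.0 and PR in out.clamped

    def test_qualifying_lenient_reading_lowers_to_limit(self):
        rng = np.random.default_rng(11)
        protein = rng.uniform(6.0, 20.0, size=60)  # all above the limit
        satfat = rng.uniform(2.0, 30.0, size=60)
        df = make_products(saturated_fat=satfat, protein=protein)
        ts = common_percentile_thresholds(df, [SF, PR], 20.0)
        assert ts.thresholds[PR] > 5.0
        out = clamp_and_rerun(df, ts, qualifying_clamp="lower")
        assert out.thresholds[PR] == 5.0 and PR in out.clamped

    def test_all_clamped_reports_achieved_coverage_with_flag(self):
        rng = np.random.default_rng(12)
        df = make_products(
            saturated_fat=rng.uniform(0.1, 1.0, size=30),  # all low-in
            total_sodium=rng.uniform(0.01, 0.10, size=30),
        )
        out = derive_thresholds(df, [SF, NA], 50.0)
        assert out.all_clamped
        assert out.thresholds == {SF: 1.50, NA: 0.120}
        assert out.coverage == 1.0  # every product is below both limits


class TestThresholdReport:
    def _pair(self, frm, to):
        mk = lambda d: ThresholdSet(
            x=50.0, thresholds={Nutrient(k): v for k, v in d.items()}, p=50.0,
            coverage=0.5,
        )
        return mk(frm), mk(to)

    def test_bread_sodium_relative_change(self):
        a, b = self._pair({"total_sodium": 0.560}, {"total_sodium": 0.412})
        rep = threshold_report(a, b)
        assert rep[NA]["relative_change_pct"] == -26
        assert rep[NA]["rendered"] == "-26%"

    def test_pizza_saturated_fat_relative_change(self):
        a, b = self._pair({"saturated_fat": 5.0}, {"saturated_fat": 4.0})
        assert threshold_report(a, b)[SF]["relative_change_pct"] == -20

    def test_identical_thresholds_render_zero(self):
        a, b = self._pair({"protein": 7.0}, {"protein": 7.0})
        rep = threshold_report(a, b)
        assert rep[PR]["relative_change_pct"] == 0
        assert rep[PR]["rendered"] == "0%"

    def test_rounding_half_away_from_zero(self):
        from nutriprofile.thresholds import _round_half_away

        assert _round_half_away(2.5) == 3
        assert _round_half_away(-2.5) == -3
        assert _round_half_away(2.4) == 2
        assert _round_half_away(-0.4) == 0

    def test_bread_and_cheese_protein_changes(self):
        a, b = self._pair({"protein": 7.6}, {"protein": 9.3})
        assert threshold_report(a, b)[PR]["rendered"] == "+22%"
        a, b = self._pair({"protein": 23.0}, {"protein": 25.3})
        assert threshold_report(a, b)[PR]["rendered"] == "+10%"

    def test_zero_baseline_is_not_applicable(self):
        a, b = self._pair({"total_sodium": 0.0}, {"total_sodium": 0.1})
        rep = threshold_report(a, b)
        assert rep[NA]["relative_change_pct"] is None
        assert rep[NA]["rendered"] == "n/a"

    def test_mismatched_nutrients_rejected(self):
        a, _ = self._pair({"protein": 7.0}, {"protein": 7.0})
        _, b = self._pair({"total_sodium": 0.5}, {"total_sodium": 0.5})
        with pytest.raises(ValueError):
            threshold_report(a, b)
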