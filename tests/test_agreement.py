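import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transectopt.agreement import (
    AcceptanceCriteria,
    InsufficientSubjectsError,
    NestedLoA,
    check_difference_normality,
    compute_differences,
    evaluate_criteria,
    fit_nested_loa,
)
from transectopt.indicators import IndicatorSet
from transectopt.simulate import simulate_differences

from _oracles import anova_oracle


def _fit(d, groups, level=0.95):
    return NestedLoA(d, groups).fit(level=level)


class TestNestedFit:
    def test_hand_anova_example(self):
        """Plots A:(1,3), B:(-1,1), C:(0,2): bias 1, sigma_e2 2, sigma_b2 0."""
        groups = {"A": [1, 3], "B": [-1, 1], "C": [0, 2]}
        oracle = anova_oracle(groups)
        res = _fit([1, 3, -1, 1, 0, 2], ["A", "A", "B", "B", "C", "C"])
        assert res.bias == pytest.approx(oracle["bias"], abs=1e-12)
        assert res.sigma_e2 == pytest.approx(oracle["sigma_e2"], abs=1e-12)
        assert res.sigma_b2 == pytest.approx(oracle["sigma_b2"], abs=1e-12)
        z = stats.norm.ppf(0.975)
        assert res.agree_halfwidth == pytest.approx(z * np.sqrt(2.0), abs=1e-9)

    def test_all_zero_differences_degenerate(self):
        res = _fit([0.0] * 6, ["A", "A", "B", "B", "C", "C"])
        assert res.bias == 0.0
        assert res.agree_halfwidth == 0.0
        assert (res.limit_lo, res.limit_hi) == (0.0, 0.0)
        assert res.mover_lo == pytest.approx(res.bias_ci[0])
        assert res.mover_hi == pytest.approx(res.bias_ci[1])

    def test_bound_ordering_invariant(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 2.0, 60)
        groups = np.repeat(np.arange(10), 6)
        for level in (0.80, 0.95):
            r = _fit(d, groups, level)
            assert r.mover_lo <= r.limit_lo <= r.bias <= r.limit_hi <= r.mover_hi
            assert r.sigma_b2 >= 0 and r.sigma_e2 >= 0 and r.agree_halfwidth >= 0

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(8)
        d = rng.normal(1.0, 1.5, 40)
        groups = np.repeat(np.arange(8), 5)
        base = _fit(d, groups)
        shifted = _fit(d + 3.7, groups)
        assert shifted.bias == pytest.approx(base.bias + 3.7)
        assert shifted.limit_lo == pytest.approx(base.limit_lo + 3.7)
        assert shifted.mover_hi == pytest.approx(base.mover_hi + 3.7)
        assert shifted.agree_halfwidth == pytest.approx(base.agree_halfwidth)
        scaled = _fit(2.5 * d, groups)
        assert scaled.bias == pytest.approx(2.5 * base.bias)
        assert scaled.agree_halfwidth == pytest.approx(2.5 * base.agree_halfwidth)
        assert scaled.mover_hi - scaled.bias == pytest.approx(
            2.5 * (base.mover_hi - base.bias)
        )

    def test_reduces_to_classical_bland_altman_with_single_replicates(self):
        """One difference per plot: limits = mean +/- z * sd(d)."""
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 2.0, 15)
        groups = [f"P{i}" for i in range(15)]
        res = _fit(d, groups)
        z = stats.norm.ppf(0.975)
        assert res.bias == pytest.approx(d.mean())
        assert res.agree_halfwidth == pytest.approx(z * d.std(ddof=1))
        assert res.sigma_e2 == 0.0
        assert res.mover_hi > res.limit_hi

    def test_single_plot_rejected(self):
        with pytest.raises(InsufficientSubjectsError):
            NestedLoA([1.0, 2.0], ["A", "A"])

    def test_fit_from_dataframe_wrapper(self):
        df = pd.DataFrame({"plot_id": ["A", "A", "B", "B"], "d": [1.0, 2.0, 0.0, 1.0]})
        res = fit_nested_loa(df, level=0.80)
        assert res.level == 0.80
        assert res.k == 2 and res.N == 4

    def test_summary_mentions_key_quantities(self):
        res = _fit([1, 3, -1, 1, 0, 2], list("AABBCC"))
        text = res.summary()
        assert "bias" in text and "MOVER" in text and "sigma_b2" in text


class TestNestedVersusPooled:
    def test_bias_ci_coverage_nested_ok_pooled_anticonservative(self):
        """With large between-plot variance, ignoring the nesting understates
        the bias uncertainty; the nested CI keeps near-nominal coverage."""
        rng = np.random.default_rng(99)
        level, k, n_per, reps = 0.95, 13, 8, 500
        nested_hits = pooled_hits = 0
        for _ in range(reps):
            b = rng.normal(0, 2.0, k)
            d = np.repeat(b, n_per) + rng.normal(0, 0.5, k * n_per)
            groups = np.repeat(np.arange(k), n_per)
            res = _fit(d, groups, level)
            nested_hits += res.bias_ci[0] <= 0.0 <= res.bias_ci[1]
            # deliberately wrong pooled analysis: all d treated independent
            m, s = d.mean(), d.std(ddof=1) / np.sqrt(d.size)
            t = stats.t.ppf(0.975, d.size - 1)
            pooled_hits += (m - t * s) <= 0.0 <= (m + t * s)
        assert abs(nested_hits / reps - level) <= 0.03
        assert pooled_hits / reps < level - 0.03


class TestComputeDifferences:
    def _iset(self, cover=50.0, species=10, height=20.0):
        gaps = {n: 1.0 for n in
                ["GapPct_5_24", "GapPct_25_50", "GapPct_51_100",
                 "GapPct_101_200", "GapPct_200_plus"]}
        return IndicatorSet(cover, species, gaps, height)

    def test_identical_sets_give_zero(self):
        full = {("P1", "E1"): self._iset()}
        diffs = compute_differences(full, full)
        assert (diffs["d"] == 0).all()

    def test_sign_convention_full_minus_sub(self):
        full = {("P1", "E1"): self._iset(cover=50.0)}
        sub = {("P1", "E1"): self._iset(cover=45.0)}
        diffs = compute_differences(full, sub)
        d = diffs.loc[diffs["indicator"] == "AH_TotalFoliarCover", "d"].iloc[0]
        assert d == pytest.approx(5.0)

    def test_species_difference_positive(self):
        full = {("P1", "E1"): self._iset(species=12)}
        sub = {("P1", "E1"): self._iset(species=9)}
        diffs = compute_differences(full, sub)
        assert diffs.loc[diffs["indicator"] == "NumSpecies", "d"].iloc[0] == 3

    def test_undefined_cells_excluded_pairwise(self):
        full = {("P1", "E1"): self._iset(height=20.0)}
        sub = {("P1", "E1"): IndicatorSet(45.0, 9, None, None)}
        diffs = compute_differences(full, sub)
        assert "Hgt_Mean_cm" not in set(diffs["indicator"])
        assert "GapPct_5_24" not in set(diffs["indicator"])

    def test_no_overlapping_keys_raises(self):
        with pytest.raises(ValueError, match="no overlapping"):
            compute_differences({("P1", "E1"): self._iset()},
                                {("P2", "E1"): self._iset()})


class TestCriteria:
    def _result(self, bias_ci, mover_lo, mover_hi, bias=0.1):
        res = _fit([1, 3, -1, 1, 0, 2], list("AABBCC"))
        res.bias, res.bias_ci = bias, bias_ci
        res.mover_lo, res.mover_hi = mover_lo, mover_hi
        return res

    def test_unbiased_and_within_passes(self):
        res = self._result((-0.5, 0.7), -2.9, 3.0)
        flags = evaluate_criteria(res, "AH_TotalFoliarCover", AcceptanceCriteria())
        assert flags == {"flag_unbiased": True, "flag_interval": True, "passed": True}

    def test_biased_fails_first_criterion(self):
        res = self._result((0.2, 1.4), -2.9, 3.0)
        flags = evaluate_criteria(res, "AH_TotalFoliarCover", AcceptanceCriteria())
        assert not flags["flag_unbiased"] and not flags["passed"]

    def test_species_threshold_is_two(self):
        res = self._result((-0.5, 0.7), -2.4, 2.6, bias=0.1)
        flags = evaluate_criteria(res, "NumSpecies", AcceptanceCriteria())
        assert not flags["flag_interval"]  # bound reach 2.5 > 2 species

    def test_unknown_indicator_is_configuration_error(self):
        res = self._result((-0.5, 0.5), -1, 1)
        with pytest.raises(KeyError):
            evaluate_criteria(res, "NotAnIndicator", AcceptanceCriteria())


class TestNormalityDiagnostics:
    def test_normal_draws_rarely_rejected(self):
        """Seeded standard-normal samples: p > 0.01 in >= 98% of 500 runs."""
        rng = np.random.default_rng(1)
        ok = 0
        for _ in range(500):
            diffs = pd.DataFrame({"indicator": "x", "d": rng.normal(size=100)})
            rep = check_difference_normality(diffs)
            ok += rep["p_value"].iloc[0] > 0.01
        assert ok / 500 >= 0.98

    def test_heavy_tails_strongly_rejected(self):
        rng = np.random.default_rng(2)
        reject = 0
        for _ in range(200):
            diffs = pd.DataFrame({"indicator": "x", "d": rng.standard_t(1, size=200)})
            rep = check_difference_normality(diffs)
            reject += rep["p_value"].iloc[0] < 0.05
        assert reject / 200 > 0.5  # far above the 5% nominal rate

    def test_constant_differences_reported_degenerate(self):
        diffs = pd.DataFrame({"indicator": "x", "d": [1.0] * 10})
        rep = check_difference_normality(diffs)
        assert np.isnan(rep["shapiro_w"].iloc[0])
        assert "degenerate" in rep["note"].iloc[0]


def test_simulated_differences_feed_the_fit():
    rng = np.random.default_rng(7)
    diffs = simulate_differences(0.5, 1.0, 1.0, 13, rng.integers(5, 21, 13), rng)
    res = fit_nested_loa(diffs)
    assert res.k == 13
    assert res.N == len(diffs)
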