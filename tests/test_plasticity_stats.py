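"""Immediate/entrained summaries, setpoint regression, nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from okrent.plasticity_stats import (
    AnimalSummary,
    immediate_entrained,
    kruskal_dunn,
    mann_whitney_u,
    population_cycle_average,
    regress_change,
    variability_metrics,
    wilcoxon_signed_rank,
)
from okrent.synthetic_data import PlasticityParams, amplitude_series


def table_from_amplitudes(amps, valid=None):
    n = len(amps)
    valid = [True] * n if valid is None else valid
    return pd.DataFrame(
        {
            "cycle_index": np.arange(1, n + 1),
            "t_start_s": np.arange(n) * 10.0,
            "t_end_s": (np.arange(n) + 1) * 10.0,
            "pp_deg": amps,
            "valid": valid,
            "reason": ["" if v else "fast_phase" for v in valid],
        }
    )


class TestImmediateEntrained:
    def test_constant_amplitudes(self):
        s = immediate_entrained(table_from_amplitudes([4.0] * 20))
        assert s.immediate == s.entrained == 4.0
        assert s.delta == 0.0

    def test_window_means(self):
        s = immediate_entrained(table_from_amplitudes(np.arange(1.0, 11.0)))
        assert s.immediate == pytest.approx(3.0)
        assert s.entrained == pytest.approx(8.0)

    def test_invalid_cycle_skipped_window_extended(self):
        amps = np.arange(1.0, 13.0)
        valid = [False] + [True] * 11
        s = immediate_entrained(table_from_amplitudes(amps, valid))
        assert s.immediate == pytest.approx(np.mean(amps[1:6]))

    def test_too_few_valid_cycles_rejected(self):
        with pytest.raises(ValueError, match="too few valid"):
            immediate_entrained(table_from_amplitudes([1.0] * 8))

    def test_delta_identity(self):
        s = AnimalSummary("a", immediate=3.25, entrained=5.5)
        assert s.delta == 5.5 - 3.25


def line_summaries(slope, x0, n=8, lo=1.0, hi=12.0):
    initials = np.linspace(lo, hi, n)
    return [
        AnimalSummary(f"a{i}", immediate=i0, entrained=i0 + slope * (i0 - x0))
        for i, i0 in enumerate(initials)
    ]


class TestRegression:
    def test_exact_line(self):
        fit = regress_change(line_summaries(-0.5, 6.0))
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.x_zero_intercept == pytest.approx(6.0, abs=1e-9)

    def test_flat_changes_undefined_setpoint(self):
        fit = regress_change(line_summaries(0.0, 0.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.x_zero_intercept is None

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            regress_change(line_summaries(-0.5, 6.0, n=2))
        same = [AnimalSummary(f"a{i}", 5.0, 4.0) for i in range(5)]
        with pytest.raises(ValueError):
            regress_change(same)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_unit_scale_equivariance(self, scale):
        """Rescaling amplitudes leaves slope and R^2; scales the setpoint."""
        rng = np.random.default_rng(3)
        initials = rng.uniform(1.0, 12.0, 15)
        noise = rng.normal(0, 0.5, 15)
        base = [
            AnimalSummary(f"a{i}", i0, max(i0 - 0.5 * (i0 - 6.0) + e, 0.0))
            for i, (i0, e) in enumerate(zip(initials, noise))
        ]
        scaled = [
            AnimalSummary(s.animal_id, s.immediate * scale, s.entrained * scale)
            for s in base
        ]
        f0, f1 = regress_change(base), regress_change(scaled)
        assert f1.slope == pytest.approx(f0.slope, rel=1e-9)
        assert f1.r_squared == pytest.approx(f0.r_squared, rel=1e-9)
        assert f1.x_zero_intercept == pytest.approx(
            f0.x_zero_intercept * scale, rel=1e-9
        )

    def test_confidence_band_contains_fit(self):
        fit = regress_change(line_summaries(-0.5, 6.0) + [AnimalSummary("x", 5.0, 5.4)])
        x = np.linspace(1, 12, 5)
        lo, hi = fit.confidence_band(x)
        mid = fit.intercept + fit.slope * x
        assert np.all(lo <= mid) and np.all(mid <= hi)


class TestVariability:
    def test_identical_animals_zero_sd(self):
        summaries = [AnimalSummary(f"a{i}", 5.0, 4.0, group="g", profile_id=1) for i in range(4)]
        frame = variability_metrics(summaries)
        assert (frame["sd_immediate_deg"] == 0).all()
        assert (frame["sd_entrained_deg"] == 0).all()

    def test_homeostatic_contraction_matches_propagation(self):
        """SD(E) ~ |1+m| SD(I) for the noiseless rule: variance contraction."""
        rng = np.random.default_rng(5)
        m, x0 = -0.59, 6.4
        initials = rng.normal(7.4, 5.4, 300).clip(0.5)
        summaries = [
            AnimalSummary(f"a{i}", i0, i0 + m * (i0 - x0)) for i, i0 in enumerate(initials)
        ]
        frame = variability_metrics(summaries)
        row = frame[frame["profile_id"] == "pooled"].iloc[0]
        assert row["sd_entrained_deg"] < row["sd_immediate_deg"]
        assert row["sd_entrained_deg"] == pytest.approx(
            abs(1 + m) * row["sd_immediate_deg"], rel=1e-9
        )

    def test_slope_zero_no_contraction(self):
        rng = np.random.default_rng(6)
        initials = rng.normal(7.0, 2.0, 100).clip(0.5)
        summaries = [AnimalSummary(f"a{i}", i0, i0) for i, i0 in enumerate(initials)]
        frame = variability_metrics(summaries)
        row = frame[frame["profile_id"] == "pooled"].iloc[0]
        assert row["sd_entrained_deg"] == pytest.approx(row["sd_immediate_deg"])


class TestPopulationAverage:
    def test_identical_animals_equal_individual(self):
        amps = np.linspace(8.0, 6.0, 20)
        tables = [table_from_amplitudes(amps) for _ in range(3)]
        curve = population_cycle_average(tables)
        np.testing.assert_allclose(curve["mean_pp_deg"], amps)
        assert (curve["n"] == 3).all()

    def test_noiseless_cohort_matches_geometric_relaxation(self):
        params = PlasticityParams(slope_m=-0.59, setpoint_x0=6.4, cycle_count=30)
        tables = [
            table_from_amplitudes(amplitude_series(i0, params)) for i0 in (3.0, 9.0, 12.0)
        ]
        curve = population_cycle_average(tables)
        expected = np.mean(
            [amplitude_series(i0, params) for i0 in (3.0, 9.0, 12.0)], axis=0
        )
        np.testing.assert_allclose(curve["mean_pp_deg"], expected, atol=1e-12)

    def test_all_invalid_animal_excluded_with_warning(self, caplog):
        import logging

        good = table_from_amplitudes([5.0] * 12)
        bad = table_from_amplitudes([9.0] * 12, valid=[False] * 12)
        with caplog.at_level(logging.WARNING):
            curve = population_cycle_average([good, bad])
        assert np.allclose(curve["mean_pp_deg"], 5.0)
        assert any("no valid cycles" in r.message for r in caplog.records)


class TestWilcoxon:
    def test_five_positive_pairs_exact(self):
        # all-positive differences: only 2 of the 2^5 sign patterns are as extreme
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 32)

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])

    @given(
        st.lists(
            st.integers(min_value=-40, max_value=40).filter(lambda v: v != 0),
            min_size=5,
            max_size=12,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_exact_p_matches_scipy_enumeration(self, diffs):
        """Tie-free exact p agrees with the independent scipy implementation."""
        diffs = np.array(diffs, dtype=float)
        diffs += np.linspace(0, 1e-3, diffs.size)  # break |d| ties
        res = wilcoxon_signed_rank(diffs)
        oracle = sps.wilcoxon(diffs, method="exact")
        assert res.exact
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed_rank(x)
        oracle = sps.wilcoxon(x, method="approx", correction=False)
        assert not res.exact
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-6)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 20)

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 2.5, 7.0], [3.0, 4.0, 6.0]
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r2.statistic == pytest.approx(len(a) * len(b) - r1.statistic)

    def test_ties_use_corrected_approximation(self):
        res = mann_whitney_u([1, 1, 2, 2], [1, 2, 2, 3])
        assert not res.exact
        assert 0.0 <= res.p_value <= 1.0

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=6, unique=True),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_exact_p_matches_scipy(self, x, y):
        rng = np.random.default_rng(len(x) + len(y))
        pooled = np.array(x + y, dtype=float)
        rng.shuffle(pooled)
        x2, y2 = pooled[: len(x)], pooled[len(x):]
        res = mann_whitney_u(x2, y2)
        oracle = sps.mannwhitneyu(x2, y2, method="exact", alternative="two-sided")
        assert res.exact
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalDunn:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        omnibus, pairwise = kruskal_dunn([g, g, g])
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-9)
        assert all(r.p_value == pytest.approx(1.0) for r in pairwise.values())

    def test_hand_ranked_oracle(self):
        # ranks 1..9; rank sums 12, 15, 18 -> H = 12/(9*10)*sum(R^2/3) - 30 = 0.8
        omnibus, _ = kruskal_dunn([[1, 4, 7], [2, 5, 8], [3, 6, 9]])
        assert omnibus.statistic == pytest.approx(0.8, abs=1e-12)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        c = rng.normal(8, 1, 12)  # shift >> spread
        omnibus, pairwise = kruskal_dunn([a, b, c], labels=["a", "b", "c"])
        assert omnibus.p_value < 0.05
        assert pairwise[("a", "c")].p_value < 0.05
        assert pairwise[("a", "b")].p_value > 0.05

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1, 2], [3, 4]])
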