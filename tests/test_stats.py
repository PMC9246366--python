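"""Per-fish aggregation and the statistical battery."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lateralline as ll
from lateralline.containers import BoutRates, FishMetadata, SwimBout
from lateralline.stats import compact_letter_display


def make_rates(n, pre=10.0, swim=3.0, rng=None):
    out = []
    for i in range(n):
        d = 0.4
        pre_n = max(1, int(round(pre * d)))
        swim_n = int(round(swim * d))
        out.append(BoutRates(
            bout=SwimBout(10.0 + i, 10.4 + i, n_bursts=8),
            pre_count=pre_n, swim_count=swim_n, post_count=pre_n,
            pre_rate=pre_n / d, swim_rate=swim_n / d, post_rate=pre_n / d,
            relative_rate=swim_n / pre_n, inhibition=1 - swim_n / pre_n,
            label="reduced" if swim_n < pre_n else "non_reduced",
            retained=True,
        ))
    return out


class TestSummarizeFish:
    def test_weight_is_sqrt_n_swims(self):
        s = ll.summarize_fish(make_rates(100), 12.0, FishMetadata("f1"))
        assert s.n_swims == 100
        assert s.weight == 10.0

    def test_single_bout_means_equal_that_bout(self):
        rates = make_rates(1)
        s = ll.summarize_fish(rates, 12.0, FishMetadata("f1"))
        assert s.mean_pre_rate == rates[0].pre_rate
        assert s.mean_swim_rate == rates[0].swim_rate
        assert s.mean_inhibition == rates[0].inhibition

    def test_no_retained_bouts_excludes_fish(self):
        r = ll.score_bout(np.array([2.1]), SwimBout(2.0, 2.4, n_bursts=5), 10.0)
        with pytest.raises(ValueError, match="no retained"):
            ll.summarize_fish([r], 12.0, FishMetadata("f1"))

    def test_per_fish_inhibition_recovers_generator_truth(self):
        cfg = ll.SimulationConfig(baseline_rate=25.0, inhibition_fraction=0.5,
                                  session_duration=2000.0, bout_rate=0.5,
                                  bout_duration_mean=0.5, bout_duration_sd=0.0)
        _, truth = ll.simulate_session(cfg, rng=np.random.default_rng(31),
                                       render=False)
        swim = ll.true_swim_bouts(truth.bouts, truth.burst_times)
        scored = ll.score_bouts(truth.spike_times, swim, 2000.0)
        assert sum(s.retained for s in scored) >= 300
        s = ll.summarize_fish(
            scored,
            ll.spontaneous_rate(truth.spike_times, truth.bouts, 2000.0),
            FishMetadata("f1"),
        )
        # pooled ratio of per-fish mean rates is nearly unbiased at
        # lambda*d = 12.5 expected pre-swim spikes per bout
        assert abs(1 - s.mean_swim_rate / s.mean_pre_rate - 0.5) < 0.05


class TestMaybeLogTransform:
    def _frame(self, rng, structured, n_groups=8, n_per=10):
        rows = []
        for g in range(n_groups):
            mu = 5.0 * (g + 1)
            for _ in range(n_per):
                if structured:
                    rows.append((f"g{g}", rng.poisson(mu)))
                else:
                    rows.append((f"g{g}", rng.normal(mu, 3.0)))
        return pd.DataFrame(rows, columns=["group", "value"])

    def test_homoscedastic_groups_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flagged = sum(
            ll.maybe_log_transform(
                self._frame(rng, False, n_groups=12), "group"
            )[1]["value"]
            for _ in range(200)
        )
        assert flagged / 200 < 0.12  # about the nominal alpha

    def test_poisson_structure_triggers_transform(self):
        # detection probability grows with the number of groups; at 12
        # groups spanning a 12-fold mean range it is essentially certain
        rng = np.random.default_rng(1)
        flagged = sum(
            ll.maybe_log_transform(
                self._frame(rng, True, n_groups=12, n_per=12), "group"
            )[1]["value"]
            for _ in range(50)
        )
        assert flagged / 50 > 0.9
        out, flags = ll.maybe_log_transform(
            self._frame(rng, True, n_groups=12), "group")
        if flags["value"]:
            assert out["value"].max() < 10  # log scale

    def test_constant_variable_not_flagged(self):
        df = pd.DataFrame({
            "group": np.repeat(list("abcd"), 5), "value": 7.0,
        })
        _, flags = ll.maybe_log_transform(df, "group")
        assert flags["value"] is False

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "value": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            ll.maybe_log_transform(df, "group")

    def test_zeros_handled_with_offset(self):
        rng = np.random.default_rng(2)
        df = self._frame(rng, True)
        df.loc[df.index[:5], "value"] = 0.0
        out, flags = ll.maybe_log_transform(df, "group")
        assert np.isfinite(out["value"]).all()


class TestWeightedUnityTest:
    def test_identity_line_has_unit_slope(self):
        x = np.array([5.0, 10.0, 15.0, 20.0])
        r = ll.weighted_unity_test(x, x)
        assert r.slope == pytest.approx(1.0)
        assert not r.excludes_unity

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(5, 25, 12)
        y = 0.4 * x + rng.normal(0, 1, 12)
        w = rng.uniform(0.5, 4, 12)
        r = ll.weighted_unity_test(x, y, w)
        # closed-form WLS oracle
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert r.intercept == pytest.approx(beta[0], rel=1e-9)
        assert r.slope == pytest.approx(beta[1], rel=1e-9)

    def test_unit_weights_reduce_to_ols(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 15)
        y = 2.0 * x + rng.normal(0, 1, 15)
        r1 = ll.weighted_unity_test(x, y)
        r2 = ll.weighted_unity_test(x, y, np.ones(15))
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        assert r1.slope == pytest.approx(r2.slope) == pytest.approx(slope_ols)
        assert r1.slope_ci_low == pytest.approx(r2.slope_ci_low)

    def test_wide_interval_reported_unclamped(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(5, 20, 15)
        y = 0.1 * x + rng.normal(0, 8, 15)
        r = ll.weighted_unity_test(x, y)
        assert r.slope_ci_low < r.slope < r.slope_ci_high
        assert r.excludes_unity == (r.slope_ci_high < 1 or r.slope_ci_low > 1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ll.weighted_unity_test([1, 2], [1, 2])
        with pytest.raises(ValueError):
            ll.weighted_unity_test([3, 3, 3], [1, 2, 3])


class TestTTests:
    def test_identical_pairs_give_t_zero_p_one(self):
        assert ll.paired_swim_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_paired_matches_textbook_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.2, 1.9, 3.4, 4.1, 4.8])
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, p = ll.paired_swim_test(a, b)
        assert t == pytest.approx(t_oracle)
        assert 0 < p < 1

    def test_paired_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (4000, 8))
        b = rng.normal(0, 1, (4000, 8))
        rejections = sum(
            ll.paired_swim_test(ai, bi)[1] < 0.05 for ai, bi in zip(a, b)
        )
        assert abs(rejections / 4000 - 0.05) < 0.015

    def test_unpaired_identical_samples(self):
        t, p = ll.unpaired_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert t == 0.0

    def test_unpaired_matches_pooled_closed_form(self):
        a = np.array([4.0, 5.5, 6.0, 5.0])
        b = np.array([3.0, 2.5, 4.0])
        sp2 = ((3 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 5)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        t, _ = ll.unpaired_test(a, b)
        assert t == pytest.approx(t_oracle)

    def test_unpaired_type_i_error_with_unequal_n(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(3000):
            t, p = ll.unpaired_test(rng.normal(5, 2, 6), rng.normal(5, 2, 11))
            rejections += p < 0.05
        assert abs(rejections / 3000 - 0.05) < 0.02

    def test_sample_size_checks(self):
        with pytest.raises(ValueError):
            ll.paired_swim_test([1.0], [2.0])
        with pytest.raises(ValueError):
            ll.unpaired_test([1.0], [2.0, 3.0])


class TestGroupComparison:
    def _frame(self, means, n=10, sd=1.0, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for name, mu in means.items():
            for _ in range(n):
                rows.append((name, rng.normal(mu, sd)))
        return pd.DataFrame(rows, columns=["population", "rate"])

    def test_f_statistic_matches_sum_of_squares_oracle(self):
        df = self._frame({"a": 5.0, "b": 8.0, "c": 6.0}, n=4)
        comp = ll.group_comparison(df, "rate", ["population"])
        v = df["rate"].to_numpy()
        groups = [g["rate"].to_numpy() for _, g in df.groupby("population")]
        ss_between = sum(g.size * (g.mean() - v.mean()) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / 9)
        assert comp.anova_table["F"].iloc[0] == pytest.approx(f_oracle)

    def test_well_separated_groups_get_distinct_letters(self):
        df = self._frame({"a": 0.0, "b": 30.0}, n=8, sd=1.0)
        comp = ll.group_comparison(df, "rate", ["population"])
        assert comp.letters["a"] != comp.letters["b"]
        assert set(comp.letters.values()) == {"a", "b"}

    def test_null_groups_usually_share_one_letter(self):
        rng = np.random.default_rng(9)
        shared = 0
        for _ in range(40):
            df = self._frame({k: 5.0 for k in "abcd"}, n=10, rng=rng)
            comp = ll.group_comparison(df, "rate", ["population"])
            shared += len(set(comp.letters.values())) == 1
        assert shared / 40 >= 0.85

    def test_eight_cell_design_degrees_of_freedom(self):
        rng = np.random.default_rng(10)
        rows = []
        for pop in ("surface", "pachon"):
            for treat in ("control", "ablated"):
                for period in ("pre", "swim"):
                    for _ in range(6):
                        rows.append((pop, treat, period, rng.normal(10, 2)))
        df = pd.DataFrame(rows, columns=["population", "treatment",
                                         "period", "rate"])
        comp = ll.group_comparison(df, "rate",
                                   ["population", "treatment", "period"])
        assert comp.anova_table["df"].iloc[0] == 7  # 8 cells
        assert len(comp.letters) == 8

    def test_singleton_group_error_names_the_group(self):
        df = pd.DataFrame({"population": ["a", "a", "b"],
                           "rate": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="b"):
            ll.group_comparison(df, "rate", ["population"])


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert set(letters.values()) == {"a"}

    def test_chain_structure(self):
        # x differs from z; y bridges both
        letters = compact_letter_display(
            ["x", "y", "z"], {frozenset(("x", "z"))}
        )
        assert set(letters["x"]) & set(letters["z"]) == set()
        assert set(letters["y"]) & set(letters["x"])
        assert set(letters["y"]) & set(letters["z"])

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_letters_consistent_with_pairwise_decisions(self, data):
        groups = ["g0", "g1", "g2", "g3", "g4"]
        pairs = list(itertools.combinations(groups, 2))
        sig = {
            frozenset(p)
            for p in pairs
            if data.draw(st.booleans(), label=str(p))
        }
        letters = compact_letter_display(groups, sig)
        for a, b in pairs:
            shares = bool(set(letters[a]) & set(letters[b]))
            if frozenset((a, b)) in sig:
                assert not shares
            else:
                assert shares
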