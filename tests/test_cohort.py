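"""Cohort statistics: binning, nonparametric association, correlation,
survival estimators against hand-computed / grid-search oracles, and the
small quantitation utilities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincscout.cohort import (
    SurvivalRecord,
    apply_transplant_censoring,
    bin_expressors,
    correlation_rank,
    ddct,
    fraction_distribution,
    group_association,
    km_logrank,
    median_split,
    ph_multivariable,
)


class TestBinning:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "zero"), (0.4, "low_nonexpr"), (0.5, "low_nonexpr"),
         (0.50001, "expressor_low"), (2.0, "expressor_low"),
         (2.0001, "expressor_high"), (2.5, "expressor_high")],
    )
    def test_boundary_closure(self, value, expected):
        labels, _ = bin_expressors([value])
        assert labels == [expected]

    def test_partition_every_value_exactly_one_bin(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([[0.0, 0.5, 2.0], rng.uniform(0, 6, 500)])
        labels, summary = bin_expressors(values)
        assert len(labels) == len(values)
        assert summary["count"].sum() == len(values)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_expressors([-0.1])


class TestGroupAssociation:
    def test_all_tied_degenerate(self):
        h, p, _ = group_association([1.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_two_group_kw_equals_ranksum_normal_approx(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 15)
        values = np.concatenate([x, y])
        groups = ["a"] * 12 + ["b"] * 15
        _, p_kw, _ = group_association(values, groups)
        p_rs = stats.ranksums(x, y).pvalue
        assert p_kw == pytest.approx(p_rs, rel=1e-9)

    def test_h_matches_rank_formula_on_fixture(self):
        # 3 groups x 4 untied values: H from the textbook rank formula
        values = [1.2, 3.4, 5.6, 7.8, 2.3, 4.5, 6.7, 8.9, 0.1, 9.9, 10.1, 11.2]
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ranks = stats.rankdata(values)
        n = len(values)
        h_hand = 12.0 / (n * (n + 1)) * sum(
            4 * (ranks[np.array(groups) == g].mean() - (n + 1) / 2) ** 2
            for g in "abc"
        )
        h, _, _ = group_association(values, groups)
        assert h == pytest.approx(h_hand)

    def test_dunn_flags_the_shifted_group(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([
            rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        _, p, pw = group_association(values, groups)
        assert p < 0.001
        pw = pw.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_adj"] < 0.01
        assert pw.loc[("b", "c"), "p_adj"] < 0.01
        assert pw.loc[("a", "b"), "p_adj"] > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_association([1, 2], ["a", "a"])


class TestCorrelation:
    def test_self_and_anti_correlation_rank_first_and_last(self):
        rng = np.random.default_rng(7)
        target = pd.Series(rng.normal(0, 1, 10),
                           index=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame(
            {"same": target, "anti": -target,
             "noise": rng.normal(0, 1, 10)},
            index=target.index).T
        ranked = correlation_rank(target, expr)
        assert ranked.index[0] == "same"
        assert ranked["r"].iloc[0] == pytest.approx(1.0)
        assert ranked.index[-1] == "anti"
        assert ranked["r"].iloc[-1] == pytest.approx(-1.0)

    def test_r_matches_covariance_formula_on_five_points(self):
        x = pd.Series([1.0, 2.0, 4.0, 4.5, 7.0], index=list("abcde"))
        g = np.array([2.0, 1.0, 3.5, 5.0, 6.0])
        expr = pd.DataFrame([g], index=["gene"], columns=x.index)
        r_hand = (np.mean((g - g.mean()) * (x.to_numpy() - x.mean()))
                  / (g.std() * x.to_numpy().std()))
        ranked = correlation_rank(x, expr)
        assert ranked.loc["gene", "r"] == pytest.approx(r_hand)
        # p via the t transform, as scipy computes it
        assert ranked.loc["gene", "p"] == pytest.approx(
            stats.pearsonr(g, x.to_numpy()).pvalue, rel=1e-6)

    def test_zero_variance_gene_excluded(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        expr = pd.DataFrame({"flat": [5.0, 5.0, 5.0], "ok": [1.0, 2.0, 2.5]},
                            index=x.index).T
        ranked = correlation_rank(x, expr)
        assert np.isnan(ranked.loc["flat", "r"])
        assert ranked.index[-1] == "flat"  # pushed to the end


class TestMedianSplit:
    def test_ties_at_median_go_high(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        out = median_split(s)
        assert (out == ["low", "high", "high", "high"]).all()

    def test_split_sizes(self):
        rng = np.random.default_rng(11)
        s = pd.Series(rng.normal(0, 1, 101))
        out = median_split(s)
        assert (out == "high").sum() == 51
        assert (out == "low").sum() == 50


class TestSurvival:
    def _records(self, times, events, xs=None, tx=None):
        return [
            SurvivalRecord(
                f"s{i}", t, bool(e),
                transplant_time=None if tx is None else tx[i],
                covariates={} if xs is None else {"x": float(xs[i])})
            for i, (t, e) in enumerate(zip(times, events))
        ]

    def test_product_limit_hand_fixture(self):
        # 4 subjects, events at t=1 and t=2, censoring later:
        # S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2
        recs = self._records([1, 2, 3, 4], [1, 1, 0, 0])
        curves, chi2, p = km_logrank(recs, {f"s{i}": "all" for i in range(4)})
        curve = curves["all"].iloc[:, 0]
        assert curve.loc[1.0] == pytest.approx(0.75)
        assert curve.loc[2.0] == pytest.approx(0.5)

    def test_km_curve_monotone_from_one(self, bundle):
        strata = {r.sample_id: "all" for r in bundle["survival"]}
        curves, _, _ = km_logrank(bundle["survival"], strata)
        curve = curves["all"].iloc[:, 0]
        assert curve.iloc[0] == pytest.approx(1.0)
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()

    def test_no_events_logrank_undefined(self):
        recs = self._records([5, 6, 7, 8], [0, 0, 0, 0])
        strata = {f"s{i}": ("a" if i < 2 else "b") for i in range(4)}
        curves, chi2, p = km_logrank(recs, strata)
        assert chi2 is None and p is None
        for curve in curves.values():
            assert np.allclose(curve.iloc[:, 0], 1.0)

    def test_identical_strata_logrank_null(self):
        times = [1, 2, 3, 4, 5, 6] * 2
        events = [1, 1, 0, 1, 0, 1] * 2
        strata = {f"s{i}": ("a" if i < 6 else "b") for i in range(12)}
        _, chi2, p = km_logrank(self._records(times, events), strata)
        assert p > 0.9

    def test_transplant_censoring(self):
        recs = self._records([10.0, 10.0], [1, 1], tx=[4.0, None])
        df = apply_transplant_censoring(recs)
        assert df.loc["s0", "time"] == 4.0 and not df.loc["s0", "event"]
        assert df.loc["s1", "time"] == 10.0 and df.loc["s1", "event"]

    def test_cox_matches_partial_likelihood_grid_oracle(self):
        # 5 subjects, one binary covariate, no ties: exact partial
        # likelihood maximized by grid search
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 0, 1]
        xs = [1, 0, 1, 0, 1]
        recs = self._records(times, events, xs=xs)

        def neg_log_pl(beta: float) -> float:
            order = np.argsort(times)
            ll = 0.0
            for idx in order:
                if not events[idx]:
                    continue
                risk = [j for j in range(5) if times[j] >= times[idx]]
                ll += beta * xs[idx] - np.log(
                    sum(np.exp(beta * xs[j]) for j in risk))
            return -ll

        grid = np.arange(-3, 3, 0.001)
        beta_grid = grid[np.argmin([neg_log_pl(b) for b in grid])]
        ph = ph_multivariable(recs, ["x"])
        assert ph.loc["x", "coef"] == pytest.approx(beta_grid, abs=0.01)

    def test_identical_event_patterns_hr_near_one(self):
        times = [1, 2, 3, 4, 5, 6] * 2
        events = [1, 1, 0, 1, 0, 1] * 2
        xs = [0] * 6 + [1] * 6
        ph = ph_multivariable(self._records(times, events, xs=xs), ["x"])
        assert ph.loc["x", "HR"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_covariate_rejected(self):
        recs = self._records([1, 2, 3], [1, 1, 1], xs=[1, 1, 1])
        with pytest.raises(ValueError):
            ph_multivariable(recs, ["x"])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("s", 0.0, True)


class TestQuantitation:
    @pytest.mark.parametrize("cts, expected", [
        ((20.0, 20.0, 18.0, 18.0), 1.0),   # ddCT = 0
        ((21.0, 20.0, 18.0, 18.0), 0.5),   # ddCT = 1
        ((18.0, 20.0, 18.0, 18.0), 4.0),   # ddCT = -2
    ])
    def test_ddct_closed_forms(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_ddct_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ddct(np.nan, 20, 18, 18)

    def test_equal_signal_equal_spike_uniform(self):
        out = fraction_distribution([3.0] * 13, [2.0] * 13)
        assert np.allclose(out, 100.0 / 13)

    def test_doubling_spike_halves_share_pre_renormalization(self):
        sig = np.array([1.0, 1.0])
        a = fraction_distribution(sig, [1.0, 1.0])
        b = fraction_distribution(sig, [1.0, 2.0])
        assert b[1] / b[0] == pytest.approx(0.5 * a[1] / a[0])

    def test_sums_to_hundred_on_random_inputs(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            k = int(rng.integers(2, 15))
            out = fraction_distribution(rng.uniform(0.1, 10, k),
                                        rng.uniform(0.1, 10, k))
            assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_spike_names_fraction(self):
        with pytest.raises(ValueError, match="1"):
            fraction_distribution([1.0, 1.0], [1.0, 0.0])
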