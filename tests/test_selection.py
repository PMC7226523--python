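import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radsurv import (
    SelectionSpec,
    correlation_prune,
    fdr_adjust,
    resampled_selection,
    screen_features,
    sffs,
    univariate_anova,
    univariate_cox,
)

import _oracles as oracles


class TestUnivariateCox:
    def test_perfect_ordering_gives_extreme_ci(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1, 100, 20))
        feature = np.argsort(np.argsort(times)).astype(float)  # rank of time
        res = univariate_cox(feature, times, np.ones(20, int))
        assert res.statistic in (pytest.approx(0.0), pytest.approx(1.0))
        assert abs(res.coefficient) > 1.0

    def test_independent_feature_ci_near_half(self):
        rng = np.random.default_rng(1)
        n = 200
        times = rng.exponential(100, n)
        events = (rng.random(n) < 0.8).astype(int)
        res = univariate_cox(rng.normal(size=n), times, events)
        assert abs(res.statistic - 0.5) < 0.05
        assert res.raw_p > 0.001

    def test_score_at_zero_matches_hand_formula(self):
        # toy n=5, untied: U(0) = sum_events (x_i - risk-set mean)
        x = np.array([0.2, -1.0, 0.7, 1.5, -0.3])
        times = np.array([3.0, 5.0, 7.0, 11.0, 13.0])
        events = np.array([1, 0, 1, 1, 0])
        u_hand = oracles.cox_score_at_zero(x, times, events)
        from radsurv._cox import cox_gradient_f

        # score wrt beta at 0 equals x . dll/df at f=0
        grad_f = cox_gradient_f(times, events, np.zeros(5))
        assert float(x @ grad_f) == pytest.approx(u_hand, abs=1e-10)

    def test_constant_feature_flagged(self):
        res = univariate_cox(np.ones(10), np.arange(1, 11), np.ones(10, int))
        assert res.failed


class TestUnivariateAnova:
    def test_hand_anova_table(self):
        res = univariate_anova([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(13.5)

    def test_matched_means_give_small_f(self):
        res = univariate_anova([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            res = univariate_anova(x, y)
            expected = oracles.anova_f([x[y == 0], x[y == 1]])
            assert res.statistic == pytest.approx(expected, abs=1e-10)


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.042])[0] == pytest.approx(0.042)

    def test_hand_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.max(np.abs(fdr_adjust(p) - oracles.bh_adjust(p))) < 1e-12

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_elementwise_bounds(self, pvals):
        adj = fdr_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)

    def test_nan_passthrough(self):
        adj = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestCorrelationPrune:
    def test_duplicate_column_keeps_stronger_name(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        df = pd.DataFrame({"f1": a, "f2": a.copy(), "f3": rng.normal(size=50)})
        kept = correlation_prune(df, {"f1": 2.0, "f2": 1.0, "f3": 0.5}, 0.8)
        assert kept == ["f1", "f3"]

    def test_three_feature_recursion_trace(self):
        rng = np.random.default_rng(5)
        f1 = rng.normal(size=200)
        f2 = 0.97 * f1 + 0.1 * rng.normal(size=200)  # r ~ 0.95 with f1
        f3 = rng.normal(size=200)                     # r ~ 0 with f1
        df = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        kept = correlation_prune(df, {"f1": 1.0, "f2": 0.5, "f3": 0.1}, 0.8)
        assert kept == ["f1", "f3"]

    def test_orthogonal_features_all_kept(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        kept = correlation_prune(df, {c: 1.0 for c in df}, 0.8)
        assert kept == list("abcde")

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(60, 4))
        df = pd.DataFrame(
            np.column_stack([base, base[:, 0] + 0.3 * rng.normal(size=60)]),
            columns=list("abcde"),
        )
        scores = {c: i for i, c in enumerate(df.columns)}
        loose = set(correlation_prune(df, scores, 0.95))
        strict = set(correlation_prune(df, scores, 0.5))
        assert strict <= loose


class TestSFFS:
    def test_dominant_feature_selected_first(self):
        weights = {"a": 5.0, "b": 1.0, "c": 0.5}
        obj = lambda s: sum(weights[f] for f in s) - 0.1 * len(s) ** 2
        subset = sffs(list("abc"), obj, max_size=2)
        assert "a" in subset

    def test_matches_exhaustive_optimum_with_floating(self):
        # objective with complementarity: {b, c} beats any superset of {a}
        table = {
            frozenset("a"): 3.0, frozenset("b"): 2.0, frozenset("c"): 2.0,
            frozenset("ab"): 3.5, frozenset("ac"): 3.4, frozenset("bc"): 6.0,
            frozenset("abc"): 5.0, frozenset("d"): 0.1, frozenset("bd"): 2.1,
        }
        obj = lambda s: table.get(frozenset(s), 0.0)
        best = sffs(list("abcd"), obj, max_size=3)
        assert set(best) == {"b", "c"}

    def test_at_least_as_good_as_greedy_forward(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            feats = list("abcde")
            table = {
                frozenset(s): float(rng.normal())
                for r in range(1, 4)
                for s in __import__("itertools").combinations(feats, r)
            }
            obj = lambda s: table.get(frozenset(s), -np.inf)
            # plain greedy forward
            current, best_greedy = [], -np.inf
            for _ in range(3):
                cands = [(obj(current + [f]), f) for f in feats if f not in current]
                sc, f = max(cands)
                current.append(f)
                best_greedy = max(best_greedy, sc)
            assert obj(sffs(feats, obj, 3)) >= best_greedy - 1e-12

    def test_monotone_objective_stops_at_max_size(self):
        subset = sffs(list("abcdef"), lambda s: len(s), max_size=3)
        assert len(subset) == 3

    def test_objective_failure_scores_minus_inf(self):
        def obj(s):
            if "b" in s:
                raise RuntimeError("boom")
            return len(s)

        subset = sffs(list("abc"), obj, max_size=2)
        assert "b" not in subset


class TestScreenVectorization:
    def test_survival_screen_matches_single_fits(self):
        rng = np.random.default_rng(9)
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
        times = rng.exponential(100, n) * np.exp(-df["f0"])
        events = (rng.random(n) < 0.7).astype(int)
        out = {"time": times.to_numpy(), "event": events}
        screen = screen_features(df, out, "survival")
        for i, col in enumerate(df.columns):
            single = univariate_cox(df[col].to_numpy(), out["time"], out["event"], col)
            assert screen["raw_p"].iloc[i] == pytest.approx(single.raw_p, rel=1e-4, abs=1e-8)
            assert screen["statistic"].iloc[i] == pytest.approx(single.statistic, abs=1e-9)


class TestResampledSelection:
    @staticmethod
    def _planted_table(rng, n=120, p_noise=40, beta=1.0):
        z = rng.normal(size=(n, 3))
        noise = rng.normal(size=(n, p_noise))
        cols = {f"signal_{i}": z[:, i] for i in range(3)}
        cols.update({f"noise_{i}": noise[:, i] for i in range(p_noise)})
        table = pd.DataFrame(cols)
        times = rng.exponential(300, n) * np.exp(-beta * z.sum(axis=1))
        events = (rng.random(n) < 0.75).astype(int)
        return table, {"time": times, "event": events}

    def test_planted_signals_rank_top_by_frequency(self):
        rng = np.random.default_rng(10)
        table, out = self._planted_table(rng)
        spec = SelectionSpec(n_resamples=30, max_candidates=15, max_signature_size=5, seed=0)
        report = resampled_selection(table, out, spec, endpoint="survival")
        top5 = set(report.selection_frequency.head(5).index)
        assert {"signal_0", "signal_1", "signal_2"} <= top5
        assert set(report.final_signature) <= set(table.columns)
        assert ((report.selection_frequency >= 0) & (report.selection_frequency <= 1)).all()

    def test_pure_noise_low_frequencies(self):
        rng = np.random.default_rng(11)
        n = 120
        table = pd.DataFrame(
            rng.normal(size=(n, 60)), columns=[f"n{i}" for i in range(60)]
        )
        times = rng.exponential(300, n)
        events = (rng.random(n) < 0.75).astype(int)
        spec = SelectionSpec(n_resamples=40, max_candidates=15, seed=1)
        report = resampled_selection(
            table, {"time": times, "event": events}, spec, endpoint="survival"
        )
        assert report.selection_frequency.max() < 0.3

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(12)
        table, out = self._planted_table(rng, n=80, p_noise=20)
        spec = SelectionSpec(n_resamples=10, max_candidates=10, seed=3)
        a = resampled_selection(table, out, spec, endpoint="survival")
        b = resampled_selection(table, out, spec, endpoint="survival")
        assert a.final_signature == b.final_signature
        assert a.selection_frequency.equals(b.selection_frequency)
        assert a.per_resample == b.per_resample

    def test_recurrence_endpoint_runs_and_reports(self, tmp_path):
        rng = np.random.default_rng(13)
        n = 90
        z = rng.normal(size=n)
        table = pd.DataFrame(
            {"sig": z, **{f"n{i}": rng.normal(size=n) for i in range(10)}}
        )
        labels = (rng.random(n) < 1 / (1 + np.exp(-2 * z))).astype(int)
        spec = SelectionSpec(n_resamples=10, max_candidates=8, seed=4)
        report = resampled_selection(table, labels, spec, endpoint="recurrence")
        assert report.selection_frequency.idxmax() == "sig"
        report.to_json(tmp_path / "sel.json")
        report.to_csv(tmp_path / "sel.csv")
        back = pd.read_csv(tmp_path / "sel.csv")
        assert "selection_frequency" in back.columns
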