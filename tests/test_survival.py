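import numpy as np
import pytest

from radsurv import (
    BoostedCoxModel,
    average_km,
    concordance_index,
    fit_boosted_cox,
    km_curve,
    stratify_and_km,
)

import _oracles as oracles


class TestConcordance:
    def test_perfect_anti_ordering(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-times, times, np.ones(4, int)) == 1.0

    def test_all_risks_equal(self):
        assert concordance_index([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_six_pair_example(self):
        got = concordance_index([0.9, 0.1, 0.8, 0.2], [2, 4, 6, 8], [1, 0, 1, 1])
        expected = oracles.harrell_ci([0.9, 0.1, 0.8, 0.2], [2, 4, 6, 8], [1, 0, 1, 1])
        assert got == pytest.approx(expected)
        assert got == 1.0

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            times = np.round(rng.exponential(10, n), 1) + 0.1
            events = (rng.random(n) < 0.7).astype(int)
            risks = np.round(rng.normal(size=n), 1)  # provoke risk ties
            if not (((times[:, None] > times[None, :]) & (events[None, :] == 1)).any()):
                continue
            try:
                expected = oracles.harrell_ci(risks, times, events)
            except ValueError:
                with pytest.raises(ValueError):
                    concordance_index(risks, times, events)
                continue
            assert concordance_index(risks, times, events) == pytest.approx(expected)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 25)
        events = (rng.random(25) < 0.6).astype(int)
        events[0] = 1
        risks = rng.normal(size=25)
        c1 = concordance_index(risks, times, events)
        c2 = concordance_index(-risks, times, events)
        assert c1 + c2 == pytest.approx(1.0)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [5, 5], [1, 1])


class TestBoostedCox:
    def test_zero_stages_constant_risk(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        m = fit_boosted_cox(X, t, e, {"n_stages": 0})
        risks = m.predict(X)
        assert np.ptp(risks) == 0
        assert concordance_index(risks, t, e) == 0.5

    def test_recovers_strong_signal(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=(n, 1))
        # strong hazard (beta = 3) so the oracle concordance itself exceeds 0.85
        t = rng.exponential(300, n) * np.exp(-3.0 * x[:, 0])
        e = (rng.random(n) < 0.8).astype(int)
        m = fit_boosted_cox(x[:200], t[:200], e[:200], {"n_stages": 100})
        ci = concordance_index(m.predict(x[200:]), t[200:], e[200:])
        assert ci > 0.85

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        t = rng.exponential(100, 60) * np.exp(-X[:, 0])
        e = (rng.random(60) < 0.8).astype(int)
        perm = [2, 0, 3, 1]
        m1 = fit_boosted_cox(X, t, e, {"n_stages": 30}, seed=0)
        m2 = fit_boosted_cox(X[:, perm], t, e, {"n_stages": 30}, seed=0)
        assert np.allclose(m1.predict(X), m2.predict(X[:, perm]))

    def test_training_loss_nonincreasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        t = rng.exponential(100, 50)
        e = (rng.random(50) < 0.7).astype(int)
        e[:2] = 1
        m = fit_boosted_cox(X, t, e, {"n_stages": 60})
        assert all(np.diff(m.train_loss_) <= 1e-9)

    def test_staged_predict_consistent_with_predict(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        t = rng.exponential(100, 40)
        e = np.ones(40, int)
        m = fit_boosted_cox(X, t, e, {"n_stages": 20})
        stages = list(m.staged_predict(X))
        assert len(stages) == 20
        assert np.allclose(stages[-1], m.predict(X), atol=1e-5)
        payload = m.to_json()
        assert len(payload["trees"]) == 20
        assert len(payload["stage_scales"]) == 20

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_boosted_cox(np.zeros((10, 1)), np.arange(1, 11), np.zeros(10, int))

    def test_agrees_with_sksurv_ranking(self):
        sksurv = pytest.importorskip("sksurv.ensemble")
        from sksurv.util import Surv
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        n = 150
        X = rng.normal(size=(n, 3))
        t = rng.exponential(300, n) * np.exp(-X[:, 0] + 0.5 * X[:, 1])
        e = (rng.random(n) < 0.8).astype(int)
        mine = fit_boosted_cox(X, t, e, {"n_stages": 100})
        ref = sksurv.GradientBoostingSurvivalAnalysis(
            n_estimators=100, max_depth=2, learning_rate=0.1
        ).fit(X, Surv.from_arrays(e.astype(bool), t))
        rho = spearmanr(mine.predict(X), ref.predict(X)).statistic
        assert rho > 0.9


class TestKaplanMeier:
    def test_km_without_censoring_is_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        curve = km_curve(times, np.ones(4, int))
        for t, expected in [(1.0, 0.75), (2.5, 0.5), (4.0, 0.0)]:
            assert curve.evaluate([t])[0] == pytest.approx(expected)

    def test_km_monotone_from_one(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40)
        events = (rng.random(40) < 0.6).astype(int)
        curve = km_curve(times, events)
        vals = curve.evaluate(np.linspace(0, times.max(), 50))
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_identical_groups_logrank_null(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.ones(8, int)
        risks = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = stratify_and_km(risks, times, events)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0)

    def test_toy_logrank_matches_hand_table(self):
        t_lo = [4.0, 5.0, 6.0]
        t_hi = [1.0, 2.0, 3.0]
        risks = [0, 0, 0, 1, 1, 1]
        times = np.array(t_lo + t_hi)
        events = np.ones(6, int)
        res = stratify_and_km(np.array(risks), times, events)
        expected = oracles.logrank_2group(t_lo, [1, 1, 1], t_hi, [1, 1, 1])
        assert res.logrank_statistic == pytest.approx(expected, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stratify_and_km(np.ones(4), [1, 2, 3, 4], [1, 1, 1, 1])

    def test_average_km_single_and_identical(self):
        c = km_curve([1.0, 2.0, 3.0], [1, 1, 0])
        avg1 = average_km([c])
        assert np.allclose(avg1.evaluate(c.times), c.evaluate(c.times))
        avg2 = average_km([c, c])
        assert np.allclose(avg2.survival, avg1.survival)

    def test_average_km_midpoint_of_two_steps(self):
        c1 = km_curve([1.0, 2.0], [1, 1])
        c2 = km_curve([1.5, 2.5], [1, 1])
        grid = np.array([0.5, 1.25, 1.75, 2.25, 3.0])
        avg = average_km([c1, c2], grid)
        expected = (c1.evaluate(grid) + c2.evaluate(grid)) / 2
        assert np.allclose(avg.survival, expected)
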