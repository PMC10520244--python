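import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcube
from pcube import mtlr
from pcube.mtlr import (
    MTLRError,
    MTLRModel,
    TimeGrid,
    encode_targets,
    make_grid,
    neg_log_likelihood,
    predict_curve,
    risk_score,
    survival_at,
)
from .conftest import make_cohort


def brute_force_probs(theta, bias, x):
    """Enumerate all m+1 legal sequences and normalize explicitly."""
    m = theta.shape[0]
    g = theta @ x + bias
    f = np.array([g[k:].sum() for k in range(m)] + [0.0])
    e = np.exp(f - f.max())
    return e / e.sum()


def targets_for(times, events, grid_points):
    cohort = make_cohort(times, events)
    return encode_targets(cohort, TimeGrid(np.asarray(grid_points, dtype=float)))


class TestMakeGrid:
    def test_single_point_is_median(self):
        cohort = make_cohort([1, 2, 3], [1, 1, 1])
        grid = make_grid(cohort, m=1)
        np.testing.assert_array_equal(grid.points, [2.0])

    def test_auto_uses_sqrt_of_events(self):
        cohort = make_cohort(np.linspace(1, 10, 100), np.ones(100, dtype=int))
        assert make_grid(cohort, m="auto").m == 10

    def test_tied_event_times_deduplicate(self):
        cohort = make_cohort([5, 5, 5, 9], [1, 1, 1, 0])
        grid = make_grid(cohort, m=3)
        np.testing.assert_array_equal(grid.points, [5.0])

    def test_no_events_rejected(self):
        cohort = make_cohort([1, 2], [0, 0])
        with pytest.raises(MTLRError, match="no observed events"):
            make_grid(cohort)


class TestEncodeTargets:
    def test_event_between_grid_points(self):
        tg = targets_for([1.5], [1], [1, 2, 3])
        assert tg.first_k[0] == 2  # sequence (0, 1, 1)

    def test_event_beyond_grid(self):
        tg = targets_for([4.0], [1], [1, 2, 3])
        assert tg.first_k[0] == 4  # all-zero terminal sequence

    def test_censored_mid_grid_admissible_suffix(self):
        # censored at 2.5: sequences with y1 = y2 = 0, i.e. {3, 4}
        tg = targets_for([2.5], [0], [1, 2, 3])
        assert tg.first_k[0] == 3

    def test_censored_past_grid_only_terminal(self):
        tg = targets_for([3.5], [0], [1, 2, 3])
        assert tg.first_k[0] == 4

    def test_censoring_tie_counts_as_survived(self):
        tg = targets_for([2.0], [0], [1, 2, 3])
        assert tg.first_k[0] == 3


class TestObjective:
    def test_zero_parameters_give_log_m_plus_one(self):
        for m in (1, 3, 7):
            tg = targets_for([0.5], [1], np.arange(1, m + 1))
            nll, _, _ = neg_log_likelihood(
                np.zeros((m, 2)), np.zeros(m), np.zeros((1, 2)), tg, 0.0, 0.0
            )
            assert nll == pytest.approx(np.log(m + 1), abs=1e-12)

    def test_fully_uninformative_censoring_contributes_zero(self):
        # censored before t1: every sequence admissible, term = log Z - log Z
        tg = targets_for([0.5], [0], [1, 2, 3])
        rng = np.random.default_rng(0)
        theta, bias = rng.normal(size=(3, 2)), rng.normal(size=3)
        nll, gt, gb = neg_log_likelihood(theta, bias, rng.normal(size=(1, 2)), tg, 0.0, 0.0)
        assert nll == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(gt, 0.0, atol=1e-12)
        np.testing.assert_allclose(gb, 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n, m, p = 10, int(rng.integers(1, 6)), int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            tg = targets_for(
                rng.uniform(0.2, 6, n), rng.integers(0, 2, n), np.linspace(1, 5, m)
            )
            theta, bias = rng.normal(size=(m, p)), rng.normal(size=m)
            _, gt, gb = neg_log_likelihood(theta, bias, X, tg, 0.7, 0.3)
            eps = 1e-6
            for i, j in [(0, 0), (m - 1, p - 1)]:
                tp, tm_ = theta.copy(), theta.copy()
                tp[i, j] += eps
                tm_[i, j] -= eps
                fd = (
                    neg_log_likelihood(tp, bias, X, tg, 0.7, 0.3)[0]
                    - neg_log_likelihood(tm_, bias, X, tg, 0.7, 0.3)[0]
                ) / (2 * eps)
                assert abs(fd - gt[i, j]) / max(1.0, abs(fd)) < 1e-6
            bp, bm = bias.copy(), bias.copy()
            bp[0] += eps
            bm[0] -= eps
            fd = (
                neg_log_likelihood(theta, bp, X, tg, 0.7, 0.3)[0]
                - neg_log_likelihood(theta, bm, X, tg, 0.7, 0.3)[0]
            ) / (2 * eps)
            assert abs(fd - gb[0]) / max(1.0, abs(fd)) < 1e-6

    def test_objective_convex_along_lines_uncensored(self):
        rng = np.random.default_rng(2)
        n, m, p = 30, 4, 3
        X = rng.normal(size=(n, p))
        tg = targets_for(rng.uniform(0.2, 6, n), np.ones(n, dtype=int), np.linspace(1, 5, m))
        w0 = rng.normal(size=m * p + m)
        direction = rng.normal(size=w0.size)

        def f(t):
            w = w0 + t * direction
            return neg_log_likelihood(
                w[: m * p].reshape(m, p), w[m * p:], X, tg, 0.0, 0.0
            )[0]

        ts = np.linspace(-1, 1, 9)
        vals = np.array([f(t) for t in ts])
        second_diffs = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        assert (second_diffs >= -1e-8).all()


class TestPrediction:
    def test_zero_parameters_uniform_tail(self):
        model = MTLRModel(TimeGrid(np.array([1.0, 2.0, 3.0])), np.zeros((3, 2)), np.zeros(3))
        curve = predict_curve(model, np.zeros(2))
        np.testing.assert_allclose(curve.probs, [0.75, 0.5, 0.25], atol=1e-15)

    @given(st.integers(0, 10_000))
    def test_probabilities_normalize_and_survival_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m, p = int(rng.integers(1, 11)), int(rng.integers(1, 5))
        model = MTLRModel(
            TimeGrid(np.linspace(1, 8, m)),
            rng.normal(scale=2, size=(m, p)),
            rng.normal(scale=2, size=m),
        )
        x = rng.normal(size=p)
        probs = model.sequence_probabilities(x)[0]
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(probs, brute_force_probs(model.theta, model.bias, x), atol=1e-12)
        curve = predict_curve(model, x)
        assert (np.diff(curve.probs) <= 1e-12).all()

    def test_large_early_bias_forces_early_event(self):
        model = MTLRModel(
            TimeGrid(np.array([1.0, 2.0, 3.0])),
            np.zeros((3, 1)),
            np.array([10.0, 0.0, 0.0]),
        )
        curve = predict_curve(model, np.zeros(1))
        assert curve.probs[0] < 1e-3

    def test_survival_at_interpolation_contract(self):
        curve = mtlr.SurvivalCurve(TimeGrid(np.array([2.0, 4.0])), np.array([0.8, 0.4]))
        assert survival_at(curve, 0.0) == 1.0
        assert survival_at(curve, 3.0) == pytest.approx(0.6)  # midpoint
        assert survival_at(curve, 9.0) == 0.4  # constant extension
        with pytest.raises(MTLRError):
            survival_at(curve, -1.0)

    def test_risk_score_orders_dominated_curves(self):
        grid = TimeGrid(np.array([1.0, 2.0]))
        good = MTLRModel(grid, np.zeros((2, 1)), np.array([-3.0, -3.0]))
        bad = MTLRModel(grid, np.zeros((2, 1)), np.array([3.0, 3.0]))
        x = np.zeros((1, 1))
        assert risk_score(bad, x)[0] > risk_score(good, x)[0]
        assert risk_score(bad, x)[0] == risk_score(bad, x)[0]


class TestFitting:
    def test_m1_no_censoring_reduces_to_ridge_logistic(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        n, p = 400, 3
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 0.0])
        t1 = 2.0
        probs = 1 / (1 + np.exp(-(X @ beta)))
        event_by_t1 = rng.uniform(size=n) < probs
        times = np.where(event_by_t1, 1.0, 3.0)
        cohort = make_cohort(times, np.ones(n, dtype=int))
        c1 = 1.0
        model = mtlr.fit(X, cohort, grid=TimeGrid(np.array([t1])), c1=c1, c2=0.0, tol=1e-9)
        p_mtlr = 1.0 - model.survival_matrix(X)[:, 0]
        lr = LogisticRegression(C=1.0 / c1, tol=1e-10, max_iter=5000)
        lr.fit(X, event_by_t1.astype(int))
        p_lr = lr.predict_proba(X)[:, 1]
        assert np.max(np.abs(p_mtlr - p_lr)) < 1e-4

    def test_saturated_limit_matches_empirical_fraction(self):
        # one shared covariate value, single grid point: the fitted interval
        # probability approaches the empirical event fraction as C1 -> 0
        n_event, n_surv = 60, 40
        times = np.concatenate([np.full(n_event, 5.0), np.full(n_surv, 10.0)])
        events = np.concatenate([np.ones(n_event, int), np.zeros(n_surv, int)])
        cohort = make_cohort(times, events)
        X = np.zeros((n_event + n_surv, 1))
        model = mtlr.fit(X, cohort, grid=TimeGrid(np.array([5.0])), c1=1e-6, c2=0.0, tol=1e-10)
        s = model.survival_matrix(X)[0, 0]
        assert abs((1 - s) - 0.6) < 1e-3

    def test_ridge_shrinkage_monotone(self):
        cohort = pcube.simulate_cohort(pcube.homogeneous_preset(n=300, seed=1))
        spec = pcube.fit_encoding(cohort)
        fm = pcube.transform(cohort, spec)
        norms = []
        for c1 in [0.5, 1.0, 2.0, 4.0, 8.0]:
            model = mtlr.fit(fm.values, cohort, m=5, c1=c1, c2=1.0)
            norms.append(np.linalg.norm(model.theta))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_planted_sign_recovery(self):
        from pcube.simulate import Effect, SimConfig, SubgroupSpec, simulate_cohort

        betas = {"x1": 1.0, "x2": -1.0, "x3": 0.6, "x4": 0.0, "x5": 0.0}
        sg = SubgroupSpec(
            name="only",
            continuous={f: (0.0, 1.0, -5.0, 5.0) for f in betas},
            counts={},
            categorical={},
            effects=tuple(Effect(f, b) for f, b in betas.items() if b != 0),
            weibull_shape=1.0,
            weibull_scale=8.0,
        )
        config = SimConfig(
            n=2000, mixing=(1.0,), subgroups=(sg,), censor_rate=0.05,
            admin_horizon=12.0, seed=4,
        )
        cohort = simulate_cohort(config)
        spec = pcube.fit_encoding(cohort)
        fm = pcube.transform(cohort, spec)
        model = mtlr.fit(fm.values, cohort, c1=5.0, c2=20.0, feature_names=fm.feature_names)
        net = model.theta.sum(axis=0)
        for f, b in betas.items():
            if abs(b) >= 0.5:
                j = fm.feature_names.index(f)
                assert np.sign(net[j]) == np.sign(b)

    def test_training_discrimination_beats_random(self, preset_cohort, preset_encoded):
        from pcube.evaluate import c_index

        spec, fm = preset_encoded
        model = mtlr.fit(fm.values, preset_cohort, c1=5.0, c2=20.0)
        scores = risk_score(model, fm.values)
        assert c_index(scores, preset_cohort.time, preset_cohort.event) >= 0.65
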