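import numpy as np
import pandas as pd
import pytest

import pcube
from pcube.evaluate import (
    EvaluationError,
    bootstrap_ci,
    brier,
    c_index,
    compare_models,
    fit_baseline,
    km_censoring,
    perturbation_stability,
)
from .conftest import make_cohort


def c_index_brute(scores, times, events):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brier_brute(pred, horizon, times, events):
    G = km_censoring(times, events)
    total = 0.0
    for i in range(len(times)):
        if times[i] <= horizon and events[i] == 1:
            total += (0.0 - pred[i]) ** 2 / float(G.at_left(times[i]))
        elif times[i] > horizon:
            total += (1.0 - pred[i]) ** 2 / float(G.at(horizon))
    return total / len(times)


class TestCIndex:
    def test_perfect_ranking(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        scores = -times  # higher risk fails earlier
        assert c_index(scores, times, np.ones(4, int)) == 1.0

    def test_all_tied_scores(self):
        times = np.array([1.0, 2.0, 3.0])
        assert c_index(np.zeros(3), times, np.ones(3, int)) == 0.5

    def test_reversal_maps_to_complement(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1, 10, 20)
        scores = rng.normal(size=20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        c = c_index(scores, times, events)
        assert c_index(-scores, times, events) == pytest.approx(1 - c, abs=1e-12)

    def test_matches_brute_force_on_random_censored_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 30
            times = np.round(rng.uniform(1, 10, n), 1)  # induce time ties
            events = rng.integers(0, 2, n)
            events[rng.integers(0, n)] = 1
            scores = np.round(rng.normal(size=n), 1)  # induce score ties
            assert c_index(scores, times, events) == c_index_brute(scores, times, events)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(2)
        n = 80
        times = rng.uniform(1, 10, n)
        events = rng.integers(0, 2, n).astype(bool)
        events[0] = True
        scores = rng.normal(size=n)
        ours = c_index(scores, times, events.astype(int))
        theirs = concordance_index_censored(events, times, scores)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestKMCensoring:
    def test_no_censoring_gives_unit_G(self):
        G = km_censoring(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert float(G.at(100.0)) == 1.0

    def test_all_censored_at_two(self):
        G = km_censoring(np.array([2.0, 2.0]), np.array([0, 0]))
        assert float(G.at(1.9)) == 1.0
        assert float(G.at(2.0)) == 0.0
        assert float(G.at_left(2.0)) == 1.0

    def test_hand_computed_product_limit(self):
        # censoring events at t=2 (1 of 4 at risk) and t=4 (1 of 2 at risk)
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 0, 1, 0, 1])
        G = km_censoring(times, events)
        assert float(G.at(2.5)) == pytest.approx(3 / 4)
        assert float(G.at(4.5)) == pytest.approx(3 / 4 * 1 / 2)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        times = rng.uniform(0.5, 10, 60)
        events = rng.integers(0, 2, 60)
        G = km_censoring(times, events)
        km = KaplanMeierFitter().fit(times, 1 - events)
        for t in [1.0, 3.0, 6.0, 9.0]:
            assert float(G.at(t)) == pytest.approx(float(km.predict(t)), abs=1e-12)


class TestBrier:
    def test_perfect_deterministic_predictions(self):
        times = np.array([1.0, 2.0, 8.0, 9.0])
        events = np.array([1, 1, 1, 1])
        pred = np.array([0.0, 0.0, 1.0, 1.0])  # S_hat(5) matching outcomes
        assert brier(pred, 5.0, times, events) == 0.0

    def test_constant_half_prediction_quarter(self):
        times = np.array([1.0, 2.0, 8.0, 9.0])
        events = np.array([1, 1, 1, 1])
        assert brier(np.full(4, 0.5), 5.0, times, events) == pytest.approx(0.25)

    def test_ipcw_reduces_to_mse_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(1, 10, 50)
        events = np.ones(50, int)
        pred = rng.uniform(size=50)
        with_w = brier(pred, 5.0, times, events, ipcw=True)
        without = brier(pred, 5.0, times, events, ipcw=False)
        assert with_w == pytest.approx(without, abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 40
            times = rng.uniform(0.5, 10, n)
            events = rng.integers(0, 2, n)
            pred = rng.uniform(size=n)
            ours = brier(pred, 5.0, times, events)
            assert ours == pytest.approx(brier_brute(pred, 5.0, times, events), abs=1e-12)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda idx: 0.7, n=50, B=100, seed=0)
        assert (lo, hi) == (0.7, 0.7)

    def test_point_estimate_within_interval(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        lo, hi = bootstrap_ci(lambda idx: float(x[idx].mean()), n=200, B=200, seed=1)
        assert lo <= x.mean() <= hi

    def test_interval_width_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        widths = {}
        for n in (100, 1000):
            ws = []
            for seed in range(3):
                x = rng.normal(size=n)
                lo, hi = bootstrap_ci(lambda idx: float(x[idx].mean()), n=n, B=150, seed=seed)
                ws.append(hi - lo)
            widths[n] = np.mean(ws)
        assert widths[1000] < widths[100]


class TestBaseline:
    def test_planted_hazard_ratio_sign_recovered(self):
        from pcube.simulate import Effect, SimConfig, SubgroupSpec, simulate_cohort

        sg = SubgroupSpec(
            name="only", continuous={"x": (0.0, 1.0, -5.0, 5.0)}, counts={},
            categorical={"g": (["0", "1"], [0.5, 0.5])},
            effects=(Effect("g", beta=1.5, level="1"),),
            weibull_shape=1.0, weibull_scale=8.0,
        )
        cohort = simulate_cohort(SimConfig(
            n=800, mixing=(1.0,), subgroups=(sg,), censor_rate=0.05,
            admin_horizon=12.0, seed=8,
        ))
        spec = pcube.fit_encoding(cohort)
        baseline = fit_baseline(cohort, spec, penalizer=0.01)
        assert baseline.coefs["g=1"] > 0.5

    def test_risk_ordering_invariant_to_affine_rescaling(self, preset_cohort):
        spec = pcube.fit_encoding(preset_cohort)
        fm = pcube.transform(preset_cohort, spec)
        baseline = fit_baseline(preset_cohort, spec)
        scores = baseline.risk_scores(fm.values)
        # rescaling a raw covariate leaves z-scores, hence the ordering, unchanged
        rescaled = preset_cohort.data.copy()
        rescaled["donor_age"] = rescaled["donor_age"] * 12.0 + 7.0
        from pcube.cohort import CohortTable

        cohort2 = CohortTable(rescaled, preset_cohort.schema)
        spec2 = pcube.fit_encoding(cohort2)
        fm2 = pcube.transform(cohort2, spec2)
        baseline2 = fit_baseline(cohort2, spec2)
        scores2 = baseline2.risk_scores(fm2.values)
        assert (np.argsort(scores) == np.argsort(scores2)).all()


class TestCompareModels:
    def test_leakage_detected_by_id(self, preset_cohort):
        from pcube.pipeline import RunConfig, fit_pcube

        config = RunConfig(seed=0, k_min=2, k_max=3, kmeans_restarts=2, bootstrap_B=100)
        model = fit_pcube(preset_cohort, config)
        baseline = fit_baseline(preset_cohort, model.encoding)
        with pytest.raises(EvaluationError, match="overlap"):
            compare_models(
                model, baseline, preset_cohort, derivation_ids=preset_cohort.ids, B=100
            )

    def test_evaluation_deterministic(self, preset_cohort):
        from pcube.pipeline import RunConfig, run_pipeline

        config = RunConfig(seed=3, k_min=2, k_max=3, kmeans_restarts=2, bootstrap_B=100)
        r1 = run_pipeline(preset_cohort, config)
        r2 = run_pipeline(preset_cohort, config)
        assert r1.report.to_dict() == r2.report.to_dict()


class TestPerturbationStability:
    def test_constant_predictions_flagged_degenerate(self, preset_cohort):
        from pcube.mtlr import MTLRModel, TimeGrid
        from pcube.pipeline import RunConfig, fit_pcube

        config = RunConfig(seed=1, k_min=2, k_max=3, kmeans_restarts=2)
        model = fit_pcube(preset_cohort, config)
        for lab in model.subgroup_models:
            old = model.subgroup_models[lab]
            # single-point zero model: S = 1/2 for every patient and time
            model.subgroup_models[lab] = MTLRModel(
                TimeGrid(np.array([5.0])), np.zeros((1, old.p)), np.zeros(1),
                feature_names=old.feature_names,
            )

        res = perturbation_stability(
            preset_cohort, lambda c, k: model, original_model=model,
            fraction=0.8, seed=0,
        )
        assert res.degenerate
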