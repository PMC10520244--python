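"""Model evaluation: Harrell's C-index, IPCW Brier score, pooled Cox
baseline, bootstrap intervals, and the perturbation stability analysis.

The C-index follows Harrell's convention: a pair (i, j) is comparable when
t_i < t_j and patient i had the event; it is concordant when the
earlier-failing patient carries the higher risk score, score ties count
one half, and pairs tied on time with both events are incomparable.

The Brier score at horizon t* uses Graf-style inverse probability of
censoring weights: a patient with an event before t* contributes
(0 - S_hat(t*))^2 / G(T-), a patient still at risk past t* contributes
(1 - S_hat(t*))^2 / G(t*), and a patient censored before t* contributes
nothing; G is the Kaplan-Meier estimate of the censoring distribution.

The "classical regression" comparator is a single ridge-stabilized Cox
proportional-hazards model fit on the pooled encoded cohort (lifelines),
ignoring subgroup structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sstats
from scipy.optimize import linear_sum_assignment

from .cohort import CohortTable, EVENT_COL, TIME_COL
from .preprocess import EncodingSpec, transform


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def c_index(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance index (higher score must mean earlier event)."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = scores.size
    if n < 2 or events.sum() < 1:
        raise EvaluationError("need at least two patients and one event")
    # comparable: t_i < t_j with event_i; vectorized over ordered pairs
    ti = times[:, None]
    tj = times[None, :]
    ei = events[:, None].astype(bool)
    comparable = (ti < tj) & ei
    si = scores[:, None]
    sj = scores[None, :]
    concordant = comparable & (si > sj)
    tied = comparable & (si == sj)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise EvaluationError("no comparable pairs (all times tied or no events first)")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Censoring Kaplan-Meier and Brier score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Right-continuous product-limit step function with G(0) = 1."""

    times: np.ndarray  # ordered distinct event times of the step function
    survival: np.ndarray  # G(t) just after each time

    def at(self, t) -> np.ndarray:
        """G(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]

    def at_left(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]


def km_censoring(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier estimate of the censoring distribution G (censoring is
    the 'event'; observed failures are treated as censored observations)."""
    times = np.asarray(times, dtype=float)
    cens = 1 - np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    c_sorted = cens[order]
    n = len(times)
    uniq = np.unique(t_sorted[c_sorted == 1])
    surv = []
    g = 1.0
    for u in uniq:
        at_risk = np.sum(t_sorted >= u)
        d = np.sum((t_sorted == u) & (c_sorted == 1))
        g *= 1.0 - d / at_risk
        surv.append(g)
    return KMEstimate(times=uniq, survival=np.asarray(surv, dtype=float))


def brier(
    pred_surv: np.ndarray,
    horizon: float,
    times: np.ndarray,
    events: np.ndarray,
    ipcw: bool = True,
) -> float:
    """Brier score at ``horizon`` for predicted survival probabilities.

    ``pred_surv`` holds S_hat(horizon) per patient.  With ``ipcw`` (default)
    the Graf weights above apply; without it, the unweighted mean squared
    error over patients whose status at the horizon is known.
    """
    pred_surv = np.asarray(pred_surv, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    died = (times <= horizon) & (events == 1)
    at_risk = times > horizon
    if ipcw:
        G = km_censoring(times, events)
        g_event = G.at_left(times[died])
        g_horizon = float(G.at(horizon))
        if np.any(g_event <= 0) or (at_risk.any() and g_horizon <= 0):
            raise EvaluationError(
                "censoring survival G is zero at a required time; use an earlier horizon"
            )
        total = np.sum((0.0 - pred_surv[died]) ** 2 / g_event)
        total += np.sum((1.0 - pred_surv[at_risk]) ** 2) / g_horizon
        return float(total / n)
    known = died | at_risk
    if not known.any():
        raise EvaluationError("no patient has known status at the horizon")
    outcome = at_risk[known].astype(float)  # 1 = survived past horizon
    return float(np.mean((outcome - pred_surv[known]) ** 2))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    metric: Callable[[np.ndarray], float],
    n: int,
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric`` over patient-level resamples.

    ``metric`` receives an index array into the cohort.  Resamples on which
    the metric is undefined are redrawn (at most 10 retries each, logged).
    """
    if B < 100:
        raise EvaluationError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = metric(idx)
                break
            except EvaluationError:
                if attempt == 9:
                    raise
                warnings.warn("metric undefined on a bootstrap resample; redrawing")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Pooled Cox baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineCoxModel:
    """Pooled proportional-hazards comparator (no subgroup structure)."""

    encoding: EncodingSpec
    fitter: CoxPHFitter
    feature_names: tuple[str, ...]

    def risk_scores(self, X_encoded: np.ndarray) -> np.ndarray:
        df = pd.DataFrame(np.atleast_2d(X_encoded), columns=list(self.feature_names))
        return self.fitter.predict_partial_hazard(df).to_numpy(dtype=float)

    def survival_probabilities(self, X_encoded: np.ndarray, times: Sequence[float]) -> np.ndarray:
        df = pd.DataFrame(np.atleast_2d(X_encoded), columns=list(self.feature_names))
        sf = self.fitter.predict_survival_function(df, times=np.asarray(times, dtype=float))
        return sf.to_numpy().T  # (n, len(times))

    @property
    def coefs(self) -> pd.Series:
        return self.fitter.params_


def fit_baseline(
    cohort: CohortTable,
    encoding: EncodingSpec,
    penalizer: float = 0.1,
) -> BaselineCoxModel:
    """Fit the ridge-stabilized pooled Cox model on the encoded cohort."""
    fm = transform(cohort, encoding)
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    df[TIME_COL] = cohort.time
    df[EVENT_COL] = cohort.event
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col=TIME_COL, event_col=EVENT_COL)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise EvaluationError(f"pooled Cox baseline failed to converge: {exc}") from exc
    return BaselineCoxModel(encoding=encoding, fitter=cph, feature_names=fm.feature_names)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class MetricWithCI:
    value: float
    ci_lower: float
    ci_upper: float

    def to_dict(self) -> dict[str, float]:
        return {"value": self.value, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}


@dataclass
class EvalReport:
    pcube_c_index: MetricWithCI
    baseline_c_index: MetricWithCI
    pcube_brier: dict[float, float]
    baseline_brier: dict[float, float]
    per_subgroup: dict[int, dict[str, Any]]
    n_validation: int
    config: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "pcube_c_index": self.pcube_c_index.to_dict(),
            "baseline_c_index": self.baseline_c_index.to_dict(),
            "pcube_brier": {str(k): v for k, v in self.pcube_brier.items()},
            "baseline_brier": {str(k): v for k, v in self.baseline_brier.items()},
            "per_subgroup": {str(k): v for k, v in self.per_subgroup.items()},
            "n_validation": self.n_validation,
            "config": self.config,
        }


def _c_with_ci(scores, times, events, B, seed) -> MetricWithCI:
    point = c_index(scores, times, events)

    def metric(idx: np.ndarray) -> float:
        return c_index(scores[idx], times[idx], events[idx])

    lo, hi = bootstrap_ci(metric, n=len(times), B=B, seed=seed)
    return MetricWithCI(point, lo, hi)


def compare_models(
    pcube,
    baseline: BaselineCoxModel,
    validation: CohortTable,
    horizons: Sequence[float] = (5.0, 10.0),
    derivation_ids: np.ndarray | None = None,
    B: int = 200,
    seed: int = 0,
) -> EvalReport:
    """Head-to-head evaluation of the precision pathway vs the pooled model
    on an independent validation cohort (leakage checked by patient id)."""
    if derivation_ids is not None:
        overlap = set(map(str, derivation_ids)) & set(map(str, validation.ids))
        if overlap:
            raise EvaluationError(
                f"validation cohort overlaps derivation by {len(overlap)} patient ids"
            )
    fm = transform(validation, pcube.encoding)
    times = validation.time
    events = validation.event

    pc_scores = pcube.risk_scores(fm.values)
    bl_scores = baseline.risk_scores(fm.values)
    pc_c = _c_with_ci(pc_scores, times, events, B, seed)
    bl_c = _c_with_ci(bl_scores, times, events, B, seed + 1)

    pc_surv = pcube.survival_probabilities(fm.values, horizons)
    bl_surv = baseline.survival_probabilities(fm.values, horizons)
    pc_brier = {}
    bl_brier = {}
    for j, h in enumerate(horizons):
        pc_brier[float(h)] = brier(pc_surv[:, j], float(h), times, events)
        bl_brier[float(h)] = brier(bl_surv[:, j], float(h), times, events)

    per_subgroup: dict[int, dict[str, Any]] = {}
    routed = pcube.route_matrix(fm.values)
    for lab in np.unique(routed):
        idx = routed == lab
        entry: dict[str, Any] = {"n": int(idx.sum())}
        try:
            entry["pcube_c_index"] = c_index(pc_scores[idx], times[idx], events[idx])
            entry["baseline_c_index"] = c_index(bl_scores[idx], times[idx], events[idx])
        except EvaluationError as exc:
            entry["error"] = str(exc)
        per_subgroup[int(lab)] = entry

    return EvalReport(
        pcube_c_index=pc_c,
        baseline_c_index=bl_c,
        pcube_brier=pc_brier,
        baseline_brier=bl_brier,
        per_subgroup=per_subgroup,
        n_validation=len(validation),
        config={"horizons": [float(h) for h in horizons], "bootstrap_B": B, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Perturbation stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    pearson_r: float
    degenerate: bool
    n_pairs: int
    scatter: pd.DataFrame  # columns: patient_id, time, original, perturbed
    subgroup_mapping: dict[int, int]  # perturbed label -> matched original label


def align_subgroups(
    original_centroids: np.ndarray,
    original_labels: np.ndarray,
    perturbed_centroids: np.ndarray,
    perturbed_labels: np.ndarray,
) -> dict[int, int]:
    """Hungarian matching of perturbed subgroup centroids to the original."""
    d = np.linalg.norm(
        perturbed_centroids[:, None, :] - original_centroids[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(d)
    return {int(perturbed_labels[r]): int(original_labels[c]) for r, c in zip(rows, cols)}


def perturbation_stability(
    cohort: CohortTable,
    fit_fn: Callable[[CohortTable, int | None], Any],
    original_model=None,
    fraction: float = 0.8,
    seed: int = 0,
) -> StabilityResult:
    """Refit the full pipeline on a random subsample and correlate predictions.

    ``fit_fn(cohort, K_override)`` must fit and return a PCubeModel; the
    perturbed refit keeps K fixed to the original model's subgroup count so
    the correlation measures parameter stability rather than K-selection
    variance.  Both models' survival probabilities are evaluated at the
    original model's per-subgroup grids for every patient in the original
    cohort, and the Pearson correlation over all (patient, time) pairs is
    returned along with the scatter data.
    """
    if not (0 < fraction <= 1):
        raise EvaluationError("fraction must lie in (0, 1]")
    if original_model is None:
        original_model = fit_fn(cohort, None)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=int(np.floor(fraction * n)), replace=False))
    perturbed_model = fit_fn(cohort.subset(keep), len(original_model.labels))

    mapping = align_subgroups(
        original_model.centroids,
        original_model.centroid_labels,
        perturbed_model.centroids,
        perturbed_model.centroid_labels,
    )

    fm = transform(cohort, original_model.encoding)
    routed = original_model.route_matrix(fm.values)
    rows = []
    for lab in np.unique(routed):
        idx = np.flatnonzero(routed == lab)
        grid = original_model.subgroup_models[int(lab)].grid.points
        orig = original_model.survival_probabilities(fm.values[idx], grid)
        pert = perturbed_model.survival_probabilities(fm.values[idx], grid)
        for i, row_i in enumerate(idx):
            for j, t in enumerate(grid):
                rows.append((cohort.ids[row_i], float(t), float(orig[i, j]), float(pert[i, j])))
    scatter = pd.DataFrame(rows, columns=["patient_id", "time", "original", "perturbed"])
    x = scatter["original"].to_numpy()
    y = scatter["perturbed"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return StabilityResult(
            pearson_r=np.nan, degenerate=True, n_pairs=len(x), scatter=scatter,
            subgroup_mapping=mapping,
        )
    # identical prediction vectors have correlation 1 by definition; computing
    # it via pearsonr would lose an ulp to floating-point square roots
    r = 1.0 if np.array_equal(x, y) else float(sstats.pearsonr(x, y).statistic)
    return StabilityResult(
        pearson_r=r, degenerate=False, n_pairs=len(x), scatter=scatter,
        subgroup_mapping=mapping,
    )
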