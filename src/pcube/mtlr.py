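"""Multi-task logistic regression (MTLR) for discrete-time survival.

MTLR places a separate logistic score g_j(x) = theta_j . x + b_j at each of
m time-grid points t_1 < ... < t_m and models the joint distribution over
the m+1 *legal* (monotone) event-indicator sequences s_k: sequence s_k has
y_j = 1 exactly for j >= k, i.e. the event falls in the interval
(t_{k-1}, t_k]; s_{m+1} is the all-zero "survived past t_m" sequence.  The
sequence score is the suffix sum

    f_k(x) = sum_{j=k}^{m} g_j(x),        f_{m+1}(x) = 0

and P(s_k | x) = exp(f_k) / Z(x) with Z = sum_k exp(f_k).  The survival
function at a grid point is a tail sum, S(t_j | x) = sum_{k>j} P(s_k | x),
which makes monotonicity automatic.

An uncensored patient with event time T contributes the single sequence
k(T) = min{j : t_j >= T} (or m+1 when T > t_m).  A patient censored at c
contributes the marginal likelihood of every sequence consistent with
"no event up to c": all s_k with y_j = 0 for every t_j <= c, which is the
suffix {k0, ..., m+1} with k0 = #{j : t_j <= c} + 1.

The fitted objective is the negative log-likelihood plus a ridge penalty
(C1/2) sum_j ||theta_j||^2 and a temporal-smoothness penalty
(C2/2) sum_j ||theta_{j+1} - theta_j||^2 (biases unpenalized), minimized
by L-BFGS from zero initialization.  All log-sum-exp computations are
max-shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.optimize import minimize

from .cohort import CohortTable


class MTLRError(ValueError):
    pass


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing positive time points (years)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise MTLRError("time grid must be a non-empty 1-d array")
        if not (np.all(pts > 0) and np.all(np.diff(pts) > 0)):
            raise MTLRError("time grid must be strictly increasing and positive")
        object.__setattr__(self, "points", pts)

    @property
    def m(self) -> int:
        return int(self.points.size)


def make_grid(cohort: CohortTable, m: int | str = "auto") -> TimeGrid:
    """Event-time quantile grid: quantiles at (1..m)/(m+1), de-duplicated.

    ``m="auto"`` uses ceil(sqrt(#events)), capped at 50.
    """
    event_times = cohort.time[cohort.event == 1]
    if event_times.size == 0:
        raise MTLRError("cannot build a time grid: no observed events")
    if m == "auto":
        m_int = min(50, int(np.ceil(np.sqrt(event_times.size))))
    else:
        m_int = int(m)
        if m_int < 1:
            raise MTLRError("m must be >= 1")
    qs = np.arange(1, m_int + 1) / (m_int + 1)
    pts = np.quantile(event_times, qs)
    return TimeGrid(np.unique(pts))


@dataclass(frozen=True)
class Targets:
    """Per-patient likelihood targets on a grid.

    ``first_k`` holds, 1-based, the single sequence index for an uncensored
    patient, or the first admissible sequence index for a censored patient
    (the admissible set is always the suffix {first_k .. m+1}).
    """

    first_k: np.ndarray  # (n,) int, 1-based
    is_event: np.ndarray  # (n,) bool
    m: int


def encode_targets(cohort: CohortTable, grid: TimeGrid) -> Targets:
    t = grid.points
    m = grid.m
    times = cohort.time
    events = cohort.event.astype(bool)
    # uncensored: k(T) = min{j : t_j >= T}, m+1 if T > t_m
    k_event = np.searchsorted(t, times, side="left") + 1  # 1-based
    # censored at c: first admissible k = #{j : t_j <= c} + 1
    k_cens = np.searchsorted(t, times, side="right") + 1
    first_k = np.where(events, k_event, k_cens).astype(int)
    first_k = np.minimum(first_k, m + 1)
    return Targets(first_k=first_k, is_event=events, m=m)


def _sequence_scores(X: np.ndarray, theta: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """F[:, k-1] = f_k(x) for k = 1..m+1 (suffix sums of g, last column 0)."""
    G = X @ theta.T + bias  # (n, m)
    F = np.zeros((X.shape[0], G.shape[1] + 1))
    F[:, :-1] = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    return F


def neg_log_likelihood(
    theta: np.ndarray,
    bias: np.ndarray,
    X: np.ndarray,
    targets: Targets,
    c1: float,
    c2: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalized NLL with analytic gradients (d/dtheta, d/dbias).

    The per-patient term is  logsumexp(f over admissible suffix) - log Z,
    which for an uncensored patient reduces to f_{k(i)} - log Z.
    """
    if not (np.isfinite(theta).all() and np.isfinite(bias).all() and np.isfinite(X).all()):
        raise MTLRError("non-finite input to the MTLR objective")
    n, p = X.shape
    m = targets.m
    F = _sequence_scores(X, theta, bias)  # (n, m+1)
    shift = F.max(axis=1, keepdims=True)
    E = np.exp(F - shift)
    Z = E.sum(axis=1)
    logZ = np.log(Z) + shift[:, 0]
    cols = targets.first_k - 1
    rows = np.arange(n)
    ev = targets.is_event
    # uncensored: the single sequence f_{k(i)};
    # censored: logsumexp over the admissible suffix {first_k .. m+1}
    suffix = np.cumsum(E[:, ::-1], axis=1)[:, ::-1]  # suffix[:, k-1] = sum_{k'>=k} e^{f-shift}
    ll = np.where(
        ev,
        F[rows, cols] - logZ,
        np.log(suffix[rows, cols]) + shift[:, 0] - logZ,
    )
    nll = -float(np.sum(ll))

    # gradient wrt g_j: d_i,j = cumP_j - target_j with
    # target_j = 1{j >= k(i)} (uncensored) or the admissible-posterior mass
    # sum_{k in adm, k <= j} Q_k (censored)
    P = E / Z[:, None]  # (n, m+1)
    cumP = np.cumsum(P[:, :m], axis=1)  # cum over k=1..j
    jgrid = np.arange(1, m + 1)[None, :]
    Q = E / suffix[rows, cols][:, None]  # posterior over the admissible suffix
    Qmasked = Q[:, :m].copy()
    Qmasked[jgrid < targets.first_k[:, None]] = 0.0
    cumT_cens = np.cumsum(Qmasked, axis=1)
    cumT_event = (jgrid >= targets.first_k[:, None]).astype(float)
    cumT = np.where(ev[:, None], cumT_event, cumT_cens)
    D = cumP - cumT  # (n, m)

    grad_theta = D.T @ X
    grad_bias = D.sum(axis=0)

    # penalties (theta only)
    nll += 0.5 * c1 * float(np.sum(theta * theta))
    grad_theta += c1 * theta
    if m > 1 and c2 > 0:
        diff = np.diff(theta, axis=0)  # theta_{j+1} - theta_j
        nll += 0.5 * c2 * float(np.sum(diff * diff))
        lap = np.zeros_like(theta)
        lap[:-1] -= diff
        lap[1:] += diff
        grad_theta += c2 * lap
    return float(nll), grad_theta, grad_bias


@dataclass
class MTLRModel:
    """Fitted MTLR: time grid, m x p weight matrix, length-m bias."""

    grid: TimeGrid
    theta: np.ndarray
    bias: np.ndarray
    c1: float = 1.0
    c2: float = 1.0
    feature_names: tuple[str, ...] = ()
    fit_info: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        m = self.grid.m
        if self.theta.shape[0] != m or self.bias.shape != (m,):
            raise MTLRError("theta/bias dimensions inconsistent with the grid")

    @property
    def m(self) -> int:
        return self.grid.m

    @property
    def p(self) -> int:
        return int(self.theta.shape[1])

    def sequence_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n, m+1) matrix of P(s_k | x)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise MTLRError(f"expected {self.p} features, got {X.shape[1]}")
        F = _sequence_scores(X, self.theta, self.bias)
        F -= F.max(axis=1, keepdims=True)
        E = np.exp(F)
        return E / E.sum(axis=1, keepdims=True)

    def survival_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, m) matrix of S(t_j | x) = tail sums of sequence probabilities."""
        P = self.sequence_probabilities(X)
        tail = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]  # tail[:, k-1] = sum_{k' >= k}
        S = tail[:, 1:]  # S(t_j) = sum_{k >= j+1}
        return np.clip(S, 0.0, 1.0)

    def to_dict(self) -> dict[str, Any]:
        return {
            "grid": self.grid.points.tolist(),
            "theta": self.theta.tolist(),
            "bias": self.bias.tolist(),
            "c1": self.c1,
            "c2": self.c2,
            "feature_names": list(self.feature_names),
            "fit_info": {k: v for k, v in self.fit_info.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MTLRModel":
        return cls(
            grid=TimeGrid(np.asarray(d["grid"], dtype=float)),
            theta=np.asarray(d["theta"], dtype=float),
            bias=np.asarray(d["bias"], dtype=float),
            c1=float(d["c1"]),
            c2=float(d["c2"]),
            feature_names=tuple(d.get("feature_names", ())),
            fit_info=dict(d.get("fit_info", {})),
        )


def fit(
    X: np.ndarray,
    cohort: CohortTable,
    grid: TimeGrid | None = None,
    c1: float = 1.0,
    c2: float = 1.0,
    m: int | str = "auto",
    tol: float = 1e-5,
    max_iter: int = 500,
    feature_names: tuple[str, ...] = (),
) -> MTLRModel:
    """Fit MTLR by L-BFGS from zero initialization.

    Non-convergence never fails silently: the returned model carries
    ``fit_info["converged"]`` and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if c1 <= 0:
        raise MTLRError("ridge strength c1 must be positive")
    if n < p:
        warnings.warn(f"fewer patients ({n}) than features ({p}); fit may be unstable")
    if grid is None:
        grid = make_grid(cohort, m=m)
    targets = encode_targets(cohort, grid)
    mm = grid.m

    def pack(theta: np.ndarray, bias: np.ndarray) -> np.ndarray:
        return np.concatenate([theta.ravel(), bias])

    def unpack(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return w[: mm * p].reshape(mm, p), w[mm * p :]

    def obj(w: np.ndarray) -> tuple[float, np.ndarray]:
        theta, bias = unpack(w)
        val, gt, gb = neg_log_likelihood(theta, bias, X, targets, c1, c2)
        return val, pack(gt, gb)

    w0 = np.zeros(mm * p + mm)
    res = minimize(
        obj,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol},
    )
    theta, bias = unpack(res.x)
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or gnorm <= tol)
    if not converged:
        warnings.warn(f"MTLR fit did not converge: {res.message} (|grad|_inf={gnorm:.3g})")
    return MTLRModel(
        grid=grid,
        theta=theta,
        bias=bias,
        c1=c1,
        c2=c2,
        feature_names=tuple(feature_names),
        fit_info={
            "objective": float(res.fun),
            "iterations": int(res.nit),
            "grad_inf_norm": gnorm,
            "converged": converged,
        },
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Monotone survival probabilities on a grid, with S(0) = 1 implicit.

    Between grid points the curve is evaluated by linear interpolation
    through (0, 1), (t_1, S_1), ..., (t_m, S_m); beyond t_m it is extended
    as the constant S_m.
    """

    grid: TimeGrid
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (self.grid.m,):
            raise MTLRError("curve length does not match its grid")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise MTLRError("survival probabilities outside [0, 1]")
        if np.any(np.diff(probs) > 1e-12):
            raise MTLRError("survival probabilities must be non-increasing")
        object.__setattr__(self, "probs", np.clip(probs, 0.0, 1.0))

    def __call__(self, t) -> np.ndarray | float:
        return survival_at(self, t)


def predict_curve(model: MTLRModel, x: np.ndarray) -> SurvivalCurve:
    S = model.survival_matrix(np.atleast_2d(x))[0]
    S = np.minimum.accumulate(S)  # guard against float jitter
    return SurvivalCurve(grid=model.grid, probs=S)


def survival_at(curve: SurvivalCurve, t) -> np.ndarray | float:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise MTLRError("survival requested at negative time")
    xp = np.concatenate([[0.0], curve.grid.points])
    fp = np.concatenate([[1.0], curve.probs])
    out = np.interp(t_arr, xp, fp)  # np.interp right-extends with fp[-1]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def risk_score(model: MTLRModel, X: np.ndarray, horizon: float | None = None) -> np.ndarray:
    """Scalar risk = negative trapezoidal area under the survival curve.

    Integration runs over [0, horizon] (default: the last grid point) with
    the implicit point (0, 1) and constant extension beyond the grid.
    Higher scores mean higher risk, and stochastically ordered curves yield
    ordered scores.  When scores from different models are compared (e.g.
    across routed subgroups), pass a shared ``horizon`` so the areas are
    taken over a common time range.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = model.survival_matrix(X)
    xp = np.concatenate([[0.0], model.grid.points])
    fp = np.concatenate([np.ones((S.shape[0], 1)), S], axis=1)
    if horizon is not None and horizon > xp[-1]:
        xp = np.concatenate([xp, [horizon]])
        fp = np.concatenate([fp, fp[:, -1:]], axis=1)
    area = np.trapezoid(fp, xp, axis=1)
    return -area
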