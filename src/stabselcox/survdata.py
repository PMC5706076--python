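"""Core survival-data containers and the quantities that anchor the lasso path.

The Cox proportional-hazards model relates a covariate vector x to the hazard
rate through h(t | x) = h0(t) exp(x' beta).  With right-censored observations
(y_i, x_i, delta_i) the coefficient vector is estimated from Breslow's partial
likelihood, which conditions on the observed failure ordering and eliminates
the baseline hazard h0.

This module provides

* :class:`SurvivalDataset` -- the universal input container,
* :func:`build_failure_index` -- unique failure times and their risk sets,
* :func:`neg_log_partial_likelihood` -- the (Breslow) negative log partial
  likelihood, stabilised with log-sum-exp,
* :func:`compute_working_response` -- the null-model working response
  (martingale-residual scores) used to locate the top of the lasso path,
* :func:`compute_lambda_upper` -- the smallest penalty at which the lasso-Cox
  active set is empty,
* :func:`make_lambda_grid` -- the geometric candidate grid on
  [eps * lambda_upper, lambda_upper].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "FailureTimeIndex",
    "WorkingResponse",
    "RegularizationGrid",
    "build_failure_index",
    "neg_log_partial_likelihood",
    "partial_likelihood_gradient",
    "compute_working_response",
    "compute_lambda_upper",
    "make_lambda_grid",
    "read_survival_csv",
    "write_survival_csv",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data: covariates, follow-up times, event flags.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric covariate matrix.
    times : ndarray of shape (n,)
        Strictly positive survival or censoring times.
    events : ndarray of shape (n,)
        Event indicators; 1 = observed failure, 0 = right-censored.  At least
        one event is required (the partial likelihood is undefined otherwise).
    """

    X: np.ndarray
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        times = np.asarray(self.times, dtype=float).ravel()
        events = np.asarray(self.events).ravel().astype(np.int8)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if not (len(times) == len(events) == X.shape[0]):
            raise ValueError(
                f"inconsistent lengths: X has {X.shape[0]} rows, "
                f"{len(times)} times, {len(events)} event flags"
            )
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all times must be finite and strictly positive")
        if not np.all((events == 0) | (events == 1)):
            raise ValueError("event flags must be 0 or 1")
        if events.sum() < 1:
            raise ValueError(
                "dataset contains no observed events; the Cox partial "
                "likelihood is undefined"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset (used for subsampling and cross-validation folds)."""
        idx = np.asarray(idx)
        return SurvivalDataset(self.X[idx], self.times[idx], self.events[idx])

    @property
    def variable_names(self) -> list[str]:
        """1-based names ``x1 .. xp`` used in all reports."""
        return [f"x{j + 1}" for j in range(self.p)]


@dataclass(frozen=True)
class FailureTimeIndex:
    """Unique failure times t_1 < ... < t_m with their risk sets.

    ``risk_sets[i]`` holds the indices j with y_j >= t_i (still under
    observation just before t_i); ``failer_index[i]`` the observations that
    fail at t_i (more than one only under ties, handled by Breslow's
    approximation downstream).
    """

    failure_times: np.ndarray
    failer_index: list[np.ndarray]
    risk_sets: list[np.ndarray]

    @property
    def m(self) -> int:
        return len(self.failure_times)


def build_failure_index(dataset: SurvivalDataset) -> FailureTimeIndex:
    """Enumerate unique failure times, failing observations and risk sets.

    Risk sets use the non-strict rule y_j >= t_i, so an observation censored
    exactly at a failure time still counts as at risk there.
    """
    times, events = dataset.times, dataset.events
    failure_times = np.unique(times[events == 1])
    failer_index = [
        np.flatnonzero((times == t) & (events == 1)) for t in failure_times
    ]
    risk_sets = [np.flatnonzero(times >= t) for t in failure_times]
    return FailureTimeIndex(failure_times, failer_index, risk_sets)


def neg_log_partial_likelihood(
    dataset: SurvivalDataset, beta: np.ndarray
) -> float:
    """Negative log Breslow partial likelihood at ``beta``.

    -log L(beta) = sum_i [ d_i * log sum_{j in R_i} exp(x_j' beta)
                           - sum_{k failing at t_i} x_k' beta ],
    where d_i is the number of failures at t_i (Breslow's tie approximation:
    each tied failure contributes the full risk-set denominator).  The inner
    log-sums are evaluated with log-sum-exp stabilisation.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != dataset.p:
        raise ValueError(f"beta must have length p={dataset.p}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite entries")
    eta = dataset.X @ beta
    index = build_failure_index(dataset)
    total = 0.0
    for t_i, failers, risk in zip(
        index.failure_times, index.failer_index, index.risk_sets
    ):
        eta_risk = eta[risk]
        mx = eta_risk.max()
        lse = mx + np.log(np.exp(eta_risk - mx).sum())
        total += len(failers) * lse - eta[failers].sum()
    return float(total)


def partial_likelihood_gradient(
    dataset: SurvivalDataset, beta: np.ndarray
) -> np.ndarray:
    """Gradient of the negative log partial likelihood (Breslow ties)."""
    beta = np.asarray(beta, dtype=float).ravel()
    eta = dataset.X @ beta
    index = build_failure_index(dataset)
    grad = np.zeros(dataset.p)
    for failers, risk in zip(index.failer_index, index.risk_sets):
        w = np.exp(eta[risk] - eta[risk].max())
        w /= w.sum()
        xbar = w @ dataset.X[risk]
        grad += len(failers) * xbar - dataset.X[failers].sum(axis=0)
    return grad


@dataclass(frozen=True)
class WorkingResponse:
    """Null-model working response of the partial likelihood.

    With s_i the number at risk at failure time t_i and C_k the failure times
    preceding observation k's follow-up time, the martingale-residual score of
    observation k at beta = 0 is

        score_k = delta_k - sum_{i in C_k} 1 / s_i,

    and the associated curvature weight is w_k = sum_{i in C_k} (s_i-1)/s_i^2.
    The product w_k z_k (the score) is stored directly, never through the
    ratio z_k = score_k / w_k, so observations with empty C_k are well-defined.
    """

    risk_counts: np.ndarray
    prior_time_sets: list[np.ndarray]
    score: np.ndarray
    weights: np.ndarray


def compute_working_response(
    dataset: SurvivalDataset, strict: bool = False
) -> WorkingResponse:
    """Risk counts s_i, prior-failure sets C_k, scores and weights.

    By default the inclusive convention is used: s_i counts y_j >= t_i and
    C_k = {i : t_i <= y_k}.  It makes the scores the exact negative gradient
    of the partial likelihood at beta = 0 (so scores sum to zero without ties
    and :func:`compute_lambda_upper` satisfies the empty-model KKT property).
    ``strict=True`` switches to the strict inequalities (s_i counts y_j > t_i,
    C_k = {i : t_i < y_k}); terms with s_i = 0, which can arise when the
    largest observed time is a failure, are dropped.
    """
    times, events = dataset.times, dataset.events
    failure_times = np.unique(times[events == 1])
    if strict:
        s = np.array([(times > t).sum() for t in failure_times], dtype=float)
    else:
        s = np.array([(times >= t).sum() for t in failure_times], dtype=float)
    inv_s = np.where(s > 0, 1.0 / np.maximum(s, 1.0), 0.0)
    w_terms = np.where(s > 0, (s - 1.0) * inv_s**2, 0.0)
    cum_inv = np.concatenate([[0.0], np.cumsum(inv_s)])
    cum_w = np.concatenate([[0.0], np.cumsum(w_terms)])
    # number of failure times in C_k for each observation
    side = "left" if strict else "right"
    counts = np.searchsorted(failure_times, times, side=side)
    score = events.astype(float) - cum_inv[counts]
    weights = cum_w[counts]
    prior_time_sets = [np.arange(c) for c in counts]
    return WorkingResponse(
        risk_counts=s.astype(int),
        prior_time_sets=prior_time_sets,
        score=score,
        weights=weights,
    )


def compute_lambda_upper(
    dataset: SurvivalDataset, strict: bool = False
) -> float:
    """Smallest penalty for which the lasso-Cox model is empty.

    lambda_upper = max_j (1/n) | sum_k score_k x_kj |, the largest absolute
    component of the (1/n-scaled) partial-likelihood gradient at beta = 0.
    Under the inclusive convention fitting at any lambda >= lambda_upper
    yields the empty active set (the KKT subgradient condition holds exactly).
    The absolute value makes the maximum well-defined for arbitrary covariate
    signs; the penalty must be positive either way.
    """
    wr = compute_working_response(dataset, strict=strict)
    inner = np.abs(dataset.X.T @ wr.score) / dataset.n
    lam = float(inner.max()) if dataset.p else 0.0
    if lam == 0.0:
        warnings.warn(
            "all covariate/score inner products are zero; lambda_upper = 0 "
            "and the regularization grid is degenerate",
            stacklevel=2,
        )
    return lam


@dataclass(frozen=True)
class RegularizationGrid:
    """Geometric grid of K+1 penalties from lambda_upper down to lambda_lower.

    values[j] = lambda_upper * (lambda_lower/lambda_upper)^(j/K).
    """

    lambda_upper: float
    lambda_lower: float
    values: np.ndarray = field(repr=False)
    epsilon: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)

    def truncate(self, lambda_min: float) -> "RegularizationGrid":
        """Keep candidates >= lambda_min; append lambda_min itself if absent.

        Used when the lower end of the candidate region is fixed externally
        (either a derived value or an explicit numeric override).
        """
        if lambda_min >= self.lambda_upper:
            vals = np.array([self.lambda_upper])
        else:
            vals = self.values[self.values >= lambda_min]
            if not np.isclose(vals[-1], lambda_min):
                vals = np.append(vals, lambda_min)
        return RegularizationGrid(
            lambda_upper=self.lambda_upper,
            lambda_lower=float(vals[-1]),
            values=vals,
            epsilon=float(vals[-1] / self.lambda_upper),
        )

    def truncate_at_index(self, j: int) -> "RegularizationGrid":
        """Keep the first j+1 candidates (largest penalties)."""
        vals = self.values[: j + 1]
        return RegularizationGrid(
            lambda_upper=self.lambda_upper,
            lambda_lower=float(vals[-1]),
            values=vals,
            epsilon=float(vals[-1] / self.lambda_upper),
        )


def make_lambda_grid(
    lambda_upper: float, n: int, p: int, K: int = 100
) -> RegularizationGrid:
    """Geometric penalty grid with the dimension-dependent floor.

    lambda_lower = eps * lambda_upper with eps = 0.05 when n < p and
    eps = 0.0001 when n >= p; the K+1 values interpolate geometrically.
    """
    if lambda_upper <= 0:
        raise ValueError("lambda_upper must be positive")
    if K < 1:
        raise ValueError("K must be at least 1")
    eps = 0.05 if n < p else 0.0001
    j = np.arange(K + 1)
    values = lambda_upper * eps ** (j / K)
    return RegularizationGrid(
        lambda_upper=float(lambda_upper),
        lambda_lower=float(values[-1]),
        values=values,
        epsilon=eps,
    )


def read_survival_csv(path) -> SurvivalDataset:
    """Read the standard CSV layout: header ``time,status,x1,...,xp``."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "time" not in cols or "status" not in cols:
        raise ValueError("CSV must contain 'time' and 'status' columns")
    df.columns = cols
    covars = [c for c in cols if c not in ("time", "status")]
    return SurvivalDataset(
        X=df[covars].to_numpy(dtype=float),
        times=df["time"].to_numpy(dtype=float),
        events=df["status"].to_numpy(),
    )


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    """Write a dataset in the standard ``time,status,x1,...,xp`` layout."""
    df = pd.DataFrame(dataset.X, columns=dataset.variable_names)
    df.insert(0, "status", dataset.events)
    df.insert(0, "time", dataset.times)
    df.to_csv(path, index=False)
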