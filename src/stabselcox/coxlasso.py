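"""L1-penalized Cox partial-likelihood fitting along a penalty grid.

The estimator solves

    min_beta  (1/n) * [-log partial likelihood(beta)] + lam * sum_j |beta_j|

by cyclical coordinate descent on the iteratively reweighted quadratic
approximation of the Breslow partial likelihood (the coxnet algorithm; the
compiled solver from scikit-survival backs the descent loop).  Covariates are
fitted on their original scale, without internal standardisation, so the
penalty stays on the same scale as the null-gradient bound
:func:`~stabselcox.survdata.compute_lambda_upper` and explicit numeric
penalty floors are meaningful.

The unpenalized fit (lam = 0) is obtained by direct Newton-type maximisation
of the partial likelihood instead, since the penalized path solver is not
reliable at a zero penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survdata import (
    RegularizationGrid,
    SurvivalDataset,
    neg_log_partial_likelihood,
    partial_likelihood_gradient,
)

__all__ = [
    "ACTIVE_TOL",
    "CoxLassoPath",
    "fit_coxlasso",
    "fit_path",
    "cv_select_lambda",
    "penalized_objective",
]

#: coefficients with |beta_j| above this count as nonzero (solver tolerance guard)
ACTIVE_TOL = 1e-10


@dataclass(frozen=True)
class CoxLassoPath:
    """Coefficient vectors and active sets along a penalty grid."""

    grid: RegularizationGrid
    coefficients: np.ndarray  # (len(grid), p)
    active_sets: list[np.ndarray]

    def active_sizes(self) -> np.ndarray:
        return np.array([len(a) for a in self.active_sets])

    def to_frame(self):
        """Tidy (lambda, variable, coefficient) table of the path."""
        import pandas as pd

        p = self.coefficients.shape[1]
        return pd.DataFrame(
            {
                "lambda": np.repeat(self.grid.values, p),
                "variable": np.tile(
                    [f"x{j + 1}" for j in range(p)], len(self.grid.values)
                ),
                "coefficient": self.coefficients.ravel(),
            }
        )


def penalized_objective(
    dataset: SurvivalDataset, beta: np.ndarray, lam: float
) -> float:
    """(1/n) negative log partial likelihood plus the L1 penalty."""
    return neg_log_partial_likelihood(dataset, beta) / dataset.n + lam * float(
        np.abs(beta).sum()
    )


def _surv_array(dataset: SurvivalDataset):
    return Surv.from_arrays(
        event=dataset.events.astype(bool), time=dataset.times
    )


def _coxnet_path(
    dataset: SurvivalDataset, alphas: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Coefficients (len(alphas), p) of the coxnet solver at the given grid.

    The compiled path solver may stop a path early once the deviance ratio
    saturates; the requested grid is the contract here, so remaining
    penalties are refitted in follow-up calls until every value is covered.
    """
    alphas = np.asarray(alphas, dtype=float)
    y = _surv_array(dataset)
    out = np.empty((len(alphas), dataset.p))
    start = 0
    while start < len(alphas):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=alphas[start:],
            normalize=False,
            fit_baseline_model=False,
            tol=tol,
            max_iter=100000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(dataset.X, y)
        got = model.coef_.shape[1]
        if got == 0:
            raise RuntimeError(
                "path solver returned no solutions; offending penalty "
                f"{alphas[start]:.4g}"
            )
        out[start : start + got] = model.coef_.T
        start += got
    return out


def fit_coxlasso(
    dataset: SurvivalDataset,
    lam: float,
    warm_start: np.ndarray | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Fit the lasso-Cox model at a single penalty; returns the p-vector.

    ``lam = 0`` falls back to unpenalized maximum-partial-likelihood
    estimation (requires a well-conditioned problem, typically n >> p).
    When a warm start is supplied the returned solution is checked to not
    exceed its penalized objective.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0.0:
        res = minimize(
            lambda b: neg_log_partial_likelihood(dataset, b),
            x0=np.zeros(dataset.p) if warm_start is None else warm_start,
            jac=lambda b: partial_likelihood_gradient(dataset, b),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
        )
        if not res.success and res.status != 2:  # 2: precision loss at optimum
            raise RuntimeError(
                f"unpenalized Cox fit did not converge: {res.message}"
            )
        return res.x
    beta = _coxnet_path(dataset, np.array([lam]), tol=tol)[0]
    if warm_start is not None:
        obj = penalized_objective(dataset, beta, lam)
        obj_ws = penalized_objective(dataset, warm_start, lam)
        if obj > obj_ws + 1e-8:
            raise RuntimeError(
                f"solution objective {obj:.6g} exceeds warm-start objective "
                f"{obj_ws:.6g} at lam={lam:.4g}"
            )
    return beta


def fit_path(
    dataset: SurvivalDataset, grid: RegularizationGrid, tol: float = 1e-9
) -> CoxLassoPath:
    """Fit the penalty path from largest to smallest value with warm starts."""
    coefs = _coxnet_path(dataset, grid.values, tol=tol)
    active = [np.flatnonzero(np.abs(b) > ACTIVE_TOL) for b in coefs]
    return CoxLassoPath(grid=grid, coefficients=coefs, active_sets=active)


def path_active_sizes_until(
    dataset: SurvivalDataset,
    values: np.ndarray,
    q_stop: int,
    chunk: int = 10,
) -> np.ndarray:
    """Active-set sizes along the path, stopping once ``q_stop`` is reached.

    Fits the grid in chunks from the largest penalty downward and returns the
    sizes of the fitted prefix; avoids solving the dense low end of the path
    when only the top matters (the lambda_min search).
    """
    values = np.asarray(values, dtype=float)
    sizes: list[int] = []
    for start in range(0, len(values), chunk):
        coefs = _coxnet_path(dataset, values[start : start + chunk])
        sizes.extend(int(np.sum(np.abs(b) > ACTIVE_TOL)) for b in coefs)
        if sizes[-1] >= q_stop or max(sizes[-len(coefs):]) >= q_stop:
            break
    return np.array(sizes)


def cv_select_lambda(
    dataset: SurvivalDataset,
    grid: RegularizationGrid,
    folds: int = 10,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[float, np.ndarray]:
    """Cross-validated penalty choice for the plain lasso-Cox baseline.

    The loss is the out-of-fold partial-likelihood deviance in the
    Verweij--Van Houwelingen form: for each fold, 2 * [nlpl(all data, beta)
    - nlpl(training part, beta)], summed over folds.  Folds with no events
    in the training part trigger a reshuffle with a fresh seed (bounded
    retries).  Returns (lambda_opt, active set of the full-data fit there).
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    n = dataset.n
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        fold_ids = np.array_split(perm, folds)
        if all(dataset.events[np.setdiff1d(perm, f)].sum() >= 1 for f in fold_ids):
            break
    else:
        raise RuntimeError(
            f"could not build {folds} folds with events in every training "
            f"part after {max_retries} reshuffles"
        )
    deviance = np.zeros(len(grid))
    for fold in fold_ids:
        train_idx = np.setdiff1d(np.arange(n), fold)
        train = dataset.subset(train_idx)
        coefs = _coxnet_path(train, grid.values)
        for k, beta in enumerate(coefs):
            deviance[k] += 2.0 * (
                neg_log_partial_likelihood(dataset, beta)
                - neg_log_partial_likelihood(train, beta)
            )
    k_opt = int(np.argmin(deviance))
    lam_opt = float(grid.values[k_opt])
    beta_full = _coxnet_path(dataset, grid.values)[k_opt]
    selected = np.flatnonzero(np.abs(beta_full) > ACTIVE_TOL)
    return lam_opt, selected
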