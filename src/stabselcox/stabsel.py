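"""Stability selection for the Cox model with lasso as the base learner.

Stability selection turns a single variable selector into an ensemble: draw
B half-size subsamples without replacement, refit the lasso-Cox path on each,
estimate per-variable selection probabilities at every candidate penalty,
take each variable's maximum probability over the candidate region as its
importance, and keep the variables whose importance reaches a threshold
pi_thr in (0.5, 1).

The candidate region matters.  Its top is lambda_upper (empty model); its
bottom, lambda_min, is chosen so the base learner selects at most q_Lambda
variables anywhere in the region.  q_Lambda in turn is tied to the
false-discovery budget through the bound

    E(V) <= q_Lambda^2 / ((2 pi_thr - 1) p),

where V counts falsely selected variables.  Setting any two of E(V), pi_thr
and q_Lambda fixes the third.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coxlasso import fit_path, path_active_sizes_until
from .survdata import (
    RegularizationGrid,
    SurvivalDataset,
    compute_lambda_upper,
    make_lambda_grid,
)

__all__ = [
    "StabSelConfig",
    "SelectionProfile",
    "q_from_error_bound",
    "error_bound",
    "determine_lambda_min",
    "run_stability_selection",
    "select_variables",
]


@dataclass(frozen=True)
class StabSelConfig:
    """Tuning parameters of the stability-selection ensemble.

    Exactly one of ``q_lambda``, ``ev_budget`` or ``lambda_min`` fixes the
    bottom of the candidate penalty region: an explicit per-fit selection
    budget, a false-discovery budget it is derived from, or a direct numeric
    penalty floor.
    """

    B: int = 200
    pi_thr: float = 0.6
    ev_budget: float | None = None
    q_lambda: int | None = None
    lambda_min: float | None = None
    subsample_fraction: float = 0.5
    seed: int = 0
    K: int = 100
    keep_replicates: bool = False
    paper_strict: bool = False  # strict risk-set inequalities in lambda_upper

    def __post_init__(self) -> None:
        if not 0.5 < self.pi_thr < 1:
            raise ValueError("pi_thr must lie in (0.5, 1)")
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if (
            self.q_lambda is None
            and self.ev_budget is None
            and self.lambda_min is None
        ):
            raise ValueError(
                "one of q_lambda, ev_budget or lambda_min must be given"
            )
        if self.q_lambda is not None and self.q_lambda < 1:
            raise ValueError("q_lambda must be at least 1")


@dataclass(frozen=True)
class SelectionProfile:
    """Estimated selection probabilities and the thresholded selection.

    ``probabilities[j, k]`` estimates the probability that variable j is in
    the lasso active set at the k-th candidate penalty of ``grid_used``;
    every entry is a multiple of 1/B.  ``importance`` is the row-wise maximum
    and ``selected`` the 0-based indices with importance >= pi_thr.
    """

    probabilities: np.ndarray
    importance: np.ndarray
    selected: np.ndarray
    grid_used: RegularizationGrid
    lambda_min: float
    q_lambda: int | None
    pi_thr: float
    B: int
    subsample_active_sets: list[list[np.ndarray]] | None = field(
        default=None, repr=False
    )


def q_from_error_bound(p: int, pi_thr: float, ev_budget: float) -> int:
    """Largest per-fit selection budget consistent with the E(V) bound.

    Inverting E(V) <= q^2 / ((2 pi_thr - 1) p) gives
    q = ceil( sqrt( (2 pi_thr - 1) * E(V) * p ) ).
    """
    if not 0.5 < pi_thr < 1:
        raise ValueError("pi_thr must lie in (0.5, 1)")
    if ev_budget <= 0:
        raise ValueError("ev_budget must be positive")
    q = math.ceil(math.sqrt((2 * pi_thr - 1) * ev_budget * p))
    if q > p:
        warnings.warn(
            f"derived q_lambda={q} exceeds p={p}; capping at p", stacklevel=2
        )
        q = p
    return q


def error_bound(p: int, pi_thr: float, q_lambda: int) -> float:
    """Upper bound on the expected number of falsely selected variables."""
    if pi_thr <= 0.5:
        raise ValueError("bound undefined for pi_thr <= 0.5")
    return q_lambda**2 / ((2 * pi_thr - 1) * p)


def determine_lambda_min(
    dataset: SurvivalDataset,
    grid: RegularizationGrid,
    q_lambda: int,
) -> RegularizationGrid:
    """Truncate the grid where the full-data lasso path first selects q_Lambda.

    Walks the path from the largest penalty downward and stops at the first
    grid value whose active set reaches q_lambda variables (the operational
    reading of "decrease lambda gradually until the lasso detects q_Lambda
    variables").  If the path never reaches q_lambda the full grid is
    returned with a warning.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    if q_lambda < 1:
        raise ValueError("q_lambda must be at least 1")
    sizes = path_active_sizes_until(dataset, grid.values, q_lambda)
    hit = np.flatnonzero(sizes >= q_lambda)
    if len(hit) == 0:
        warnings.warn(
            f"lasso path never reaches {q_lambda} active variables; "
            "using the full grid",
            stacklevel=2,
        )
        return grid
    return grid.truncate_at_index(int(hit[0]))


def _candidate_grid(
    dataset: SurvivalDataset, config: StabSelConfig
) -> tuple[RegularizationGrid, float, int | None]:
    """Full-data grid construction and truncation at lambda_min."""
    lam_up = compute_lambda_upper(dataset, strict=config.paper_strict)
    grid = make_lambda_grid(lam_up, dataset.n, dataset.p, config.K)
    q: int | None = config.q_lambda
    if config.lambda_min is not None:
        if config.lambda_min >= lam_up:
            warnings.warn(
                f"lambda_min={config.lambda_min:.4g} >= lambda_upper="
                f"{lam_up:.4g}; candidate region collapses to lambda_upper",
                stacklevel=2,
            )
        truncated = grid.truncate(config.lambda_min)
    else:
        if q is None:
            q = q_from_error_bound(dataset.p, config.pi_thr, config.ev_budget)
        truncated = determine_lambda_min(dataset, grid, q)
    return truncated, truncated.lambda_lower, q


def run_stability_selection(
    dataset: SurvivalDataset, config: StabSelConfig
) -> SelectionProfile:
    """Run the full stability-selection ensemble on a dataset.

    The penalty grid is computed once on the full dataset and truncated at
    lambda_min; each of the B ensemble members then refits the lasso path on
    a subsample of floor(subsample_fraction * n) distinct observations drawn
    without replacement.  Subsamples without any event, or on which the path
    solver fails, are redrawn (bounded retries).  Fully reproducible from
    ``config.seed``.
    """
    grid, lambda_min, q = _candidate_grid(dataset, config)
    n, p = dataset.n, dataset.p
    m = int(np.floor(config.subsample_fraction * n))
    if m < 2:
        raise ValueError("subsample size must be at least 2")
    rng = np.random.default_rng(config.seed)
    counts = np.zeros((p, len(grid)), dtype=np.int64)
    kept: list[list[np.ndarray]] | None = (
        [] if config.keep_replicates else None
    )
    max_retries = 100
    for _ in range(config.B):
        for attempt in range(max_retries):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            if dataset.events[idx].sum() < 1:
                continue
            try:
                path = fit_path(dataset.subset(idx), grid)
            except (RuntimeError, ArithmeticError) as err:  # redraw, log
                warnings.warn(
                    f"subsample path fit failed ({err}); redrawing",
                    stacklevel=2,
                )
                continue
            break
        else:
            raise RuntimeError(
                f"no valid subsample found after {max_retries} redraws"
            )
        for k, active in enumerate(path.active_sets):
            counts[active, k] += 1
        if kept is not None:
            kept.append(path.active_sets)
    probabilities = counts / config.B
    importance = probabilities.max(axis=1)
    selected = np.flatnonzero(importance >= config.pi_thr)
    return SelectionProfile(
        probabilities=probabilities,
        importance=importance,
        selected=selected,
        grid_used=grid,
        lambda_min=lambda_min,
        q_lambda=q,
        pi_thr=config.pi_thr,
        B=config.B,
        subsample_active_sets=kept,
    )


def select_variables(profile: SelectionProfile, pi_thr: float) -> np.ndarray:
    """Variables whose importance reaches the threshold (ties included)."""
    if not 0.5 < pi_thr < 1:
        raise ValueError("pi_thr must lie in (0.5, 1)")
    return np.flatnonzero(profile.importance >= pi_thr)
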