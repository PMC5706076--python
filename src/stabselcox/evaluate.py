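"""Replication harness and selection/prediction metrics.

Metrics over R replicated selections:

* selection frequency -- per-variable count of replicates selecting it,
  summarised as (min, median, max) within the important (IV) and unimportant
  (UIV) groups;
* success rate -- fraction of replicates recovering exactly the true set;
* TPR / TNR -- average selection indicator over IV members, average
  non-selection indicator over UIV members;
* mean model size;
* ranking recovery -- fraction of replicates whose top-ceil(gamma * s)
  variables (by importance, or anywhere on a lasso path) all lie in the
  true set;
* Harrell's concordance index for censored predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sksurv.metrics import concordance_index_censored

from .coxlasso import cv_select_lambda
from .simulate import SimulationDesign, make_scenario
from .stabsel import StabSelConfig, run_stability_selection
from .survdata import compute_lambda_upper, make_lambda_grid

__all__ = [
    "RunRecord",
    "EvaluationReport",
    "selection_frequency",
    "success_rate",
    "tpr_tnr",
    "mean_model_size",
    "ranking_recovery",
    "concordance_index",
    "replicate_experiment",
]


@dataclass(frozen=True)
class RunRecord:
    """One replicate's selection outcome."""

    replicate_id: int
    selected: frozenset
    importance: np.ndarray | None = None
    seed: int = 0
    true_set: frozenset | None = None
    path_active_sets: list[np.ndarray] | None = field(default=None, repr=False)


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate metrics of one replicated experiment."""

    scenario: str
    method: str
    n_replicates: int
    n_failures: int
    iv_frequency: tuple[int, int, int]
    uiv_frequency: tuple[int, int, int]
    success_rate: float
    mean_size: float
    tpr: float
    tnr: float
    iv_selection_rate: float
    uiv_selection_rate: float
    records: list[RunRecord] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "method": self.method,
            "n_replicates": self.n_replicates,
            "n_failures": self.n_failures,
            "iv_frequency": list(self.iv_frequency),
            "uiv_frequency": list(self.uiv_frequency),
            "success_rate": self.success_rate,
            "mean_size": self.mean_size,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "iv_selection_rate": self.iv_selection_rate,
            "uiv_selection_rate": self.uiv_selection_rate,
        }


def _median_halfup(values: np.ndarray) -> int:
    """Median with the even-length convention: mean of the central pair,
    rounded half-up to an integer for reporting."""
    v = np.sort(np.asarray(values))
    k = len(v)
    if k % 2 == 1:
        return int(v[k // 2])
    mid = (v[k // 2 - 1] + v[k // 2]) / 2.0
    return int(math.floor(mid + 0.5))


def selection_frequency(
    records: list[RunRecord], group
) -> tuple[int, int, int]:
    """(min, median, max) over group members of per-variable selection counts."""
    if not records:
        raise ValueError("at least one record required")
    group = sorted(group)
    if not group:
        raise ValueError("group must be nonempty")
    counts = np.array(
        [sum(j in r.selected for r in records) for j in group]
    )
    return int(counts.min()), _median_halfup(counts), int(counts.max())


def success_rate(records: list[RunRecord], true_set) -> float:
    """Fraction of replicates selecting exactly the true set (no more, no less)."""
    if not records:
        raise ValueError("at least one record required")
    target = frozenset(int(j) for j in true_set)
    return float(np.mean([r.selected == target for r in records]))


def tpr_tnr(records: list[RunRecord], iv, uiv) -> tuple[float, float]:
    """Average selection rate over IV and average exclusion rate over UIV."""
    iv, uiv = set(iv), set(uiv)
    if iv & uiv:
        raise ValueError("iv and uiv must be disjoint")
    tpr = float(
        np.mean([[j in r.selected for j in sorted(iv)] for r in records])
    )
    tnr = float(
        np.mean([[j not in r.selected for j in sorted(uiv)] for r in records])
    )
    return tpr, tnr


def mean_model_size(records: list[RunRecord]) -> float:
    return float(np.mean([len(r.selected) for r in records]))


def ranking_recovery(
    records: list[RunRecord],
    true_set=None,
    gamma: float = 0.3,
    mode: str = "stabsel",
) -> float:
    """Fraction of replicates correctly recovering the top gamma-share of S.

    ``stabsel`` mode: the ceil(gamma * |S|) variables with highest importance
    (ties broken toward the smaller index) must all lie in the true set S.
    ``lasso_path`` mode: some penalty on the recorded path must have at least
    ceil(gamma * |S|) active variables from S and none from its complement.
    ``true_set=None`` uses each record's own true set (scenarios whose sparse
    support is redrawn per replicate).
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    hits = []
    for r in records:
        S = set(
            int(j)
            for j in (true_set if true_set is not None else r.true_set)
        )
        k = math.ceil(gamma * len(S))
        if mode == "stabsel":
            if r.importance is None:
                raise ValueError("stabsel mode requires importance vectors")
            order = np.lexsort(
                (np.arange(len(r.importance)), -np.asarray(r.importance))
            )
            hits.append(all(int(j) in S for j in order[:k]))
        elif mode == "lasso_path":
            if r.path_active_sets is None:
                raise ValueError("lasso_path mode requires per-record path data")
            ok = False
            for active in r.path_active_sets:
                a = set(int(j) for j in active)
                if len(a & S) >= k and not (a - S):
                    ok = True
                    break
            hits.append(ok)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(hits))


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly by risk.

    A pair (i, j) with y_i < y_j and delta_i = 1 is comparable; it is
    concordant when risk_i > risk_j, with score ties counting 1/2.  Returns
    NaN when no comparable pair exists.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    risk = np.asarray(risk_scores, dtype=float)
    if not len(times) == len(events) == len(risk):
        raise ValueError("times, events and risk_scores must have equal length")
    try:
        c, *_ = concordance_index_censored(events, times, risk)
    except Exception:
        return float("nan")
    return float(c)


def _per_replicate_seeds(seed: int, R: int) -> list[int]:
    """Deterministic per-replicate seeds via a splittable seed sequence."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(R)]


def replicate_experiment(
    scenario: str,
    method: str,
    R: int,
    seed: int,
    censor_rate: float = 0.0,
    stabsel_config: StabSelConfig | None = None,
    cv_folds: int = 10,
    keep_paths: bool = False,
    scenario_kwargs: dict | None = None,
) -> EvaluationReport:
    """Run R independent replicates of a scenario/method pair and aggregate.

    ``method`` is one of ``stabsel`` (the ensemble), ``cvlasso`` (active set
    of the cross-validated lasso fit) or ``oracle`` (the true set, the
    benchmark selector).  Replicate seeds derive deterministically from the
    master seed, so replicates are individually reproducible and the whole
    report is a pure function of its arguments.  A replicate on which the
    method fails is logged and excluded from the aggregates.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    kwargs = scenario_kwargs or {}
    records: list[RunRecord] = []
    failures = 0
    design: SimulationDesign | None = None
    for r, rep_seed in enumerate(_per_replicate_seeds(seed, R)):
        dataset, design = make_scenario(
            scenario, censor_rate=censor_rate, seed=rep_seed, **kwargs
        )
        try:
            rec = _run_method(
                dataset, design, method, rep_seed, r,
                stabsel_config, cv_folds, keep_paths,
            )
        except (RuntimeError, ValueError, ArithmeticError):
            failures += 1
            continue
        records.append(rec)
    if not records:
        raise RuntimeError("every replicate failed")
    fixed_support = all(r.true_set == records[0].true_set for r in records)
    p = design.p
    if fixed_support:
        iv = set(int(j) for j in records[0].true_set)
        uiv = set(range(p)) - iv
        tpr = (
            float(np.mean([[j in r.selected for j in sorted(iv)] for r in records]))
            if iv
            else float("nan")
        )
        tnr = (
            float(
                np.mean(
                    [[j not in r.selected for j in sorted(uiv)] for r in records]
                )
            )
            if uiv
            else float("nan")
        )
        iv_freq = selection_frequency(records, iv) if iv else (0, 0, 0)
        uiv_freq = selection_frequency(records, uiv) if uiv else (0, 0, 0)
        succ = success_rate(records, iv)
    else:
        # support redrawn per replicate: only per-record metrics aggregate
        tprs = [
            np.mean([j in r.selected for j in sorted(r.true_set)])
            if r.true_set
            else np.nan
            for r in records
        ]
        tnrs = [
            np.mean(
                [
                    j not in r.selected
                    for j in sorted(set(range(p)) - set(r.true_set))
                ]
            )
            for r in records
        ]
        tpr, tnr = float(np.nanmean(tprs)), float(np.nanmean(tnrs))
        iv_freq = uiv_freq = (0, 0, 0)
        succ = float(np.mean([r.selected == r.true_set for r in records]))
        iv = uiv = None
    return EvaluationReport(
        scenario=scenario,
        method=method,
        n_replicates=len(records),
        n_failures=failures,
        iv_frequency=iv_freq,
        uiv_frequency=uiv_freq,
        success_rate=succ,
        mean_size=mean_model_size(records),
        tpr=tpr,
        tnr=tnr,
        iv_selection_rate=tpr,
        uiv_selection_rate=1.0 - tnr,
        records=records,
    )


def _run_method(
    dataset, design, method, rep_seed, replicate_id,
    stabsel_config, cv_folds, keep_paths,
) -> RunRecord:
    if method == "stabsel":
        if stabsel_config is None:
            raise ValueError("stabsel method requires a StabSelConfig")
        from dataclasses import replace as dc_replace

        cfg = dc_replace(stabsel_config, seed=rep_seed)
        profile = run_stability_selection(dataset, cfg)
        return RunRecord(
            replicate_id=replicate_id,
            selected=frozenset(int(j) for j in profile.selected),
            importance=profile.importance,
            seed=rep_seed,
            true_set=frozenset(int(j) for j in design.true_set),
        )
    if method == "cvlasso":
        lam_up = compute_lambda_upper(dataset)
        grid = make_lambda_grid(lam_up, dataset.n, dataset.p)
        _, selected = cv_select_lambda(dataset, grid, folds=cv_folds, seed=rep_seed)
        paths = None
        if keep_paths:
            from .coxlasso import fit_path

            paths = fit_path(dataset, grid).active_sets
        return RunRecord(
            replicate_id=replicate_id,
            selected=frozenset(int(j) for j in selected),
            importance=None,
            seed=rep_seed,
            true_set=frozenset(int(j) for j in design.true_set),
            path_active_sets=paths,
        )
    if method == "oracle":
        return RunRecord(
            replicate_id=replicate_id,
            selected=frozenset(int(j) for j in design.true_set),
            importance=None,
            seed=rep_seed,
            true_set=frozenset(int(j) for j in design.true_set),
        )
    raise ValueError(f"unknown method {method!r}")
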