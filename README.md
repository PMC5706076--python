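# stabselcox

Stability selection with the lasso as base learner for Cox
proportional-hazards models — variable selection for right-censored survival
data with finite-sample control of false discoveries.

## The problem

Given survival data {(y_i, x_i, δ_i)}, i = 1…n, with p covariates, the Cox
model relates covariates to the hazard through

    h(t | x) = h0(t) · exp(xᵀβ),

and a sparse β is estimated by maximizing the L1-penalized partial
likelihood

    β̂(λ) = argmax_β  Σ_i [ x_{j(i)}ᵀβ − log Σ_{j∈R_i} exp(x_jᵀβ) ] − λ Σ_j |β_j|,

where R_i is the risk set at the i-th unique failure time.  Cross-validated
lasso tends to over-select.  Stability selection fixes this by ensembling:
draw B half-size subsamples without replacement, refit the lasso path on
each over a candidate region Λ = [λ_min, λ_upper], estimate per-variable
selection probabilities Π̂_j(λ), and keep the variables whose maximal
probability over Λ reaches a threshold π_thr ∈ (0.5, 1).  The expected
number V of falsely selected variables then satisfies

    E(V) ≤ q_Λ² / ((2·π_thr − 1) · p),

where q_Λ is the number of variables the base learner may select per fit.

The package's distinctive piece is the principled construction of Λ:

* **λ_upper** — the smallest penalty giving the empty model, computed in
  closed form from the null-model working response (martingale-residual
  scores): λ_upper = max_j (1/n)|Σ_k ω_k x_kj z_k|.
* **λ_lower = ε·λ_upper** with ε = 0.05 for n < p and ε = 0.0001 for n ≥ p;
  K+1 candidates are geometrically spaced.
* **λ_min** — walk the full-data path from λ_upper downward and truncate the
  grid where the active set first reaches q_Λ variables (q_Λ derived from an
  E(V) budget via the bound above, or given directly).

## Worked example

```python
from stabselcox import make_scenario, run_stability_selection, StabSelConfig

# n=80, p=20, correlated covariates (x_j = z + eps_j), true signal on
# variables x5, x10, x15 with coefficients 0.5, 1.0, 1.5, no censoring
dataset, design = make_scenario("sim3", censor_rate=0.0, seed=3)

config = StabSelConfig(B=200, pi_thr=0.6, q_lambda=6, seed=3)
profile = run_stability_selection(dataset, config)
print("lambda_upper:", round(profile.grid_used.lambda_upper, 3))
print("lambda_min:  ", round(profile.lambda_min, 3))
print("selected:    ", [f"x{j+1}" for j in profile.selected])
print("importance:  ", profile.importance.round(2))
```

prints

```
lambda_upper: 1.172
lambda_min:   0.388
selected:     ['x4', 'x5', 'x10', 'x15']
importance:   [0.02 0.06 0.08 0.78 0.94 0.06 0.06 0.04 0.08 0.94 0.04 0.01 0.29 0.26
 1.   0.02 0.52 0.   0.02 0.18]
```

The three signal variables reach importance 0.94-1.0 and are selected; on
this particular draw one correlated noise variable (x4, importance 0.78)
slips past the 0.6 threshold — exactly the kind of event the E(V) bound keeps
rare on average.

The same workflow is available from the shell:

```sh
stabsel simulate --scenario sim3 --censor 0.2 --seed 7 --out data.csv
stabsel run --input data.csv --B 200 --pi-thr 0.6 --q-lambda 6 --seed 1 --out profile.csv
stabsel evaluate --scenario sim3 --method stabsel --R 100 --q-lambda 6 --seed 1 --out report.json
stabsel reproduce-table --table table1 --reduced --seed 1 --out table1.json
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs, from scratch, the replicated simulation experiments behind the
headline numbers: 100 replicates of the shared-factor design (n=80, p=20,
three signal variables) at 0/20/40% censoring under stability selection with
B=200, π_thr=0.6, q_Λ=6 — reporting exact-recovery rate, TPR/TNR, mean model
size and median selection counts — plus 100 replicates of the AR(1) design
(n=50, p=8) at 20% censoring with an explicit λ_min = 0.2.  Runtime is a few
minutes on one CPU; all inputs are generated internally from the given seed.
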