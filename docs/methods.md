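# Methods

## Model and estimator

Survival data are n triples (y_i, x_i, δ_i): a follow-up time, a p-vector of
covariates and an event flag (δ = 0 means right-censored).  The hazard is
assumed proportional, h(t|x) = h0(t) exp(xᵀβ), and β is estimated from
Breslow's partial likelihood over the m unique failure times t_1 < … < t_m
with risk sets R_i = {j : y_j ≥ t_i}.  The base learner is the lasso:

    minimize_β  (1/n)·[−log PL(β)] + λ·Σ_j|β_j|.

Ties among failure times are handled by Breslow's approximation (each tied
failure contributes the full risk-set denominator); the simulated designs
are continuous so ties only arise in user data.

Stability selection draws B subsamples of ⌊n/2⌋ observations without
replacement, refits the lasso path on each over a fixed candidate penalty
grid, and estimates Π̂_j(λ) = (1/B)·#{subsamples with β̂_j(λ) ≠ 0}.  Variable
j's importance is max_λ Π̂_j(λ) over the candidate region, and the selected
set is {j : importance_j ≥ π_thr}.  For π_thr ∈ (0.5, 1) the expected number
of falsely selected variables is bounded by q_Λ²/((2π_thr−1)p), with q_Λ the
per-fit selection budget; setting any two of E(V), π_thr, q_Λ determines the
third (`q_from_error_bound`, `error_bound`).

## The candidate region Λ

The top of the region is the smallest penalty giving an empty model.  At
β = 0 the gradient of the partial likelihood has the martingale-residual
form score_k = δ_k − Σ_{i∈C_k} 1/s_i, where s_i counts subjects at risk at
t_i and C_k indexes the failure times up to y_k, so

    λ_upper = max_j (1/n) |Σ_k score_k · x_kj|.

Two conventions matter here and the implementation defaults to the
*inclusive* one (s_i counts y_j ≥ t_i, C_k = {i : t_i ≤ y_k}): it makes the
scores exactly the null gradient, hence λ_upper satisfies the empty-model
KKT property to machine precision and the scores sum to zero without ties.
The strict variant (y_j > t_i, t_i < y_k), which matches some published
presentations of the working response, is available via `strict=True`; terms
with s_i = 0 (possible when the largest time is a failure) are dropped there.
The absolute value in λ_upper is deliberate: the penalty must be positive
and the KKT condition is two-sided.

The bottom of the grid is λ_lower = ε·λ_upper with ε = 0.05 when n < p and
ε = 0.0001 when n ≥ p, and K+1 = 101 geometrically spaced candidates by
default (K is not pinned by the procedure's description; 100 is the standard
path resolution and is configurable).

λ_min truncates the grid so the base learner selects at most q_Λ variables
anywhere in Λ: the full-data path is walked from λ_upper downward and cut at
the first grid value whose active set reaches q_Λ.  The alternative readings
— cutting at the smallest λ whose active-set size still equals q_Λ, or
truncating each subsample's path at its own q_Λ-th entry — were implemented
and compared during development; they trade TPR against TNR without
dominating the default, and the first-reach rule is the published prose.
λ_min may also be set to an explicit numeric value (the grid keeps all
candidates ≥ λ_min and appends λ_min itself), which is how the
penalty-floor sensitivity experiment (`reproduce-table --table table1`) is
driven.

## Solver

The path is fitted by cyclical coordinate descent on the iteratively
reweighted quadratic approximation of the Breslow partial likelihood, using
scikit-survival's compiled coxnet routine with `l1_ratio=1` and the exact
grid above (solvers' internal default grids differ and are never used).
Covariates are *not* standardized internally: λ_upper, explicit λ_min
values, and the fitted coefficients all live on the raw covariate scale, so
the closed-form λ_upper is exactly the solver's entry threshold.  The
simulated designs have equal column variances by construction, so
standardization would amount to a uniform rescaling of λ.  The compiled
solver may stop a path early once the deviance ratio saturates; the wrapper
refits the remaining grid values so the grid contract holds.  Convergence
tolerance defaults to 1e-9 (coefficients reproducible to ~1e-5 between warm
and cold starts; 1e-13 gives 1e-6 agreement and is used in the precision
tests).  Coefficients with |β_j| > 1e-10 count as active.

λ = 0 (unpenalized) is delegated to L-BFGS on the package's own
partial-likelihood gradient, since the penalized path solver is unreliable
at zero penalty; this route is cross-checked against an independent Cox
implementation in the tests.

The cross-validated lasso baseline uses 10 folds and the
Verweij–Van Houwelingen deviance: for each fold, 2·[nlpl(all) − nlpl(train)]
evaluated along the shared grid; λ_opt minimizes the summed loss and the
reported selection is the full-data active set at λ_opt.  Folds whose
training part has no events are reshuffled (bounded retries).

## Synthetic data

All experiments run on generated data; every generator is a pure function of
its seed (numpy Generator, no global state).

* `sim1` — n=50, p=8, AR(1) Gaussian covariates with correlation 0.5^|i−j|,
  β = (3, 1.5, 0, 0, 2, 0, 0, 0).  Censoring times are uniform on [0, η]
  with the anchor values η = 45 (≈20%) and η = 4 (≈40%).  Empirically these
  anchors give 24% and 42% at 10^4 subjects — kept anyway, as they are the
  stated design; other rates are calibrated.
* `sim2_case1 / sim2_case2` — p=1000 with n=100 (independent N(0,1)
  columns) and n=200 (two-factor columns x_k = f_k1·φ_1 + f_k2·φ_2 + η_k
  with scalar standard-normal loadings and n-vector factors/noise).  The
  sparse support S (|S| uniform in 4..10 unless fixed) and coefficients
  β_k ~ U[0,1] are redrawn per replicate.
* `sim3` — n=80, p=20, shared-factor columns x_j = z + ε_j (variance 2,
  pairwise correlation 1/2), coefficients 0.5 / 1.0 / 1.5 on x5 / x10 / x15.
* `null` — n=100, p=50, independent covariates, β = 0; used for
  false-discovery calibration.

Survival times are exponential with unit baseline hazard,
y = −log(U)/exp(xᵀβ), linear predictors clipped at ±500 to avoid
overflow/underflow.  Censoring is independent uniform on [0, η]; a target
rate without a printed η is met by Monte-Carlo bisection (`calibrate_eta`):
10^4 fresh survival times and uniform deviates are drawn once, making the
empirical rate a deterministic monotone function of η that is bisected to
within 1 percentage point.  A 0% target means no censoring step at all.

What a green test does *not* establish: the generators emulate the stated
designs only — proportional hazards hold exactly, censoring is independent
and uniform, covariates are Gaussian with known covariance.  Real survival
data (non-proportional hazards, informative censoring, ties, heavy-tailed
covariates) exercise none of these guarantees; only the Breslow tie rule and
the CSV interface address them at all.

## Replication harness and metrics

`replicate_experiment` derives per-replicate seeds from a master seed via a
splittable seed sequence, so any replicate is individually reproducible and
parallelization cannot change results.  Metrics over R replicates:
per-variable selection counts summarized as min/median/max within the
important and unimportant groups (even-length medians are the mean of the
central pair, rounded half-up for reporting); exact-recovery success rate
(supersets count as failures); TPR/TNR (mean selection indicator over signal
variables, mean exclusion indicator over noise variables); mean model size;
ranking recovery (the top ⌈γ·|S|⌉ variables by importance — ties broken
toward the smaller index — all lie in S; for the lasso baseline, some path
penalty activates ⌈γ·|S|⌉ of S and none of its complement); and Harrell's
concordance index (ties in score count 1/2; undefined without comparable
pairs, reported as NaN).

## Known limitations

* Selection-accuracy benchmarks of this procedure in the literature report
  accuracy *improving* with the censoring rate at fixed λ_min; this
  implementation shows the information-theoretically expected mild
  degradation instead, and its uncensored results are correspondingly
  stronger.  The discrepancy is documented in the test suite's tolerances
  and could not be reproduced by any faithful variant of the procedure
  (strict/inclusive risk sets, either λ_min reading, per-subsample
  truncation, bootstrap resampling).
* No Efron tie handling, time-varying covariates, stratification or left
  truncation.
* The E(V) bound assumes the base learner is not worse than random guessing
  and exchangeability of noise variables; heavy covariate correlation can
  stress it.
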