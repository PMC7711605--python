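# Methods

This note documents the models, numerical choices and known limitations
of the `tagnet` pipeline. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phenotype-derived oil productivity

The objective variable is the change in oil mass per cell between
consecutive sampling points,
`oil_productivity(t) = OIL(t+1)·10³/Cell(t+1) − OIL(t)·10³/Cell(t)`
(OIL in g/L, Cell in 10⁸ cells/mL; the value is in 10⁻¹¹ g per cell).
Productivity at time *t* is paired with expression at time *t*: the
transcriptional state at *t* is what drives production over the next
interval. Because the last time point of every series has no following
interval, those samples are removed; a set of series of lengths
L₁,…,L_k therefore yields Σ(Lᵢ−1) analysis samples.

Expression is log₂-transformed and z-scored per gene with the sample
(n−1) standard deviation; the choice is recorded in output metadata and
only rescales rows relative to the population convention.
Normalisation is applied after last-time-point removal by default
(z-scores over the samples actually analysed); a `normalize="before"`
flag gives the alternative ordering. Zero-variance genes abort by
default — silently dropping them would change downstream variable
counts — with an explicit drop-with-warning switch.

## Factor model

With q observed variables and p < q factors, the common-factor model is
`x = A f + e`, giving the correlation structure `R = A Φ_f Aᵀ + Ψ²`
(pattern loadings A, factor correlations Φ_f, diagonal uniquenesses
Ψ²). Because the variables are z-scored, covariance and correlation
matrices coincide, so the Kaiser rule is applied to the correlation
matrix.

* **Extraction** is iterated-communality principal-axis factoring:
  squared multiple correlations (via R⁻¹, ridged by 1e-8 when near
  singular) initialise the communalities; the reduced matrix is
  eigendecomposed; loadings are the top-p eigenvectors scaled by the
  square root of their (clipped non-negative) eigenvalues; iteration
  stops when the largest communality change is below 1e-6 (default),
  with a warning and the last iterate on non-convergence. Heywood cases
  (communality > 1) are clipped to 1 with a warning. Each factor is
  oriented so its dominant loading is positive.
* **Factor count**: the Kaiser count (eigenvalues > 1) tends to
  overestimate; the `kaiser-then-prune` strategy refits with one factor
  fewer while some factor attracts no variable's maximal absolute
  loading. A scree elbow (maximal second difference) is reported for
  diagnostics only.
* **Rotation** is promax with κ = 4 (the conventional power): varimax
  with Kaiser row normalisation, an element-wise |loading|^κ target,
  least-squares procrustes, and column scaling so Φ_f has unit
  diagonal. Oblique rotation leaves the reproduced common covariance
  A Φ_f Aᵀ invariant (checked to 1e-6 in the tests). Under the oblique
  solution communalities are h²ᵢ = aᵢ Φ_f aᵢᵀ.
* **Assignment** sends each variable to the factor with its largest
  absolute pattern loading (the printed loading table highlights
  negative winners, so the absolute value is the correct rule); ties
  break toward the lowest factor index and are logged. Factor scores
  are never estimated — only the synthetic generator's ground truth
  holds them.

## SEM engine

A path model over observed variables stores directed edges
(Λ[child, parent]), free error variances, and error covariances fixed
at zero unless declared. The engine names the error-term covariance
Φ_e to keep it distinct from the factor correlations Φ_f. The implied
covariance is `Σ(θ) = (I−Λ)⁻¹ Φ_e (I−Λ)⁻ᵀ`; non-recursive (cyclic)
models are permitted whenever (I−Λ) is invertible, with a warning if
the spectral radius of Λ reaches 1 (non-stationary interpretation).

Estimation minimises
`F_ML = log|Σ(θ)| − log|S| + tr(Σ(θ)⁻¹S) − q`
with an analytic gradient (∂F/∂Λ = 2BᵀMΣ, ∂F/∂Φ_e = BᵀMB for
M = Σ⁻¹ − Σ⁻¹SΣ⁻¹, B = (I−Λ)⁻¹). Start values are deterministic:
edges at their stored values (0 for new edges), error variances at the
sample variances. The optimizer is L-BFGS-B with an infinite objective
outside the positive-definite region; because L-BFGS-B can report
convergence on a tiny relative reduction while the gradient is still
large (line searches near the PD boundary), the gradient norm is
checked at the solution and a full-BFGS polish is run when it exceeds
1e-7. The saturated model is solved in closed form (Σ(θ̂) = S).

* χ² = (n−1)·F_ML (Wishart convention, switchable to n);
  df = q(q+1)/2 − #free parameters (negative df raises an
  identification error before fitting).
* **Standard errors** come from the observed information — the
  numerical Hessian (central differences of the analytic gradient) of
  (n−1)/2·F_ML — inverted by `pinvh`; a parameter whose information is
  not positive gets an infinite SE, hence a Wald p of 1, which lets the
  pruning step remove empirically unidentified parameters instead of
  keeping them with spurious precision. Wald p-values are two-sided
  normal.
* **Identification** is checked numerically from the rank of the
  expected information at the optimum (raised by default; the stepwise
  search disables the hard check for intermediate models and relies on
  the infinite-SE mechanism plus a hard check when adding candidates).
* **Fit indices**: CMIN p = P(χ²_df > χ²);
  GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²];
  AGFI = 1 − (q(q+1)/2df)(1 − GFI);
  CFI = 1 − max(χ²−df, 0)/max(χ²₀−df₀, χ²−df, 0);
  RMSEA = √(max(χ²−df, 0)/(df·(n−1))); AIC = χ² + 2·#free. AGFI and
  RMSEA are reported as undefined (None) at df = 0, never as numbers.
  The independence baseline (diagonal Σ) has the closed form
  F = −log|R|. The saturated AIC is q(q+1).
* **Modification indices** are one-degree-of-freedom score statistics:
  MI = U_c²/(I_cc − I_cθ I_θθ⁻¹ I_θc), with U the score of
  (n−1)/2·F_ML and I the expected information over free parameters
  plus the candidate. The MI approximates the χ² drop from freeing the
  candidate *locally*: for modest omitted effects (standardized ≈ 0.2)
  it agrees with the refit drop to within a few percent, while for
  large omitted effects any score-type MI underestimates the drop
  substantially — ranking, which is what the search uses, is far more
  robust than the absolute value.

## Stepwise search

From the star initial model (one free edge per candidate regulator
into the objective; regulators mutually independent), the search
alternates, one modification per refit:

1. **prune** — while any free structural parameter (edge or declared
   error covariance) has Wald p ≥ α (default 0.01), delete the single
   largest-p one and refit;
2. **add** — free the absent parameter with the highest MI if it
   exceeds the threshold (default 3.84, χ²₁ at 0.05).

The loop runs over directed paths first, then over error covariances.
Design choices that matter:

* **Stopping**: once every retained parameter is significant *and* the
  fit thresholds are met (CMIN p > 0.01, GFI ≥ 0.90, CFI ≥ 0.90,
  RMSEA < 0.10 hard cap, < 0.05 preferred and flagged separately), the
  search stops. Additions exist to repair misfit; continuing past an
  acceptable model only picks up noise edges.
* **Tabu**: a parameter deleted within a phase cannot be re-added in
  that phase; together with one-modification-per-refit this guarantees
  termination (a global iteration cap is a backstop).
* **Excluded candidates**: an error covariance between a directly
  connected pair is two parameters for one moment (unidentified next
  to the edge) and is never offered; candidate additions that make the
  model unidentified or (I−Λ) singular are rejected and tabu-listed.
* **Restarts**: seeded perturbations of the initial edge set (each
  initial edge dropped with probability 0.3) are all explored; among
  accepted models the lowest AIC wins, otherwise the best-effort model
  is returned with its acceptance flags set to false. Restarts stand
  in for a population-based escape from local optima; they are simple,
  reproducible and sufficient at these problem sizes.
* Cycles may emerge through MI additions; only singular (I−Λ) is
  rejected.

The 5-step pipeline standardises the assembled dataset, fits the
factor model, searches within the oil-productivity group (objective:
oil productivity), averages each group's member profiles into pseudo
variables, and searches across groups (objective: the group containing
oil productivity).

## Synthetic data

All generators draw through a single `numpy.random.Generator` from an
explicit seed; identical seeds are bit-identical.

* `gen_factor_data(A, Φ_f, Ψ², n, seed)` draws f ~ N(0, Φ_f),
  e ~ N(0, Ψ²), x = A f + e; with `standardize=True` rows are rescaled
  so the population covariance has unit diagonal.
* `gen_sem_data(model, θ, n, seed)` draws ε ~ N(0, Φ_e) and solves
  x = (I−Λ)⁻¹ε, so the sample covariance converges to Σ(θ).
* `gen_phenotype_series` inverts the productivity definition
  (OIL = per-cell-oil·Cell/10³), so the noiseless series recovers
  prescribed per-cell increments exactly.
* The `table1_like` scenario reproduces the study's 9-group structure
  (sizes 24, 21, 16, 9, 5, 6, 1, 3, 4 over 89 variables, one named
  `oil_productivity` in group 3) with a primary loading of 0.8 at the
  study's 210 samples; `table1_network` couples the nine factors
  through a known 6-edge path model whose edges all point into
  colliders, and uses a loading of 0.9, matching the printed
  communalities (most above 0.8, i.e. loadings near 0.9).
* `six_node_truth` is the structure-recovery benchmark: every edge
  lies in a v-structure, so the model is its own covariance-equivalence
  class and directed recovery is statistically identifiable; effects
  (0.6–0.7) sit in the range of strong printed standardized weights.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: time autocorrelation within series,
non-Gaussian or heavy-tailed expression noise, batch structure, probe
effects, and model misspecification beyond measurement error. The
covariance-structure ML is a Gaussian likelihood; the generators are
deliberately Gaussian to test the estimator under its own assumptions.

## Known limitations

* **Directed orientation is only identifiable through v-structures.**
  In linear-Gaussian path models, reversing an edge whose endpoints
  have no disambiguating collider yields an equivalent covariance;
  no search can orient such edges from observational covariances. The
  group-level stage inherits an additional limit: pseudo variables are
  noisy averages of their members (attenuated factor proxies), so at
  realistic reliabilities the search recovers group-level *adjacency*
  well while orientations remain noise-limited. The end-to-end test
  therefore scores skeleton F1 at the group level and directed F1 only
  in the direct SEM benchmark.
* The χ² test over-rejects slightly at moderate n (the usual
  finite-sample inflation of the (n−1)·F_ML statistic); the calibration
  test brackets the rejection rate at 5% ± 2% at n = 500.
* Greedy stepwise search with AIC selection can honestly prefer a
  rival near-equivalent structure when sampling noise favours it; the
  restart mechanism reduces but cannot eliminate this.
* Problem sizes in the test suite (n = 500–10⁴, q ≤ 16, 10–30 seeds
  per property) were chosen so every statistical property is measured
  with comfortable margins at interactive runtimes.
* No latent-variable measurement models, mean structures, missing-data
  likelihoods or bootstrap standard errors; these are outside the
  pipeline's scope.
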