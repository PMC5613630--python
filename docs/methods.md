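# Methods

## Scope

`polydif` detects uniform (and, via an omnibus variant, nonuniform)
differential item functioning in ordered categorical item responses
collected under two-level sampling (persons nested in clusters), using
likelihood-ratio tests in proportional-odds models with and without a
cluster random intercept, and provides a multilevel graded-response-model
simulator plus a Monte-Carlo harness for Type I error and power studies of
these tests.

## Analysis models

### Proportional odds (OLR)

For a single item with observed categories `0..C−1`,

    logit P(Y ≤ c | x) = α_c − x'β,   c = 0..C−2,

with increasing cutpoints and slopes common to all cutpoints.  A positive
slope moves mass toward higher categories (latent-variable convention
`Y* = x'β + logistic error`).  The DIF battery conditions on the ability
proxy θ = raw total score over **all** items, including the studied item
(a rest-score option exists but is off by default; the total-score
convention is the field's standard and what the harness uses).  The score is
not standardized: the likelihood-ratio statistics are invariant to linear
rescaling of predictors, so standardization would change nothing that is
tested.

Uniform DIF: LR(R2 vs R1), 1 df.  Omnibus: LR(full vs R1), 2 df.  The
simulation harness uses the 1-df uniform test, matching the uniform-DIF
generating mechanism; the omnibus test is exposed but not used by the
harness.

Estimation is maximum likelihood via L-BFGS-B with analytic gradients.
Cutpoints are reparameterized as (first cutpoint, log-increments), which
enforces ordering; convergence is declared at gradient sup-norm 1e−6 or
relative log-likelihood change 1e−12, with a 200-iteration cap and
exp-arguments clipped at 300 for wild line-search trial points.  Observed
(possibly non-consecutive) categories are collapsed to consecutive codes
before fitting; both members of any LR comparison see the same response
vector, hence the same collapse, and the collapse is recorded on the fit.
Standard errors invert the observed information, obtained by central finite
differences of the analytic gradient.  Non-convergence and complete
separation surface as `converged_ = False`, which marks the downstream DIF
result invalid (never a silent estimate).

### Random-intercept cumulative logit (HOLR)

The same linear predictor plus a cluster intercept `u_j ~ N(0, σ_u²)`,
random intercept only — no random slopes, matching the two analysis models
the harness needs (person-level group in the level-1 equation; cluster-level
group in the intercept equation; algebraically both are columns of the same
design matrix, with the cluster-level column validated to be constant within
each cluster).

The marginal likelihood integrates the cluster product likelihood over `u`
by **adaptive Gauss–Hermite quadrature** (default 15 nodes).  Per cluster
the log-integrand is strictly concave in `u`, so its mode is found by a
globally convergent vectorized Newton iteration and the node scale is the
curvature at the mode; clusters where the Newton step degenerates
numerically fall back to prior-centred (plain) nodes.  Node positions are
frozen during an optimizer run, which makes the quadrature approximation an
explicit smooth function of all parameters with closed-form gradients
(σ_u² then enters only through the Gaussian density evaluated at the fixed
nodes); after each run the nodes are re-adapted at the new estimate and the
optimization repeated until the re-adapted log-likelihood is stable to
1e−8 (at most 6 rounds, typically 2–3).  Test-suite checks hold the result
to 1e−4 of 4001-point dense-grid integration, including a stress case with
clusters of 20 and σ_u² ≈ 1.4 where non-adaptive quadrature of the same
order is off by ~0.3.

σ_u² is optimized as log σ_u² within [1e−10, 100].  Before optimizing, the
score of the marginal likelihood with respect to σ_u² at σ_u² = 0 is
evaluated in closed form at the fixed-effects MLE
(½ Σ_j [(Σ_i ℓ′_ij)² + Σ_i ℓ″_ij]); a non-positive score means the MLE is on
the boundary, and the fit returns the exact fixed-effects solution with
`sigma_u2_ = 0` and `boundary_ = True`.  The same polish is applied if the
optimizer lands below 1e−7.  This makes the boundary consistency between the
mixed and flat engines exact rather than approximate, and it is why
null-cell Monte-Carlo runs are fast (most null replications sit on the
boundary once the total score has absorbed the cluster effect).

LR tests between mixed fits compare marginal log-likelihoods and count
**fixed-effect** parameter differences only; both models share the
random-intercept structure, so the standard χ² reference applies and no
boundary-mixture correction is needed.  Standard errors come from the
observed information of (cutpoints, slopes, σ_u) with a delta-method
conversion to σ_u²; they are skipped at the boundary.

Starting values: fixed effects from the flat fit, σ_u² = 0.1.

## Simulator (the study conditions)

One replication of a design cell draws, in order and from a single seeded
generator:

1. **Item bank** — 16 items (15 core + 1 studied, the last by default),
   5 categories.  Discrimination per item uniform on (0.5, 0.99) ("low") or
   (1.5, 2.0) ("high").  Each item's four thresholds are drawn i.i.d.
   uniform on [−2.5, 2.5] and sorted (exact ties redrawn); this keeps every
   threshold inside the stated difficulty interval while giving
   heterogeneous category boundaries.  Banks are re-drawn every replication,
   so cell-level rates average over the item population rather than
   conditioning on one bank.
2. **Abilities** — θ_ij = u_0j + e_ij with Var(u_0j) = ρ ∈ {0.05, 0.25,
   0.45} and Var(e_ij) = 1 − ρ: the total latent variance is fixed at 1 so
   that discrimination ranges are comparable across ICC levels, and ρ is
   exactly the intraclass correlation.  Both groups share the same ability
   distribution.
3. **Groups** — balanced.  Within-cluster level: each cluster is split
   half/half; for odd cluster sizes (the design includes size 5) half the
   clusters carry the extra focal person and half the extra reference
   person, so the overall design is exactly balanced and every cluster is
   within one person of balance.  Between-cluster level: exactly half the
   clusters are focal.
4. **Responses** — logistic GRM, `P(Y ≥ k | θ) = expit(a(θ − b_k))`.
   Uniform DIF of magnitude d ∈ {0, 0.4, 0.8} adds d to **all four**
   thresholds of the studied item for focal persons (a pure location shift);
   core items and reference persons are never shifted.

The logistic link is used for generation as well as analysis, keeping the
generating and fitted models on the same scale.  This is a consequential
convention: with identical (a, b) values a probit/normal-ogive generator
produces markedly more informative items (roughly a factor 1.7 on the latent
slope), and published power figures for nominally identical designs vary
accordingly.  Absolute power levels from this simulator therefore
characterize *these* conditions; the qualitative conclusions (see below) are
stable across link conventions.

What the simulator does **not** emulate: nonuniform DIF, unbalanced or
>2-group designs, group differences in the ability distribution, mixed
dichotomous/polytomous instruments, disordered category functioning, item-
or person-level missingness, three-level nesting.  Passing tests say nothing
about robustness to those features of real data.

## Monte-Carlo harness

Cells cross ICC × clusters {50, 100, 200} × cluster size {5, 10, 20} ×
DIF {0, 0.4, 0.8} × discrimination {low, high} × grouping level.  Per
replication both methods test the studied item on the *same* dataset (paired
comparison); rejection is the 1-df uniform-test p-value below α = 0.05.
Replication seeds derive from `SeedSequence(base_seed, spawn_key=(rep,))`,
and per-cell seeds from the design seed by the cell's index, so any subset
reruns identically regardless of order or parallel grouping.  Replications
with a non-converged fit are dropped from that method's denominator and
counted (`n_failed_fits`); a cell where every fit fails raises with
diagnostics.  Output is a tidy long table (factors × method with rejection
rate, binomial Monte-Carlo standard error, valid/failed counts), resumable
per cell.

The acceptance script runs the anchor cells at 500 replications for flat
power estimates, 300 for hierarchical power (the paired subset), and 1000
for the null cell — sizes at which the binomial standard error (~0.02) is
small against the effects of interest while the full run stays in the
minutes range on one CPU.

Reproduced qualitative findings (asserted by the acceptance tests): Type I
error of both methods inside the 99% binomial band around 0.05; power
non-decreasing in cluster count, cluster size, DIF magnitude and
discrimination; power ≈ 1 at DIF 0.8 with high discrimination; OLR at least
as powerful as HOLR for between-cluster grouping, with the two methods
nearly indistinguishable for within-cluster grouping.

## Diagnostics

The item characteristic function E[X | θ] = Σ_x x·p_x(θ) is computed from
the GRM category probabilities and equals the tail sum Σ_k P(Y ≥ k | θ)
(asserted as an identity test); overlaid focal/reference curves visualize
uniform DIF as a vertical gap.  Per-item ICC for clustered ordinal responses
comes from an intercept-only random-intercept fit on the latent logistic
scale, ICC = σ_u²/(σ_u² + π²/3); for data generated by a GRM with
discrimination a and latent ICC ρ this estimates a²ρ/(a² + π²/3), the
θ-scale ICC mapped through the logistic model (verified by
simulate-and-recover tests).  The design effect is the standard
1 + (m − 1)·ICC for mean cluster size m, with a conventional “hierarchical
analysis recommended” flag above 2 — guidance only, not a gate.

## Data interface

Delimited text with one row per person; a `DatasetSchema` declares item
columns, the cluster column, group columns with their level, the category
count, and any reverse-coded items (recoded x → K−1−x on read, for
instruments scored so that higher raw categories mean less of the
construct).  Validation names the offending row/column for out-of-range or
non-integer categories, rejects non-binary groups, and verifies
between-level groups are constant per cluster.  Rows with missing values in
analyzed columns are dropped listwise with a logged count — the simplest
defensible default given that the methods are complete-case likelihoods;
users with substantial missingness should impute upstream.  Results are
written as CSV (item / β / χ² / p layout, stable ordering, 6 significant
digits) or JSON with full fit metadata.

## Known limitations

- Absolute power levels are tied to the generating conventions documented
  above (link function, threshold sampling, total-score matching); they
  transfer across those conventions only qualitatively.
- No effect-size measure of DIF magnitude is provided — the tests are purely
  significance-based.
- No purification / anchor-item iteration: every item is tested against the
  raw total score, so heavy multi-item DIF contaminates the matching score.
- Random intercepts only; random ability slopes, crossed effects and
  three-level designs are out of scope.
- The σ_u² standard error is a plain observed-information/delta-method
  quantity and is unreliable near the boundary (it is suppressed at the
  boundary itself).
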