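# Methods

## Model

Bulk DNA methylation beta-values are modelled as a two-layer Gaussian
hierarchy.  For CpG site j (j = 1..m), sample i (i = 1..n) and cell type k
(k = 1..K), the latent cell-type-specific methylation signal is

    u_ijk ~ N( mu_jk + sum_l beta_jkl x_il , sigma_jk^2 ),

where x_i = (x_i1, ..., x_iq) are the sample's phenotypes (dummy-coded where
categorical) and beta_jkl is the effect of phenotype l on site j in cell
type k.  The observed bulk value is the composition-weighted mixture

    O_ji ~ N( sum_k u_ijk p_ki , sigma_eps_j^2 ),

with p_i = (p_1i, ..., p_Ki) on the probability simplex.  A site is a
risk-CpG site for phenotype l in cell type k when beta_jkl != 0, and a
risk site at the aggregate level when beta_jkl != 0 for at least one k.

Assumptions worth stating explicitly: beta-values are treated as Gaussian
despite their [0, 1] support (the baselines mu_jk are constrained to
[0, 1] and compositions to the simplex, so fitted means rarely leave the
unit interval); CpG sites are independent given the parameters; phenotype
effects are linear in the covariates.  Marginally over u,

    O_ji ~ N( p_i' mu_j + sum_l x_il p_i' B_l^(j),
              sum_k sigma_jk^2 p_ki^2 + sigma_eps_j^2 ),

which is the observed-data likelihood used for convergence monitoring and
model selection.  The model is identifiable under sufficient conditions
checked by `check_identifiability` (two rank conditions on the compositions
and covariates) and `check_anchor_condition` (each cell type owns a
phenotype-free CpG site fully methylated in it and unmethylated elsewhere,
or the flipped variant); the checkers report conditions, not a verdict,
because the conditions are sufficient only.

## Fitting

Parameters are estimated by a generalized EM algorithm on the complete-data
log-likelihood.  The E-step is closed-form: u_ij | O_ji is Gaussian with a
diagonal-minus-rank-one covariance, computed without any K x K inversion,
so one iteration costs O(n m K q) plus n simplex QPs of size K.  The M-step
is block coordinate ascent:

* (mu, B): per (site, cell type) least squares of E[u_ijk] on (1, x);
  mu_jk is clipped to [0, 1], and where clipping binds B is refitted at the
  clipped value;
* variances: closed-form expected squared residuals, floored at 1e-10;
  the `single_sigma` mode pools all sigma_jk^2 into one parameter — a
  variance-stabilized variant useful below roughly 150 samples;
* compositions: per sample, an exact active-set solver for the
  simplex-constrained quadratic program min_p p'A_i p - 2 b_i'p
  (projected-gradient fallback for degenerate curvature).

Each block increases the expected complete-data log-likelihood, so the
observed log-likelihood is non-decreasing along iterations; the test suite
asserts this on every fit it runs, which is the primary end-to-end oracle
tying the E- and M-steps together.

Initialization: compositions from an alternating constrained least-squares
decomposition O ~ mu P (columns of P on the simplex, mu clipped to [0, 1],
at most 50 alternations, two restarts keeping the lower residual, seeded
from K random sample columns); baselines from per-site regression on the
initial P; all phenotype effects at zero; variances drawn from an
inverse-gamma with shape 5 and mean 1e-3.  Label switching is not broken
during fitting (the likelihood is symmetric in cell-type labels);
`align_cell_types` resolves it afterwards by maximum-correlation optimal
assignment, for evaluation and annotation only.

Convergence: relative change of the observed log-likelihood below `tol`
(default 1e-6) or `max_iter` (default 1000).  On the benchmark designs the
likelihood keeps creeping for hundreds of iterations after the composition
estimates and the downstream test decisions have stabilised; the benchmark
driver and the acceptance runs therefore cap iterations (documented where
used) rather than run to full likelihood convergence.

## Association testing

Combining the two layers, E[O_ji] = mu_j1 + sum_{k>=2} (mu_jk - mu_j1) p_ki
+ sum_k sum_l beta_jkl x_il p_ki: compositions act multiplicatively on the
phenotype effects.  The test therefore regresses each site's bulk values on
the design [1, p_2., ..., p_K., x_l * p_k. (l = 1..q, k = 1..K)] with the
estimated compositions plugged in, and performs two-sided t-tests on the
q*K interaction coefficients with n - (q+1)K residual degrees of freedom
(the regression has (q+1)K columns, so this is the usual OLS choice).  Plug-in testing ignores the uncertainty in the estimated
compositions; this is a known approximation.  Family-wise error is
controlled by Bonferroni at alpha / (m K q) per cell-type-level test
(alpha = 0.01 by default); a site is significant at the aggregate level for
a phenotype if it is significant in at least one cell type.  The additive
baseline ("unadjusted analysis") regresses O_j. on (1, x) at threshold
alpha / m; because compositions depend on phenotypes, this baseline is
confounded and its false positive rate inflates by orders of magnitude on
the null benchmark — the phenomenon the multiplicative model removes.

## Choosing K

K is chosen on a user grid by a penalized BIC,

    pBIC(K) = -2 loglik
              + lambda_pen * [ (1 + 2K + qK) m log(n) + (K - 1) n log(m) ],

with several restarts per K and the best likelihood kept.  The penalty
mirrors the two parameter blocks: each site-level parameter (baseline,
effects, variances) is informed by the n samples and carries the usual BIC
weight log(n); each free composition coordinate is informed by the m sites
and carries log(m).  A uniform log(mn) penalty was evaluated and
over-penalizes — it exceeds the likelihood gain of a genuine extra cell
type and collapses the selection to the smallest K — while a plain log(n)
BIC ignores that the parameter count itself grows with m.  lambda_pen
(default 1) is exposed so the criterion can be recalibrated without an API
change.

## Reference annotation

Estimated baselines are annotated against reference methylomes (replicate
profiles averaged per cell type) by three similarity measures — cosine,
Pearson, Spearman — computed on the shared CpG sites.  Each measure votes
for its most similar reference; a cell type is annotated when at least two
measures agree and the agreeing measures exceed 0.5, otherwise it is
declared novel.  A zero-variance profile makes the correlation measures
abstain; ties break toward the smallest reference index.  Several
estimated cell types may map to one reference.

## Synthetic benchmark

The generator emulates a case-control EWAS with a continuous age covariate:

* baselines beta(3, 6) per site; lineage cell types 2..K_sim copy cell
  type 1 on a random 80% of sites plus N(0, 0.01^2) noise (clipped to
  [0, 1]) and are redrawn on the other 20% — inducing a lineage Pearson
  correlation of about 0.8.  The noise scale matches the model's two
  layers; the "small randomness" distribution is otherwise unspecified, so
  the same scale was chosen once.  K_sim = 2, 2, 3 for K = 3, 5, 7;
* the first n/3 samples are controls, the rest cases; age ~ Unif(20, 50);
* compositions Dirichlet(4, 4, 2 + 0.1 age) for controls and
  Dirichlet(4, 4, 5 + 0.1 age) for cases at K = 3 (analogous published
  vectors at K = 5 and 7), so compositions depend on both phenotypes in
  the null and the alternative scenario alike — this is what confounds
  the additive baseline;
* under the alternative, disease affects sites 1-10 in all cell types,
  11-20 in the lineage cell types, and one private 10-site block per
  non-lineage cell type (20 + 10(K - K_sim) risk sites per phenotype: 30,
  50, 60 for K = 3, 5, 7); age effects use the same layout on the block of
  sites immediately following the disease blocks (K = 3: sites 31-60).
  An alternative convention (`overlapping_age_block=True`) starts the age
  layout at site 21 instead, overlapping the disease blocks on sites
  21..20+10(K-K_sim).  The non-overlapping convention is the default
  because the overlap interacts badly with raw-age effects: age shifts of
  up to 0.75 at the overlapped sites push roughly a fifth of their
  observations into [0, 1]-truncation, which caps the disease power
  achievable there even when the true compositions are plugged into the
  test — an oracle ceiling below the benchmark levels this generator is
  meant to support.  Both risk masks are tracked separately under either
  convention;
* effect sizes are signed uniforms, |beta_disease| ~ Unif(0.07, 0.15),
  |beta_age| ~ Unif(0.007, 0.015), signs equiprobable;
* observations are the two-layer Gaussian draw with sd 0.01 at each layer;
  only O is truncated to [0, 1], never u.  The optional correlated-noise
  variant makes the observation noise AR(1) within 50-site blocks
  (correlation rho^|i-j|, marginal sd unchanged) to probe the independence
  assumption.

What the generator does not emulate: probe-level measurement artefacts,
batch effects, beta-value heteroscedasticity near the boundaries, genomic
dependence beyond the block-AR(1) variant, and reference-panel shift.
Passing benchmarks therefore demonstrate correctness of the machinery
under the model's own generative assumptions (plus the AR(1) violation),
not performance on any particular real cohort.

## Numerical choices and problem sizes

Variances are floored at 1e-10; simplex feasibility is enforced to 1e-10;
numerical rank uses the max(shape) * eps * sigma_max cut.  The QP
active-set loop is exact for strictly convex problems and falls back to
projected gradient otherwise.

Benchmark fitting protocol: four EM starts probed for 35 iterations each on
a random 3,000-site subsample (compositions are global, so initialization
basins — which differ mainly in how the lineage-correlated pair is mixed —
are distinguishable on a subset), the best observed likelihood continued on
all sites with an iteration cap of 100 and tolerance 1e-8.  Detection
metrics were verified to be stable from roughly iteration 100 to 500, far
before the likelihood plateau, so the cap trades nothing measurable.
Likelihood-ranked restarts measurably improve recovery: single-start fits
occasionally land in basins where one lineage cell type's detection drops
sharply.

Reported problem sizes: the unit suite exercises the pipeline at m around
100-5,000 with few EM iterations (structure and oracles); the acceptance
script runs the K = 3, n = 180 designs (null and alternative) at the full
m = 10,000 with 5 replicates each, and the K = 5, n = 300 design at full
m = 10,000 with one replicate.  A full acceptance run completes on a
single CPU in roughly a quarter of an hour.

## Known limitations

* The Gaussian observation model can place mass outside [0, 1]; extreme
  baseline sites (mean < 0.2 or > 0.8) are conventionally filtered first.
* Plug-in tests understate uncertainty in the compositions slightly;
  p-values under the null with *estimated* compositions are near-uniform
  in the benchmark but carry no formal guarantee.
* The EM objective is multimodal; lineage-correlated cell types create
  near-flat directions, so composition estimates retain a small bias at
  moderate n even at the likelihood optimum.  Restarts (and the pBIC
  curve's restarts) mitigate but do not remove this.
* The pBIC penalty weight is a calibration choice, not a derived constant.
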