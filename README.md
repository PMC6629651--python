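# hire-ewas

Cell-type-specific risk-CpG detection for epigenome-wide association
studies (EWAS).

## The problem

EWAS measure DNA methylation in bulk tissue, so every observed beta-value
is a mixture over cell types, weighted by each sample's unknown cellular
composition.  Compositions differ between samples and are themselves
associated with phenotypes such as disease status and age, which confounds
naive per-site regressions; and a phenotype may shift methylation in some
cell types only, which aggregate-level tests cannot see.  This package
implements a high-resolution reference-free deconvolution model for exactly
this setting: it estimates each sample's cell-type proportions, the
cell-type baseline methylomes, and per-(site, cell type, phenotype) effects
from the bulk matrix alone, then tests those effects.

## The model

For site j, sample i, cell type k, with phenotypes x_i:

    u_ijk ~ N( mu_jk + sum_l beta_jkl x_il , sigma_jk^2 )     (cell layer)
    O_ji  ~ N( sum_k u_ijk p_ki , sigma_eps_j^2 )             (bulk layer)

with p_i on the simplex and mu_jk in [0, 1].  Parameters are estimated by
a generalized EM algorithm (closed-form E-step; M-step with per-site
regressions, closed-form variances, and one exact simplex-constrained QP
per sample).  Plugging the estimated compositions into the implied
per-site regression

    E[O_ji] = mu_j1 + sum_{k>=2}(mu_jk - mu_j1) p_ki
              + sum_k sum_l beta_jkl x_il p_ki

gives two-sided t-tests of H0: beta_jkl = 0 — the compositions act
*multiplicatively* on the phenotype effects, which is what removes the
confounding that inflates additive baselines.  Bonferroni control at
alpha/(mKq) defines cell-type-level calls; a site is significant at the
aggregate level if it is significant in at least one cell type.  The
number of cell types can be chosen by a penalized BIC, and estimated cell
types can be annotated against reference methylomes by a cosine/Pearson/
Spearman 2-of-3 vote.  See `docs/methods.md` for details and assumptions.

## Worked example

```python
import hire_ewas as h

# a synthetic case-control EWAS: 3 cell types (two from one lineage),
# 180 samples, 2,000 CpG sites, 30 disease and 30 age risk sites
data = h.simulate_dataset(h.SimulationDesign(n=180, K=3, m=2000, seed=1))

model = h.HireModel(data.O, data.X)
result = model.fit(K=3, max_iter=150, seed=1, n_starts=3, probe_iter=30,
                   probe_sites=1000)
print(result.summary())

assoc = result.test_associations(alpha=0.01)
perm = h.align_cell_types(result.params.mu, data.truth.params.mu)
scores = h.evaluate_calls(assoc.permute_cell_types(perm).calls_cell,
                          data.truth, "cell_type")
print("disease TPR per cell type:", scores["tpr"][:, 0])
print("disease FPR per cell type:", scores["fpr"][:, 0])
```

Output from this exact script:

```
Hierarchical methylation deconvolution (generalized EM)
==========================================================
CpG sites:            2000
Samples:              180
Cell types (K):       3
Phenotypes (q):       2
Free parameters:      26360
Log-likelihood:       1097377.88
pBIC:                 -2057002.55
Converged:            False (150 iterations)
----------------------------------------------------------
Mean cell-type proportions: 0.490, 0.251, 0.259
Cell-type-level calls (p < 8.33e-07): 114
Aggregate-level risk-CpG sites (any phenotype): 59
disease TPR per cell type: [0.95 0.8  0.95]
disease FPR per cell type: [0. 0. 0.]
```

The summary reports the data dimensions, the log-likelihood and penalized
BIC of the fit, and the significance calls: 114 per-(site, cell type,
phenotype) associations at the Bonferroni threshold 0.01/(2000*3*2), which
collapse to 59 distinct risk-CpG sites at the aggregate level (the 60
planted sites minus one miss, at the iteration cap used here).  The final
two lines score the calls against the simulation truth after aligning the
(arbitrarily labelled) estimated cell types to the true ones: 95/80/95% of
the cell-type-specific disease effects are recovered with no false calls.

A command-line interface mirrors the library:

```sh
hire-ewas simulate --K 3 --n 180 --m 10000 --scenario alt --seed 1 --out sim/
hire-ewas fit --methylation sim/O.tsv --covariates sim/X.tsv --K 3 --out fit/
hire-ewas test --methylation sim/O.tsv --covariates sim/X.tsv --fit fit/ --out assoc/
hire-ewas select-k --methylation sim/O.tsv --covariates sim/X.tsv --kmin 2 --kmax 6 --out sel/
hire-ewas annotate --profiles fit/mu_hat.tsv --references refs.tsv --out annotations.tsv
hire-ewas benchmark --K 3 --n 180 --scenario both --replicates 5 --out bench/
```

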