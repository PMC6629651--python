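"""Synthetic EWAS data with known cell-type-specific risk-CpG sites.

The generator emulates a bulk methylation study in which each sample is a
mixture of K cell types, some from a shared lineage, with a binary disease
status and a continuous age covariate.  Structure:

* baselines mu_jk ~ beta(3, 6), with lineage cell types 2..K_sim copying
  cell type 1 on a random 80% of sites (plus small noise);
* the first n/3 samples are controls (disease = 0), the rest cases;
  age ~ Unif(20, 50);
* under the alternative, disease affects sites 1-10 in all cell types,
  11-20 in the lineage cell types only, and a private 10-site block per
  non-lineage cell type; age effects follow the same layout on the next
  block of sites (by default starting right after the disease blocks;
  ``overlapping_age_block=True`` instead starts the age layout at site 21,
  overlapping the disease blocks -- see the methods note for why the
  non-overlapping convention is the default).  Effect sizes are signed
  uniforms: |beta|~Unif(0.07, 0.15) for disease, Unif(0.007, 0.015) for
  age, and age enters the mean as the raw Unif(20, 50) covariate, so
  overlapping age effects push many observations into truncation;
* compositions are Dirichlet with phenotype-dependent concentrations (the
  last concentration is 2 + 0.1*age for controls and 5 + 0.1*age for cases),
  so compositions confound phenotypes even when all effects are zero;
* observations are a two-layer Gaussian draw with sd 0.01 at each layer,
  truncated to [0, 1]; optionally the observation noise is AR(1)-correlated
  within 50-site blocks to emulate dependence between nearby CpG sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .data import MethylationMatrix, PhenotypeMatrix, ValidationError
from .params import HireParams

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "SimulatedDataset",
    "default_K_sim",
    "generate_baseline",
    "generate_phenotypes",
    "generate_effects",
    "generate_compositions",
    "generate_observations",
    "simulate_dataset",
    "evaluate_calls",
    "align_cell_types",
]

SD_LAYER = 0.01  # Gaussian sd of both the latent and the observation layer
DIRICHLET_BASE = {
    3: [4.0, 4.0],
    5: [3.0, 3.0, 3.0, 3.0],
    7: [1.0, 3.0, 3.0, 3.0, 2.0, 2.0],
}


def default_K_sim(K: int) -> int:
    """Lineage-similar cell count used in the benchmark designs."""
    return {3: 2, 5: 2, 7: 3}.get(K, 2)


@dataclass
class SimulationDesign:
    n: int = 180
    K: int = 3
    K_sim: int | None = None
    m: int = 10000
    scenario: str = "true_alternative"  # or "true_null"
    rho: Optional[float] = None
    block_size: int = 50
    seed: int | None = None
    overlapping_age_block: bool = False

    def __post_init__(self) -> None:
        if self.K_sim is None:
            self.K_sim = default_K_sim(self.K)
        if self.K_sim > self.K or self.K_sim < 1:
            raise ValidationError(f"K_sim={self.K_sim} must be in [1, K={self.K}]")
        if self.n % 3 != 0:
            raise ValidationError(f"n={self.n} must be divisible by 3 (one third controls)")
        if self.scenario not in ("true_null", "true_alternative"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.rho is not None and not (0.0 <= self.rho < 1.0):
            raise ValidationError(f"rho={self.rho} must be in [0, 1)")

    @property
    def n_risk_sites(self) -> int:
        """Risk-CpG count per phenotype: 20 + 10 (K - K_sim)."""
        return 20 + 10 * (self.K - self.K_sim)


@dataclass
class SimulationTruth:
    params: HireParams
    risk_sites_disease: np.ndarray  # sorted site indices
    risk_sites_age: np.ndarray
    risk_mask: np.ndarray  # m x K x 2 booleans, consistent with B != 0 layout


@dataclass
class SimulatedDataset:
    O: MethylationMatrix
    X: PhenotypeMatrix
    truth: SimulationTruth
    u: np.ndarray = field(repr=False, default=None)  # latent signals (n, m, K)
    design: SimulationDesign | None = None


# ---------------------------------------------------------------------------

def generate_baseline(
    m: int, K: int, K_sim: int, rng: np.random.Generator,
    lineage_sd: float = SD_LAYER,
) -> np.ndarray:
    """Baseline profiles mu (m x K) with a lineage of K_sim similar cell types.

    Cell types 1 and K_sim+1..K are i.i.d. beta(3, 6) per site.  Each lineage
    cell type k' = 2..K_sim redraws an independent random 20% of sites from
    beta(3, 6) and copies cell type 1 on the other 80%, plus N(0, lineage_sd^2)
    noise, clipped to [0, 1].
    """
    if K_sim < 1 or K_sim > K:
        raise ValidationError(f"K_sim={K_sim} must be in [1, K={K}]")
    mu = np.empty((m, K))
    mu[:, 0] = rng.beta(3, 6, size=m)
    for k in range(K_sim, K):
        mu[:, k] = rng.beta(3, 6, size=m)
    for k in range(1, K_sim):
        redraw = rng.random(m) < 0.2
        col = mu[:, 0] + rng.normal(0.0, lineage_sd, size=m)
        col[redraw] = rng.beta(3, 6, size=int(redraw.sum()))
        mu[:, k] = np.clip(col, 0.0, 1.0)
    return mu


def generate_phenotypes(n: int, rng: np.random.Generator) -> PhenotypeMatrix:
    """Disease status (first n/3 controls, rest cases) and age ~ Unif(20, 50)."""
    if n % 3 != 0:
        raise ValidationError(f"n={n} must be divisible by 3")
    disease = np.zeros(n)
    disease[n // 3:] = 1.0
    age = rng.uniform(20.0, 50.0, size=n)
    return PhenotypeMatrix(
        values=np.column_stack([disease, age]),
        phenotype_names=["disease", "age"],
        sample_ids=[f"sample_{i + 1}" for i in range(n)],
    )


def _effect_layout(m: int, K: int, K_sim: int, offset: int) -> np.ndarray:
    """Boolean m x K mask of nonzero effects starting at site ``offset``.

    Sites offset..offset+9 in all cell types; offset+10..offset+19 in the
    lineage cell types 1..K_sim only; then one private 10-site block per
    non-lineage cell type.
    """
    mask = np.zeros((m, K), dtype=bool)
    mask[offset:offset + 10, :] = True
    mask[offset + 10:offset + 20, :K_sim] = True
    for k in range(K_sim, K):
        start = offset + 20 + 10 * (k - K_sim)
        mask[start:start + 10, k] = True
    return mask


def generate_effects(
    m: int, K: int, K_sim: int, scenario: str, rng: np.random.Generator,
    overlapping_age_block: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Effect tensor B (m x K x 2) and its boolean risk mask.

    The age layout mirrors the disease layout.  By default it occupies the
    block of sites immediately after the disease blocks; with
    ``overlapping_age_block=True`` it starts at site 21 instead, overlapping
    the disease layout on sites 21..20+10(K-K_sim).

    Note that the draws below are made in a fixed order, so a shared RNG
    stream yields identical null/alternative layouts up to the effect values.
    """
    extent = 20 + 10 * (K - K_sim)  # risk sites per phenotype
    age_offset = 20 if overlapping_age_block else extent
    needed = age_offset + extent
    if m < needed:
        raise ValidationError(
            f"m={m} too small for the risk-site layout; need at least {needed}"
        )
    mask = np.zeros((m, K, 2), dtype=bool)
    B = np.zeros((m, K, 2))
    if scenario == "true_null":
        return B, mask
    if scenario != "true_alternative":
        raise ValidationError(f"unknown scenario {scenario!r}")
    mask[:, :, 0] = _effect_layout(m, K, K_sim, 0)           # disease from site 1
    mask[:, :, 1] = _effect_layout(m, K, K_sim, age_offset)  # age block follows
    for l, (lo, hi) in enumerate([(0.07, 0.15), (0.007, 0.015)]):
        idx = np.nonzero(mask[:, :, l])
        n_eff = idx[0].size
        omega = rng.uniform(lo, hi, size=n_eff)
        sign = rng.choice([-1.0, 1.0], size=n_eff)
        B[idx[0], idx[1], l] = sign * omega
    return B, mask


def generate_compositions(
    n: int,
    K: int,
    X: PhenotypeMatrix,
    rng: np.random.Generator,
    base_concentration: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Phenotype-dependent Dirichlet compositions, K x n.

    The last concentration entry is 2 + 0.1*age for controls and 5 + 0.1*age
    for cases; the leading entries are the design constants for K in
    {3, 5, 7}, or a user-supplied vector of length K - 1 otherwise.
    """
    if base_concentration is None:
        if K not in DIRICHLET_BASE:
            raise ValidationError(
                f"no built-in Dirichlet design for K={K}; pass base_concentration"
            )
        base = np.asarray(DIRICHLET_BASE[K], dtype=float)
    else:
        base = np.asarray(base_concentration, dtype=float)
        if base.size != K - 1:
            raise ValidationError("base_concentration must have length K - 1")
    disease = X.values[:, 0]
    age = X.values[:, 1]
    P = np.empty((K, n))
    for i in range(n):
        last = (5.0 if disease[i] > 0.5 else 2.0) + 0.1 * age[i]
        P[:, i] = rng.dirichlet(np.append(base, last))
    return P


def _ar1_noise(
    m: int, n: int, sd: float, rho: float, block_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Observation noise (m x n) AR(1)-correlated within consecutive site blocks.

    Within a block the correlation between sites i and j is rho^|i-j|; the
    marginal sd stays at ``sd``; blocks (and samples) are independent.
    """
    eps = np.empty((m, n))
    scale = np.sqrt(1.0 - rho ** 2)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        z = rng.normal(0.0, 1.0, size=(stop - start, n))
        e = np.empty_like(z)
        e[0] = z[0]
        for t in range(1, stop - start):
            e[t] = rho * e[t - 1] + scale * z[t]
        eps[start:stop] = sd * e
    return eps


def generate_observations(
    mu: np.ndarray,
    B: np.ndarray,
    P: np.ndarray,
    X: PhenotypeMatrix,
    rng: np.random.Generator,
    sd_u: float = SD_LAYER,
    sd_eps: float = SD_LAYER,
    rho: Optional[float] = None,
    block_size: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-layer draw of the bulk matrix O (m x n) and latent signals u.

    u_ijk ~ N(mu_jk + B_jk. x_i, sd_u^2); O_ji ~ N(sum_k u_ijk p_ki, sd_eps^2);
    O is truncated to [0, 1] (u is not).  When ``rho`` is given the
    observation-layer noise is AR(1)-correlated within site blocks.
    """
    m, K = mu.shape
    n = P.shape[1]
    prior = mu[None, :, :] + np.einsum("mkq,nq->nmk", B, X.values, optimize=True)
    u = prior + rng.normal(0.0, sd_u, size=(n, m, K)) if sd_u > 0 else prior
    signal = np.einsum("nmk,kn->mn", u, P, optimize=True)
    if rho is None or rho == 0.0:
        eps = rng.normal(0.0, sd_eps, size=(m, n)) if sd_eps > 0 else 0.0
    else:
        eps = _ar1_noise(m, n, sd_eps, rho, block_size, rng)
    O = np.clip(signal + eps, 0.0, 1.0)
    return O, u


def simulate_dataset(design: SimulationDesign, rng=None) -> SimulatedDataset:
    """Generate one full dataset (O, X, truth) under the given design."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu = generate_baseline(design.m, design.K, design.K_sim, rng)
    X = generate_phenotypes(design.n, rng)
    B, mask = generate_effects(design.m, design.K, design.K_sim, design.scenario,
                               rng, overlapping_age_block=design.overlapping_age_block)
    P = generate_compositions(design.n, design.K, X, rng)
    O, u = generate_observations(
        mu, B, P, X, rng, rho=design.rho, block_size=design.block_size
    )
    params = HireParams(
        P=P, mu=mu, B=B,
        Sigma=np.full((design.m, design.K), SD_LAYER ** 2),
        sigma_eps=np.full(design.m, SD_LAYER ** 2),
    )
    truth = SimulationTruth(
        params=params,
        risk_sites_disease=np.flatnonzero(mask[:, :, 0].any(axis=1)),
        risk_sites_age=np.flatnonzero(mask[:, :, 1].any(axis=1)),
        risk_mask=mask,
    )
    O_mat = MethylationMatrix(
        values=O,
        site_ids=[f"cpg_{j + 1}" for j in range(design.m)],
        sample_ids=list(X.sample_ids),
    )
    return SimulatedDataset(O=O_mat, X=X, truth=truth, u=u, design=design)


# ---------------------------------------------------------------------------
# Benchmark metrics and label alignment
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: np.ndarray, truth: SimulationTruth, level: str = "aggregate"
) -> dict:
    """FPR/TPR of significance calls against the simulation truth.

    ``aggregate``: ``calls`` is m x q booleans (a site is at risk for
    phenotype l if it is at risk in at least one cell type).
    ``cell_type``: ``calls`` is m x K x q booleans, compared per (site, cell
    type); the caller must have aligned estimated cell types to the truth.
    """
    calls = np.asarray(calls, dtype=bool)
    if level == "aggregate":
        true_mask = truth.risk_mask.any(axis=1)  # m x q
    elif level == "cell_type":
        true_mask = truth.risk_mask
    else:
        raise ValidationError(f"unknown level {level!r}")
    if calls.shape != true_mask.shape:
        raise ValidationError(
            f"calls shape {calls.shape} does not match truth shape {true_mask.shape}"
        )
    tp = np.logical_and(calls, true_mask).sum(axis=0)
    fp = np.logical_and(calls, ~true_mask).sum(axis=0)
    n_pos = true_mask.sum(axis=0)
    n_neg = (~true_mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(n_pos > 0, tp / np.maximum(n_pos, 1), np.nan)
        fpr = np.where(n_neg > 0, fp / np.maximum(n_neg, 1), np.nan)
    return {"tpr": tpr, "fpr": fpr, "n_risk": n_pos, "n_null": n_neg}


def align_cell_types(mu_hat: np.ndarray, mu_true: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` with mu_hat[:, perm[k]] matched to mu_true[:, k].

    Chosen to maximise the sum of per-pair Pearson correlations between
    matched baseline profiles (optimal assignment); resolves label switching
    for evaluation and annotation only.
    """
    K = mu_true.shape[1]
    if mu_hat.shape != mu_true.shape:
        raise ValidationError("mu_hat and mu_true must share a shape to be aligned")
    corr = np.empty((K, K))
    for k_true in range(K):
        for k_hat in range(K):
            corr[k_true, k_hat] = pearsonr(mu_true[:, k_true], mu_hat[:, k_hat])[0]
    corr = np.nan_to_num(corr, nan=-1.0)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm
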