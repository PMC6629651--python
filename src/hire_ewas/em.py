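"""Generalized EM fitting of the hierarchical deconvolution model.

The complete-data log-likelihood is, up to a constant,

    l_c = sum_ij { -1/2 log sigma_eps_j^2 - (O_ji - u_ij' p_i)^2 / (2 sigma_eps_j^2)
                   - 1/2 sum_k log sigma_jk^2
                   - 1/2 (u_ij - mu_j - B^(j) x_i)' Sigma_j^{-1} (u_ij - mu_j - B^(j) x_i) }.

The E-step computes the Gaussian conditional of u_ij given O_ji in closed
form (diagonal-minus-rank-one posterior covariance, so no K x K inversion is
needed).  The M-step is a block coordinate ascent on the expected complete
log-likelihood: (mu, B) by per-(site, cell type) least squares with mu
projected to [0, 1]; the variances in closed form; the compositions by one
simplex-constrained quadratic program per sample.  Each block increases the
expected complete log-likelihood, so the observed log-likelihood is
non-decreasing across iterations (the GEM guarantee, used as the primary
correctness oracle in the tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DimensionError, MethylationMatrix, PhenotypeMatrix, ValidationError, check_paired
from .likelihood import observed_loglikelihood
from .params import HireParams, LatentMoments
from .qp import solve_simplex_qp

__all__ = [
    "FitConfig",
    "FitResult",
    "initialize",
    "e_step",
    "m_step_mu_B",
    "m_step_variances",
    "m_step_proportions",
    "fit",
]

VARIANCE_FLOOR = 1e-10


@dataclass
class FitConfig:
    max_iter: int = 1000
    tol: float = 1e-6
    variance_mode: str = "per_site_celltype"  # or "single_sigma"
    seed: int | None = None
    init: HireParams | None = None  # user-supplied start; default is ALS-based
    init_alternations: int = 50
    init_restarts: int = 2
    n_starts: int = 1     # independent EM starts; best likelihood kept
    probe_iter: int = 25  # iterations run per start before the winner is picked
    probe_sites: int | None = None  # probe starts on a site subsample (cheaper)

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.n_starts < 1 or self.probe_iter < 1:
            raise ValidationError("n_starts and probe_iter must be >= 1")
        if self.variance_mode not in ("per_site_celltype", "single_sigma"):
            raise ValidationError(f"unknown variance_mode {self.variance_mode!r}")


@dataclass
class FitResult:
    params: HireParams
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


# ---------------------------------------------------------------------------
# Initialization: alternating constrained least squares on O ~ mu P
# ---------------------------------------------------------------------------

def _als_decompose(
    O: np.ndarray, K: int, rng: np.random.Generator, n_alt: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of alternating least squares O ~ mu P with mu in [0,1]^(mxK)
    and the columns of P on the simplex.  Returns (mu, P, residual norm)."""
    m, n = O.shape
    # seed mu with K randomly chosen sample columns (a standard NMF start)
    cols = rng.choice(n, size=K, replace=False)
    mu = np.clip(O[:, cols] + rng.normal(0.0, 0.01, size=(m, K)), 0.0, 1.0)
    P = np.full((K, n), 1.0 / K)
    prev_resid = np.inf
    for _ in range(n_alt):
        A = mu.T @ mu
        Bmat = mu.T @ O  # K x n
        for i in range(n):
            P[:, i] = solve_simplex_qp(A, Bmat[:, i])
        # mu step: unconstrained ridge-free LS then projection to [0, 1]
        PPt = P @ P.T
        try:
            mu = np.clip(np.linalg.solve(PPt, P @ O.T).T, 0.0, 1.0)
        except np.linalg.LinAlgError:
            mu = np.clip((np.linalg.pinv(PPt) @ (P @ O.T)).T, 0.0, 1.0)
        resid = float(np.linalg.norm(O - mu @ P))
        if prev_resid - resid < 1e-8 * max(prev_resid, 1.0):
            break
        prev_resid = resid
    return mu, P, float(np.linalg.norm(O - mu @ P))


def initialize(
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    K: int,
    rng: np.random.Generator | None = None,
    n_alternations: int = 50,
    n_restarts: int = 2,
) -> HireParams:
    """Starting values: compositions from a simplex-constrained matrix
    decomposition of O, baselines from per-site least squares, phenotype
    effects at zero, variances drawn inverse-gamma with small mean (~1e-3).
    """
    rng = np.random.default_rng(rng)
    m, n = O.values.shape
    if K > n or K > m:
        raise ValidationError(f"K={K} exceeds the number of samples ({n}) or sites ({m})")
    check_paired(O, X)
    q = X.n_phenotypes

    if K == 1:
        mu = np.clip(O.values.mean(axis=1, keepdims=True), 0.0, 1.0)
        P = np.ones((1, n))
    else:
        best: tuple[np.ndarray, np.ndarray, float] | None = None
        for _ in range(max(1, n_restarts)):
            cand = _als_decompose(O.values, K, rng, n_alternations)
            if best is None or cand[2] < best[2]:
                best = cand
        mu, P, _ = best
        # refit the baselines by per-site regression of O_j. on the fitted P
        try:
            mu = np.clip(np.linalg.solve(P @ P.T, P @ O.values.T).T, 0.0, 1.0)
        except np.linalg.LinAlgError:
            pass

    B = np.zeros((m, K, q))
    # inverse-gamma(shape=5, scale=4e-3): mean = scale / (shape - 1) = 1e-3
    shape_ig, scale_ig = 5.0, 4e-3
    Sigma = scale_ig / rng.gamma(shape_ig, 1.0, size=(m, K))
    sigma_eps = scale_ig / rng.gamma(shape_ig, 1.0, size=m)
    return HireParams(P=P, mu=mu, B=B, Sigma=np.maximum(Sigma, VARIANCE_FLOOR),
                      sigma_eps=np.maximum(sigma_eps, VARIANCE_FLOOR))


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def e_step(params: HireParams, O: MethylationMatrix, X: PhenotypeMatrix) -> LatentMoments:
    """Posterior moments of u_ij given O_ji.

    With prior mean m_ij = mu_j + B^(j) x_i, the conditional is Gaussian with
    covariance Sigma_j - (Sigma_j p_i)(Sigma_j p_i)' / d_ij and mean
    m_ij + (Sigma_j p_i) (O_ji - p_i' m_ij) / d_ij, where
    d_ij = p_i' Sigma_j p_i + sigma_eps_j^2.
    """
    P, mu, B, Sigma = params.P, params.mu, params.B, params.Sigma
    Xv = X.values
    # prior means, (n, m, K)
    prior = mu[None, :, :] + np.einsum("mkq,nq->nmk", B, Xv, optimize=True)
    denom = (Sigma @ (P ** 2) + params.sigma_eps[:, None]).T  # (n, m)
    resid = O.values.T - np.einsum("nmk,kn->nm", prior, P, optimize=True)
    a = Sigma[None, :, :] * P.T[:, None, :]  # (n, m, K): Sigma_j * p_i
    gain = a / denom[:, :, None]
    mean = prior + gain * resid[:, :, None]
    var_diag = Sigma[None, :, :] - a * gain
    return LatentMoments(mean=mean, var_diag=var_diag, denom=denom,
                         Sigma=Sigma.copy(), P=P.copy())


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def m_step_mu_B(
    moments: LatentMoments, X: PhenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Update (mu, B) by per-(site, cell type) least squares of E[u] on (1, X).

    mu is then projected to [0, 1] coordinate-wise; wherever the projection
    is active, B is refitted with the projected mu held fixed.
    """
    Xv = X.values
    n, m, K = moments.mean.shape
    q = Xv.shape[1]
    D = np.hstack([np.ones((n, 1)), Xv])  # n x (q+1)
    DtD = D.T @ D
    if q > 0:
        col_var = Xv.var(axis=0)
        if np.any(col_var <= 0):
            bad = int(np.argmin(col_var))
            name = (X.phenotype_names[bad] if X.phenotype_names else f"column {bad}")
            raise ValidationError(f"covariate {name!r} is constant; design is singular")
    try:
        G = np.linalg.solve(DtD, D.T)  # (q+1) x n
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular regression design for the (mu, B) update") from exc
    theta = np.einsum("pn,nmk->pmk", G, moments.mean, optimize=True)
    mu_raw = theta[0]
    B = np.moveaxis(theta[1:], 0, 2) if q > 0 else np.zeros((m, K, 0))
    mu = np.clip(mu_raw, 0.0, 1.0)
    clipped = mu != mu_raw
    if q > 0 and clipped.any():
        # refit B at the projected mu for the clipped (j, k) entries
        GX = np.linalg.solve(Xv.T @ Xv, Xv.T)  # q x n
        jj, kk = np.nonzero(clipped)
        resid = moments.mean[:, jj, kk] - mu[jj, kk][None, :]  # n x n_clip
        B[jj, kk, :] = (GX @ resid).T
    return mu, B


def m_step_variances(
    moments: LatentMoments,
    mu: np.ndarray,
    B: np.ndarray,
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    mode: str = "per_site_celltype",
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form variance updates.

    sigma_jk^2 = (1/n) sum_i E[(u_ijk - mu_jk - B_jk. x_i)^2]
    sigma_eps_j^2 = (1/n) sum_i E[(O_ji - u_ij' p_i)^2]

    ``single_sigma`` pools all sigma_jk^2 into one value (the variance-
    stabilized variant for small samples).
    """
    n, m, K = moments.mean.shape
    fitted = mu[None, :, :] + np.einsum("mkq,nq->nmk", B, X.values, optimize=True)
    sq = (moments.mean - fitted) ** 2 + moments.var_diag
    Sigma_new = sq.mean(axis=0)  # m x K
    if mode == "single_sigma":
        Sigma_new = np.full_like(Sigma_new, Sigma_new.mean())
    elif mode != "per_site_celltype":
        raise ValidationError(f"unknown variance mode {mode!r}")

    P = moments.P
    resid_obs = O.values.T - np.einsum("nmk,kn->nm", moments.mean, P, optimize=True)
    # p' V p = s - s^2/d = s (d - s)/d with s = p' Sigma p (from the E-step)
    s = (moments.Sigma @ (P ** 2)).T  # (n, m)
    pVp = s * (moments.denom - s) / moments.denom
    sigma_eps_new = (resid_obs ** 2 + pVp).mean(axis=0)  # m
    return (
        np.maximum(Sigma_new, VARIANCE_FLOOR),
        np.maximum(sigma_eps_new, VARIANCE_FLOOR),
    )


def m_step_proportions(
    moments: LatentMoments, O: MethylationMatrix, sigma_eps: np.ndarray
) -> np.ndarray:
    """Update each sample's composition by a simplex-constrained QP.

    For sample i: minimise p' A_i p - 2 b_i' p over the simplex, with
    A_i = sum_j E[u_ij u_ij'] / sigma_eps_j^2 and
    b_i = sum_j O_ji E[u_ij] / sigma_eps_j^2.
    """
    n, m, K = moments.mean.shape
    w = 1.0 / np.asarray(sigma_eps, dtype=float)  # m
    Sigma = moments.Sigma
    P_new = np.empty((K, n))
    diag_base = (Sigma * w[:, None]).sum(axis=0)  # sum_j Sigma_j w_j, length K
    for i in range(n):
        mean_i = moments.mean[i]  # m x K
        a_i = Sigma * moments.P[:, i][None, :]  # m x K
        scale = np.sqrt(w / moments.denom[i])  # m
        A = (
            (mean_i * w[:, None]).T @ mean_i
            + np.diag(diag_base)
            - (a_i * scale[:, None]).T @ (a_i * scale[:, None])
        )
        b = (O.values[:, i] * w) @ mean_i
        try:
            P_new[:, i] = solve_simplex_qp(A, b)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"composition QP failed for sample {i}") from exc
    return P_new


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------

def fit(
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    K: int,
    config: FitConfig | None = None,
) -> FitResult:
    """Run generalized EM until the relative observed log-likelihood change
    drops below ``config.tol`` or ``config.max_iter`` is reached."""
    config = config or FitConfig()
    check_paired(O, X)
    q = X.n_phenotypes
    n = O.n_samples
    if n < (q + 1) * K:
        warnings.warn(
            f"n={n} samples is below (q+1)K={(q + 1) * K}; estimates and "
            "plug-in tests may be unstable",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)

    def _new_start() -> HireParams:
        return initialize(
            O, X, K, rng,
            n_alternations=config.init_alternations,
            n_restarts=config.init_restarts,
        )

    if config.init is not None or config.n_starts == 1:
        params = config.init.copy() if config.init is not None else _new_start()
        trace = [observed_loglikelihood(params, O, X)]
        return _em_loop(params, O, X, config, config.max_iter, trace)

    # multi-start: probe each start briefly, keep the best likelihood.
    # Compositions are shared across sites, so the probes may run on a site
    # subsample: basins of the optimisation (which differ mainly in how the
    # lineage-correlated cell types are mixed) show up on a subset just as
    # they do on the full matrix, at a fraction of the cost.
    probe = min(config.probe_iter, config.max_iter)
    m = O.n_sites
    subsample = (config.probe_sites is not None and config.probe_sites < m
                 and config.n_starts > 1)
    if subsample:
        sub_idx = np.sort(rng.choice(m, size=config.probe_sites, replace=False))
        O_probe = MethylationMatrix(
            O.values[sub_idx],
            site_ids=[O.site_ids[j] for j in sub_idx],
            sample_ids=list(O.sample_ids),
        )
    else:
        O_probe = O
    best: FitResult | None = None
    for _ in range(config.n_starts):
        params = initialize(
            O_probe, X, K, rng,
            n_alternations=config.init_alternations,
            n_restarts=config.init_restarts,
        )
        trace = [observed_loglikelihood(params, O_probe, X)]
        cand = _em_loop(params, O_probe, X, config, probe, trace)
        if best is None or cand.loglik > best.loglik:
            best = cand
    if not subsample:
        if best.converged or best.n_iter >= config.max_iter:
            return best
        return _em_loop(best.params, O, X, config,
                        config.max_iter - best.n_iter, best.loglik_trace,
                        start_iter=best.n_iter)
    # lift the winning compositions to the full site set: baselines by
    # per-site least squares on P, effects at zero, variances re-drawn
    P0 = best.params.P
    try:
        mu0 = np.clip(np.linalg.solve(P0 @ P0.T, P0 @ O.values.T).T, 0.0, 1.0)
    except np.linalg.LinAlgError:
        mu0 = np.clip((np.linalg.pinv(P0 @ P0.T) @ (P0 @ O.values.T)).T, 0.0, 1.0)
    shape_ig, scale_ig = 5.0, 4e-3
    params = HireParams(
        P=P0, mu=mu0, B=np.zeros((m, K, X.n_phenotypes)),
        Sigma=np.maximum(scale_ig / rng.gamma(shape_ig, 1.0, (m, K)), VARIANCE_FLOOR),
        sigma_eps=np.maximum(scale_ig / rng.gamma(shape_ig, 1.0, m), VARIANCE_FLOOR),
    )
    trace = [observed_loglikelihood(params, O, X)]
    return _em_loop(params, O, X, config, config.max_iter, trace)


def _em_loop(
    params: HireParams,
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    config: FitConfig,
    n_iter: int,
    trace: list[float],
    start_iter: int = 0,
) -> FitResult:
    converged = False
    it = start_iter
    for it in range(start_iter + 1, start_iter + n_iter + 1):
        try:
            moments = e_step(params, O, X)
            mu, B = m_step_mu_B(moments, X)
            Sigma, sigma_eps = m_step_variances(
                moments, mu, B, O, X, mode=config.variance_mode
            )
            P = m_step_proportions(moments, O, sigma_eps)
        except Exception as exc:
            raise RuntimeError(f"EM iteration {it} failed: {exc}") from exc
        params = HireParams(P=P, mu=mu, B=B, Sigma=Sigma, sigma_eps=sigma_eps)
        ll = observed_loglikelihood(params, O, X)
        trace.append(ll)
        rel_change = abs(ll - trace[-2]) / (abs(trace[-2]) + 1e-300)
        if rel_change < config.tol:
            converged = True
            break
    return FitResult(params=params, loglik_trace=trace, converged=converged, n_iter=it)
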