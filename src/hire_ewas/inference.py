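"""Association testing.

Cell-type-specific tests plug the estimated compositions into a per-site
linear regression whose mean follows from the hierarchy:

    E[O_ji] = mu_j1 + sum_{k=2}^K (mu_jk - mu_j1) p_ki
              + sum_k sum_l beta_jkl x_il p_ki.

The design therefore concatenates an intercept, the K-1 composition columns
p_ki (k = 2..K), and the q*K multiplicative interaction columns x_il * p_ki;
a two-sided t-test on each interaction coefficient tests H0: beta_jkl = 0.
Significance uses a Bonferroni family-wise rule at alpha / (m K q); a site is
significant at the aggregate level for phenotype l if it is significant in at
least one cell type.

The additive baseline ("unadjusted analysis") regresses O_j. on (1, X) with
no composition terms at threshold alpha / m; because compositions depend on
the phenotypes, this baseline's false positive rate inflates dramatically
under the null — the confounding the multiplicative model removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DimensionError, MethylationMatrix, PhenotypeMatrix, ValidationError, check_paired

__all__ = ["AssociationResults", "build_design", "test_hire", "test_unadjusted"]


@dataclass
class AssociationResults:
    """Per (site, cell type, phenotype) plug-in test results."""

    beta_hat: np.ndarray      # m x K x q
    t_stat: np.ndarray        # m x K x q
    p_value: np.ndarray       # m x K x q
    aggregate_p: np.ndarray   # m x q, min over cell types
    calls_cell: np.ndarray    # m x K x q booleans
    calls_aggregate: np.ndarray  # m x q booleans
    alpha: float
    threshold_cell: float
    df_resid: int
    threshold_aggregate_rule: str = (
        "significant at aggregate level if significant in >= 1 cell type"
    )

    def permute_cell_types(self, perm) -> "AssociationResults":
        """Relabel the cell-type axis (e.g. after alignment to a truth)."""
        perm = np.asarray(perm, dtype=int)
        return AssociationResults(
            beta_hat=self.beta_hat[:, perm, :],
            t_stat=self.t_stat[:, perm, :],
            p_value=self.p_value[:, perm, :],
            aggregate_p=self.aggregate_p,
            calls_cell=self.calls_cell[:, perm, :],
            calls_aggregate=self.calls_aggregate,
            alpha=self.alpha,
            threshold_cell=self.threshold_cell,
            df_resid=self.df_resid,
            threshold_aggregate_rule=self.threshold_aggregate_rule,
        )


def build_design(P_hat: np.ndarray, X: PhenotypeMatrix) -> np.ndarray:
    """n x (q+1)K design: [1, p_2.., p_K., x_1*p_1., ..., x_q*p_K.].

    Interaction columns are ordered phenotype-major: for each phenotype l,
    the K columns x_il * p_ki, k = 1..K.
    """
    P_hat = np.asarray(P_hat, dtype=float)
    K, n = P_hat.shape
    Xv = X.values if isinstance(X, PhenotypeMatrix) else np.asarray(X, dtype=float)
    if Xv.shape[0] != n:
        raise DimensionError(
            f"sample axis: P_hat covers {n} samples, covariates have {Xv.shape[0]}"
        )
    q = Xv.shape[1]
    cols = [np.ones((n, 1)), P_hat[1:, :].T]
    for l in range(q):
        cols.append(Xv[:, l][:, None] * P_hat.T)
    D = np.hstack(cols)
    s = np.linalg.svd(D, compute_uv=False)
    cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    if cond > 1e8:
        warnings.warn(
            f"association design is near-collinear (condition number {cond:.3g})",
            UserWarning,
            stacklevel=2,
        )
    return D


def _ols_all_sites(D: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of every row of Y (m x n) on the shared design D (n x p).

    Returns (coefficients p x m, standard errors p x m, residual df).
    """
    n, p = D.shape
    df = n - p
    if df <= 0:
        raise ValidationError(
            f"no residual degrees of freedom: n={n} samples, {p} regression columns"
        )
    DtD = D.T @ D
    G = np.linalg.solve(DtD, D.T)          # p x n
    coef = G @ Y.T                          # p x m
    resid = Y.T - D @ coef                  # n x m
    s2 = (resid ** 2).sum(axis=0) / df      # m
    diag = np.diag(np.linalg.inv(DtD))      # p
    se = np.sqrt(np.outer(diag, s2))        # p x m
    return coef, se, df


def test_hire(
    O: MethylationMatrix,
    P_hat: np.ndarray,
    X: PhenotypeMatrix,
    alpha: float = 0.01,
) -> AssociationResults:
    """Cell-type-specific plug-in tests of beta_jkl = 0 for every site."""
    check_paired(O, X)
    P_hat = np.asarray(P_hat, dtype=float)
    K = P_hat.shape[0]
    q = X.n_phenotypes
    m = O.n_sites
    D = build_design(P_hat, X)
    coef, se, df = _ols_all_sites(D, O.values)
    # interaction block: columns K..K+qK-1, phenotype-major then cell type
    inter = slice(K, K + q * K)
    beta = coef[inter].reshape(q, K, m).transpose(2, 1, 0)   # m x K x q
    se_b = se[inter].reshape(q, K, m).transpose(2, 1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_b > 0, beta / se_b, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    threshold = alpha / (m * K * q)
    calls_cell = p < threshold
    return AssociationResults(
        beta_hat=beta,
        t_stat=t,
        p_value=p,
        aggregate_p=p.min(axis=1),
        calls_cell=calls_cell,
        calls_aggregate=calls_cell.any(axis=1),
        alpha=alpha,
        threshold_cell=threshold,
        df_resid=df,
    )


@dataclass
class UnadjustedResults:
    """Per (site, phenotype) results of the additive no-composition baseline."""

    tau_hat: np.ndarray    # m x q
    t_stat: np.ndarray
    p_value: np.ndarray
    calls: np.ndarray      # m x q booleans at alpha / m
    alpha: float
    threshold: float
    df_resid: int


def test_unadjusted(
    O: MethylationMatrix, X: PhenotypeMatrix, alpha: float = 0.01
) -> UnadjustedResults:
    """Additive baseline: per site, OLS of O_j. on (1, X); call if p < alpha/m."""
    check_paired(O, X)
    q = X.n_phenotypes
    m = O.n_sites
    if q > 0 and np.any(X.values.var(axis=0) <= 0):
        bad = int(np.argmin(X.values.var(axis=0)))
        raise ValidationError(
            f"covariate {X.phenotype_names[bad]!r} is constant; cannot test it"
        )
    D = np.hstack([np.ones((O.n_samples, 1)), X.values])
    coef, se, df = _ols_all_sites(D, O.values)
    tau = coef[1:].T       # m x q
    se_t = se[1:].T
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_t > 0, tau / se_t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    threshold = alpha / m
    return UnadjustedResults(
        tau_hat=tau, t_stat=t, p_value=p, calls=p < threshold,
        alpha=alpha, threshold=threshold, df_resid=df,
    )
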