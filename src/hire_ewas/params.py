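"""Full parameter set of the hierarchical deconvolution model.

The model has two Gaussian layers.  For sample i with covariates x_i, the
latent cell-type-specific signal at site j in cell type k is

    u_ijk ~ N(mu_jk + sum_l beta_jkl * x_il, sigma_jk^2),

and the observed bulk beta-value is the composition-weighted average

    O_ji ~ N(sum_k u_ijk * p_ki, sigma_eps_j^2).

Parameters: compositions P (K x n, columns on the simplex), baseline profiles
mu (m x K, entries in [0, 1]), phenotype effects B (m x K x q), cell-type
variances Sigma (m x K, > 0) and observation variances sigma_eps (m, > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DimensionError, ValidationError

__all__ = ["HireParams", "LatentMoments", "count_parameters", "SIMPLEX_TOL"]

SIMPLEX_TOL = 1e-10


@dataclass
class HireParams:
    P: np.ndarray          # K x n
    mu: np.ndarray         # m x K
    B: np.ndarray          # m x K x q
    Sigma: np.ndarray      # m x K, cell-type variances sigma_jk^2
    sigma_eps: np.ndarray  # m, observation variances sigma_eps_j^2

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float).ravel()
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def K(self) -> int:
        return self.P.shape[0]

    @property
    def n(self) -> int:
        return self.P.shape[1]

    @property
    def m(self) -> int:
        return self.mu.shape[0]

    @property
    def q(self) -> int:
        return self.B.shape[2]

    # --------------------------------------------------------------------
    def validate(self) -> None:
        if self.P.ndim != 2:
            raise DimensionError("P must be K x n")
        K, n = self.P.shape
        if K < 1:
            raise ValidationError("K must be >= 1")
        if self.mu.ndim != 2 or self.mu.shape[1] != K:
            raise DimensionError(
                f"cell-type axis: mu has {self.mu.shape[-1]} columns, expected K={K}"
            )
        m = self.mu.shape[0]
        if self.B.ndim != 3 or self.B.shape[0] != m or self.B.shape[1] != K:
            raise DimensionError(
                f"B must be m x K x q = ({m}, {K}, q), got {self.B.shape}"
            )
        if self.Sigma.shape != (m, K):
            raise DimensionError(
                f"Sigma must be m x K = ({m}, {K}), got {self.Sigma.shape}"
            )
        if self.sigma_eps.shape != (m,):
            raise DimensionError(
                f"sigma_eps must have length m={m}, got {self.sigma_eps.shape}"
            )
        for arr, name in ((self.P, "P"), (self.mu, "mu"), (self.B, "B"),
                          (self.Sigma, "Sigma"), (self.sigma_eps, "sigma_eps")):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if self.P.min() < -SIMPLEX_TOL:
            raise ValidationError("P has negative entries; columns must lie on the simplex")
        col_sums = self.P.sum(axis=0)
        if np.max(np.abs(col_sums - 1.0)) > 1e-8:
            worst = int(np.argmax(np.abs(col_sums - 1.0)))
            raise ValidationError(
                f"column {worst} of P sums to {col_sums[worst]:.12g}, not 1"
            )
        if self.mu.min() < 0.0 or self.mu.max() > 1.0:
            raise ValidationError("baseline profiles mu must lie in [0, 1]")
        if self.Sigma.min() <= 0.0:
            raise ValidationError("cell-type variances Sigma must be positive")
        if self.sigma_eps.min() <= 0.0:
            raise ValidationError("observation variances sigma_eps must be positive")

    def permute_cell_types(self, perm) -> "HireParams":
        """Return a copy with cell-type labels jointly relabelled by ``perm``.

        ``perm[k]`` gives the old index placed at new position k; the observed
        likelihood is invariant under this relabelling.
        """
        perm = np.asarray(perm, dtype=int)
        return HireParams(
            P=self.P[perm, :],
            mu=self.mu[:, perm],
            B=self.B[:, perm, :],
            Sigma=self.Sigma[:, perm],
            sigma_eps=self.sigma_eps.copy(),
        )

    def copy(self) -> "HireParams":
        return HireParams(self.P.copy(), self.mu.copy(), self.B.copy(),
                          self.Sigma.copy(), self.sigma_eps.copy())


@dataclass
class LatentMoments:
    """Posterior moments of the latent signals u given the observations.

    ``mean`` is E[u_ijk | O], shape (n, m, K).  The posterior covariance of
    u_ij is the diagonal-minus-rank-one matrix

        V_ij = diag(Sigma_j) - a_ij a_ij^T / d_ij,

    with a_ij = Sigma_j * p_i (elementwise) and
    d_ij = p_i^T Sigma_j p_i + sigma_eps_j.  Rather than materialising the
    (n, m, K, K) second-moment array, we store ``var_diag`` (the diagonal of
    V, shape (n, m, K)) and ``denom`` = d (shape (n, m)); together with the
    model's Sigma and P these reconstruct every cross-product the M-step
    needs in O(K) per entry.
    """

    mean: np.ndarray      # (n, m, K)
    var_diag: np.ndarray  # (n, m, K)
    denom: np.ndarray     # (n, m)
    Sigma: np.ndarray     # (m, K) -- the Sigma the E-step was run with
    P: np.ndarray         # (K, n) -- the compositions the E-step was run with

    def second_moment(self, i: int, j: int) -> np.ndarray:
        """Full K x K posterior second moment E[u_ij u_ij^T | O]."""
        a = self.Sigma[j] * self.P[:, i]
        V = np.diag(self.Sigma[j]) - np.outer(a, a) / self.denom[i, j]
        mu_post = self.mean[i, j]
        return V + np.outer(mu_post, mu_post)


def count_parameters(m: int, n: int, K: int, q: int) -> int:
    """Number of free parameters: (1 + 2K + qK) m + (K - 1) n.

    Per site: one observation variance, K baseline means, K cell-type
    variances and qK phenotype effects; per sample: K - 1 free composition
    coordinates (the simplex constraint removes one).
    """
    for name, v, lo in (("m", m, 1), ("n", n, 1), ("K", K, 1), ("q", q, 0)):
        if not isinstance(v, (int, np.integer)):
            raise ValidationError(f"{name} must be an integer, got {type(v).__name__}")
        if v < lo:
            raise ValidationError(f"{name} must be >= {lo}, got {v}")
    return (1 + 2 * K + q * K) * m + (K - 1) * n
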