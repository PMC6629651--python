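"""Observed-data log-likelihood of the two-layer deconvolution model.

Integrating the latent signals u out of the hierarchy gives a Gaussian
marginal for each observed entry:

    O_ji ~ N( p_i' mu_j + sum_l x_il p_i' B_l^(j),
              sum_k sigma_jk^2 p_ki^2 + sigma_eps_j^2 ).

The total log-likelihood is the sum of these m*n univariate normal log
densities.
"""

from __future__ import annotations

import numpy as np

from .data import DimensionError, MethylationMatrix, PhenotypeMatrix, check_paired
from .params import HireParams

__all__ = ["observed_loglikelihood", "marginal_mean", "marginal_variance"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def marginal_mean(params: HireParams, X: np.ndarray) -> np.ndarray:
    """Marginal mean of O, shape (m, n): mu P + sum_l B_l (P * x_l)."""
    mean = params.mu @ params.P
    for l in range(params.q):
        mean += params.B[:, :, l] @ (params.P * X[:, l][None, :])
    return mean


def marginal_variance(params: HireParams) -> np.ndarray:
    """Marginal variance of O, shape (m, n): Sigma (P*P) + sigma_eps."""
    return params.Sigma @ (params.P ** 2) + params.sigma_eps[:, None]


def observed_loglikelihood(
    params: HireParams, O: MethylationMatrix, X: PhenotypeMatrix
) -> float:
    check_paired(O, X)
    if params.n != O.n_samples:
        raise DimensionError(
            f"sample axis: params cover {params.n} samples, data has {O.n_samples}"
        )
    if params.m != O.n_sites:
        raise DimensionError(
            f"site axis: params cover {params.m} sites, data has {O.n_sites}"
        )
    if params.q != X.n_phenotypes:
        raise DimensionError(
            f"phenotype axis: params cover {params.q} phenotypes, data has "
            f"{X.n_phenotypes}"
        )
    mean = marginal_mean(params, X.values)
    var = marginal_variance(params)
    resid2 = (O.values - mean) ** 2
    ll = -0.5 * float(np.sum(_LOG_2PI + np.log(var) + resid2 / var))
    if not np.isfinite(ll):
        raise FloatingPointError("observed log-likelihood is not finite")
    return ll
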