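"""Choosing the number of cell types K by a penalized BIC.

pBIC(K) = -2 loglik + lambda_pen * [ (1 + 2K + qK) m log(n) + (K - 1) n log(m) ]

The two penalty terms mirror the two parameter blocks: each of the
(1 + 2K + qK) m site-level parameters (baselines, effects, variances) is
informed by the n samples, so it carries the usual BIC weight log(n); each
of the (K - 1) n free composition coordinates is informed by the m sites,
so it carries log(m).  Penalising every parameter by log(m n) instead would
overwhelm the likelihood gain of a true extra cell type (each parameter
never sees m n observations), while a plain log(n) BIC ignores that the
parameter count itself grows with m.  ``lambda_pen`` exposes the overall
penalty weight so alternative calibrations can be tried without an API
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import MethylationMatrix, PhenotypeMatrix, ValidationError
from .em import FitConfig, FitResult, fit
from .likelihood import observed_loglikelihood

__all__ = ["SelectionResult", "pbic", "select_K"]


@dataclass
class SelectionResult:
    K_grid: list[int]
    pbic_values: list[float]
    chosen_K: int
    fits: dict[int, FitResult] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)


def pbic(
    fit_result: FitResult,
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    lambda_pen: float = 1.0,
) -> float:
    if not fit_result.converged:
        warnings.warn(
            "pBIC evaluated on a non-converged fit; the criterion may be "
            "dominated by optimisation noise",
            UserWarning,
            stacklevel=2,
        )
    params = fit_result.params
    ll = observed_loglikelihood(params, O, X)
    m, n, K, q = params.m, params.n, params.K, params.q
    penalty = (1 + 2 * K + q * K) * m * np.log(n) + (K - 1) * n * np.log(m)
    return -2.0 * ll + lambda_pen * float(penalty)


def select_K(
    O: MethylationMatrix,
    X: PhenotypeMatrix,
    K_grid,
    config: FitConfig | None = None,
    n_seeds: int = 3,
    lambda_pen: float = 1.0,
) -> SelectionResult:
    """Fit each K with several restarts (best likelihood kept); argmin pBIC wins."""
    K_grid = [int(K) for K in K_grid]
    if not K_grid:
        raise ValidationError("K_grid must be non-empty")
    if any(K < 1 for K in K_grid):
        raise ValidationError("every K in K_grid must be >= 1")
    config = config or FitConfig()
    base_seed = config.seed if config.seed is not None else 0

    fits: dict[int, FitResult] = {}
    failures: dict[int, str] = {}
    values: list[float] = []
    for K in K_grid:
        best: FitResult | None = None
        err: str | None = None
        for s in range(max(1, n_seeds)):
            cfg = replace(config, seed=(base_seed + 1000003 * s + K) % (2 ** 31))
            try:
                res = fit(O, X, K, cfg)
            except Exception as exc:
                err = str(exc)
                continue
            if best is None or res.loglik > best.loglik:
                best = res
        if best is None:
            failures[K] = err or "all restarts failed"
            values.append(np.inf)
            continue
        fits[K] = best
        values.append(pbic(best, O, X, lambda_pen=lambda_pen))
    if not fits:
        raise RuntimeError(f"every candidate K failed to fit: {failures}")
    chosen = K_grid[int(np.argmin(values))]
    return SelectionResult(
        K_grid=K_grid, pbic_values=values, chosen_K=chosen, fits=fits, failures=failures
    )
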