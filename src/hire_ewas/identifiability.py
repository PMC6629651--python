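"""Runnable checks of the model's sufficient identifiability conditions.

Two kinds of conditions are checked.  The composition/covariate conditions
ask that (i) the n x (q+1)K matrix obtained by horizontally stacking P' and
the covariate-scaled copies x_l * P' has full column rank (q+1)K, and (ii)
the entrywise square of (1_n, P') has full column rank K + 1 — i.e. the
compositions genuinely vary across samples.  The anchor condition asks that
each cell type owns a "pure" CpG site: no phenotype effect, baseline 1 in
that cell type and 0 in all others (or the flipped variant, 0 vs 1).

These are sufficient conditions: failing them does not prove the model
unidentifiable, so the checkers report conditions and ranks, not a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DimensionError, PhenotypeMatrix

__all__ = [
    "IdentifiabilityReport",
    "AnchorReport",
    "check_identifiability",
    "check_anchor_condition",
    "numerical_rank",
]


def numerical_rank(A: np.ndarray) -> tuple[int, float]:
    """Numerical rank and the singular-value gap at the rank cut.

    Singular values below max(shape) * eps * sigma_max count as zero (the
    standard numerical-rank convention).  The gap is sigma_r / sigma_{r+1}
    (inf when no singular value falls below the cut).
    """
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0, np.inf
    cut = max(A.shape) * np.finfo(float).eps * s[0]
    r = int(np.sum(s > cut))
    gap = np.inf if r == s.size else float(s[r - 1] / s[r]) if s[r] > 0 else np.inf
    return r, gap


@dataclass
class IdentifiabilityReport:
    condition_b1: bool
    condition_b2: bool
    rank_b1: int
    required_rank_b1: int
    rank_b2: int
    required_rank_b2: int
    gap_b1: float
    gap_b2: float

    @property
    def all_hold(self) -> bool:
        return self.condition_b1 and self.condition_b2


def check_identifiability(P: np.ndarray, X: PhenotypeMatrix) -> IdentifiabilityReport:
    """Check the two rank conditions on compositions P (K x n) and covariates X."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise DimensionError("P must be K x n")
    K, n = P.shape
    Xv = X.values if isinstance(X, PhenotypeMatrix) else np.asarray(X, dtype=float)
    if Xv.shape[0] != n:
        raise DimensionError(
            f"sample axis: P covers {n} samples, covariates have {Xv.shape[0]} rows"
        )
    q = Xv.shape[1]

    Pt = P.T  # n x K
    blocks = [Pt] + [Xv[:, l][:, None] * Pt for l in range(q)]
    A = np.hstack(blocks)  # n x (q+1)K
    rank_b1, gap_b1 = numerical_rank(A)

    W = np.hstack([np.ones((n, 1)), Pt])
    B = W * W  # entrywise square of (1_n, P')
    rank_b2, gap_b2 = numerical_rank(B)

    return IdentifiabilityReport(
        condition_b1=rank_b1 == (q + 1) * K,
        condition_b2=rank_b2 == K + 1,
        rank_b1=rank_b1,
        required_rank_b1=(q + 1) * K,
        rank_b2=rank_b2,
        required_rank_b2=K + 1,
        gap_b1=gap_b1,
        gap_b2=gap_b2,
    )


@dataclass
class AnchorReport:
    """Per cell type: whether an anchor (pure) CpG site exists."""

    satisfied: list[bool]
    anchor_sites: list[list[int]] = field(default_factory=list)
    flipped: list[list[int]] = field(default_factory=list)

    @property
    def all_hold(self) -> bool:
        return all(self.satisfied)


def check_anchor_condition(
    mu: np.ndarray, B: np.ndarray, tol: float = 1e-8
) -> AnchorReport:
    """Find, per cell type k, sites with mu_jk ~ 1, mu_jk' ~ 0 (k' != k) and B_j ~ 0.

    The flipped variant (mu_jk ~ 0 while every other entry ~ 1) also
    certifies an anchor and is reported separately.
    """
    mu = np.asarray(mu, dtype=float)
    B = np.asarray(B, dtype=float)
    m, K = mu.shape
    effect_free = np.max(np.abs(B.reshape(m, -1)), axis=1) <= tol if B.size else np.ones(m, bool)

    satisfied: list[bool] = []
    anchors: list[list[int]] = []
    flipped: list[list[int]] = []
    for k in range(K):
        others = np.delete(np.arange(K), k)
        direct = (
            (np.abs(mu[:, k] - 1.0) <= tol)
            & np.all(np.abs(mu[:, others]) <= tol, axis=1)
            & effect_free
        )
        flip = (
            (np.abs(mu[:, k]) <= tol)
            & np.all(np.abs(mu[:, others] - 1.0) <= tol, axis=1)
            & effect_free
        )
        anchors.append(np.flatnonzero(direct).tolist())
        flipped.append(np.flatnonzero(flip).tolist())
        satisfied.append(bool(direct.any() or flip.any()))
    return AnchorReport(satisfied=satisfied, anchor_sites=anchors, flipped=flipped)
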