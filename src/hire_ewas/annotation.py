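"""Annotating estimated cell types against reference methylomes.

Each estimated baseline profile is compared with every reference profile by
three similarity measures — cosine similarity, Pearson correlation, and
Spearman correlation — on the shared CpG sites.  Each measure votes for its
most similar reference; the estimate is annotated with a reference cell type
when at least two measures agree on it and the agreeing measures' similarity
values exceed the threshold (default 0.5); otherwise it is declared a novel
cell type.  Several estimated cell types may map to the same reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .data import ValidationError

__all__ = ["ReferencePanel", "Annotation", "build_reference", "match_cell_types"]

NOVEL = "novel"
_MEASURES = ("cosine", "pearson", "spearman")


@dataclass
class ReferencePanel:
    """Reference profiles phi, m shared sites x H cell types, values in [0,1]."""

    profiles: np.ndarray
    names: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValidationError("reference profiles must be a 2-D matrix")
        if self.profiles.shape[1] != len(self.names):
            raise ValidationError("one name per reference column is required")
        if len(self.site_ids) != self.profiles.shape[0]:
            raise ValidationError("one site ID per reference row is required")
        if self.profiles.min() < 0.0 or self.profiles.max() > 1.0:
            raise ValidationError("reference profiles must lie in [0, 1]")


def build_reference(
    replicate_profiles: dict[str, np.ndarray], site_ids: list[str]
) -> ReferencePanel:
    """Average replicate methylomes per cell type into one reference profile.

    ``replicate_profiles[name]`` is an m x r matrix (or length-m vector) of r
    replicate profiles on the shared ``site_ids``.
    """
    names = list(replicate_profiles)
    if not names:
        raise ValidationError("at least one reference cell type is required")
    m = len(site_ids)
    cols = []
    for name in names:
        arr = np.asarray(replicate_profiles[name], dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != m:
            raise ValidationError(
                f"reference {name!r} has {arr.shape[0]} sites, expected {m}; "
                "site IDs must match"
            )
        cols.append(arr.mean(axis=1))
    return ReferencePanel(profiles=np.column_stack(cols), names=names, site_ids=list(site_ids))


@dataclass
class Annotation:
    cell_type: int
    label: str                      # reference name or "novel"
    similarities: pd.DataFrame      # measures x references
    votes: dict[str, str]           # measure -> argmax reference (or "abstain")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Annotation(cell_type={self.cell_type}, label={self.label!r})"


def _cosine(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return np.nan
    return float(x @ y / (nx * ny))


def match_cell_types(
    mu_hat: np.ndarray,
    panel: ReferencePanel,
    mu_site_ids: list[str] | None = None,
    threshold: float = 0.5,
) -> list[Annotation]:
    """Annotate each estimated profile by the 2-of-3 similarity-vote protocol.

    Similarities are computed on the intersection of site IDs (all rows when
    ``mu_site_ids`` is None and the row counts agree).  A measure abstains on
    a zero-variance profile; with only two live measures both must agree.
    Ties in a measure's argmax are broken by the smallest reference index.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    if mu_site_ids is None:
        if mu_hat.shape[0] != len(panel.site_ids):
            raise ValidationError(
                "without explicit site IDs, mu_hat must cover the panel's sites"
            )
        mu_use, ref_use = mu_hat, panel.profiles
    else:
        shared = [s for s in mu_site_ids if s in set(panel.site_ids)]
        if not shared:
            raise ValidationError("no shared site IDs between estimate and references")
        mu_idx = {s: j for j, s in enumerate(mu_site_ids)}
        ref_idx = {s: j for j, s in enumerate(panel.site_ids)}
        mu_use = mu_hat[[mu_idx[s] for s in shared], :]
        ref_use = panel.profiles[[ref_idx[s] for s in shared], :]
    if mu_use.shape[0] < 20:
        warnings.warn(
            f"only {mu_use.shape[0]} shared sites; annotation may be unreliable",
            UserWarning,
            stacklevel=2,
        )

    H = ref_use.shape[1]
    out: list[Annotation] = []
    for k in range(mu_hat.shape[1]):
        v = mu_use[:, k]
        sims = np.full((3, H), np.nan)
        for h in range(H):
            r = ref_use[:, h]
            sims[0, h] = _cosine(v, r)
            if v.std() > 0 and r.std() > 0:
                sims[1, h] = pearsonr(v, r)[0]
                sims[2, h] = spearmanr(v, r)[0]
        table = pd.DataFrame(sims, index=list(_MEASURES), columns=panel.names)
        votes: dict[str, str] = {}
        for mi, measure in enumerate(_MEASURES):
            row = sims[mi]
            votes[measure] = "abstain" if np.all(np.isnan(row)) else panel.names[int(np.nanargmax(row))]
        live = [ms for ms in _MEASURES if votes[ms] != "abstain"]
        label = NOVEL
        counts: dict[str, list[str]] = {}
        for ms in live:
            counts.setdefault(votes[ms], []).append(ms)
        for ref_name, voters in counts.items():
            need = 2 if len(live) >= 2 else len(live) + 1  # <2 live -> cannot annotate
            qualified = [ms for ms in voters if table.loc[ms, ref_name] > threshold]
            if len(qualified) >= need:
                label = ref_name
                break
        out.append(Annotation(cell_type=k, label=label, similarities=table, votes=votes))
    return out
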