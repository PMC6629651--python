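"""Core data containers: bulk methylation matrix and phenotype/covariate matrix.

Orientation convention used throughout the package: CpG sites index the rows
of the methylation matrix ``O`` (m x n) and of the baseline profiles ``mu``
(m x K); samples index the columns of ``O`` and of the composition matrix
``P`` (K x n).  File I/O converts to/from this convention explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "PhenotypeMatrix", "DimensionError", "ValidationError"]


class ValidationError(ValueError):
    """An input violates a model invariant (range, positivity, simplex...)."""


class DimensionError(ValidationError):
    """Array shapes are inconsistent; the message names the offending axis."""


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class MethylationMatrix:
    """Observed beta-values, shape m CpG sites x n samples, entries in [0, 1]."""

    values: np.ndarray
    site_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "methylation values")
        m, n = self.values.shape
        if not self.site_ids:
            self.site_ids = [f"cpg_{j + 1}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i + 1}" for i in range(n)]
        if len(self.site_ids) != m:
            raise DimensionError(
                f"site axis: {len(self.site_ids)} site_ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise DimensionError(
                f"sample axis: {len(self.sample_ids)} sample_ids for {n} columns"
            )
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            bad = np.unravel_index(
                int(np.argmax(np.abs(self.values - 0.5))), self.values.shape
            )
            raise ValidationError(
                "beta-values must lie in [0, 1]; offending entry at "
                f"(site {bad[0]}, sample {bad[1]}) = {self.values[bad]:.4g}"
            )

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            site_ids=[str(s) for s in frame.index],
            sample_ids=[str(s) for s in frame.columns],
        )


@dataclass
class PhenotypeMatrix:
    """Numeric covariates, n samples x q phenotypes, dummy-coded upstream.

    Sample order must match the columns of the paired :class:`MethylationMatrix`.
    """

    values: np.ndarray
    phenotype_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "phenotype values")
        n, q = self.values.shape
        if not self.phenotype_names:
            self.phenotype_names = [f"phenotype_{l + 1}" for l in range(q)]
        if len(self.phenotype_names) != q:
            raise DimensionError(
                f"phenotype axis: {len(self.phenotype_names)} names for {q} columns"
            )
        if self.sample_ids and len(self.sample_ids) != n:
            raise DimensionError(
                f"sample axis: {len(self.sample_ids)} sample_ids for {n} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = self.sample_ids if self.sample_ids else None
        return pd.DataFrame(self.values, index=index, columns=self.phenotype_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            phenotype_names=[str(c) for c in frame.columns],
            sample_ids=[str(s) for s in frame.index],
        )


def check_paired(O: MethylationMatrix, X: PhenotypeMatrix) -> None:
    """Raise if the methylation and phenotype matrices disagree on samples."""
    if O.n_samples != X.n_samples:
        raise DimensionError(
            f"sample axis: methylation has {O.n_samples} samples but "
            f"phenotypes have {X.n_samples}"
        )
    if X.sample_ids and O.sample_ids and list(X.sample_ids) != list(O.sample_ids):
        raise ValidationError("sample IDs of methylation and phenotype tables differ")
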