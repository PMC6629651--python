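"""Table I/O, preprocessing filters, and covariate dummy coding.

Methylation tables are written sites-as-rows (m x n) with site IDs in the
first column and sample IDs in the header, TSV or CSV by file extension,
floats at 10 significant digits.  Values slightly outside [0, 1] (within
0.05 of the boundary) are clipped on read; anything further out is rejected
with coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MethylationMatrix, PhenotypeMatrix, ValidationError

__all__ = [
    "read_methylation",
    "write_methylation",
    "read_phenotypes",
    "write_phenotypes",
    "filter_sites",
    "FilterReport",
    "encode_covariates",
]

FLOAT_FORMAT = "%.10g"
_SLOP = 0.05  # tolerated float slop around [0, 1] on read


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_table(df: pd.DataFrame, path: Path) -> None:
    dup_rows = df.index[df.index.duplicated()].unique()
    if len(dup_rows):
        raise ValidationError(f"{path}: duplicate site ID(s): {list(dup_rows)[:5]}")
    dup_cols = df.columns[df.columns.duplicated()].unique()
    if len(dup_cols):
        raise ValidationError(f"{path}: duplicate sample ID(s): {list(dup_cols)[:5]}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad_row = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad_row[0] if len(bad_row) else "?"
        raise ValidationError(
            f"{path}: non-numeric value in column {col!r} at row {where!r}"
        )


def read_methylation(path: str | Path) -> MethylationMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    _check_table(df, path)
    values = df.to_numpy(dtype=float)
    out = (values < -_SLOP) | (values > 1.0 + _SLOP)
    if out.any():
        j, i = map(int, np.argwhere(out)[0])
        raise ValidationError(
            f"{path}: beta-value {values[j, i]:.6g} outside [0, 1] at "
            f"site {df.index[j]!r}, sample {df.columns[i]!r}"
        )
    return MethylationMatrix(
        values=np.clip(values, 0.0, 1.0),
        site_ids=[str(s) for s in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_methylation(O: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    O.to_frame().to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT,
                        index_label="site_id")


def read_phenotypes(path: str | Path) -> PhenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        raise ValidationError(
            f"{path}: covariate column {non_numeric[0]!r} is not numeric; "
            "dummy-code categories first (encode_covariates)"
        )
    return PhenotypeMatrix.from_frame(df)


def write_phenotypes(X: PhenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    X.to_frame().to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT,
                        index_label="sample_id")


@dataclass
class FilterReport:
    kept_indices: np.ndarray       # positions in the original matrix
    dropped_mean: np.ndarray       # dropped by the mean filter
    dropped_variance: np.ndarray   # dropped by the top-variance cut
    n_input: int


def filter_sites(
    O: MethylationMatrix,
    low: float = 0.2,
    high: float = 0.8,
    top_variable: int = 10000,
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop sites with extreme mean methylation, keep the most variable rest.

    Sites with row mean > ``high`` or < ``low`` are consistently hyper- or
    hypo-methylated and carry little deconvolution signal; of the survivors,
    the ``top_variable`` sites with the largest row variance are kept.
    """
    means = O.values.mean(axis=1)
    mean_ok = (means >= low) & (means <= high)
    surviving = np.flatnonzero(mean_ok)
    if surviving.size > top_variable:
        variances = O.values[surviving].var(axis=1)
        order = np.argsort(variances)[::-1][:top_variable]
        kept = np.sort(surviving[order])
    else:
        kept = surviving
    report = FilterReport(
        kept_indices=kept,
        dropped_mean=np.flatnonzero(~mean_ok),
        dropped_variance=np.setdiff1d(surviving, kept),
        n_input=O.n_sites,
    )
    filtered = MethylationMatrix(
        values=O.values[kept],
        site_ids=[O.site_ids[j] for j in kept],
        sample_ids=list(O.sample_ids),
    )
    return filtered, report


def encode_covariates(
    table: pd.DataFrame,
    codings: dict[str, list[str]] | None = None,
) -> PhenotypeMatrix:
    """Dummy-code a covariate table into a numeric phenotype matrix.

    ``codings`` maps a categorical column name to its ordered level list; the
    first level is the reference and maps to all-zero dummies, so L levels
    yield L - 1 columns.  Numeric columns pass through unchanged; binary
    columns should already be coded {0, 1}.
    """
    codings = codings or {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for col in table.columns:
        series = table[col]
        if col in codings:
            levels = list(codings[col])
            unseen = sorted(set(series.astype(str)) - set(levels))
            if unseen:
                raise ValidationError(
                    f"covariate {col!r} has level(s) {unseen} absent from the coding"
                )
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{col}_{level}")
        else:
            if not np.issubdtype(series.dtype, np.number):
                raise ValidationError(
                    f"covariate {col!r} is non-numeric and has no declared coding"
                )
            cols.append(series.to_numpy(dtype=float))
            names.append(str(col))
    return PhenotypeMatrix(
        values=np.column_stack(cols) if cols else np.empty((len(table), 0)),
        phenotype_names=names,
        sample_ids=[str(s) for s in table.index],
    )
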