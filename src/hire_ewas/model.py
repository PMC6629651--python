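"""Model/results facade over the EM engine, in the statsmodels idiom.

``HireModel`` holds the data (bulk methylation + covariates); ``fit``
returns a ``HireResults`` carrying the estimated parameters, the likelihood
trace, association tests, the pBIC, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation, ReferencePanel, match_cell_types
from .data import MethylationMatrix, PhenotypeMatrix, ValidationError, check_paired
from .em import FitConfig, FitResult, fit as _fit
from .identifiability import IdentifiabilityReport, check_identifiability
from .inference import AssociationResults, UnadjustedResults, test_hire, test_unadjusted
from .likelihood import observed_loglikelihood
from .params import HireParams, count_parameters
from .selection import SelectionResult, pbic as _pbic, select_K as _select_K

__all__ = ["HireModel", "HireResults"]


class HireModel:
    """Hierarchical deconvolution model for one bulk methylation study.

    Parameters
    ----------
    methylation : MethylationMatrix
        Beta-values, m CpG sites x n samples, in [0, 1].
    phenotypes : PhenotypeMatrix
        Numeric covariates, n x q, in the same sample order.
    """

    def __init__(self, methylation: MethylationMatrix, phenotypes: PhenotypeMatrix):
        check_paired(methylation, phenotypes)
        self.methylation = methylation
        self.phenotypes = phenotypes

    @classmethod
    def from_dataframes(
        cls, methylation: pd.DataFrame, phenotypes: pd.DataFrame
    ) -> "HireModel":
        """Build from a sites-x-samples beta table and a samples-x-covariates table."""
        O = MethylationMatrix.from_frame(methylation)
        X = PhenotypeMatrix.from_frame(phenotypes)
        if list(methylation.columns.astype(str)) != list(phenotypes.index.astype(str)):
            raise ValidationError(
                "methylation columns and phenotype rows must list the same "
                "samples in the same order"
            )
        return cls(O, X)

    # ------------------------------------------------------------------
    def fit(self, K: int, config: FitConfig | None = None, **kwargs) -> "HireResults":
        """Fit with K cell types by generalized EM; kwargs feed FitConfig."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a FitConfig or keyword options, not both")
        result = _fit(self.methylation, self.phenotypes, K, config)
        return HireResults(self, result, config)

    def select_K(self, K_grid, config: FitConfig | None = None,
                 n_seeds: int = 3, lambda_pen: float = 1.0) -> SelectionResult:
        """Fit a K grid and choose the argmin of the penalized BIC."""
        return _select_K(self.methylation, self.phenotypes, K_grid,
                         config=config, n_seeds=n_seeds, lambda_pen=lambda_pen)

    def loglike(self, params: HireParams) -> float:
        return observed_loglikelihood(params, self.methylation, self.phenotypes)


@dataclass
class HireResults:
    """Estimates, diagnostics and downstream tests for a fitted model."""

    model: HireModel
    fit_result: FitResult
    config: FitConfig

    # -- basic accessors -------------------------------------------------
    @property
    def params(self) -> HireParams:
        return self.fit_result.params

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def llf_trace(self) -> list[float]:
        return self.fit_result.loglik_trace

    @property
    def df_model(self) -> int:
        p = self.params
        return count_parameters(p.m, p.n, p.K, p.q)

    def compositions(self) -> pd.DataFrame:
        """Estimated cell-type proportions, samples x cell types."""
        return pd.DataFrame(
            self.params.P.T,
            index=self.model.methylation.sample_ids,
            columns=[f"cell_type_{k + 1}" for k in range(self.K)],
        )

    def baseline_profiles(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.params.mu,
            index=self.model.methylation.site_ids,
            columns=[f"cell_type_{k + 1}" for k in range(self.K)],
        )

    def effects(self) -> pd.DataFrame:
        """Phenotype effects in long format (site, cell_type, phenotype, estimate)."""
        p = self.params
        names = self.model.phenotypes.phenotype_names
        sites = self.model.methylation.site_ids
        rows = []
        for l in range(p.q):
            for k in range(p.K):
                rows.append(pd.DataFrame({
                    "site": sites,
                    "cell_type": k + 1,
                    "phenotype": names[l],
                    "estimate": p.B[:, k, l],
                }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["site", "cell_type", "phenotype", "estimate"])

    # -- downstream ------------------------------------------------------
    def test_associations(self, alpha: float = 0.01) -> AssociationResults:
        """Plug-in cell-type-specific t-tests of beta_jkl = 0 (Bonferroni alpha/(mKq))."""
        return test_hire(self.model.methylation, self.params.P,
                         self.model.phenotypes, alpha=alpha)

    def test_unadjusted(self, alpha: float = 0.01) -> UnadjustedResults:
        """Additive no-composition baseline tests (threshold alpha/m)."""
        return test_unadjusted(self.model.methylation, self.model.phenotypes, alpha=alpha)

    def pbic(self, lambda_pen: float = 1.0) -> float:
        return _pbic(self.fit_result, self.model.methylation,
                     self.model.phenotypes, lambda_pen=lambda_pen)

    def annotate(self, panel: ReferencePanel, threshold: float = 0.5) -> list[Annotation]:
        """Match estimated baseline profiles to reference methylomes."""
        return match_cell_types(
            self.params.mu, panel,
            mu_site_ids=self.model.methylation.site_ids, threshold=threshold,
        )

    def identifiability(self) -> IdentifiabilityReport:
        """Rank checks of the sufficient identifiability conditions at the estimate."""
        return check_identifiability(self.params.P, self.model.phenotypes)

    # ------------------------------------------------------------------
    def summary(self, alpha: float = 0.01) -> str:
        p = self.params
        assoc = self.test_associations(alpha=alpha)
        n_cell_calls = int(assoc.calls_cell.sum())
        n_agg = int(assoc.calls_aggregate.any(axis=1).sum())
        comp_mean = p.P.mean(axis=1)
        lines = [
            "Hierarchical methylation deconvolution (generalized EM)",
            "=" * 58,
            f"CpG sites:            {p.m}",
            f"Samples:              {p.n}",
            f"Cell types (K):       {p.K}",
            f"Phenotypes (q):       {p.q}",
            f"Free parameters:      {self.df_model}",
            f"Log-likelihood:       {self.llf:.2f}",
            f"pBIC:                 {self.pbic():.2f}",
            f"Converged:            {self.converged} ({self.fit_result.n_iter} iterations)",
            "-" * 58,
            "Mean cell-type proportions: "
            + ", ".join(f"{v:.3f}" for v in comp_mean),
            f"Cell-type-level calls (p < {assoc.threshold_cell:.3g}): {n_cell_calls}",
            f"Aggregate-level risk-CpG sites (any phenotype): {n_agg}",
        ]
        return "\n".join(lines)
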