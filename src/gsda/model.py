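"""Model/Results interface for gene-set distance analysis.

:class:`GSDA` wraps an expression frame and an endpoint the way a
statsmodels model wraps endog/exog; ``fit()`` runs the distance-correlation
t-test for one gene set and returns a :class:`GSDAResults` with the
estimate, its test statistic and p-values, and a ``summary()`` table.
``screen()`` and ``drivers()`` expose the collection screen and the
backward-elimination driver search on the same data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import analysis, drivers as _drivers
from .distance_core import DCorResult
from .endpoints import Endpoint
from .exceptions import InputError
from .io import GeneSet, align_subjects

__all__ = ["GSDA", "GSDAResults", "DriverResults"]


class GSDA:
    """Distance-correlation association model for gene-set expression data.

    Parameters
    ----------
    endpoint : Endpoint
        The outcome: quantitative, categorical, or censored event-time.
    expression : DataFrame
        Subjects x genes numeric matrix; subjects are aligned with the
        endpoint by id (inner join) when the endpoint carries subject ids.
    transform : {'none', 'zscore', 'commensurate'}
        Optional variance-equalising transform applied to each tested
        submatrix.

    Examples
    --------
    >>> model = GSDA(endpoint, expression)
    >>> res = model.fit(["TP53", "MDM2"], permutations=10000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, endpoint: Endpoint, expression: pd.DataFrame, transform: str = "none"):
        if not isinstance(expression, pd.DataFrame):
            expression = pd.DataFrame(expression)
        if expression.columns.duplicated().any():
            raise InputError("duplicate gene identifiers in expression matrix")
        if expression.index.duplicated().any():
            raise InputError("duplicate subject identifiers in expression matrix")
        self.expression, self.endpoint = align_subjects(expression, endpoint)
        self.transform = transform

    @classmethod
    def from_frames(
        cls,
        expression: pd.DataFrame,
        phenotype: pd.DataFrame,
        column: str | None = None,
        endpoint_type: str = "quantitative",
        time_col: str | None = None,
        status_col: str | None = None,
        transform: str = "none",
    ) -> "GSDA":
        """Build a model from an expression frame and a phenotype frame.

        The phenotype frame is indexed by subject id; name either one column
        (quantitative/categorical) or a time/status pair (survival, status
        1 = event / 0 = censored).
        """
        ids = phenotype.index.tolist()
        if time_col is not None:
            ep = Endpoint.survival(phenotype[time_col], phenotype[status_col], subject_ids=ids)
        elif endpoint_type == "categorical":
            ep = Endpoint.categorical(phenotype[column].astype(str).to_numpy(), subject_ids=ids)
        else:
            ep = Endpoint.quantitative(phenotype[column], subject_ids=ids)
        return cls(ep, expression, transform=transform)

    @property
    def nobs(self) -> int:
        return self.expression.shape[0]

    def fit(self, gene_set=None, permutations: int = 0, seed=None) -> "GSDAResults":
        """Test one gene set (default: all genes) against the endpoint."""
        if gene_set is None:
            gene_set = GeneSet("all_genes", tuple(self.expression.columns))
        result = analysis.gsda_test(
            self.expression, gene_set, self.endpoint,
            transform=self.transform, permutations=permutations, seed=seed,
        )
        gs = gene_set if isinstance(gene_set, GeneSet) else GeneSet("gene_set", tuple(gene_set))
        return GSDAResults(self, gs, result)

    def screen(
        self,
        collection,
        permutations: int = 10_000,
        perm_threshold: float = 0.05,
        fdr_method: str = "bh",
        seed=None,
    ) -> pd.DataFrame:
        """Screen a gene-set collection; see :func:`gsda.analysis.gsda_screen`."""
        return analysis.gsda_screen(
            self.expression, collection, self.endpoint,
            transform=self.transform, permutations=permutations,
            perm_threshold=perm_threshold, fdr_method=fdr_method, seed=seed,
        )

    def drivers(self, gene_set, permutations: int = 0, seed=None) -> "DriverResults":
        """Backward-eliminate the set's genes to find the empirical drivers."""
        if permutations > 0:
            trace, p_perm = _drivers.eliminate_with_permutation(
                self.expression, gene_set, self.endpoint, permutations,
                seed=seed, transform=self.transform,
            )
        else:
            trace = _drivers.backward_eliminate(
                self.expression, gene_set, self.endpoint, transform=self.transform
            )
            p_perm = None
        return DriverResults(self, trace, p_perm, permutations if permutations else None)


class GSDAResults:
    """Results of one gene-set distance-correlation test."""

    def __init__(self, model: GSDA, gene_set: GeneSet, result: DCorResult):
        self.model = model
        self.gene_set = gene_set
        self.r_d = result.r_d
        self.t_d = result.t_d
        self.df = result.df
        self.p_t = result.p_t
        self.p_perm = result.p_perm
        self.n_perm = result.n_perm
        self.nobs = model.nobs

    def permutation_test(self, n_perm: int = 10_000, seed=None) -> "GSDAResults":
        """Return a new results object carrying a permutation p-value."""
        return self.model.fit(self.gene_set, permutations=n_perm, seed=seed)

    def summary(self) -> SimpleTable:
        rows = [
            ("Gene set", self.gene_set.name),
            ("Genes tested", f"{len(self.gene_set)}"),
            ("No. subjects", f"{self.nobs}"),
            ("Distance correlation r_d", f"{self.r_d:.6g}"),
            ("t statistic", f"{self.t_d:.6g}"),
            ("Degrees of freedom", f"{self.df}"),
            ("P (t-test, two-sided)", f"{self.p_t:.6g}"),
        ]
        if self.p_perm is not None:
            rows.append((f"P (permutation, B={self.n_perm})", f"{self.p_perm:.6g}"))
        return SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="Gene-Set Distance Analysis",
        )

    def __repr__(self):
        return (
            f"<GSDAResults {self.gene_set.name}: r_d={self.r_d:.4f}, "
            f"t_d={self.t_d:.4f}, df={self.df}, p_t={self.p_t:.3g}>"
        )


class DriverResults:
    """Backward-elimination trace with the selected driver subset.

    The ``best_p`` reported here is selection-biased — the subset was chosen
    to minimise it — and must not be read as a Type I error rate; ``p_perm``
    (when permutations were requested) is the selection-adjusted
    significance.
    """

    selection_biased = True

    def __init__(self, model, trace, p_perm, n_perm):
        self.model = model
        self.trace = trace
        self.best_subset = trace.best_subset
        self.best_p = trace.best_p
        self.p_perm = p_perm
        self.n_perm = n_perm

    def to_frame(self) -> pd.DataFrame:
        return self.trace.to_frame()

    def summary(self) -> SimpleTable:
        rows = [
            ("Genes at start", f"{len(self.trace.steps) + 1}"),
            ("Best subset size", f"{len(self.best_subset)}"),
            ("Best subset", ", ".join(self.best_subset)),
            ("Best p (selection-biased)", f"{self.best_p:.6g}"),
        ]
        if self.p_perm is not None:
            rows.append((f"P (selection-adjusted, B={self.n_perm})", f"{self.p_perm:.6g}"))
        return SimpleTable(
            [[v] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="GSDA Backward Elimination",
        )
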