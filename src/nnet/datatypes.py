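"""Shared domain containers for the coexpression-network pipeline.

The pipeline operates on three central objects: the cell-by-gene expression
matrix (log-normalized, nonnegative), the response/predictor gene selection
that defines the orientation of the regression, and the network ensemble --
a representatives x responses x predictors cube of cell-specific coexpression
values, optionally paired with a same-shape cube of significance scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected layout."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of log-normalized expression values.

    Values must be finite and nonnegative (the input is assumed to already be
    log-normalized; raw-count normalization is out of scope). Identifiers are
    matched exactly and case-sensitively throughout the package.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        self.cell_ids = _check_unique(self.cell_ids, "cell identifiers")
        self.gene_ids = _check_unique(self.gene_ids, "gene identifiers")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError(
                "negative expression values; input must be log-normalized"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from the expression matrix: {missing[:5]}")
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(self.values[:, idx], list(self.cell_ids), list(genes))

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self._gene_index[gene]]


@dataclass
class GeneSetSelection:
    """Ordered response and predictor gene lists.

    Responses are the regression targets (typically TFs); predictors are the
    genes entering the PCA embedding (typically known target genes). Keeping
    the response list shorter than the predictor list is advisory only.
    """

    responses: list[str]
    predictors: list[str]

    def __post_init__(self) -> None:
        self.responses = _check_unique(self.responses, "response genes")
        self.predictors = _check_unique(self.predictors, "predictor genes")
        if len(self.responses) < 1:
            raise ValidationError("at least one response gene is required")
        if len(self.predictors) < 2:
            raise ValidationError("at least two predictor genes are required")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        expr.gene_indices(self.responses)
        expr.gene_indices(self.predictors)


@dataclass
class EnsembleContainer:
    """Representatives x responses x predictors coexpression cube.

    ``coexpression`` holds the squared-form scores (always >= 0); the optional
    ``significance`` cube holds per-edge probabilistic scores in [0, 1].
    ``provenance`` records the parameters (k, number of PCs, ridge penalty,
    seeds, ...) that produced the cube.
    """

    coexpression: np.ndarray
    representative_ids: list[str]
    response_ids: list[str]
    predictor_ids: list[str]
    significance: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coexpression = np.asarray(self.coexpression, dtype=float)
        if self.coexpression.ndim != 3:
            raise ValidationError("coexpression cube must be 3-D")
        self.representative_ids = _check_unique(self.representative_ids, "representatives")
        self.response_ids = _check_unique(self.response_ids, "responses")
        self.predictor_ids = _check_unique(self.predictor_ids, "predictors")
        shape = (
            len(self.representative_ids),
            len(self.response_ids),
            len(self.predictor_ids),
        )
        if self.coexpression.shape != shape:
            raise ValidationError(
                f"cube shape {self.coexpression.shape} does not match labels {shape}"
            )
        if not np.all(np.isfinite(self.coexpression)):
            raise ValidationError("coexpression cube contains non-finite values")
        if np.any(self.coexpression < 0):
            raise ValidationError("coexpression values must be nonnegative")
        if self.significance is not None:
            self.significance = np.asarray(self.significance, dtype=float)
            if self.significance.shape != self.coexpression.shape:
                raise ValidationError("significance cube shape mismatch")
            if not np.all(np.isfinite(self.significance)):
                raise ValidationError("significance cube contains non-finite values")
            if np.any(self.significance < 0) or np.any(self.significance > 1):
                raise ValidationError("significance scores must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coexpression.shape  # type: ignore[return-value]

    def slice_cell(self, representative: str) -> np.ndarray:
        i = self.representative_ids.index(representative)
        return self.coexpression[i]

    def with_significance(self, scores: np.ndarray) -> "EnsembleContainer":
        return EnsembleContainer(
            self.coexpression,
            list(self.representative_ids),
            list(self.response_ids),
            list(self.predictor_ids),
            significance=scores,
            provenance=dict(self.provenance),
        )
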