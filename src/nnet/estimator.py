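"""The end-to-end estimator tying embedding, regression and significance
together in a scikit-learn-compatible interface."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EnsembleContainer, ExpressionMatrix, GeneSetSelection, ValidationError
from .embedding import (
    RepresentativeSet,
    build_knn_graph,
    fit_pca,
    select_representatives,
)
from .regression import build_ensemble, local_variance
from .significance import (
    fit_null,
    representative_walk_operator,
    significance_scores,
    smooth_ensemble,
)

#: default cap on the number of representative cells
DEFAULT_MAX_REPRESENTATIVES = 2000


class NeighbourNet(TransformerMixin, BaseEstimator):
    """Cell-specific coexpression networks by KNN principal-component regression.

    ``fit`` embeds the predictor genes with a centered/scaled PCA, builds the
    weighted geodesic KNN graph of cells, optionally subsamples representative
    cells, and assembles the representatives x responses x predictors
    coexpression cube (stored as ``ensemble_``). ``transform`` returns the
    cube flattened to cells x (responses * predictors), ready for downstream
    factorization or model selection.

    Parameters
    ----------
    responses, predictors:
        Gene lists. Defaults: all genes as predictors, all genes as responses.
    n_neighbors:
        Neighborhood size k (default 30).
    n_pcs:
        Retained PCs, or "auto" for the scree-elbow rule (capped at 50).
    ridge:
        Ridge penalty of the local PC regression (default 0.5).
    n_representatives:
        Number of representative cells (default min(N, 2000)); None keeps all.
    smoothing_steps / n_null / random_state:
        Random-walk smoothing depth, null replicate count, and master seed for
        the significance stage.
    """

    def __init__(
        self,
        responses: list[str] | None = None,
        predictors: list[str] | None = None,
        n_neighbors: int = 30,
        n_pcs: int | str = "auto",
        ridge: float = 0.5,
        n_representatives: int | None = None,
        smoothing_steps: int = 1,
        n_null: int = 20,
        normalize_pfi: bool = True,
        random_state: int | None = 0,
    ) -> None:
        self.responses = responses
        self.predictors = predictors
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.ridge = ridge
        self.n_representatives = n_representatives
        self.smoothing_steps = smoothing_steps
        self.n_null = n_null
        self.normalize_pfi = normalize_pfi
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _as_expression(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(
                X.to_numpy(dtype=float), [str(c) for c in X.index], [str(g) for g in X.columns]
            )
        X = np.asarray(X, dtype=float)
        return ExpressionMatrix(
            X,
            [f"cell{i}" for i in range(X.shape[0])],
            [f"g{j}" for j in range(X.shape[1])],
        )

    def fit(self, X, y=None):
        expr = self._as_expression(X)
        predictors = self.predictors or list(expr.gene_ids)
        responses = self.responses or list(expr.gene_ids)
        selection = GeneSetSelection(responses=list(responses), predictors=list(predictors))
        selection.validate_against(expr)

        self.pca_ = fit_pca(expr, predictors=selection.predictors, n_components=self.n_pcs)
        self.knn_graph_ = build_knn_graph(self.pca_.scores, k=self.n_neighbors)
        m = self.n_representatives
        if m is None:
            m = min(expr.n_cells, DEFAULT_MAX_REPRESENTATIVES)
        if m >= expr.n_cells:
            self.representatives_ = RepresentativeSet(
                np.arange(expr.n_cells), np.arange(expr.n_cells)
            )
        else:
            self.representatives_ = select_representatives(
                self.pca_.scores, m, seed=self.random_state
            )
        self.local_variances_ = local_variance(
            expr.values[:, expr.gene_indices(self.pca_.gene_ids)], self.knn_graph_
        )
        self.ensemble_ = build_ensemble(
            expr,
            selection,
            self.pca_,
            self.knn_graph_,
            representatives=self.representatives_,
            ridge=self.ridge,
            normalize=self.normalize_pfi,
            local_variances=self.local_variances_,
            provenance={"seed": self.random_state, "k": self.n_neighbors},
        )
        self._expr = expr
        self._selection = selection
        return self

    # ------------------------------------------------------------------
    def smooth(self) -> EnsembleContainer:
        """Random-walk smoothing of the fitted ensemble (cached)."""
        self._check_fitted()
        if not hasattr(self, "smoothed_"):
            op = representative_walk_operator(
                self.knn_graph_, self.representatives_, steps=self.smoothing_steps
            )
            self.smoothed_ = smooth_ensemble(self.ensemble_, op)
        return self.smoothed_

    def score_significance(self) -> EnsembleContainer:
        """Neighborhood-shuffle null, significance scores, and the scored
        smoothed ensemble (stored as ``scored_``)."""
        self._check_fitted()
        smoothed = self.smooth()
        self.null_ = fit_null(
            self._expr,
            self.pca_,
            self.knn_graph_,
            self._selection,
            n_replicates=self.n_null,
            seed=self.random_state,
            representatives=self.representatives_,
            ridge=self.ridge,
            steps=self.smoothing_steps,
            normalize=self.normalize_pfi,
        )
        scores = significance_scores(smoothed, self.null_)
        self.scored_ = smoothed.with_significance(scores)
        return self.scored_

    def transform(self, X=None):
        self._check_fitted()
        cube = self.ensemble_.coexpression
        return cube.reshape(cube.shape[0], -1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "ensemble_"):
            raise ValidationError("estimator is not fitted; call fit first")
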