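"""The method core: local weighted ridge PC regression and the analytic
permutation-feature-importance coexpression score.

Within each cell's KNN neighborhood, each response gene's low-rank
reconstruction is regressed on the PC scores with cell weights taken from the
KNN graph. The coexpression of predictor gene q with response p in cell n is
the analytic permutation feature importance of q propagated through the PC
loadings:

    CSN_npq = 2 * Var(X_.q) * (sum_r beta_npr V_qr / ||V_q.||)^2

where Var(X_.q) is the weighted local variance of q's original expression in
the neighborhood and V is the PC loading matrix. All scores are nonnegative
by construction; a predictor that is constant within the neighborhood
contributes exactly zero to every response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import EnsembleContainer, ExpressionMatrix, GeneSetSelection, ValidationError
from .embedding import KNNGraph, PCAModel, RepresentativeSet, lra_matrix


@dataclass
class LocalModel:
    """One fitted weighted ridge regression (response p within cell n)."""

    cell: int
    response: str
    coefficients: np.ndarray
    intercept: float
    ridge: float


def local_variance(values: np.ndarray, graph: KNNGraph) -> np.ndarray:
    """Weighted local variance of each gene within each cell's neighborhood.

    Weights are the KNN-graph connection strengths (master cell included at
    weight 1), normalized to sum to one; the variance is the weighted
    population variance. Returns a cells x genes table, nonnegative, zero
    exactly where the gene is constant within the weighted neighborhood.
    """
    values = np.asarray(values, dtype=float)
    n = graph.n_cells
    if values.shape[0] != n:
        raise ValidationError("expression rows must match the KNN graph")
    out = np.empty((n, values.shape[1]))
    for i in range(n):
        idx, w = graph.neighborhood(i)
        omega = w / w.sum()
        sub = values[idx]
        mu = omega @ sub
        out[i] = omega @ (sub - mu) ** 2
    return np.maximum(out, 0.0)


def fit_local_ridge(
    S_neighborhood: np.ndarray,
    y_neighborhood: np.ndarray,
    weights: np.ndarray,
    ridge: float = 0.5,
    cell: int = -1,
    response: str = "",
) -> LocalModel:
    """Closed-form weighted ridge with an unpenalized intercept.

    Minimizes sum_m w_m (y_m - a - S_m beta)^2 + ridge * ||beta||^2. Weights
    are used as given (not normalized). A singular system at ridge = 0 falls
    back to the minimum-norm solution with a warning.
    """
    beta, intercept = _ridge_multi(
        S_neighborhood, np.asarray(y_neighborhood, float)[:, None], weights, ridge
    )
    return LocalModel(cell, response, beta[:, 0], float(intercept[0]), ridge)


def _ridge_multi(
    S: np.ndarray, Y: np.ndarray, weights: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted ridge for several responses sharing one design. Returns
    (coefficients R x P, intercepts P)."""
    S = np.asarray(S, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if ridge < 0:
        raise ValidationError("ridge penalty must be nonnegative")
    if S.shape[0] < 2:
        raise ValidationError("neighborhood must contain at least 2 cells")
    sw = w.sum()
    s_bar = (w @ S) / sw
    y_bar = (w @ Y) / sw
    Sc = S - s_bar
    Yc = Y - y_bar
    A = Sc.T @ (w[:, None] * Sc) + ridge * np.eye(S.shape[1])
    B = Sc.T @ (w[:, None] * Yc)
    if ridge > 0:
        beta = np.linalg.solve(A, B)
    else:
        try:
            beta = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            warnings.warn("singular local system at ridge=0; minimum-norm solution")
            beta = np.linalg.lstsq(A, B, rcond=None)[0]
        if not np.all(np.isfinite(beta)):
            beta = np.linalg.lstsq(A, B, rcond=None)[0]
    intercepts = y_bar - s_bar @ beta
    return beta, intercepts


def pfi_coexpression(
    model: LocalModel | np.ndarray,
    loadings: np.ndarray,
    local_variances: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Analytic permutation-feature-importance coexpression for one response.

    Evaluates 2 * Var(X_.q) * (beta . V_q / ||V_q.||)^2 per predictor gene q.
    With ``normalize=False`` the loading-row norm is omitted, giving the raw
    expected-MSE-increase form. Predictors with all-zero loading rows score 0.
    """
    beta = model.coefficients if isinstance(model, LocalModel) else np.asarray(model, float)
    V = np.asarray(loadings, dtype=float)
    var = np.asarray(local_variances, dtype=float)
    proj = V @ beta
    if normalize:
        norms = np.linalg.norm(V, axis=1)
        zero = norms == 0
        if np.any(zero):
            warnings.warn("predictor(s) with all-zero loading rows scored 0")
        proj = np.where(zero, 0.0, proj / np.where(zero, 1.0, norms))
    return 2.0 * var * proj**2


def build_csn(
    cell: int,
    expr: ExpressionMatrix,
    selection: GeneSetSelection,
    pca: PCAModel,
    graph: KNNGraph,
    local_variances: np.ndarray,
    ridge: float = 0.5,
    response_lra: np.ndarray | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """One cell-specific network: responses x predictors coexpression.

    Each response's low-rank reconstruction is regressed on the PC scores in
    the cell's weighted neighborhood; rows follow the response order.
    """
    if response_lra is None:
        response_lra = lra_matrix(
            pca, expr.values[:, expr.gene_indices(selection.responses)]
        )
    idx, w = graph.neighborhood(cell)
    betas, _ = _ridge_multi(pca.scores[idx], response_lra[idx], w, ridge)
    proj = pca.loadings @ betas  # Q x P
    if normalize:
        norms = np.linalg.norm(pca.loadings, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        proj = np.where((norms == 0)[:, None], 0.0, proj / safe[:, None])
    return (2.0 * local_variances[cell][:, None] * proj**2).T


def build_ensemble(
    expr: ExpressionMatrix,
    selection: GeneSetSelection,
    pca: PCAModel,
    graph: KNNGraph,
    representatives: RepresentativeSet | None = None,
    ridge: float = 0.5,
    normalize: bool = True,
    local_variances: np.ndarray | None = None,
    provenance: dict | None = None,
) -> EnsembleContainer:
    """Assemble the representatives x responses x predictors coexpression cube.

    Networks are built only for representative cells, but each neighborhood is
    drawn from the full KNN graph. The predictor axis is the set of predictor
    genes retained by the PCA (zero-variance predictors were dropped there).
    """
    n = expr.n_cells
    if representatives is None:
        representatives = RepresentativeSet(np.arange(n), np.arange(n))
    if local_variances is None:
        local_variances = local_variance(
            expr.values[:, expr.gene_indices(pca.gene_ids)], graph
        )
    response_lra = lra_matrix(
        pca, expr.values[:, expr.gene_indices(selection.responses)]
    )
    cube = np.empty(
        (representatives.n_representatives, len(selection.responses), len(pca.gene_ids))
    )
    for j, cell in enumerate(representatives.indices):
        cube[j] = build_csn(
            int(cell),
            expr,
            selection,
            pca,
            graph,
            local_variances,
            ridge=ridge,
            response_lra=response_lra,
            normalize=normalize,
        )
    prov = {
        "k": graph.k,
        "n_components": pca.n_components,
        "ridge": ridge,
        "n_representatives": representatives.n_representatives,
        "normalized_pfi": normalize,
    }
    if provenance:
        prov.update(provenance)
    return EnsembleContainer(
        coexpression=cube,
        representative_ids=[expr.cell_ids[i] for i in representatives.indices],
        response_ids=list(selection.responses),
        predictor_ids=list(pca.gene_ids),
        provenance=prov,
    )


def connectivity(
    ensemble: EnsembleContainer,
    gene: str,
    axis: str = "response",
    use_significance: bool = False,
    threshold: float = 0.95,
) -> np.ndarray:
    """Per-cell degree of one gene: sum of its row (response axis) or column
    (predictor axis) edge weights, optionally restricted to significant edges."""
    if axis == "response":
        if gene not in ensemble.response_ids:
            raise KeyError(f"{gene!r} is not a response gene")
        i = ensemble.response_ids.index(gene)
        values = ensemble.coexpression[:, i, :]
        sig = None if ensemble.significance is None else ensemble.significance[:, i, :]
    elif axis == "predictor":
        if gene not in ensemble.predictor_ids:
            raise KeyError(f"{gene!r} is not a predictor gene")
        i = ensemble.predictor_ids.index(gene)
        values = ensemble.coexpression[:, :, i]
        sig = None if ensemble.significance is None else ensemble.significance[:, :, i]
    else:
        raise ValidationError("axis must be 'response' or 'predictor'")
    if use_significance:
        if sig is None:
            raise ValidationError("ensemble has no significance scores")
        values = np.where(sig >= threshold, values, 0.0)
    return values.sum(axis=1)
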