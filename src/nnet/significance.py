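"""Random-walk smoothing on the cell graph and a neighborhood-shuffle null.

Local regression in small neighborhoods is noisy; the network ensemble is
therefore smoothed with a row-stochastic random-walk operator derived from
the KNN graph. Significance is assessed against a null built by recomputing
coexpression after replacing each cell's neighbor set with uniformly sampled
cells (keeping the weight profile), which destroys local dependencies while
preserving marginal distributions. Observed smoothed coexpression is compared
against the pooled null through a Wald-type z statistic mapped to a
probabilistic score in [0, 1] by the standard normal CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.special import ndtr

from .datatypes import EnsembleContainer, ExpressionMatrix, GeneSetSelection, ValidationError
from .embedding import KNNGraph, PCAModel, RepresentativeSet
from .regression import build_ensemble, local_variance

#: floor on the null standard deviation to avoid division blow-ups
S0_FLOOR = 1e-12


@dataclass
class SmoothingOperator:
    """Row-stochastic operator T acting on the cell axis of an ensemble."""

    T: np.ndarray
    steps: int

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if np.any(self.T < 0):
            raise ValidationError("smoothing operator must be nonnegative")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("smoothing operator rows must sum to 1")


@dataclass
class NullModel:
    """Per-(response, predictor) null mean and standard deviation."""

    mu0: np.ndarray
    s0: np.ndarray
    n_replicates: int
    seed: int | None
    pool: str = "pair"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 null replicates")
        self.s0 = np.maximum(np.asarray(self.s0, dtype=float), S0_FLOOR)


def random_walk_operator(graph: KNNGraph, steps: int = 1) -> SmoothingOperator:
    """T = row-normalize(W + I) raised to the given power."""
    if steps < 1:
        raise ValidationError("steps must be at least 1")
    A = graph.W + scipy.sparse.identity(graph.n_cells, format="csr")
    T = _row_normalize(np.asarray(A.todense()))
    return SmoothingOperator(np.linalg.matrix_power(T, steps), steps)


def representative_walk_operator(
    graph: KNNGraph, representatives: RepresentativeSet, steps: int = 1
) -> SmoothingOperator:
    """Random-walk operator restricted to representative cells.

    Rows of row-normalize(W + I) at the representative cells spread mass over
    all cells; each column's mass is folded onto that cell's representative,
    so smoothing borrows strength from non-representative neighbors. With
    representatives equal to all cells this reduces to
    :func:`random_walk_operator`.
    """
    if steps < 1:
        raise ValidationError("steps must be at least 1")
    A = graph.W + scipy.sparse.identity(graph.n_cells, format="csr")
    B = _row_normalize(np.asarray(A[representatives.indices].todense()))
    m = representatives.n_representatives
    T = np.zeros((m, m))
    np.add.at(T.T, representatives.assignments, B.T)
    return SmoothingOperator(np.linalg.matrix_power(T, steps), steps)


def _row_normalize(A: np.ndarray) -> np.ndarray:
    sums = A.sum(axis=1, keepdims=True)
    zero = sums.ravel() == 0
    if np.any(zero):  # isolated cell: self-loop only
        A = A.copy()
        A[zero, zero] = 1.0
        sums = A.sum(axis=1, keepdims=True)
    return A / sums


def smooth_ensemble(
    ensemble: EnsembleContainer, operator: SmoothingOperator
) -> EnsembleContainer:
    """Propagate each edge's value across neighboring cells: out_n = sum_m T_nm CSN_m."""
    if operator.T.shape[0] != ensemble.shape[0]:
        raise ValidationError("operator size does not match the ensemble cell axis")
    cube = np.einsum("nm,mpq->npq", operator.T, ensemble.coexpression)
    prov = dict(ensemble.provenance)
    prov["smoothing_steps"] = operator.steps
    return EnsembleContainer(
        np.maximum(cube, 0.0),
        list(ensemble.representative_ids),
        list(ensemble.response_ids),
        list(ensemble.predictor_ids),
        provenance=prov,
    )


def shuffle_graph(graph: KNNGraph, rng: np.random.Generator) -> KNNGraph:
    """Replace each cell's neighbor set by uniformly sampled cells of the same
    size, carrying the original weight profile."""
    n = graph.n_cells
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    neighbor_lists: list[np.ndarray] = []
    for i in range(n):
        old = graph.neighbor_lists[i]
        _, w_row = graph.neighborhood(i)
        w_nbrs = w_row[1:]  # master cell weight (1) stays on the diagonal
        pool = np.delete(np.arange(n), i)
        new = rng.choice(pool, size=len(old), replace=False)
        row_idx = np.concatenate(([i], new))
        row_w = np.concatenate(([1.0], w_nbrs))
        srt = np.argsort(row_idx)
        indices.append(row_idx[srt])
        data.append(row_w[srt])
        neighbor_lists.append(new)
        indptr.append(indptr[-1] + len(row_idx))
    W = scipy.sparse.csr_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)), shape=(n, n)
    )
    return KNNGraph(W=W, k=graph.k, neighbor_lists=neighbor_lists)


def permute_graph(graph: KNNGraph, rng: np.random.Generator) -> KNNGraph:
    """Relabel the KNN graph's nodes by a random permutation of cells.

    The graph topology and weight structure are preserved exactly; only the
    assignment of cells to nodes changes, so between-cell dependence of the
    resulting networks survives while local expression dependence is broken.
    """
    n = graph.n_cells
    perm = rng.permutation(n)  # new node i takes old node perm[i]'s row
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    W = graph.W[perm][:, perm].tocsr()
    neighbor_lists = [inv[graph.neighbor_lists[perm[i]]] for i in range(n)]
    return KNNGraph(W=W, k=graph.k, neighbor_lists=neighbor_lists)


def fit_null(
    expr: ExpressionMatrix,
    pca: PCAModel,
    graph: KNNGraph,
    selection: GeneSetSelection,
    n_replicates: int = 20,
    seed: int | None = 0,
    representatives: RepresentativeSet | None = None,
    ridge: float = 0.5,
    steps: int = 1,
    normalize: bool = True,
    pool: str = "pair",
    method: str = "resample",
) -> NullModel:
    """Neighborhood-shuffle null for smoothed coexpression values.

    Each replicate rewires the KNN graph at random (``method="resample"``
    draws each cell a fresh uniform neighbor set carrying its weight profile;
    ``method="permute"`` relabels the whole graph by one cell permutation),
    recomputes the smoothed ensemble, and pools the values per (response,
    predictor) pair across cells and replicates (``pool="global"`` pools
    across pairs as well).
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 null replicates")
    if pool not in ("pair", "global"):
        raise ValidationError("pool must be 'pair' or 'global'")
    if method not in ("resample", "permute"):
        raise ValidationError("method must be 'resample' or 'permute'")
    rng = np.random.default_rng(seed)
    if representatives is None:
        representatives = RepresentativeSet(
            np.arange(expr.n_cells), np.arange(expr.n_cells)
        )
    pred_values = expr.values[:, expr.gene_indices(pca.gene_ids)]
    pooled = []
    shuffler = shuffle_graph if method == "resample" else permute_graph
    for _ in range(n_replicates):
        g = shuffler(graph, rng)
        lv = local_variance(pred_values, g)
        ens = build_ensemble(
            expr,
            selection,
            pca,
            g,
            representatives=representatives,
            ridge=ridge,
            normalize=normalize,
            local_variances=lv,
        )
        op = representative_walk_operator(g, representatives, steps=steps)
        pooled.append(smooth_ensemble(ens, op).coexpression)
    stack = np.stack(pooled)  # B x M x P x Q
    if pool == "pair":
        mu0 = stack.mean(axis=(0, 1))
        s0 = stack.std(axis=(0, 1))
    else:
        mu0 = np.full(stack.shape[2:], stack.mean())
        s0 = np.full(stack.shape[2:], stack.std())
    return NullModel(mu0=mu0, s0=s0, n_replicates=n_replicates, seed=seed, pool=pool)


def significance_scores(
    smoothed: EnsembleContainer, null: NullModel
) -> np.ndarray:
    """One-sided probabilistic significance: Phi((c - mu0) / s0) per edge."""
    if null.mu0.shape != smoothed.shape[1:]:
        raise ValidationError("null model shape does not match the ensemble")
    z = (smoothed.coexpression - null.mu0[None]) / null.s0[None]
    return ndtr(z)


def prune(
    adjacency: np.ndarray,
    scores: np.ndarray | None,
    level: str = "high_confidence",
    grn=None,
    response_ids: list[str] | None = None,
    predictor_ids: list[str] | None = None,
    threshold: float = 0.95,
    max_steps: int = 2,
) -> np.ndarray:
    """Prune a CSN adjacency (responses x predictors) at a stringency level.

    ``none`` keeps everything; ``statistical`` zeroes edges with significance
    below the threshold; ``high_confidence`` (default) additionally zeroes
    edges whose response TF cannot reach the predictor target within
    ``max_steps`` directed steps in the gene-regulation prior network.
    """
    from .prior import support_matrix  # local import; prior does not import us

    adjacency = np.asarray(adjacency, dtype=float)
    if level == "none":
        return adjacency.copy()
    if scores is None:
        raise ValidationError("statistical pruning requires significance scores")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != adjacency.shape:
        raise ValidationError("score shape does not match the adjacency")
    out = np.where(scores >= threshold, adjacency, 0.0)
    if level == "statistical":
        return out
    if level != "high_confidence":
        raise ValidationError(f"unknown pruning level: {level!r}")
    if grn is None:
        raise ValidationError("high-confidence pruning requires a regulation PKN")
    if response_ids is None or predictor_ids is None:
        raise ValidationError("high-confidence pruning requires axis gene labels")
    support = support_matrix(grn, response_ids, predictor_ids, max_steps)
    return np.where(support, out, 0.0)


def prune_ensemble(
    ensemble: EnsembleContainer,
    level: str = "high_confidence",
    grn=None,
    threshold: float = 0.95,
    max_steps: int = 2,
) -> EnsembleContainer:
    """Apply :func:`prune` to every cell slice of an ensemble."""
    cube = np.empty_like(ensemble.coexpression)
    sig = ensemble.significance
    for i in range(ensemble.shape[0]):
        cube[i] = prune(
            ensemble.coexpression[i],
            None if sig is None else sig[i],
            level=level,
            grn=grn,
            response_ids=ensemble.response_ids,
            predictor_ids=ensemble.predictor_ids,
            threshold=threshold,
            max_steps=max_steps,
        )
    prov = dict(ensemble.provenance)
    prov["pruning"] = level
    return EnsembleContainer(
        cube,
        list(ensemble.representative_ids),
        list(ensemble.response_ids),
        list(ensemble.predictor_ids),
        significance=sig,
        provenance=prov,
    )
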