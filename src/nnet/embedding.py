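"""PCA embedding, geodesic KNN graph, and representative-cell subsampling.

The pipeline embeds the predictor genes with a centered/scaled PCA, selects
the number of retained components with a chord-distance elbow on the singular
values, and builds a weighted k-nearest-neighbor graph of cells in PC space.
Neighborhoods are defined by geodesic (graph shortest-path) distances so that
they follow the data manifold; edge weights shrink with distance through a
Gaussian kernel with a per-cell bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .datatypes import ExpressionMatrix, ValidationError

#: retained-component cap for automatic rank selection
MAX_COMPONENTS = 50


@dataclass
class PCAModel:
    """Centered/scaled PCA of the predictor genes.

    ``scores`` is the N x R score matrix S = X_std V; ``loadings`` the
    Q x R loading matrix V with orthonormal columns. Means and standard
    deviations (population, 1/N) are stored per retained predictor gene so
    low-rank reconstructions can be mapped back to the expression scale.
    """

    scores: np.ndarray
    loadings: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    gene_ids: list[str]
    singular_values: np.ndarray
    n_components: int

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


def select_rank(singular_values: np.ndarray, cap: int = MAX_COMPONENTS) -> int:
    """Elbow criterion on the singular-value scree.

    Returns the index (1-based) maximizing the perpendicular distance from
    (i, sigma_i) to the chord joining the first and last scree points, capped.
    Fewer than 3 values -> all components.
    """
    s = np.asarray(singular_values, dtype=float)
    if np.any(np.diff(s) > 1e-12):
        raise ValidationError("singular values must be sorted descending")
    n = len(s)
    if n < 3:
        return max(n, 1)
    i = np.arange(1, n + 1, dtype=float)
    p0 = np.array([1.0, s[0]])
    p1 = np.array([float(n), s[-1]])
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        return 1
    # perpendicular distance via the 2-D cross product
    dist = np.abs(d[0] * (s - p0[1]) - d[1] * (i - p0[0])) / norm
    r = int(np.argmax(dist)) + 1
    return min(max(r, 1), cap)


def fit_pca(
    X: ExpressionMatrix | np.ndarray,
    predictors: list[str] | None = None,
    n_components: int | str = "auto",
) -> PCAModel:
    """PCA (centering and population scaling) on the predictor genes.

    Zero-variance genes are dropped with a warning before scaling. With
    ``n_components="auto"`` the retained rank comes from :func:`select_rank`;
    an explicit request larger than the matrix rank is clipped with a warning.
    """
    if isinstance(X, ExpressionMatrix):
        if predictors is not None:
            X = X.subset_genes(predictors)
        values = X.values
        gene_ids = list(X.gene_ids)
    else:
        values = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(values.shape[1])]
    n, q = values.shape
    if n < 2:
        raise ValidationError("PCA requires at least 2 cells")
    means = values.mean(axis=0)
    sds = values.std(axis=0)  # population (1/N)
    keep = sds > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance predictor gene(s): {dropped[:5]}"
        )
        values = values[:, keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        means, sds = means[keep], sds[keep]
    if values.shape[1] == 0:
        raise ValidationError("no predictor gene with nonzero variance")
    x_std = (values - means) / sds
    u, s, vt = np.linalg.svd(x_std, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    rank = max(rank, 1)
    if n_components == "auto":
        r = min(select_rank(s), rank)
    else:
        r = int(n_components)
        if r > rank:
            warnings.warn(f"requested {r} components exceeds rank {rank}; clipped")
            r = rank
        r = max(r, 1)
    u, s_r, vt = u[:, :r], s[:r], vt[:r]
    # deterministic sign: the largest-magnitude loading of each component is positive
    v = vt.T
    flip = v[np.argmax(np.abs(v), axis=0), np.arange(r)] < 0
    v[:, flip] *= -1
    u[:, flip] *= -1
    scores = u * s_r
    return PCAModel(
        scores=scores,
        loadings=v,
        column_means=means,
        column_sds=sds,
        gene_ids=gene_ids,
        singular_values=s,
        n_components=r,
    )


def low_rank_approximation(model: PCAModel, column: np.ndarray) -> np.ndarray:
    """Low-rank reconstruction of one gene's expression from the PC scores.

    The centered column is regressed onto the scores (closed form; the score
    columns are orthogonal) and the fit is shifted back by the gene mean. For
    a retained predictor gene this coincides with the standard back-scaled PCA
    reconstruction mean + sd * (S V_g)."""
    column = np.asarray(column, dtype=float)
    if column.shape[0] != model.n_cells:
        raise ValidationError("gene column length does not match the score matrix")
    mean = column.mean()
    s2 = (model.scores**2).sum(axis=0)
    coef = (model.scores.T @ (column - mean)) / np.where(s2 > 0, s2, 1.0)
    coef[s2 <= 0] = 0.0
    return model.scores @ coef + mean


def lra_matrix(model: PCAModel, columns: np.ndarray) -> np.ndarray:
    """Vectorized :func:`low_rank_approximation` over columns of a matrix."""
    columns = np.asarray(columns, dtype=float)
    means = columns.mean(axis=0)
    s2 = (model.scores**2).sum(axis=0)
    coef = (model.scores.T @ (columns - means)) / np.where(s2 > 0, s2, 1.0)[:, None]
    coef[s2 <= 0, :] = 0.0
    return model.scores @ coef + means


@dataclass
class KNNGraph:
    """Weighted cell-cell graph defining neighborhoods and regression weights.

    ``neighbor_lists[n]`` holds cell n's k nearest cells by geodesic distance,
    ordered by ascending distance (ties by index) and excluding n itself;
    ``W`` stores the Gaussian-kernel weights (row maximum rescaled to 1) with
    the master cell on the diagonal at weight 1.
    """

    W: scipy.sparse.csr_matrix
    k: int
    neighbor_lists: list[np.ndarray]

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    def neighborhood(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Neighborhood of cell n (master cell first) and its weights."""
        nbrs = self.neighbor_lists[n]
        idx = np.concatenate(([n], nbrs))
        w = np.asarray(self.W[n, idx].todense()).ravel()
        return idx, w


def build_knn_graph(S: np.ndarray, k: int = 30) -> KNNGraph:
    """Two-stage geodesic KNN graph in PC space.

    Stage 1 symmetrizes the Euclidean k-NN graph with edge length equal to
    Euclidean distance; stage 2 re-ranks neighbors by shortest-path (geodesic)
    distance on that graph. Weights are exp(-d^2 / sigma_n^2) with sigma_n the
    median geodesic distance over cell n's k neighbors, rescaled so the row
    maximum is 1; the cell itself sits on the diagonal with weight 1.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 cells to build a KNN graph")
    k_eff = min(int(k), n - 1)
    if k_eff < 1:
        raise ValidationError("k must be at least 1")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(S)
    dist, idx = nn.kneighbors(S)
    rows = np.repeat(np.arange(n), k_eff + 1)
    # clamp zero distances so duplicate cells keep an explicit edge
    data = np.maximum(dist.ravel(), 1e-12)
    stage1 = scipy.sparse.csr_matrix((data, (rows, idx.ravel())), shape=(n, n))
    stage1.setdiag(0.0)
    stage1.eliminate_zeros()
    stage1 = stage1.maximum(stage1.T)
    geo = dijkstra(stage1, directed=False)

    indptr = [0]
    indices: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    neighbor_lists: list[np.ndarray] = []
    warned = False
    for i in range(n):
        d = geo[i].copy()
        d[i] = np.inf
        finite = np.flatnonzero(np.isfinite(d))
        if len(finite) < k_eff and not warned:
            warnings.warn(
                "disconnected KNN graph component; some neighborhoods are truncated"
            )
            warned = True
        order = finite[np.lexsort((finite, d[finite]))][:k_eff]
        nd = d[order]
        sigma = float(np.median(nd)) if len(nd) else 1.0
        if sigma <= 0:
            sigma = 1.0
        w = np.exp(-((nd / sigma) ** 2))
        if w.size and w.max() > 0:
            w = w / w.max()
        # master cell first at weight 1
        row_idx = np.concatenate(([i], order))
        row_w = np.concatenate(([1.0], w))
        srt = np.argsort(row_idx)
        indices.append(row_idx[srt])
        weights.append(row_w[srt])
        neighbor_lists.append(order)
        indptr.append(indptr[-1] + len(row_idx))
    W = scipy.sparse.csr_matrix(
        (np.concatenate(weights), np.concatenate(indices), np.array(indptr)),
        shape=(n, n),
    )
    return KNNGraph(W=W, k=k_eff, neighbor_lists=neighbor_lists)


@dataclass
class RepresentativeSet:
    """Subsampled cells on which networks are inferred.

    ``indices`` are the selected cell positions; ``assignments[n]`` maps every
    cell to the position (0..M-1) of its representative within ``indices``.
    """

    indices: np.ndarray
    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValidationError("representative indices must be unique")
        if self.assignments.min(initial=0) < 0 or (
            len(self.assignments)
            and self.assignments.max() >= len(self.indices)
        ):
            raise ValidationError("assignments must index into representatives")

    @property
    def n_representatives(self) -> int:
        return len(self.indices)


def select_representatives(
    S: np.ndarray, n_representatives: int, seed: int | None = 0
) -> RepresentativeSet:
    """k-means subsampling: one representative per cluster, nearest the centroid."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    m = int(n_representatives)
    if m > n:
        raise ValidationError("cannot select more representatives than cells")
    if m == n:
        return RepresentativeSet(np.arange(n), np.arange(n))
    km = KMeans(n_clusters=m, random_state=seed, n_init=10)
    labels = km.fit_predict(S)
    indices = np.empty(m, dtype=int)
    for c in range(m):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:  # pragma: no cover - sklearn avoids empty clusters
            largest = np.bincount(labels, minlength=m).argmax()
            pool = np.flatnonzero(labels == largest)
            far = pool[np.argmax(np.linalg.norm(S[pool] - km.cluster_centers_[largest], axis=1))]
            labels[far] = c
            members = np.array([far])
        d = np.linalg.norm(S[members] - km.cluster_centers_[c], axis=1)
        indices[c] = members[np.lexsort((members, d))[0]]
    return RepresentativeSet(indices=indices, assignments=labels)
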