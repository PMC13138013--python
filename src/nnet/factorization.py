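"""Nonnegative-PCA factorization of the network ensemble.

Vectorizing each cell's network stacks the ensemble into a tall (P*Q) x N
matrix A_cell which NMF-style factorization decomposes as A_cell = F H^T:
columns of H are soft cell clusters and columns of F are meta-networks. The
factorization here is a sequential nonnegative PCA (projected power iteration
with deflation) run on the items x items Gram matrix, so the tall matrix is
never materialized; the same machinery applied along a gene axis yields gene
modules (meta-TFs). Meta-networks are always derived from H through the
aggregation formula Meta-Network_i = sum_n CSN_n H_ni, and central genes are
read off the leading singular vectors of each meta-network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EnsembleContainer, ValidationError


@dataclass
class SoftClustering:
    """Nonnegative membership weights over items (cells or genes).

    Columns of ``H`` have unit Euclidean norm and are ordered by explained
    ensemble energy, non-increasing. ``membership`` rescales each column to a
    maximum of 1 for reporting.
    """

    H: np.ndarray
    item_ids: list[str]
    energy: np.ndarray
    axis: str = "cell"

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.H < 0):
            raise ValidationError("soft-cluster weights must be nonnegative")
        if self.H.shape[0] != len(self.item_ids):
            raise ValidationError("weight rows must match item labels")

    @property
    def n_components(self) -> int:
        return self.H.shape[1]

    @property
    def membership(self) -> np.ndarray:
        peaks = self.H.max(axis=0)
        return self.H / np.where(peaks > 0, peaks, 1.0)

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.H, axis=1)


def gram_matrix(ensemble: EnsembleContainer, axis: str = "cell") -> np.ndarray:
    """Items x items Gram matrix of vectorized slices along the chosen axis.

    G_ab is the inner product of slices a and b, accumulated over the other
    two axes without forming the tall matrix.
    """
    cube = ensemble.coexpression
    if axis == "cell":
        return np.einsum("ipq,jpq->ij", cube, cube)
    if axis == "response":
        return np.einsum("npq,nrq->pr", cube, cube)
    if axis == "predictor":
        return np.einsum("npq,npr->qr", cube, cube)
    raise ValidationError("axis must be 'cell', 'response' or 'predictor'")


def _power_component(
    G: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    n_restarts: int,
) -> tuple[np.ndarray, float]:
    """Best nonnegative leading direction of G over seeded restarts."""
    n = G.shape[0]
    best_w = np.zeros(n)
    best_obj = -np.inf
    for _ in range(n_restarts):
        w = rng.random(n) + 1e-3
        w /= np.linalg.norm(w)
        for _ in range(max_iter):
            v = np.maximum(G @ w, 0.0)
            nv = np.linalg.norm(v)
            if nv == 0:
                w = np.zeros(n)
                break
            v /= nv
            if np.linalg.norm(v - w) < tol:
                w = v
                break
            w = v
        obj = float(w @ G @ w)
        if obj > best_obj:
            best_obj, best_w = obj, w
    return best_w, max(best_obj, 0.0)


def npca(
    G: np.ndarray,
    n_components: int,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential nonnegative PCA on a Gram matrix.

    Components are extracted one at a time by projected power iteration
    (iterate w <- clip+(G w), renormalize); after each component the Gram is
    deflated by G <- G - (Gw)(Gw)^T / (w^T G w) and negative diagonal drift is
    clipped at zero. Returns (H items x K with unit-norm columns, per-component
    energies w^T G w in extraction order).
    """
    G = np.asarray(G, dtype=float).copy()
    n = G.shape[0]
    if G.shape != (n, n):
        raise ValidationError("Gram matrix must be square")
    if n_components > n:
        raise ValidationError("cannot extract more components than items")
    if not np.any(G):
        warnings.warn("all-zero Gram matrix; returning zero weights")
        return np.zeros((n, n_components)), np.zeros(n_components)
    rng = np.random.default_rng(seed)
    H = np.zeros((n, n_components))
    energy = np.zeros(n_components)
    for comp in range(n_components):
        w, obj = _power_component(G, rng, max_iter, tol, n_restarts)
        H[:, comp] = w
        energy[comp] = obj
        if obj > 0:
            gw = G @ w
            G = G - np.outer(gw, gw) / (w @ gw)
            d = np.diag(G).copy()
            np.fill_diagonal(G, np.maximum(d, 0.0))
    return H, energy


def soft_clusters(
    ensemble: EnsembleContainer,
    n_components: int = 20,
    axis: str = "cell",
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
) -> SoftClustering:
    """Soft clusters of cells or genes from the ensemble's Gram matrix."""
    G = gram_matrix(ensemble, axis=axis)
    H, energy = npca(
        G, n_components, seed=seed, max_iter=max_iter, tol=tol, n_restarts=n_restarts
    )
    ids = {
        "cell": ensemble.representative_ids,
        "response": ensemble.response_ids,
        "predictor": ensemble.predictor_ids,
    }[axis]
    return SoftClustering(H=H, item_ids=list(ids), energy=energy, axis=axis)


def meta_networks(
    ensemble: EnsembleContainer, clustering: SoftClustering | np.ndarray
) -> list[np.ndarray]:
    """Meta-Network_i = sum_n CSN_n H_ni -- the H-weighted aggregation of slices."""
    H = clustering.H if isinstance(clustering, SoftClustering) else np.asarray(clustering, float)
    if H.shape[0] != ensemble.shape[0]:
        raise ValidationError("weight rows must align with the ensemble cell axis")
    stacked = np.einsum("npq,nk->kpq", ensemble.coexpression, H)
    return [stacked[i] for i in range(H.shape[1])]


def meta_genes(
    ensemble: EnsembleContainer,
    axis: str = "response",
    n_components: int = 20,
    seed: int | None = 0,
    **kwargs,
) -> tuple[SoftClustering, EnsembleContainer]:
    """Gene modules along one gene axis plus the module-aggregated ensemble.

    The aggregated cube replaces that axis with H-weighted meta-gene slices
    (cells x K x other-axis for the response axis, and symmetrically for the
    predictor axis)."""
    if axis not in ("response", "predictor"):
        raise ValidationError("axis must be 'response' or 'predictor'")
    clustering = soft_clusters(ensemble, n_components, axis=axis, seed=seed, **kwargs)
    H = clustering.H
    names = [f"module_{i + 1}" for i in range(H.shape[1])]
    if axis == "response":
        cube = np.einsum("npq,pk->nkq", ensemble.coexpression, H)
        agg = EnsembleContainer(
            np.maximum(cube, 0.0),
            list(ensemble.representative_ids),
            names,
            list(ensemble.predictor_ids),
            provenance=dict(ensemble.provenance),
        )
    else:
        cube = np.einsum("npq,qk->npk", ensemble.coexpression, H)
        agg = EnsembleContainer(
            np.maximum(cube, 0.0),
            list(ensemble.representative_ids),
            list(ensemble.response_ids),
            names,
            provenance=dict(ensemble.provenance),
        )
    return clustering, agg


def central_genes(
    networks: list[np.ndarray],
    response_ids: list[str],
    predictor_ids: list[str],
    top_n: int = 10,
) -> dict:
    """SVD centrality per meta-network and the union of top-ranked genes.

    Centrality of responses (predictors) is the absolute value of the leading
    left (right) singular vector; ties break by ascending index.
    """
    if top_n < 1:
        raise ValidationError("top_n must be at least 1")
    per_component = []
    union_resp: list[str] = []
    union_pred: list[str] = []
    for net in networks:
        u, s, vt = np.linalg.svd(np.asarray(net, float))
        resp_c = np.abs(u[:, 0])
        pred_c = np.abs(vt[0])
        r_order = np.lexsort((np.arange(len(resp_c)), -resp_c))[:top_n]
        p_order = np.lexsort((np.arange(len(pred_c)), -pred_c))[:top_n]
        top_r = [response_ids[i] for i in r_order]
        top_p = [predictor_ids[i] for i in p_order]
        per_component.append(
            {
                "response_centrality": resp_c,
                "predictor_centrality": pred_c,
                "top_responses": top_r,
                "top_predictors": top_p,
            }
        )
        union_resp.extend(g for g in top_r if g not in union_resp)
        union_pred.extend(g for g in top_p if g not in union_pred)
    return {
        "components": per_component,
        "union_responses": union_resp,
        "union_predictors": union_pred,
    }


class NonnegativePCA(TransformerMixin, BaseEstimator):
    """Scikit-learn-style wrapper around the sequential nonnegative PCA.

    ``fit_transform(X)`` on an items x features matrix returns the
    nonnegative weights H (items x n_components); ``components_`` holds the
    aggregation-derived factors F^T (n_components x features), consistent
    with X ~ H @ components_.
    """

    def __init__(
        self,
        n_components: int = 20,
        seed: int | None = 0,
        max_iter: int = 500,
        tol: float = 1e-8,
        n_restarts: int = 5,
    ) -> None:
        self.n_components = n_components
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        G = X @ X.T
        H, energy = npca(
            G,
            self.n_components,
            seed=self.seed,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
        )
        self.weights_ = H
        self.energy_ = energy
        self.components_ = (X.T @ H).T
        return H

    def fit_gram(self, G):
        """Fit from a precomputed Gram matrix (no ``components_`` available)."""
        H, energy = npca(
            G,
            self.n_components,
            seed=self.seed,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
        )
        self.weights_ = H
        self.energy_ = energy
        return self

    def transform(self, X):
        """Project items onto the extracted components (nonnegative projection)."""
        X = np.asarray(X, dtype=float)
        C = self.components_
        coef, *_ = np.linalg.lstsq(C.T, X.T, rcond=None)
        return np.maximum(coef.T, 0.0)
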