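"""Prior-knowledge graphs, receptor activity, and upstream signaling paths.

Two signed directed graphs enter the analysis: a gene-regulation network
(TF -> target) used to support coexpression edges, and a signaling network
used to connect receptors to TFs. A personalized PageRank on the signaling
graph (restart mass on the receptor; dangling mass teleports back to the
restart node) gives each receptor's regulatory potential over TFs. The dot
product of that potential matrix with a pruned cell-specific network yields
per-target receptor activity; summing over targets scores the receptor.
Signs never modify activity magnitudes; they surface only in edge
classification and exports.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse

from .datatypes import ValidationError


@dataclass
class PriorKnowledgeNetwork:
    """Signed directed interaction graph (kind: 'regulation' or 'signaling')."""

    graph: nx.DiGraph
    kind: str = "regulation"

    @classmethod
    def from_edges(
        cls, edges, kind: str = "regulation"
    ) -> "PriorKnowledgeNetwork":
        """Build from (source, target, sign) triples; conflicting duplicate
        signs collapse to 0 (ambiguous)."""
        g = nx.DiGraph()
        for source, target, sign in edges:
            source, target, sign = str(source), str(target), int(sign)
            if g.has_edge(source, target) and g[source][target]["sign"] != sign:
                g[source][target]["sign"] = 0
            else:
                g.add_edge(source, target, sign=sign)
        return cls(graph=g, kind=kind)

    @classmethod
    def from_table(cls, df: pd.DataFrame, kind: str = "regulation"):
        return cls.from_edges(
            df[["source", "target", "sign"]].itertuples(index=False), kind=kind
        )

    def to_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign"])

    def sign(self, source: str, target: str) -> int | None:
        if self.graph.has_edge(source, target):
            return int(self.graph[source][target]["sign"])
        return None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class RegulatoryPotential:
    """Receptors x TFs personalized-PageRank potential matrix."""

    matrix: np.ndarray
    receptor_ids: list[str]
    tf_ids: list[str]
    damping: float = 0.85

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.receptor_ids), len(self.tf_ids)):
            raise ValidationError("potential matrix shape does not match labels")
        if np.any(self.matrix < 0):
            raise ValidationError("regulatory potential must be nonnegative")


@dataclass
class ReceptorActivityResult:
    """Per-target receptor activity and its row-sum activity scores."""

    activity: np.ndarray
    scores: np.ndarray
    receptor_ids: list[str]
    target_ids: list[str]


@dataclass
class SignalingPath:
    """A minimal receptor -> ... -> TF path in the signaling network."""

    nodes: list[str]

    @property
    def hops(self) -> int:
        return len(self.nodes) - 1


def personalized_pagerank(
    pkn: PriorKnowledgeNetwork,
    restart: str,
    damping: float = 0.85,
    dangling: str = "restart",
    tol: float = 1e-13,
    max_iter: int = 10000,
) -> dict[str, float]:
    """Personalized PageRank with all restart mass on one node.

    Out-edges are followed uniformly; dangling-node mass teleports back to the
    restart node (``dangling="uniform"`` spreads it over all nodes instead).
    The returned vector sums to 1 over all graph nodes.
    """
    if not (0 < damping < 1):
        raise ValidationError("damping must lie in (0, 1)")
    nodes = sorted(pkn.graph.nodes)
    n = len(nodes)
    if restart not in pkn.graph:
        warnings.warn(f"restart node {restart!r} absent from the graph")
        return {}
    pos = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    dangle = np.ones(n, dtype=bool)
    for u in nodes:
        succ = list(pkn.graph.successors(u))
        if succ:
            dangle[pos[u]] = False
            p = 1.0 / len(succ)
            for v in succ:
                rows.append(pos[v])
                cols.append(pos[u])
                vals.append(p)
    P = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    e = np.zeros(n)
    e[pos[restart]] = 1.0
    uniform = np.full(n, 1.0 / n)
    sink_target = e if dangling == "restart" else uniform
    x = e.copy()
    for _ in range(max_iter):
        sink_mass = x[dangle].sum()
        x_new = damping * (P @ x + sink_mass * sink_target) + (1 - damping) * e
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {v: float(x[pos[v]]) for v in nodes}


def regulatory_potential(
    pkn: PriorKnowledgeNetwork,
    receptors: list[str],
    tfs: list[str],
    damping: float = 0.85,
    dangling: str = "restart",
    tol: float = 1e-13,
) -> RegulatoryPotential:
    """Receptor-to-TF potential: personalized PageRank per receptor, restricted
    to TF columns. Receptors absent from the graph get a zero row with a
    warning; TFs absent from the graph get a zero column."""
    matrix = np.zeros((len(receptors), len(tfs)))
    for i, r in enumerate(receptors):
        vec = personalized_pagerank(pkn, r, damping=damping, dangling=dangling, tol=tol)
        for j, t in enumerate(tfs):
            matrix[i, j] = vec.get(t, 0.0)
    return RegulatoryPotential(matrix, list(receptors), list(tfs), damping)


def receptor_activity(
    potential: RegulatoryPotential,
    csn: np.ndarray,
    response_ids: list[str],
    predictor_ids: list[str],
) -> ReceptorActivityResult:
    """Activity = potential-matrix . pruned-CSN; scores are the row sums.

    The CSN's response rows are aligned to the potential's TF columns by
    symbol; TFs missing from the CSN contribute zero.
    """
    csn = np.asarray(csn, dtype=float)
    row_of = {tf: i for i, tf in enumerate(response_ids)}
    shared = [t for t in potential.tf_ids if t in row_of]
    if not shared:
        raise ValidationError("no TF shared between the potential matrix and the CSN")
    aligned = np.zeros((len(potential.tf_ids), csn.shape[1]))
    for j, tf in enumerate(potential.tf_ids):
        if tf in row_of:
            aligned[j] = csn[row_of[tf]]
    activity = potential.matrix @ aligned
    return ReceptorActivityResult(
        activity=activity,
        scores=activity.sum(axis=1),
        receptor_ids=list(potential.receptor_ids),
        target_ids=list(predictor_ids),
    )


def population_receptor_activity(
    scores: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Importance-weighted sum of per-cell receptor scores: sum_n H_ni score_n.

    ``scores`` is cells x receptors; ``weights`` a soft-cluster column over
    the same cells."""
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if scores.shape[0] != weights.shape[0]:
        raise ValidationError("cell axes of scores and weights must align")
    return weights @ scores


def reachable_within(
    pkn: PriorKnowledgeNetwork, source: str, target: str, max_steps: int = 2
) -> bool:
    """Directed BFS reachability within a step budget; unknown nodes -> False."""
    if max_steps < 1:
        raise ValidationError("max_steps must be at least 1")
    g = pkn.graph
    if source not in g or target not in g:
        return False
    frontier = {source}
    for _ in range(max_steps):
        frontier = {v for u in frontier for v in g.successors(u)}
        if target in frontier:
            return True
        if not frontier:
            return False
    return False


def support_matrix(
    pkn: PriorKnowledgeNetwork,
    response_ids: list[str],
    predictor_ids: list[str],
    max_steps: int = 2,
) -> np.ndarray:
    """Boolean responses x predictors table of prior support (one BFS per TF)."""
    out = np.zeros((len(response_ids), len(predictor_ids)), dtype=bool)
    pred_pos = {g: j for j, g in enumerate(predictor_ids)}
    g = pkn.graph
    for i, tf in enumerate(response_ids):
        if tf not in g:
            continue
        frontier = {tf}
        seen: set[str] = set()
        for _ in range(max_steps):
            frontier = {v for u in frontier for v in g.successors(u)} - seen
            for v in frontier:
                if v in pred_pos:
                    out[i, pred_pos[v]] = True
            seen |= frontier
            if not frontier:
                break
    return out


def select_mediating_tfs(
    csn: np.ndarray,
    response_ids: list[str],
    potential: RegulatoryPotential,
    receptor: str,
    top_t: int = 1,
) -> list[str]:
    """Rank TFs by (degree / max degree) x (potential / max potential).

    Degree is the TF's row sum in the pruned CSN; the potential column is the
    receptor's. Ties break by ascending symbol; an all-zero ranking yields an
    empty list."""
    if top_t < 1:
        raise ValidationError("top_t must be at least 1")
    if receptor not in potential.receptor_ids:
        raise KeyError(f"unknown receptor: {receptor!r}")
    csn = np.asarray(csn, dtype=float)
    degree = csn.sum(axis=1)
    r = potential.receptor_ids.index(receptor)
    pot = np.array(
        [
            potential.matrix[r, potential.tf_ids.index(tf)]
            if tf in potential.tf_ids
            else 0.0
            for tf in response_ids
        ]
    )
    dmax, pmax = degree.max(initial=0.0), pot.max(initial=0.0)
    if dmax <= 0 or pmax <= 0:
        return []
    rank = (degree / dmax) * (pot / pmax)
    order = sorted(range(len(response_ids)), key=lambda i: (-rank[i], response_ids[i]))
    return [response_ids[i] for i in order[:top_t] if rank[i] > 0]


def shortest_signaling_path(
    pkn: PriorKnowledgeNetwork, receptor: str, tf: str
) -> SignalingPath | None:
    """Unweighted directed shortest path; among equal-length paths the
    lexicographically smallest node sequence is returned."""
    g = pkn.graph
    if receptor not in g or tf not in g:
        return None
    # distance-to-target by reverse BFS, then greedy lexicographic descent
    dist = {tf: 0}
    queue = deque([tf])
    while queue:
        v = queue.popleft()
        for u in g.predecessors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    if receptor not in dist:
        return None
    path = [receptor]
    current = receptor
    while current != tf:
        step = dist[current] - 1
        nxt = min(v for v in g.successors(current) if dist.get(v, -1) == step)
        path.append(nxt)
        current = nxt
    return SignalingPath(nodes=path)


def usp_triplets(
    csn: np.ndarray,
    response_ids: list[str],
    predictor_ids: list[str],
    potential: RegulatoryPotential,
    signaling: PriorKnowledgeNetwork,
    receptors: list[str],
    top_t: int = 1,
) -> pd.DataFrame:
    """Receptor -> (signaling path) -> TF -> target triplets for a pruned CSN.

    For each prioritized receptor and each of its mediating TFs, one row per
    surviving TF-target edge, carrying the shortest receptor-to-TF path.
    TFs unreachable in the signaling network are skipped (logged)."""
    csn = np.asarray(csn, dtype=float)
    rows = []
    for receptor in receptors:
        for tf in select_mediating_tfs(csn, response_ids, potential, receptor, top_t):
            path = shortest_signaling_path(signaling, receptor, tf)
            if path is None:
                warnings.warn(
                    f"{tf!r} unreachable from {receptor!r} in the signaling network"
                )
                continue
            i = response_ids.index(tf)
            for j in np.flatnonzero(csn[i] > 0):
                rows.append(
                    {
                        "receptor": receptor,
                        "tf": tf,
                        "target": predictor_ids[j],
                        "coexpression": csn[i, j],
                        "path": "->".join(path.nodes),
                        "hops": path.hops,
                    }
                )
    return pd.DataFrame(
        rows, columns=["receptor", "tf", "target", "coexpression", "path", "hops"]
    )


def classify_edges(
    csn: np.ndarray,
    scores: np.ndarray,
    grn: PriorKnowledgeNetwork,
    response_ids: list[str],
    predictor_ids: list[str],
    threshold: float = 0.95,
    max_steps: int = 2,
) -> pd.DataFrame:
    """Evidence label per edge: 'none' (below threshold), 'coexpression_only'
    (significant but unsupported within the step budget), or
    'prior_supported' with its sign (activation / repression / unknown)."""
    csn = np.asarray(csn, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if csn.shape != scores.shape:
        raise ValidationError("CSN and score shapes must match")
    support = support_matrix(grn, response_ids, predictor_ids, max_steps)
    rows = []
    for i, tf in enumerate(response_ids):
        for j, target in enumerate(predictor_ids):
            if scores[i, j] < threshold:
                label, sign = "none", None
            elif support[i, j]:
                label = "prior_supported"
                sign = grn.sign(tf, target)
                sign = {1: "activation", -1: "repression"}.get(sign, "unknown")
            else:
                label, sign = "coexpression_only", None
            rows.append(
                {
                    "tf": tf,
                    "target": target,
                    "coexpression": csn[i, j],
                    "score": scores[i, j],
                    "evidence": label,
                    "sign": sign,
                }
            )
    return pd.DataFrame(rows)


def layered_dot_export(triplets: pd.DataFrame) -> str:
    """DOT text for the layered targets / TFs / receptors view of USP triplets."""
    lines = ["digraph usp {", "  rankdir=LR;"]
    receptors = sorted(triplets["receptor"].unique())
    tfs = sorted(triplets["tf"].unique())
    targets = sorted(triplets["target"].unique())
    for name, members in (("receptors", receptors), ("tfs", tfs), ("targets", targets)):
        lines.append(f"  subgraph cluster_{name} {{")
        lines.append(f'    label="{name}";')
        for m in members:
            lines.append(f'    "{m}";')
        lines.append("  }")
    seen = set()
    for row in triplets.itertuples(index=False):
        hops = row.path.split("->")
        for u, v in zip(hops[:-1], hops[1:]):
            if (u, v) not in seen:
                seen.add((u, v))
                lines.append(f'  "{u}" -> "{v}" [style=solid];')
        if (row.tf, row.target) not in seen:
            seen.add((row.tf, row.target))
            lines.append(f'  "{row.tf}" -> "{row.target}" [style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"
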