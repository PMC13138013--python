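"""Seeded generators for synthetic single-cell expression with planted,
cell-state-specific TF-target coexpression modules.

The generative model is a latent-factor one: each module has a TF and a
target set sharing a per-cell latent activity a ~ N(0, 1), active only in the
module's population, plus independent Gaussian noise everywhere. Population
identity additionally shifts a set of marker genes so that populations
separate in PC space (mimicking cluster structure). Raw values are mapped
through log1p(exp(.)) so the matrix is nonnegative on a log-expression-like
scale; see the methods note for what this emulates and what it does not.
Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError
from .prior import PriorKnowledgeNetwork


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated data set.

    Records population labels, the planted modules (TF, targets, effect,
    population), and any perturbation assignment. The pre-transform raw
    matrix and per-module latents are kept so perturbations replay exactly.
    """

    labels: np.ndarray
    modules: list[dict]
    gene_ids: list[str]
    cell_ids: list[str]
    seed: int | None
    noise_sd: float
    perturbed_tf: str | None = None
    perturbed_mask: np.ndarray | None = None
    raw: np.ndarray = field(repr=False, default=None)
    baseline: np.ndarray = field(repr=False, default=None)
    latents: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        for mod in self.modules:
            if mod["effect"] <= 0:
                raise ValidationError("module effect sizes must be positive")
            if mod["tf"] not in genes or not set(mod["targets"]) <= genes:
                raise ValidationError("planted module names genes absent from matrix")

    @property
    def planted_edges(self) -> list[tuple[str, str]]:
        return [(m["tf"], t) for m in self.modules for t in m["targets"]]

    @property
    def tf_genes(self) -> list[str]:
        return [m["tf"] for m in self.modules]

    @property
    def predictor_genes(self) -> list[str]:
        tfs = set(self.tf_genes)
        return [g for g in self.gene_ids if g not in tfs]


def _to_expression(raw: np.ndarray, cell_ids, gene_ids) -> ExpressionMatrix:
    return ExpressionMatrix(np.log1p(np.exp(raw)), cell_ids, gene_ids)


def simulate_modules(
    n_cells: int = 600,
    n_genes: int = 300,
    n_populations: int = 3,
    n_modules: int = 3,
    genes_per_module: int = 10,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    module_mean: float = 1.0,
    marker_strength: float = 2.0,
    markers_per_population: int = 20,
    confounder_strength: float = 0.0,
    seed: int | None = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted population-specific coexpression modules.

    Each module consists of one TF and ``genes_per_module - 1`` targets;
    modules are assigned round-robin to populations and are active (shared
    latent plus a mean lift) only in that population's cells. Population
    markers carry a mean shift so populations separate in PC space. Genes not
    in any module or marker set are pure noise.

    A shared co-regulation program (one global latent of strength
    ``confounder_strength``) additionally drives all module target genes in
    every cell, emulating the fact that real target genes respond to multiple
    transcriptional programs, not only to the planted TF. It enters the
    baseline, so perturbations never remove it.
    """
    if min(n_cells, n_genes, n_populations, n_modules, genes_per_module) < 1:
        raise ValidationError("all size parameters must be positive")
    if effect < 0 or noise_sd <= 0:
        raise ValidationError("effect must be >= 0 and noise_sd > 0")
    rng = np.random.default_rng(seed)

    gene_ids: list[str] = []
    modules: list[dict] = []
    for m in range(n_modules):
        tf = f"TF{m + 1:02d}"
        targets = [f"M{m + 1:02d}_T{t + 1:02d}" for t in range(genes_per_module - 1)]
        gene_ids.append(tf)
        gene_ids.extend(targets)
        modules.append(
            {
                "tf": tf,
                "targets": targets,
                "population": m % n_populations,
                "effect": max(effect, np.finfo(float).tiny),
            }
        )
    markers: list[list[str]] = []
    for c in range(n_populations):
        pop_markers = [f"P{c + 1}_MK{j + 1:02d}" for j in range(markers_per_population)]
        markers.append(pop_markers)
        gene_ids.extend(pop_markers)
    n_fill = n_genes - len(gene_ids)
    if n_fill < 0:
        raise ValidationError(
            f"n_genes={n_genes} too small for {len(gene_ids)} structured genes"
        )
    gene_ids.extend(f"NG{j + 1:04d}" for j in range(n_fill))
    cell_ids = [f"C{i + 1:04d}" for i in range(n_cells)]
    pos = {g: i for i, g in enumerate(gene_ids)}

    labels = np.arange(n_cells) % n_populations
    baseline = noise_sd * rng.standard_normal((n_cells, n_genes))
    for c, pop_markers in enumerate(markers):
        idx = [pos[g] for g in pop_markers]
        baseline[np.ix_(labels == c, idx)] += marker_strength
    if confounder_strength > 0 and modules:
        shared = rng.standard_normal(n_cells)
        all_targets = [pos[t] for mod in modules for t in mod["targets"]]
        baseline[:, all_targets] += confounder_strength * shared[:, None]
    raw = baseline.copy()
    latents = []
    for mod in modules:
        a = rng.standard_normal(n_cells)
        latents.append(a)
        active = labels == mod["population"]
        idx = [pos[mod["tf"]]] + [pos[t] for t in mod["targets"]]
        raw[np.ix_(active, idx)] += module_mean + effect * a[active, None]
    truth = SyntheticTruth(
        labels=labels,
        modules=modules,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        seed=seed,
        noise_sd=noise_sd,
        raw=raw,
        baseline=baseline,
        latents=latents,
    )
    return _to_expression(raw, cell_ids, gene_ids), truth


def simulate_perturbation(
    truth: SyntheticTruth,
    perturbed_tf: str,
    fraction: float = 0.3,
    seed: int | None = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Sever one TF's latent coupling in a random cell fraction.

    Perturbed cells lose the module contribution (mean lift and shared
    latent) on that TF's targets, leaving baseline noise; the TF's own
    expression is untouched. Emulates a pooled knockout screen where guides
    abolish the TF's regulatory output.
    """
    if not (0 <= fraction <= 1):
        raise ValidationError("fraction must lie in [0, 1]")
    matching = [m for m in truth.modules if m["tf"] == perturbed_tf]
    if not matching:
        raise ValidationError(f"{perturbed_tf!r} is not a planted module TF")
    mod = matching[0]
    rng = np.random.default_rng(seed)
    n = len(truth.cell_ids)
    n_pert = int(round(fraction * n))
    chosen = rng.choice(n, size=n_pert, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True

    pos = {g: i for i, g in enumerate(truth.gene_ids)}
    raw = truth.raw.copy()
    hit = mask & (truth.labels == mod["population"])
    target_idx = [pos[t] for t in mod["targets"]]
    raw[np.ix_(hit, target_idx)] = truth.baseline[np.ix_(hit, target_idx)]

    new_truth = SyntheticTruth(
        labels=truth.labels,
        modules=truth.modules,
        gene_ids=truth.gene_ids,
        cell_ids=truth.cell_ids,
        seed=seed,
        noise_sd=truth.noise_sd,
        perturbed_tf=perturbed_tf,
        perturbed_mask=mask,
        raw=raw,
        baseline=truth.baseline,
        latents=truth.latents,
    )
    return _to_expression(raw, truth.cell_ids, truth.gene_ids), new_truth


def toy_pkn(
    truth: SyntheticTruth,
    n_decoys: int = 0,
    chain_depth: int = 1,
    seed: int | None = 0,
) -> tuple[PriorKnowledgeNetwork, PriorKnowledgeNetwork, pd.DataFrame]:
    """Matched toy prior networks and regulon table for a synthetic truth.

    The regulation network contains exactly the planted TF -> target edges
    (sign +1) plus ``n_decoys`` random TF -> non-target edges. The signaling
    network contains a receptor node REC_<tf> per module TF connected to the
    TF through a chain of ``chain_depth`` edges (depth 1 = direct edge).
    """
    if chain_depth < 1:
        raise ValidationError("chain_depth must be at least 1")
    rng = np.random.default_rng(seed)
    planted = set(truth.planted_edges)
    reg_edges = [(tf, t, 1) for tf, t in truth.planted_edges]
    if n_decoys:
        tfs = truth.tf_genes
        candidates = [
            (tf, g)
            for tf in tfs
            for g in truth.gene_ids
            if g != tf and (tf, g) not in planted
        ]
        pick = rng.choice(len(candidates), size=min(n_decoys, len(candidates)), replace=False)
        for i in pick:
            tf, g = candidates[i]
            reg_edges.append((tf, g, int(rng.choice([-1, 1]))))
    regulation = PriorKnowledgeNetwork.from_edges(reg_edges, kind="regulation")

    sig_edges = []
    for mod in truth.modules:
        tf = mod["tf"]
        chain = [f"REC_{tf}"]
        chain += [f"SIG_{tf}_{i + 1}" for i in range(chain_depth - 1)]
        chain.append(tf)
        for u, v in zip(chain[:-1], chain[1:]):
            sig_edges.append((u, v, 1))
    signaling = PriorKnowledgeNetwork.from_edges(sig_edges, kind="signaling")

    regulon_df = pd.DataFrame(
        [(tf, t, 1) for tf, t in truth.planted_edges],
        columns=["tf", "target", "sign"],
    )
    return regulation, signaling, regulon_df
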