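"""TF activity scoring from expression or coexpression profiles.

Two scorers are provided. The rank-AUC scorer (AUCell-style) sorts a cell's
values, walks the top fraction of the ranking, and measures the area under
the target-recovery step curve relative to the best achievable area. The
univariate-regression scorer regresses a cell's values on a regulon dummy
vector (optionally signed) and reports the slope's t-value.

Applied to expression, these give expression-based TF activity (ETAS);
applied to a TF's coexpression row across the predictor universe from a
network ensemble, they give coexpression-based activity (CoETAS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EnsembleContainer, ExpressionMatrix, ValidationError

#: cap on |t| when the regression residual variance is exactly zero
T_CAP = 1e6


@dataclass
class Regulon:
    """A TF with its curated target set (optionally signed)."""

    tf: str
    targets: list[str]
    signs: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise ValidationError(f"regulon {self.tf!r} has no targets")


def regulons_from_table(df: pd.DataFrame, min_targets: int = 1) -> list[Regulon]:
    """Build regulons from a (tf, target, sign) table, dropping TFs with fewer
    than ``min_targets`` targets."""
    out = []
    for tf, group in df.groupby("tf", sort=True):
        targets = list(dict.fromkeys(group["target"]))
        if len(targets) < min_targets:
            continue
        signs = dict(zip(group["target"], group["sign"].astype(int)))
        out.append(Regulon(tf=str(tf), targets=targets, signs=signs))
    return out


def auc_score(
    values: np.ndarray,
    gene_ids: list[str],
    targets: set[str] | list[str],
    top_fraction: float = 0.05,
) -> float | None:
    """Area under the target-recovery curve over the top-ranked genes.

    Genes are ranked by descending value (ties by ascending symbol); the
    recovery curve accumulates target hits over the top ceil(tau * G) ranks
    and the area is normalized by the maximum achievable (all targets first).
    Returns None (with a warning) when no target is in the gene universe.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    g = len(values)
    target_set = set(targets) & set(gene_ids)
    if not target_set:
        warnings.warn("no regulon target present in the gene universe")
        return None
    order = np.lexsort((np.asarray(gene_ids, dtype=object), -values))
    top = math.ceil(top_fraction * g)
    hits = np.array([gene_ids[i] in target_set for i in order[:top]])
    area = float(np.cumsum(hits).sum())
    n_t = len(target_set)
    max_area = float(sum(min(i, n_t) for i in range(1, top + 1)))
    return area / max_area


def ulm_score(values: np.ndarray, dummy: np.ndarray) -> float:
    """t-value of the slope from regressing values on the regulon dummy.

    Simple least squares with intercept, G - 2 degrees of freedom. Zero
    residual variance caps the score at +/-1e6 with a warning.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(dummy, dtype=float)
    g = len(y)
    if g < 3:
        raise ValidationError("ulm_score requires at least 3 genes")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValidationError("regulon dummy vector is constant")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    resid = y - y.mean() - slope * (x - x.mean())
    ssr = float((resid**2).sum())
    if ssr <= 0:
        warnings.warn("zero residual variance; t-value capped")
        return math.copysign(T_CAP, slope) if slope != 0 else 0.0
    se = math.sqrt(ssr / (g - 2) / sxx)
    return slope / se


def _ulm_matrix(values: np.ndarray, dummy: np.ndarray) -> np.ndarray:
    """Vectorized ulm_score across rows of a cells x genes matrix."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(dummy, dtype=float)
    g = y.shape[1]
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    ssr = (yc**2).sum(axis=1) - slope**2 * sxx
    ssr = np.maximum(ssr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(ssr / (g - 2) / sxx)
    capped = ssr <= 1e-300
    if np.any(capped):
        warnings.warn("zero residual variance; t-value capped")
        t[capped] = np.sign(slope[capped]) * T_CAP
    return t


@dataclass
class ActivityMatrix:
    """TFs x cells activity scores with method and input provenance tags."""

    values: pd.DataFrame
    method: str
    input: str


def score_activity(
    matrix: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    regulons: list[Regulon],
    method: str = "ulm",
    input_tag: str = "expression",
    top_fraction: float = 0.05,
    min_targets: int = 1,
    signed: bool = True,
) -> ActivityMatrix:
    """Score every (TF, cell) pair on a cells x genes value matrix.

    TFs whose regulons resolve fewer than ``min_targets`` targets within the
    gene universe are dropped with a warning. For ``ulm`` the dummy vector is
    the signed regulon indicator (all +1 when ``signed=False`` or the regulon
    is unsigned); ``auc`` uses the unsigned target set.
    """
    if not regulons:
        raise ValidationError("empty regulon collection")
    if method not in ("ulm", "auc"):
        raise ValidationError("method must be 'ulm' or 'auc'")
    matrix = np.asarray(matrix, dtype=float)
    universe = set(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    rows = {}
    dropped = []
    for reg in regulons:
        resolved = [t for t in reg.targets if t in universe]
        if len(resolved) < max(min_targets, 1):
            dropped.append(reg.tf)
            continue
        if method == "auc":
            scores = np.array(
                [
                    auc_score(matrix[c], gene_ids, resolved, top_fraction)
                    for c in range(matrix.shape[0])
                ]
            )
        else:
            dummy = np.zeros(len(gene_ids))
            for t in resolved:
                s = reg.signs.get(t, 1) if (signed and reg.signs) else 1
                dummy[pos[t]] = s if s != 0 else 1
            scores = _ulm_matrix(matrix, dummy)
        rows[reg.tf] = scores
    if dropped:
        warnings.warn(f"dropped {len(dropped)} regulon(s) with unresolvable targets")
    if not rows:
        raise ValidationError("no regulon with resolvable targets")
    df = pd.DataFrame(rows, index=cell_ids).T
    return ActivityMatrix(values=df, method=method, input=input_tag)


def expression_activity(
    expr: ExpressionMatrix, regulons: list[Regulon], method: str = "ulm", **kwargs
) -> ActivityMatrix:
    """Expression-based TF activity (ETAS)."""
    return score_activity(
        expr.values,
        list(expr.gene_ids),
        list(expr.cell_ids),
        regulons,
        method=method,
        input_tag="expression",
        **kwargs,
    )


def coexpression_activity(
    ensemble: EnsembleContainer,
    regulons: list[Regulon],
    method: str = "ulm",
    **kwargs,
) -> ActivityMatrix:
    """Coexpression-based TF activity (CoETAS).

    For each TF with a response row in the ensemble, the per-cell value vector
    is that TF's coexpression row over the full predictor universe (non-target
    predictors sit naturally near zero).
    """
    scorable = [r for r in regulons if r.tf in ensemble.response_ids]
    if not scorable:
        raise ValidationError("no regulon TF among the ensemble responses")
    frames = []
    for reg in scorable:
        i = ensemble.response_ids.index(reg.tf)
        sub = score_activity(
            ensemble.coexpression[:, i, :],
            list(ensemble.predictor_ids),
            list(ensemble.representative_ids),
            [reg],
            method=method,
            input_tag="coexpression",
            **kwargs,
        )
        frames.append(sub.values)
    return ActivityMatrix(
        values=pd.concat(frames), method=method, input="coexpression"
    )


class TFActivityScorer(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer: cells x genes -> cells x TFs activity."""

    def __init__(
        self,
        regulons: list[Regulon] | None = None,
        method: str = "ulm",
        top_fraction: float = 0.05,
        min_targets: int = 1,
        signed: bool = True,
    ) -> None:
        self.regulons = regulons
        self.method = method
        self.top_fraction = top_fraction
        self.min_targets = min_targets
        self.signed = signed

    def fit(self, X, y=None, gene_ids: list[str] | None = None):
        if isinstance(X, ExpressionMatrix):
            gene_ids = list(X.gene_ids)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(np.asarray(X).shape[1])]
        self.gene_ids_ = gene_ids
        universe = set(gene_ids)
        self.tf_names_ = [
            r.tf
            for r in (self.regulons or [])
            if len(set(r.targets) & universe) >= max(self.min_targets, 1)
        ]
        return self

    def transform(self, X):
        if isinstance(X, ExpressionMatrix):
            values, cells = X.values, list(X.cell_ids)
        else:
            values = np.asarray(X, dtype=float)
            cells = [str(i) for i in range(values.shape[0])]
        am = score_activity(
            values,
            self.gene_ids_,
            cells,
            self.regulons or [],
            method=self.method,
            top_fraction=self.top_fraction,
            min_targets=self.min_targets,
            signed=self.signed,
        )
        return am.values.T.to_numpy()
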