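"""Readers and writers for the standard on-disk formats.

Expression matrices come in as Matrix Market sparse triplets with companion
row/column name files, or as dense TSV/CSV (genes-in-rows by default, the
common single-cell convention). Ensembles are stored in an HDF5 container
chunked along the cell axis so per-cell network slices stream without loading
the full cube. Prior-knowledge networks and regulons are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import EnsembleContainer, ExpressionMatrix, FormatError


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    fmt: str | None = None,
    cells_in_rows: bool = False,
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX or dense TSV/CSV.

    Parameters
    ----------
    path:
        The matrix file. For ``mtx``, companion name files are required:
        ``row_names``/``col_names`` or siblings named ``genes.tsv``/
        ``features.tsv`` (rows) and ``barcodes.tsv`` (columns).
    cells_in_rows:
        On-disk orientation. Defaults to genes-in-rows; the returned matrix is
        always oriented cells x genes.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        mat = scipy.sparse.coo_matrix(mat).toarray()
        rows = _read_names(_locate_names(path, row_names, ("genes.tsv", "features.tsv")))
        cols = _read_names(_locate_names(path, col_names, ("barcodes.tsv",)))
        if mat.shape != (len(rows), len(cols)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match {len(rows)} row names "
                f"and {len(cols)} column names"
            )
        if cells_in_rows:
            values, cell_ids, gene_ids = mat, rows, cols
        else:
            values, cell_ids, gene_ids = mat.T, cols, rows
    elif fmt == "tsv":
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not cells_in_rows:
            df = df.T
        values = df.to_numpy(dtype=float)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
    else:
        raise FormatError(f"unknown expression format: {fmt!r}")
    if not np.all(np.isfinite(values)):
        raise FormatError(f"non-finite values in {path}")
    return ExpressionMatrix(values, cell_ids, gene_ids)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    fmt: str | None = None,
    cells_in_rows: bool = False,
) -> None:
    """Write an expression matrix as MTX (+ name files) or dense TSV/CSV."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "mtx":
        mat = expr.values if cells_in_rows else expr.values.T
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat))
        rows = expr.cell_ids if cells_in_rows else expr.gene_ids
        cols = expr.gene_ids if cells_in_rows else expr.cell_ids
        rows_file = "barcodes.tsv" if cells_in_rows else "genes.tsv"
        cols_file = "genes.tsv" if cells_in_rows else "barcodes.tsv"
        _write_names(path.parent / rows_file, rows)
        _write_names(path.parent / cols_file, cols)
    elif fmt == "tsv":
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
        if not cells_in_rows:
            df = df.T
        df.to_csv(path, sep=sep)
    else:
        raise FormatError(f"unknown expression format: {fmt!r}")


def _locate_names(
    mtx_path: Path, explicit: str | Path | None, candidates: Sequence[str]
) -> Path:
    if explicit is not None:
        return Path(explicit)
    for name in candidates:
        cand = mtx_path.parent / name
        if cand.exists():
            return cand
    raise FormatError(
        f"no companion name file ({'/'.join(candidates)}) next to {mtx_path}"
    )


def _read_names(path: Path) -> list[str]:
    # first tab-separated field per line (10x features.tsv has extra columns)
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            names.append(line.split("\t")[0])
    if not names:
        raise FormatError(f"empty name file: {path}")
    return names


def _write_names(path: Path, names: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, order preserved."""
    symbols = [s.strip() for s in Path(path).read_text().splitlines()]
    symbols = [s for s in symbols if s]
    if not symbols:
        raise FormatError(f"empty gene list: {path}")
    return symbols


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# ensemble container (HDF5)
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def save_ensemble(ensemble: EnsembleContainer, path: str | Path) -> None:
    """Persist an ensemble; the cube is chunked along the cell axis."""
    cube = ensemble.coexpression
    if not np.all(np.isfinite(cube)):
        raise FormatError("refusing to save a cube with non-finite values")
    m, p, q = cube.shape
    chunk = (1, max(p, 1), max(q, 1))
    with h5py.File(path, "w") as f:
        f.create_dataset("coexpression", data=cube, chunks=chunk if m else None)
        if ensemble.significance is not None:
            f.create_dataset(
                "significance", data=ensemble.significance, chunks=chunk if m else None
            )
        f.create_dataset("cells", data=np.array(ensemble.representative_ids, dtype=_STR))
        f.create_dataset("responses", data=np.array(ensemble.response_ids, dtype=_STR))
        f.create_dataset("predictors", data=np.array(ensemble.predictor_ids, dtype=_STR))
        f.create_dataset("provenance", data=json.dumps(ensemble.provenance, default=str))


def load_ensemble(path: str | Path) -> EnsembleContainer:
    with h5py.File(path, "r") as f:
        for ds in ("coexpression", "cells", "responses", "predictors"):
            if ds not in f:
                raise FormatError(f"ensemble container missing /{ds}")
        cube = f["coexpression"][()]
        sig = f["significance"][()] if "significance" in f else None
        cells = [s.decode() for s in f["cells"][()]]
        responses = [s.decode() for s in f["responses"][()]]
        predictors = [s.decode() for s in f["predictors"][()]]
        prov = json.loads(f["provenance"][()]) if "provenance" in f else {}
    return EnsembleContainer(cube, cells, responses, predictors, sig, prov)


# ---------------------------------------------------------------------------
# prior-knowledge networks and regulons
# ---------------------------------------------------------------------------

def load_pkn_table(path: str | Path) -> pd.DataFrame:
    """Load a signed edge list (columns: source, target, sign).

    Duplicate edges with conflicting signs collapse to sign 0 (ambiguous).
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"source", "target", "sign"} - set(df.columns)
    if missing:
        raise FormatError(f"edge list {path} missing columns: {sorted(missing)}")
    df = df[["source", "target", "sign"]].copy()
    df["source"] = df["source"].astype(str)
    df["target"] = df["target"].astype(str)
    df["sign"] = df["sign"].astype(int)
    grouped = df.groupby(["source", "target"], sort=False)["sign"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else 0
    )
    out = grouped.reset_index()
    return out


def save_pkn_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["source", "target", "sign"]].to_csv(path, sep="\t", index=False)


def load_regulon_table(path: str | Path) -> pd.DataFrame:
    """Load a regulon table (columns: tf, target, sign)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"tf", "target"} - set(df.columns)
    if missing:
        raise FormatError(f"regulon table {path} missing columns: {sorted(missing)}")
    if "sign" not in df.columns:
        df["sign"] = 1
    df = df[["tf", "target", "sign"]].copy()
    df["tf"] = df["tf"].astype(str)
    df["target"] = df["target"].astype(str)
    df["sign"] = df["sign"].astype(int)
    return df


def write_provenance(path: str | Path, record: dict) -> None:
    """Write a provenance block (JSON) next to a CLI output."""
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
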