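"""Readers and writers for every external artifact of the pipeline.

Expression comes in as MatrixMarket triplets (with gene/barcode sidecar
lists) or a dense CSV; coordinates, cell-type proportions, cell-type labels
and the ligand-receptor database are header-ed CSV/TSV tables; results go out
as a TSV with a fixed column contract. The module also houses the
label -> one-hot matrix transform for single-cell data and the case-study
quality filters (minimum expressed genes per cell, minimum expressing-cell
fraction per gene).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import LRDatabase, LRPair, SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_coordinates",
    "read_composition",
    "read_cell_types",
    "read_lr_database",
    "cell_type_matrix",
    "qc_filter",
    "write_results",
    "read_results",
    "load_dataset",
    "normalize_log1p",
]

RESULT_COLUMNS = [
    "ligand",
    "receptor",
    "pathway",
    "sender_type",
    "receiver_type",
    "estimate",
    "std_error",
    "p_value",
    "p_adjusted",
    "rho_selected",
    "converged",
]


def _collapse_duplicate_genes(mat: np.ndarray, gene_ids: list[str]):
    """Sum rows sharing a gene symbol (keeps first-occurrence order)."""
    if len(set(gene_ids)) == len(gene_ids):
        return mat, gene_ids
    order: dict[str, int] = {}
    for g in gene_ids:
        order.setdefault(g, len(order))
    out = np.zeros((len(order), mat.shape[1]), dtype=float)
    for row, g in enumerate(gene_ids):
        out[order[g]] += mat[row]
    dups = [g for g in order if gene_ids.count(g) > 1]
    logger.warning("collapsed %d duplicated gene symbol(s) by summation: %s",
                   len(dups), dups[:10])
    return out, list(order)


def read_expression(path: str | Path, format: str | None = None):
    """Read a genes x units expression matrix.

    ``format="mtx"`` expects a MatrixMarket file plus sidecars ``genes.txt``
    / ``features.txt`` and ``barcodes.txt`` in the same directory (one id per
    line). ``format="csv"`` (or ``.tsv``) expects gene rows, unit columns,
    with ids in the first column / header. Duplicate gene symbols are summed
    with a logged warning; negative entries are rejected.

    Returns
    -------
    (matrix, gene_ids, unit_ids)
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        gdir = path.parent
        gene_file = None
        for cand in ("genes.txt", "features.txt", path.stem + ".genes.txt"):
            if (gdir / cand).exists():
                gene_file = gdir / cand
                break
        bc_file = None
        for cand in ("barcodes.txt", path.stem + ".barcodes.txt"):
            if (gdir / cand).exists():
                bc_file = gdir / cand
                break
        if gene_file is None or bc_file is None:
            raise FileNotFoundError(
                f"MTX sidecar files (genes/features + barcodes) not found next to {path}"
            )
        gene_ids = gene_file.read_text().split()
        unit_ids = bc_file.read_text().split()
        if mat.shape != (len(gene_ids), len(unit_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(unit_ids)} barcodes)"
            )
    elif format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        unit_ids = [str(u) for u in df.columns]
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if (mat < 0).any():
        r, c = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"negative expression at gene {gene_ids[r]!r}, unit {unit_ids[c]!r}"
        )
    mat, gene_ids = _collapse_duplicate_genes(mat, gene_ids)
    return mat, gene_ids, unit_ids


def read_coordinates(path: str | Path):
    """Read unit coordinates (columns: unit_id, x, y) -> (coords, unit_ids)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"unit_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate file must have columns {sorted(required)}")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    if np.isnan(coords).any():
        raise ValueError("coordinates contain missing values")
    return coords, [str(u) for u in df["unit_id"]]


def read_composition(path: str | Path):
    """Read per-spot cell-type proportions (unit_id + one column per type)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "unit_id" not in df.columns:
        raise ValueError("proportion file must have a unit_id column")
    types = [c for c in df.columns if c != "unit_id"]
    comp = df[types].to_numpy(dtype=float)
    return comp, types, [str(u) for u in df["unit_id"]]


def read_cell_types(path: str | Path) -> list[str]:
    """Read per-cell type labels (columns: unit_id, cell_type)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "cell_type" not in df.columns:
        raise ValueError("cell-type file must have a cell_type column")
    return [str(t) for t in df["cell_type"]]


def cell_type_matrix(labels: list[str]):
    """One-hot cell-type identification matrix from per-cell labels.

    Column order is the sorted unique labels; every row sums to exactly 1.

    Returns
    -------
    (matrix N x G of 0/1 floats, type_names)
    """
    if len(labels) == 0:
        raise ValueError("need at least one label")
    for i, lab in enumerate(labels):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or lab == "":
            raise ValueError(f"missing cell-type label at index {i}")
    type_names = sorted(set(labels))
    index = {t: k for k, t in enumerate(type_names)}
    mat = np.zeros((len(labels), len(type_names)))
    for i, lab in enumerate(labels):
        mat[i, index[lab]] = 1.0
    return mat, type_names


def qc_filter(expr, min_genes_per_cell: int = 100,
              min_frac_cells_per_gene: float = 0.025):
    """Case-study quality filters on a genes x cells matrix.

    Cells are kept first (>= ``min_genes_per_cell`` strictly-positive
    entries), then genes expressed in at least ``min_frac_cells_per_gene`` of
    the surviving cells. "Expressed" means a strictly positive value.

    Returns
    -------
    (filtered matrix, kept_gene_idx, kept_cell_idx)
    """
    if min_genes_per_cell < 0 or min_frac_cells_per_gene < 0:
        raise ValueError("thresholds must be non-negative")
    expr = np.asarray(expr, dtype=float)
    pos = expr > 0
    cell_keep = np.where(pos.sum(axis=0) >= min_genes_per_cell)[0]
    if len(cell_keep) == 0:
        raise ValueError(
            f"no cell passes the filter (max expressed genes per cell: "
            f"{int(pos.sum(axis=0).max() if expr.size else 0)})"
        )
    sub = pos[:, cell_keep]
    gene_keep = np.where(sub.mean(axis=1) >= min_frac_cells_per_gene)[0]
    if len(gene_keep) == 0:
        raise ValueError(
            f"no gene passes the filter among {len(cell_keep)} kept cells"
        )
    return expr[np.ix_(gene_keep, cell_keep)], gene_keep, cell_keep


def read_lr_database(path: str | Path, subunit_sep: str = "_") -> LRDatabase:
    """Read a ligand-receptor table (columns: ligand, receptor[, pathway]).

    Multi-subunit complexes are encoded as separator-joined gene symbols
    (CellChatDB-style, e.g. ``Itga6_Itgb1``). Rows with an empty ligand or
    receptor are dropped with a logged warning; empty pathway labels default
    to "unassigned".
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("LR database must have ligand and receptor columns")
    pairs = []
    for i, row in df.iterrows():
        lig = row[cols["ligand"]]
        rec = row[cols["receptor"]]
        if pd.isna(lig) or pd.isna(rec) or str(lig) == "" or str(rec) == "":
            logger.warning("dropping LR row %d: empty ligand or receptor", i)
            continue
        pathway = row.get(cols.get("pathway", "pathway"), "unassigned")
        if pd.isna(pathway) or str(pathway) == "":
            pathway = "unassigned"
        pairs.append(
            LRPair(
                ligand_genes=str(lig).split(subunit_sep),
                receptor_genes=str(rec).split(subunit_sep),
                pathway=str(pathway),
                pair_id=f"{lig}→{rec}",
            )
        )
    return LRDatabase(pairs=pairs)


def write_results(result: pd.DataFrame, path: str | Path) -> None:
    """Write the inference table as TSV (NaN -> literal "NA").

    Column contract: ligand, receptor, pathway, sender_type, receiver_type,
    estimate, std_error, p_value, p_adjusted, rho_selected, converged.
    Round-trip via :func:`read_results` reproduces values to 1e-12.
    """
    if len(result) == 0:
        raise ValueError("result table is empty")
    missing = [c for c in RESULT_COLUMNS if c not in result.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    out = result[RESULT_COLUMNS].copy()
    out["converged"] = out["converged"].map(lambda v: "true" if v else "false")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df["converged"].dtype != bool:
        df["converged"] = df["converged"].map(
            {"true": True, "false": False, True: True, False: False}
        )
    return df


def normalize_log1p(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Optional helper: log1p of library-size-scaled counts (genes x units)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * scale)


def load_dataset(
    expr_path: str | Path,
    coords_path: str | Path,
    proportions_path: str | Path | None = None,
    cell_types_path: str | Path | None = None,
    expr_format: str | None = None,
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from on-disk artifacts.

    Exactly one of ``proportions_path`` (spot-based) or ``cell_types_path``
    (single-cell labels, converted via :func:`cell_type_matrix`) must be
    given. Units are aligned by their order; ids must agree.
    """
    expr, gene_ids, unit_ids = read_expression(expr_path, format=expr_format)
    coords, coord_units = read_coordinates(coords_path)
    if coord_units != unit_ids:
        raise ValueError("coordinate unit_ids do not match expression columns")
    if (proportions_path is None) == (cell_types_path is None):
        raise ValueError("provide exactly one of proportions or cell types")
    if proportions_path is not None:
        comp, type_names, prop_units = read_composition(proportions_path)
        if prop_units != unit_ids:
            raise ValueError("proportion unit_ids do not match expression columns")
        resolution = "spot"
    else:
        labels = read_cell_types(cell_types_path)
        if len(labels) != len(unit_ids):
            raise ValueError("cell-type label count does not match unit count")
        comp, type_names = cell_type_matrix(labels)
        resolution = "single_cell"
    return SpatialDataset(
        expr=expr,
        gene_ids=gene_ids,
        unit_ids=unit_ids,
        coords=coords,
        composition=comp,
        type_names=type_names,
        resolution=resolution,
    )
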