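"""Core in-memory containers for spatial cell-cell communication analysis.

A :class:`SpatialDataset` bundles the four ingredients the regression model
needs for one tissue sample: a normalized expression matrix, spatial
coordinates, a cell-type composition matrix (per-spot deconvolved proportions,
or one-hot labels at single-cell resolution) and the gene/unit identifiers.
Ligand-receptor knowledge is carried by :class:`LRDatabase`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialDataset", "LRPair", "LRDatabase"]

_COMPOSITION_TOL = 1e-6


@dataclass
class SpatialDataset:
    """Expression + coordinates + cell-type composition for one sample.

    Parameters
    ----------
    expr
        Non-negative normalized expression, genes x units. Dense ndarray or
        scipy sparse matrix.
    gene_ids, unit_ids
        Row / column identifiers of ``expr``.
    coords
        units x 2 array of spatial X/Y positions, in the same length unit as
        any distance threshold passed to the model.
    composition
        units x G matrix of cell-type proportions; each row sums to 1. For
        single-cell resolution data rows are one-hot.
    type_names
        The G cell-type names (column order of ``composition``).
    resolution
        ``"spot"`` or ``"single_cell"``.
    """

    expr: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    unit_ids: list[str]
    coords: np.ndarray
    composition: np.ndarray
    type_names: list[str]
    resolution: str = "spot"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        n_units = self.expr.shape[1]
        if len(self.gene_ids) != self.expr.shape[0]:
            raise ValueError("gene_ids length does not match expression rows")
        if len(self.unit_ids) != n_units:
            raise ValueError("unit_ids length does not match expression columns")
        if self.coords.shape != (n_units, 2):
            raise ValueError(
                f"coords must be ({n_units}, 2), got {self.coords.shape}"
            )
        if np.isnan(self.coords).any():
            raise ValueError("coords contain missing values")
        if self.composition.shape[0] != n_units:
            raise ValueError("composition rows do not match unit count")
        if self.composition.shape[1] != len(self.type_names):
            raise ValueError("composition columns do not match type_names")
        if (self.composition < -_COMPOSITION_TOL).any():
            raise ValueError("composition has negative entries")
        rowsum = self.composition.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > _COMPOSITION_TOL:
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"composition row {bad} sums to {rowsum[bad]:.8f}, expected 1"
            )
        if self.resolution not in ("spot", "single_cell"):
            raise ValueError("resolution must be 'spot' or 'single_cell'")
        if self.resolution == "single_cell":
            onehot = np.isin(np.round(self.composition, 6), (0.0, 1.0)).all()
            if not onehot:
                raise ValueError(
                    "single_cell resolution requires one-hot composition rows"
                )

    @property
    def n_units(self) -> int:
        return self.expr.shape[1]

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class LRPair:
    """One ligand-receptor interaction (possibly multi-subunit complexes)."""

    ligand_genes: list[str]
    receptor_genes: list[str]
    pathway: str = "unassigned"
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError("ligand and receptor gene lists must be non-empty")
        if not self.pathway:
            self.pathway = "unassigned"
        if not self.pair_id:
            self.pair_id = (
                "_".join(self.ligand_genes) + "→" + "_".join(self.receptor_genes)
            )


@dataclass
class LRDatabase:
    """A collection of :class:`LRPair` with unique pair ids."""

    pairs: list[LRPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pair_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pathways(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.pathway)
        return list(seen)

    def subset_pathway(self, label: str) -> "LRDatabase":
        sub = [p for p in self.pairs if p.pathway == label]
        return LRDatabase(pairs=sub)
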