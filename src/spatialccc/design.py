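"""Pairwise regression design for the distance-decayed communication model.

For one ligand-receptor pair the model regresses the pairwise communication
score ``C_ij = L_i * R_j`` (sender unit i, receiver unit j) on the decayed
cell-type interaction covariates

    log E(C_ij) = beta_0 + exp(-rho * D_ij) * sum_{g1,g2} beta_{g1,g2}
                  * M[i, g1] * M[j, g2]  + nu_L[grid(i)] + nu_R[grid(j)]

where M is the cell-type composition matrix, D the Euclidean distance and the
two random-intercept blocks are indexed by a rectangular spatial grid. This
module builds the (sender, receiver) pair table, the decayed covariate matrix
and the grid indices; the fitting machinery lives in :mod:`spatialccc.fit`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datasets import LRPair, SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PairDesign",
    "GridPartition",
    "communication_scores",
    "build_pair_set",
    "decay_weight",
    "assign_grid",
    "default_grid",
    "build_design",
]


@dataclass
class GridPartition:
    """Rectangular tiling of the tissue bounding box, ids 1..Ngrid.

    Rectangles are numbered row-major from the bottom-left: id =
    (row - 1) * n_x + col, rows binned on y and columns on x with equal
    widths. Points on the max edge belong to the last bin.
    """

    n_x: int
    n_y: int
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_grid(self) -> int:
        return self.n_x * self.n_y

    @classmethod
    def from_coords(cls, coords: np.ndarray, n_x: int, n_y: int) -> "GridPartition":
        coords = np.asarray(coords, dtype=float)
        return cls(
            n_x=n_x,
            n_y=n_y,
            xmin=float(coords[:, 0].min()),
            xmax=float(coords[:, 0].max()),
            ymin=float(coords[:, 1].min()),
            ymax=float(coords[:, 1].max()),
        )


def default_grid(coords: np.ndarray, target_per_cell: int = 25) -> GridPartition:
    """Square grid sized so each rectangle holds ~``target_per_cell`` units."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k = max(2, int(round(np.sqrt(n / target_per_cell))))
    return GridPartition.from_coords(coords, n_x=k, n_y=k)


@dataclass
class PairDesign:
    """Design of the pairwise regression for one LR pair at a fixed rho.

    ``X`` holds the intercept column followed by the G^2 decayed interaction
    covariates, ordered sender-major: (g1, g2) -> column 1 + g1 * G + g2.
    ``beta[g1, g2]`` and ``beta[g2, g1]`` are distinct coefficients, so the
    ordering is part of the contract.
    """

    sender_idx: np.ndarray
    receiver_idx: np.ndarray
    response: np.ndarray
    distance: np.ndarray
    X: np.ndarray
    sender_grid: np.ndarray
    receiver_grid: np.ndarray
    n_grid: int
    rho: float
    dmax: float
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = len(self.response)
        if p == 0:
            raise ValueError("empty pair design")
        for name in ("sender_idx", "receiver_idx", "distance", "sender_grid",
                     "receiver_grid"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} length mismatch")
        if self.X.shape[0] != p:
            raise ValueError("X row count mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.response)

    @property
    def n_types(self) -> int:
        g2 = self.X.shape[1] - 1
        return int(round(np.sqrt(g2)))

    def interaction_names(self) -> list[str]:
        g = self.n_types
        names = self.type_names or [f"type{i + 1}" for i in range(g)]
        return [f"{names[a]}→{names[b]}" for a in range(g) for b in range(g)]

    def to_frame(self) -> pd.DataFrame:
        """Debug serialization of the pair table (no covariates)."""
        return pd.DataFrame(
            {
                "sender": self.sender_idx,
                "receiver": self.receiver_idx,
                "distance": self.distance,
                "response": self.response,
                "sender_grid": self.sender_grid,
                "receiver_grid": self.receiver_grid,
            }
        )


def communication_scores(expr, gene_ids: list[str], pair: LRPair,
                         complex_rule: str = "min"):
    """Per-unit ligand (L) and receptor (R) expression for one LR pair.

    Multi-subunit complexes are combined across subunits by ``complex_rule``:
    ``"min"`` (conservative, all subunits required; default) or ``"geom"``
    (geometric mean). Subunit genes absent from ``gene_ids`` are ignored; if
    no gene of a side is measured the pair is not measurable.

    Returns
    -------
    (L, R) : ndarray, ndarray
        Length-N non-negative vectors.

    Raises
    ------
    KeyError
        If no ligand gene or no receptor gene is present in ``gene_ids``.
    """
    index = {g: i for i, g in enumerate(gene_ids)}

    def side(genes: list[str], label: str) -> np.ndarray:
        rows = [index[g] for g in genes if g in index]
        if not rows:
            raise KeyError(
                f"pair {pair.pair_id!r} not measurable: no {label} gene of "
                f"{genes} found in expression matrix"
            )
        block = expr[rows, :]
        if sp.issparse(block):
            block = np.asarray(block.todense())
        block = np.asarray(block, dtype=float)
        if complex_rule == "min":
            return block.min(axis=0)
        if complex_rule == "geom":
            return np.exp(np.mean(np.log(block + 1e-300), axis=0)) * (
                (block > 0).all(axis=0)
            )
        raise ValueError(f"unknown complex_rule {complex_rule!r}")

    return side(pair.ligand_genes, "ligand"), side(pair.receptor_genes, "receptor")


def build_pair_set(coords: np.ndarray, dmax: float, include_self: bool = True):
    """All ordered unit pairs within Euclidean distance ``dmax``.

    Self pairs (i, i) at distance 0 model autocrine signaling and are included
    by default. The boundary is inclusive: D == dmax is kept. Uses a k-d tree
    prefilter so cost is near-linear in the number of qualifying pairs.

    Returns
    -------
    (sender_idx, receiver_idx, distance) : three aligned ndarrays.
    """
    coords = np.asarray(coords, dtype=float)
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(dmax, output_type="ndarray")  # unordered i<j
    i = pairs[:, 0]
    j = pairs[:, 1]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    sender = np.concatenate([i, j])
    receiver = np.concatenate([j, i])
    dist = np.concatenate([d, d])
    if include_self:
        n = coords.shape[0]
        sender = np.concatenate([sender, np.arange(n)])
        receiver = np.concatenate([receiver, np.arange(n)])
        dist = np.concatenate([dist, np.zeros(n)])
    if len(sender) == 0:
        raise ValueError("dmax too small: no unit pairs within range")
    order = np.lexsort((receiver, sender))
    return sender[order], receiver[order], dist[order]


def decay_weight(rho: float, distance) -> np.ndarray:
    """Exponential distance decay ``exp(-rho * D)``; 1 at D = 0 or rho = 0."""
    if rho < 0:
        raise ValueError("rho must be non-negative")
    return np.exp(-rho * np.asarray(distance, dtype=float))


def assign_grid(coords: np.ndarray, partition: GridPartition) -> np.ndarray:
    """Map each unit to its rectangle id in 1..Ngrid.

    Equal-width binning on each axis; a degenerate axis (all coordinates
    equal) collapses to a single bin. Points exactly on the max edge go to
    the last bin.
    """
    coords = np.asarray(coords, dtype=float)

    def bins(vals, lo, hi, k):
        if hi <= lo:  # degenerate axis
            if k > 1:
                logger.warning("degenerate bounding-box axis collapsed to 1 bin")
            return np.zeros(len(vals), dtype=int), 1
        idx = np.floor((vals - lo) / (hi - lo) * k).astype(int)
        return np.clip(idx, 0, k - 1), k

    col, n_x = bins(coords[:, 0], partition.xmin, partition.xmax, partition.n_x)
    row, _ = bins(coords[:, 1], partition.ymin, partition.ymax, partition.n_y)
    return row * n_x + col + 1


def build_design(
    dataset: SpatialDataset,
    L: np.ndarray,
    R: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    rho: float,
    partition: GridPartition | None = None,
    response: np.ndarray | None = None,
) -> PairDesign:
    """Assemble the :class:`PairDesign` for one LR pair at a fixed ``rho``.

    ``response[p] = L[sender] * R[receiver]`` unless an explicit ``response``
    vector (e.g. pathway-aggregated scores) is supplied. The covariate for
    (g1, g2) is ``exp(-rho D) * M[sender, g1] * M[receiver, g2]``.

    Raises
    ------
    ValueError
        If the response is identically zero ("no signal for this pair").
    """
    sender, receiver, dist = pairs
    if partition is None:
        partition = default_grid(dataset.coords)
    w = decay_weight(rho, dist)
    if response is None:
        response = np.asarray(L, dtype=float)[sender] * np.asarray(R, float)[receiver]
    response = np.asarray(response, dtype=float)
    if not (response > 0).any():
        raise ValueError("no signal for this pair: response identically zero")
    M = dataset.composition
    # (P, G, G) outer products flattened sender-major, scaled by decay
    XI = (M[sender][:, :, None] * M[receiver][:, None, :]).reshape(len(sender), -1)
    X = np.column_stack([np.ones(len(sender)), XI * w[:, None]])
    grid_ids = assign_grid(dataset.coords, partition)
    return PairDesign(
        sender_idx=np.asarray(sender),
        receiver_idx=np.asarray(receiver),
        response=response,
        distance=np.asarray(dist, dtype=float),
        X=X,
        sender_grid=grid_ids[sender],
        receiver_grid=grid_ids[receiver],
        n_grid=partition.n_grid,
        rho=float(rho),
        dmax=float(dist.max() if len(dist) else 0.0),
        type_names=list(dataset.type_names),
    )
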