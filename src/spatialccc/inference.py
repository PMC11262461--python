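"""End-to-end communication inference for ligand-receptor pairs and pathways.

For every measurable LR pair the pipeline

1. computes per-unit ligand/receptor scores and the pairwise response
   C_ij = L_i * R_j over all ordered unit pairs within ``dmax``;
2. selects the distance-decay rate rho from a candidate list by AIC,
   rebuilding the design and running the full fit at each candidate;
3. reports Wald tests for every (sender type, receiver type) coefficient,
   with Benjamini-Hochberg FDR adjustment across the emitted table.

Pathway-level inference pools the responses of all LR pairs sharing a
pathway label (C_ij = sum_k C_ijk) and sends the pooled response through the
identical fitting path as a single pseudo-pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import FitConfig
from .datasets import LRDatabase, LRPair, SpatialDataset
from .design import (
    GridPartition,
    PairDesign,
    build_design,
    build_pair_set,
    communication_scores,
    default_grid,
)
from .fit import TweedieFit, fit_design

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "default_rho_candidates",
    "select_rho",
    "fit_pair",
    "run_ccc",
    "run_pathway",
    "aggregate_pathway",
]

RESULT_COLUMNS = [
    "ligand",
    "receptor",
    "pathway",
    "sender_type",
    "receiver_type",
    "estimate",
    "std_error",
    "z_value",
    "p_value",
    "p_adjusted",
    "rho_selected",
    "power_p",
    "aic",
    "converged",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries are passed through and excluded from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def default_rho_candidates(distance: np.ndarray) -> list[float]:
    """Scale-adaptive decay candidates: 0 plus rates halving the decay weight
    to q in {0.75, 0.5, 0.25, 0.1} at the median positive pairwise distance."""
    d = np.asarray(distance, dtype=float)
    d_med = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    return [0.0] + [-np.log(q) / d_med for q in (0.75, 0.5, 0.25, 0.1)]


@dataclass
class PairFitResult:
    """Fit of one LR pair (or pathway pseudo-pair): selected rho + final fit."""

    fit: TweedieFit
    rho: float
    aic_table: pd.DataFrame  # columns rho, aic, converged
    design: PairDesign


def _fit_response(
    dataset: SpatialDataset,
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    response: np.ndarray,
    rho_candidates: list[float],
    partition: GridPartition,
    config: FitConfig,
) -> PairFitResult:
    """Select rho by AIC over candidates, running the full fit at each."""
    if not rho_candidates:
        raise ValueError("need at least one rho candidate")
    if min(rho_candidates) < 0:
        raise ValueError("rho candidates must be non-negative")
    records = []
    fits: dict[float, tuple[TweedieFit, PairDesign]] = {}
    for rho in rho_candidates:
        design = build_design(
            dataset, None, None, pairs, rho, partition=partition, response=response
        )
        fit = fit_design(design, config=config)
        fits[rho] = (fit, design)
        records.append({"rho": rho, "aic": fit.aic, "converged": fit.converged})
    table = pd.DataFrame(records)
    finite = table["aic"].notna() & table["converged"]
    if not finite.any():
        raise RuntimeError("no rho candidate produced a converged fit")
    sub = table[finite]
    best_aic = sub["aic"].min()
    # ties (within numerical noise) resolved toward the smallest rho
    tied = sub[np.abs(sub["aic"] - best_aic) <= 1e-9 * (abs(best_aic) + 1.0)]
    rho_best = float(tied["rho"].min())
    fit, design = fits[rho_best]
    return PairFitResult(fit=fit, rho=rho_best, aic_table=table, design=design)


def select_rho(
    dataset: SpatialDataset,
    pair: LRPair,
    dmax: float,
    rho_candidates: list[float] | None = None,
    config: FitConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """AIC-based selection of the decay rate for one LR pair.

    Returns the selected rho and the per-candidate AIC table.
    """
    config = config or FitConfig()
    res = fit_pair(dataset, pair, dmax, rho_candidates, config)
    return res.rho, res.aic_table


def _partition_for(dataset: SpatialDataset, config: FitConfig) -> GridPartition:
    if config.grid_nx and config.grid_ny:
        return GridPartition.from_coords(
            dataset.coords, n_x=config.grid_nx, n_y=config.grid_ny
        )
    return default_grid(dataset.coords)


def fit_pair(
    dataset: SpatialDataset,
    pair: LRPair,
    dmax: float,
    rho_candidates: list[float] | None = None,
    config: FitConfig | None = None,
    response: np.ndarray | None = None,
) -> PairFitResult:
    """Full fit of one LR pair: scores, pair set, rho selection, final fit.

    An explicit ``response`` (aligned with the pair set) bypasses the
    L_i * R_j construction; this is how pathway aggregation and simulation
    studies feed pre-computed pairwise scores through the same path.
    """
    config = config or FitConfig()
    pairs = build_pair_set(dataset.coords, dmax, include_self=config.include_self)
    if response is None:
        L, R = communication_scores(
            dataset.expr, dataset.gene_ids, pair, complex_rule=config.complex_rule
        )
        response = L[pairs[0]] * R[pairs[1]]
    if rho_candidates is None:
        rho_candidates = default_rho_candidates(pairs[2])
    partition = _partition_for(dataset, config)
    return _fit_response(dataset, pairs, response, rho_candidates, partition, config)


def _result_rows(pair: LRPair, res: PairFitResult, type_names: list[str]) -> list[dict]:
    fit = res.fit
    g = len(type_names)
    se = np.sqrt(np.diag(fit.cov_beta))[1:]
    rows = []
    for a in range(g):
        for b in range(g):
            k = a * g + b
            est = fit.beta[k]
            s = se[k]
            if np.isfinite(est) and np.isfinite(s) and s > 0:
                z = est / s
                pv = 2.0 * stats.norm.sf(abs(z))
            else:
                z = np.nan
                pv = np.nan
            rows.append(
                {
                    "ligand": "_".join(pair.ligand_genes),
                    "receptor": "_".join(pair.receptor_genes),
                    "pathway": pair.pathway,
                    "sender_type": type_names[a],
                    "receiver_type": type_names[b],
                    "estimate": est,
                    "std_error": s,
                    "z_value": z,
                    "p_value": pv,
                    "rho_selected": res.rho,
                    "power_p": fit.power_p,
                    "aic": fit.aic,
                    "converged": bool(fit.converged),
                }
            )
    return rows


def _adjust(table: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "per_pair":
        adj = np.full(len(table), np.nan)
        for _, idx in table.groupby(["ligand", "receptor"]).groups.items():
            adj[table.index.get_indexer(idx)] = bh_adjust(
                table.loc[idx, "p_value"].to_numpy()
            )
        table["p_adjusted"] = adj
    else:
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    return table[RESULT_COLUMNS]


def run_ccc(
    dataset: SpatialDataset,
    lr_db: LRDatabase,
    dmax: float,
    rho_candidates: list[float] | None = None,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Communication inference for every measurable LR pair in the database.

    Returns the tidy result table with one row per
    (ligand, receptor, sender type, receiver type); BH adjustment is applied
    across the whole table by default (``config.bh_scope``). Pairs whose
    genes are absent, whose response is identically zero, or whose fits all
    fail are skipped with a log entry.
    """
    config = config or FitConfig()
    rows: list[dict] = []
    unmatched: list[str] = []
    for pair in lr_db:
        try:
            res = fit_pair(dataset, pair, dmax, rho_candidates, config)
        except KeyError as err:
            logger.warning("skipping %s: %s", pair.pair_id, err)
            unmatched.append(pair.pair_id)
            continue
        except (ValueError, RuntimeError) as err:
            logger.warning("skipping %s: %s", pair.pair_id, err)
            continue
        rows.extend(_result_rows(pair, res, dataset.type_names))
    if not rows:
        raise ValueError(
            f"no measurable LR pair; unmatched pairs: {unmatched or 'none'}"
        )
    return _adjust(pd.DataFrame(rows), config.bh_scope)


def aggregate_pathway(
    dataset: SpatialDataset,
    lr_db: LRDatabase,
    pathway_label: str,
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: FitConfig | None = None,
) -> np.ndarray:
    """Pooled pathway response: elementwise sum of per-pair C_ij = L_i * R_j
    over all measurable LR pairs carrying ``pathway_label``, on the shared
    (sender, receiver) pair set."""
    config = config or FitConfig()
    sub = lr_db.subset_pathway(pathway_label)
    total = None
    n_used = 0
    for pair in sub:
        try:
            L, R = communication_scores(
                dataset.expr, dataset.gene_ids, pair, complex_rule=config.complex_rule
            )
        except KeyError as err:
            logger.warning("pathway %s: %s", pathway_label, err)
            continue
        contrib = L[pairs[0]] * R[pairs[1]]
        total = contrib if total is None else total + contrib
        n_used += 1
    if total is None:
        raise ValueError(f"pathway {pathway_label!r} has no measurable LR pair")
    logger.info("pathway %s pooled %d LR pairs", pathway_label, n_used)
    return total


def run_pathway(
    dataset: SpatialDataset,
    lr_db: LRDatabase,
    dmax: float,
    pathways: list[str] | None = None,
    rho_candidates: list[float] | None = None,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Pathway-level inference: pool LR-pair responses per pathway, then run
    the identical fit path on each pooled pseudo-pair."""
    config = config or FitConfig()
    pair_set = build_pair_set(dataset.coords, dmax, include_self=config.include_self)
    rows: list[dict] = []
    for label in pathways or lr_db.pathways():
        try:
            response = aggregate_pathway(dataset, lr_db, label, pair_set, config)
            pseudo = LRPair(
                ligand_genes=[f"pathway:{label}"],
                receptor_genes=[f"pathway:{label}"],
                pathway=label,
            )
            cands = rho_candidates
            if cands is None:
                cands = default_rho_candidates(pair_set[2])
            partition = _partition_for(dataset, config)
            res = _fit_response(
                dataset, pair_set, response, cands, partition, config
            )
        except (ValueError, RuntimeError) as err:
            logger.warning("skipping pathway %s: %s", label, err)
            continue
        rows.extend(_result_rows(pseudo, res, dataset.type_names))
    if not rows:
        raise ValueError("no pathway produced a fit")
    return _adjust(pd.DataFrame(rows), config.bh_scope)
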