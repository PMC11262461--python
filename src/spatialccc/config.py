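"""Run configuration shared by the fitting and inference layers."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["FitConfig"]


@dataclass
class FitConfig:
    """Tunable knobs of the fitting pipeline.

    Attributes
    ----------
    lambda_grid_size
        Points per axis of the log-spaced GCV grid for (lambda_L, lambda_R).
    lambda_min, lambda_max
        Grid range for the ridge smoothing parameters.
    refine_smoothing
        Run a local Nelder-Mead refinement after the grid search.
    p_grid
        Candidate Tweedie power indices profiled by series likelihood.
    p_init
        Power index used while selecting the smoothing parameters.
    tol, max_iter
        PIRLS convergence tolerance (relative deviance change) and cap.
    cov_type
        ``"bayesian"``: penalized covariance phi * (X'WX + S)^-1 (default);
        ``"sandwich"``: phi * (X'WX + S)^-1 X'WX (X'WX + S)^-1.
    complex_rule
        Subunit combination for multi-gene complexes: ``"min"`` or ``"geom"``.
    bh_scope
        ``"global"``: one BH family across the whole result table (default);
        ``"per_pair"``: adjust within each LR pair separately.
    grid_nx, grid_ny
        Spatial grid dimensions for the random-effect buckets; ``None`` picks
        a square grid targeting ~25 units per rectangle.
    include_self
        Include autocrine self pairs (distance 0).
    """

    lambda_grid_size: int = 7
    lambda_min: float = 1e-3
    lambda_max: float = 1e3
    refine_smoothing: bool = True
    p_grid: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9)
    p_init: float = 1.5
    tol: float = 1e-8
    max_iter: int = 200
    cov_type: str = "bayesian"
    complex_rule: str = "min"
    bh_scope: str = "global"
    grid_nx: int | None = None
    grid_ny: int | None = None
    include_self: bool = True
    significance_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.cov_type not in ("bayesian", "sandwich"):
            raise ValueError("cov_type must be 'bayesian' or 'sandwich'")
        if self.bh_scope not in ("global", "per_pair"):
            raise ValueError("bh_scope must be 'global' or 'per_pair'")
        if not all(1.0 < p < 2.0 for p in self.p_grid):
            raise ValueError("p_grid values must lie in (1, 2)")

    @classmethod
    def from_json(cls, path: str | Path) -> "FitConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "p_grid" in data:
            data["p_grid"] = tuple(data["p_grid"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["p_grid"] = list(self.p_grid)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
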