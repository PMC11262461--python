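# spatialccc

Inference of **cell–cell communication (CCC)** from spatially resolved
transcriptomics (SRT), for both single-cell-resolution platforms (seqFISH+,
STARmap) and spot-based platforms (10X Visium, Slide-seqV2) whose spots mix
several cell types.

Ligand–receptor signaling is mostly short-range (paracrine or autocrine), so
expression alone overstates communication between distant cells. `spatialccc`
regresses pairwise communication scores on *distance-decayed* cell-type
interaction covariates and reports a signed, FDR-controlled communication
strength for every (ligand, receptor, sender cell type, receiver cell type)
combination.

## The model

For a ligand–receptor pair *k*, the communication score from unit *i* to unit
*j* is C<sub>ij</sub> = L<sub>i</sub> · R<sub>j</sub> (ligand expression at
the sender times receptor expression at the receiver). Over all ordered unit
pairs within a maximum communication distance *d*<sub>max</sub>:

```
log E(C_ij) = β₀ + exp(−ρ·D_ij) · Σ_{g₁,g₂} β_{g₁g₂} · M_{i,g₁} · M_{j,g₂} + ν_L(i) + ν_R(j)
```

- **M** is the cell-type composition matrix: per-spot deconvolved proportions
  for spot data, one-hot labels for single-cell data. β<sub>g₁g₂</sub> is the
  communication strength from sender type g₁ to receiver type g₂ (directed:
  β<sub>g₁g₂</sub> ≠ β<sub>g₂g₁</sub>).
- **exp(−ρD)** makes expected communication decay with Euclidean distance;
  the decay rate ρ is chosen from a candidate list by AIC.
- **ν<sub>L</sub>, ν<sub>R</sub>** are sender/receiver random intercepts
  bucketed on a rectangular spatial grid (2·N<sub>grid</sub> levels instead
  of 2·N), ridge-penalized with smoothing parameters selected by generalized
  cross-validation (GCV).
- C<sub>ij</sub> is sparse-with-positive-continuous-values, modeled by the
  **compound Poisson–Gamma (Tweedie)** family with power index 1 < p < 2 and
  variance φ·μ<sup>p</sup>; p is profiled over a grid by the exact series
  likelihood and φ estimated by the Pearson estimator.

Fitting is penalized iteratively reweighted least squares (PIRLS, log link);
inference is Wald tests per coefficient with Benjamini–Hochberg adjustment
across the whole result table.

## Worked example

```python
from spatialccc import FitConfig, SimulationConfig, fit_pair, simulate_dataset

cfg = SimulationConfig(n_units=250, G=3, dmax=1.4, seed=42)  # plants β(type1→type2)=1.5, ρ=0.5
sim = simulate_dataset(cfg)
res = fit_pair(sim.dataset, sim.lr_db.pairs[0], cfg.dmax,
               rho_candidates=[0.0, 0.5, 2.0],
               config=FitConfig(lambda_grid_size=5, refine_smoothing=False),
               response=sim.scores["score"].to_numpy())
```

Running `python examples/01_simulate_and_infer.py` (which does this and then
an end-to-end run from the expression matrix) prints:

```
simulated 250 cells, 3 types, 3708 spatial pairs within dmax=1.4

[scores route] estimated communication matrix (sender x receiver):
[[0.038 1.554 0.207]
 [0.04  0.083 0.105]
 [0.135 0.153 0.168]]
planted beta(type1->type2) = 1.5, estimated +1.554; AIC-selected rho = 0.5 (true 0.5); power p = 1.5

[expression route] strongest cell of the LIGA→RECA table: type1 -> type2,
estimate +0.649, adjusted p = 5.9e-60
```

The planted channel dominates the estimated matrix; AIC recovers the
generative decay rate and the profiled power index lands on the generative
value. The second route runs the full pipeline from the expression matrix,
whose ligand/receptor values are an approximate rank-1 embedding of the
pairwise scores — the planted channel still tops the table. `examples/`
contains one short script per capability (pathway pooling, the Tweedie
emission law, network/heatmap rendering, and a shell pipeline via the
`spatialccc` CLI: `simulate`, `run`, `pathway`, `plot`).

## Inputs

| artifact | format |
|---|---|
| expression (genes × units, normalized) | MatrixMarket `.mtx` + `genes.txt`/`barcodes.txt`, or CSV |
| coordinates | CSV: `unit_id, x, y` |
| cell types | CSV `unit_id, cell_type` (single-cell) or `unit_id` + one proportion column per type (spot) |
| LR database | CSV: `ligand, receptor, pathway`; complexes as `Itga6_Itgb1` |

Results are written as a TSV with one row per
(ligand, receptor, sender type, receiver type): estimate, standard error,
p-value, BH-adjusted p-value, selected ρ and convergence flag.

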