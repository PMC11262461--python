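"""Render the communication heatmap and cell-type network for a fitted pair.

Writes heatmap.png and network.png (plus the auditable edge-list TSV) into
./example_output. Solid edges are positive communication, dashed negative;
width is proportional to |estimate|.
"""

from pathlib import Path

from spatialccc import (
    FitConfig,
    SimulationConfig,
    ccc_heatmap,
    ccc_network,
    run_ccc,
    simulate_dataset,
)

cfg = SimulationConfig(n_units=250, G=3, dmax=1.4, seed=42)
sim = simulate_dataset(cfg)
table = run_ccc(
    sim.dataset, sim.lr_db, dmax=cfg.dmax, rho_candidates=[0.5],
    config=FitConfig(lambda_grid_size=3, refine_smoothing=False),
)

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)
mat = ccc_heatmap(table, "LIGA→RECA", outdir / "heatmap.png", threshold=0.1)
edges = ccc_network(table, "LIGA→RECA", outdir / "network.png", threshold=0.1)

print("unmasked heatmap cells (significant communication):")
print(mat.to_string())
print(f"\n{len(edges)} significant edge(s):")
print(edges.to_string(index=False))
print(f"\nfigures written to {outdir}/ — the planted type1 -> type2 channel "
      "appears as the widest solid edge; weaker edges reflect signal the "
      "rank-1 expression embedding smears into neighboring type pairs.")
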