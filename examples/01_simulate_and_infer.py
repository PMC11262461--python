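"""Simulate a spatial dataset with one planted communication channel and
recover it with the full inference pipeline.

The generator plants a positive communication strength beta = 1.5 from cell
type 1 (senders) to cell type 2 (receivers), decaying with distance at rate
rho = 0.5, and draws pairwise scores from the exact Tweedie emission model.

Two routes are shown:
1. fitting the drawn pairwise scores (the model's exact ground truth) —
   this demonstrates estimation quality: the estimate lands near 1.5 and
   AIC recovers the generative decay rate;
2. the end-to-end run from the expression matrix, where ligand/receptor
   gene values are a rank-1 embedding of the scores — the embedding smears
   some signal into neighboring cells, but the planted channel still
   attains the largest estimate and smallest p-value.
"""

import numpy as np

from spatialccc import FitConfig, SimulationConfig, fit_pair, run_ccc, simulate_dataset

cfg = SimulationConfig(n_units=250, G=3, dmax=1.4, seed=42)
sim = simulate_dataset(cfg)
print(f"simulated {cfg.n_units} cells, {cfg.G} types, "
      f"{len(sim.scores)} spatial pairs within dmax={cfg.dmax}")

# --- route 1: fit the exact drawn pairwise scores -------------------------
res = fit_pair(
    sim.dataset, sim.lr_db.pairs[0], cfg.dmax,
    rho_candidates=[0.0, 0.5, 2.0],
    config=FitConfig(lambda_grid_size=5, refine_smoothing=False),
    response=sim.scores["score"].to_numpy(),
)
est = res.fit.beta.reshape(cfg.G, cfg.G)
print("\n[scores route] estimated communication matrix (sender x receiver):")
print(np.array2string(est, precision=3, suppress_small=True))
print(f"planted beta(type1->type2) = 1.5, estimated {est[0, 1]:+.3f}; "
      f"AIC-selected rho = {res.rho:g} (true {cfg.true_rho}); "
      f"power p = {res.fit.power_p:g}")

# --- route 2: end-to-end from the expression matrix -----------------------
table = run_ccc(
    sim.dataset, sim.lr_db, dmax=cfg.dmax, rho_candidates=[0.5],
    config=FitConfig(lambda_grid_size=5, refine_smoothing=False),
)
planted = table[table["ligand"] == "LIGA"]
best = planted.loc[planted["p_value"].idxmin()]
print("\n[expression route] strongest cell of the LIGA→RECA table: "
      f"{best.sender_type} -> {best.receiver_type}, "
      f"estimate {best.estimate:+.3f}, adjusted p = {best.p_adjusted:.3g}")
print("The planted type1 -> type2 channel tops the table even through the "
      "approximate expression embedding.")
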