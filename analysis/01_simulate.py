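"""Generate the synthetic study datasets all later stages consume.

Emulates the 6-treatment x 5-replicate microcosm design twice over:

* two neutrally assembled communities (distinct seeds) standing in for the
  bacterial and fungal kingdoms — drift-dominated, shared species pool;
* one variable-selection community (per-treatment trait optima) used by the
  network and biomarker stages, where deterministic selection induces
  co-occurrence structure and group-specific enrichment;
* lognormal enzyme activities with treatment effects and Dirichlet FTIR
  band areas.

Writes everything under results/data/.
"""

import sys
from pathlib import Path

from litterome import io
from litterome import simulate as sim

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

groups = list(sim.DEFAULT_GROUPS)

for kingdom, offset in (("bacteria", 0), ("fungi", 1000)):
    cfg = sim.SimulationConfig(seed=SEED + offset)  # neutral defaults: 60 taxa, 6x5, depth 5000
    tree = sim.simulate_tree(cfg.n_taxa, cfg.seed)
    table, truth = sim.simulate_communities(cfg, tree=tree)
    io.write_community(table, OUT / f"{kingdom}_community.tsv", stage="simulate", seed=cfg.seed)
    io.write_tree(tree, OUT / f"{kingdom}_tree.nwk")
    io.write_metadata(table.metadata, OUT / f"{kingdom}_metadata.csv")
    print(f"{kingdom}: {table.n_samples} samples x {table.n_taxa} taxa, "
          f"depth {int(table.sample_totals().iloc[0])}, regime={truth.regime}")

cfg_sel = sim.SimulationConfig(
    seed=SEED + 2000, assembly_regime="variable_selection", selection_strength=3.0
)
tree_sel = sim.simulate_tree(cfg_sel.n_taxa, cfg_sel.seed)
table_sel, _ = sim.simulate_communities(cfg_sel, tree=tree_sel)
io.write_community(table_sel, OUT / "selection_community.tsv", stage="simulate", seed=cfg_sel.seed)
io.write_tree(tree_sel, OUT / "selection_tree.nwk")
io.write_metadata(table_sel.metadata, OUT / "selection_metadata.csv")
print(f"selection: {table_sel.n_samples} samples x {table_sel.n_taxa} taxa "
      f"(variable selection, strength {cfg_sel.selection_strength})")

# treatment effects on enzymes: combined pollution suppresses ligninolytic
# activity and BG, echoing a co-stress scenario
effects = {
    "Np10": {"BG": 1.3, "Cx": 1.3},
    "Pb": {"laccase": 0.6, "peroxidase": 0.6},
    "Pb_Np100": {"BG": 0.7, "laccase": 0.5, "peroxidase": 0.5},
}
enzymes = sim.simulate_enzymes(groups, 5, effects=effects, seed=SEED + 3000)
io.write_csv_table(enzymes, OUT / "enzymes.csv", stage="simulate", seed=SEED + 3000)
bands = sim.simulate_bands(30, seed=SEED + 4000)
io.write_csv_table(bands, OUT / "bands.csv", stage="simulate", seed=SEED + 4000)
print(f"enzymes: {enzymes.shape[0]} samples x {enzymes.shape[1] - 1} activities; "
      f"bands: {bands.shape[0]} samples x {bands.shape[1]} bands")
print(f"all inputs under {OUT}")
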