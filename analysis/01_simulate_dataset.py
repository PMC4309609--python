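#!/usr/bin/env python
"""Generate one full synthetic dataset at the study conditions.

Writes replicate-level expression matrices with planted profile groups,
ordinal secretome bins, Dirichlet cell-wall compositions and biomass curves
to results/synthetic/, all in the same plain-text formats as the packaged
fixtures.  Seed 1 throughout; re-running reproduces the files byte for byte.
"""

import json
from pathlib import Path

import pandas as pd

from cazstarve.corpus import write_composition_csv
from cazstarve.simulate import (
    SimulationConfig,
    simulate_composition,
    simulate_expression,
    simulate_growth,
    simulate_proteome,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(seed=1)

records, replicates, mean, truth = simulate_expression(cfg)
mean.to_tsv(OUT / "expression_mean.tsv")
for i, rep in enumerate(replicates, start=1):
    rep.to_csv(OUT / f"expression_rep{i}.tsv", sep="\t", index_label="orf")
(OUT / "expression_truth.json").write_text(json.dumps(truth, indent=2) + "\n")

table = simulate_proteome(records, mean, cfg)
table.bins.to_csv(OUT / "proteome_bins.tsv", sep="\t", index_label="orf")

write_composition_csv(simulate_composition(cfg), OUT / "composition.csv")

rows = [
    {"strain": c.strain, "replicate": c.replicate, "time_h": t, "biomass_g_kg": b}
    for c in simulate_growth(cfg)
    for t, b in zip(c.times_h, c.biomass)
]
pd.DataFrame(rows).to_csv(OUT / "growth_curves.csv", index=False)

n_secreted = sum(r.signal_peptide for r in records)
print(f"wrote synthetic dataset to {OUT}")
print(f"  {len(records)} genes over {len(set(truth.values()))} planted groups,"
      f" {n_secreted} secreted")
print(f"  {len(rows)} biomass points across 3 strains x 2 replicates")
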