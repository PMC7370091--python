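#!/usr/bin/env python
"""Generate the default synthetic crossover dataset.

Emulates the motivating trial: 18 COPD patients, two walking tests (free
oronasal breathing vs nasal-restricted breathing), 19 cardioventilatory
variables on a 5-s grid from minute 1 to minute 11, with per-variable
baselines, condition effects and noise scales taken from the trial's
published summary statistics.  Writes the long CSV plus a ground-truth
sidecar with the generative mean and effect curves.
"""

import sys
from pathlib import Path

import pandas as pd

import respfanova as rf

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

cfg = rf.default_config(seed=SEED)
ds = rf.generate_dataset(cfg)
rf.write_long_csv(ds, OUT / "simulated_data.csv")

truth = rf.ground_truth(cfg)
rows = []
for name, curves in truth.items():
    for t, mu, delta in zip(cfg.grid, curves["mu"], curves["delta"]):
        rows.append({"variable": name, "time_s": t, "mu": mu, "delta": delta})
pd.DataFrame(rows).to_csv(OUT / "ground_truth.csv", index=False, float_format="%.10g")

print(f"seed {SEED}: {len(ds.subjects)} subjects x 2 conditions x "
      f"{len(ds.variables)} variables on a {ds.grid.size}-point grid")
print(f"wrote {OUT/'simulated_data.csv'} and {OUT/'ground_truth.csv'}")
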