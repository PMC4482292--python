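"""Fit a seeded subset of candidate structures by Differential Evolution.

Desk-scale version of the structure sweep: the generating structure plus
nine candidates drawn without replacement, fitted to the noiseless 500-point
dataset under the combined ERX criterion (alpha = 0.5) with an evaluation
budget of 500 per free parameter (the full-scale study budgets 20,000 per
parameter over all 126 structures).  Writes one JSON record per fit.
"""

import json
import time
from pathlib import Path

import numpy as np

from rabswitch import io
from rabswitch.criteria import CriterionConfig
from rabswitch.de_fit import DEConfig, fit_all
from rabswitch.model_space import enumerate_structures
from rabswitch.synthetic_data import default_switch_scenario, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

BUDGET_MULT = 500
MASTER_SEED = 7
SWEEP_SEED = 42

spec = default_switch_scenario(n_points=500, noise_level=0.0)
dataset, _ = generate(spec)
io.write_measurements(RESULTS / "fit_data.txt", dataset)

alls = enumerate_structures()
rng = np.random.default_rng(SWEEP_SEED)
others = [s for s in alls if s.index != spec.structure.index]
picked = [others[i] for i in rng.choice(len(others), size=9, replace=False)]
sweep = sorted(picked + [spec.structure], key=lambda s: s.index)
print(f"fitting {len(sweep)} structures: {[s.index for s in sweep]} "
      f"(truth = {spec.structure.index})")

start = time.time()
cc = CriterionConfig(criterion="ERX", alpha=0.5)
results = fit_all(sweep, dataset, cc, DEConfig(budget_mult=BUDGET_MULT, seed=MASTER_SEED))
for r in results:
    print(f"  {r.structure.label}: ERX = {r.value:.4f} "
          f"({r.evaluations} evaluations, {r.failures} failed simulations)")

payload = [
    {"structure_id": r.structure.index, "params": r.params, "value": r.value,
     "evaluations": r.evaluations, "seed": r.seed, "failures": r.failures,
     "criterion": r.criterion}
    for r in results
]
with open(RESULTS / "fits.json", "w") as fh:
    json.dump(payload, fh, indent=1)
io.write_run_metadata(
    RESULTS / "fits.meta.json",
    {"command": "03_fit_models", "budget_mult": BUDGET_MULT, "seed": MASTER_SEED,
     "sweep_seed": SWEEP_SEED, "criterion": "ERX", "alpha": 0.5,
     "structures": [s.index for s in sweep]},
)
print(f"done in {time.time() - start:.0f} s; wrote {RESULTS / 'fits.json'}")
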