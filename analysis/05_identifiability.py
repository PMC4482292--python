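"""Bootstrap practical-identifiability analysis of the generating structure.

Refits the truth structure 20 times to data re-perturbed with 10 %
proportional noise (reduced optimiser budget), then summarises per-parameter
confidence intervals, bound pile-ups and strongly correlated estimate pairs
— the signature of practically non-identifiable parameter combinations.
"""

import time
from pathlib import Path

import numpy as np

from rabswitch import io
from rabswitch.criteria import CriterionConfig
from rabswitch.de_fit import DEConfig
from rabswitch.identifiability import bootstrap_identify, summarize_identifiability
from rabswitch.synthetic_data import default_switch_scenario, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"

N_REPLICATES = 20
NOISE = 0.1
BUDGET_MULT = 100
MASTER_SEED = 11

spec = default_switch_scenario(n_points=300, noise_level=0.0)
dataset, _ = generate(spec)

start = time.time()
result = bootstrap_identify(
    spec.structure, dataset, noise_level=NOISE, n_replicates=N_REPLICATES,
    criterion_config=CriterionConfig(criterion="E"),
    de_config=DEConfig(budget_mult=BUDGET_MULT, seed=MASTER_SEED),
    master_seed=MASTER_SEED,
)
table, pairs = summarize_identifiability(result, corr_threshold=0.8)

table.to_csv(RESULTS / "identifiability_params.csv", index=False, float_format="%.6g")
np.savetxt(RESULTS / "identifiability_corr.csv", result.correlation(), delimiter=",",
           fmt="%.6g", header=",".join(result.param_names), comments="")
io.write_run_metadata(
    RESULTS / "identifiability.meta.json",
    {"command": "05_identifiability", "replicates": N_REPLICATES, "noise": NOISE,
     "budget_mult": BUDGET_MULT, "seed": MASTER_SEED,
     "structure": spec.structure.index},
)

print(f"{N_REPLICATES} replicates in {time.time() - start:.0f} s")
print(f"parameters flagged at bounds: {int(table['at_bound'].sum())} of {len(table)}")
print(f"estimate pairs with |r| > 0.8: {len(pairs)}")
for a, b, r in pairs[:8]:
    print(f"  {a} ~ {b}: r = {r:+.3f}")
print(f"wrote {RESULTS / 'identifiability_params.csv'}")
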