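"""Enumerate the candidate model space.

Writes the catalog of all 126 structures (slot choices, process counts,
parameter-space sizes) and prints the distribution of model complexity.
"""

from collections import Counter
from pathlib import Path

from rabswitch import io
from rabswitch.model_space import complexity, enumerate_structures

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

structures = enumerate_structures()
io.write_catalog(RESULTS / "catalog.csv", structures)

counts = Counter(complexity(s) for s in structures)
print(f"{len(structures)} candidate structures")
for c in sorted(counts):
    print(f"  C = {c}: {counts[c]} structures")
print(f"parameter-space sizes: {sorted({s.n_parameters for s in structures})}")
print(f"wrote {RESULTS / 'catalog.csv'}")
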