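"""Sequence curation: inclusion filtering and ortholog-family assignment.

Candidate protein sequences for an ortholog set arrive with varying
quality; the curation stage (1) globally aligns each candidate to a
reference, (2) keeps those with >= 50% identity AND >= 60% similarity,
(3) trims spurious N-terminal extensions back to the canonical start,
and (4) checks, via neighbor-joining against a multi-family paralog
panel, that each survivor clusters with the intended family.

Run:  python examples/03_curation.py
"""

import numpy as np

import codonsel as cs
from codonsel.curation import curate, curation_report
from codonsel.simulate import make_curation_fixture

# -- inclusion thresholds on planted identity/similarity ---------------------
targets = [(85.0, 92.0), (55.0, 70.0), (50.0, 60.0), (49.0, 59.0), (45.0, 75.0)]
reference, mutants = make_curation_fixture(targets, seed=7, length=100)
candidates = [rec for rec, _ in mutants]

records, kept = curate(candidates, reference)
print(curation_report(records).to_string(index=False))
print(f"\nretained {len(kept)}/{len(candidates)} candidates "
      "(thresholds: identity >= 50%, similarity >= 60%, both inclusive)\n")

# -- orthology assignment against a two-family panel --------------------------
# Build a toy panel: two diverged families, three members each.
rng = np.random.default_rng(99)
aas = list("ACDEFGHIKLMNPQRSTVWY")
fam_a_root = "M" + "".join(rng.choice(aas, size=79))
fam_b_root = "M" + "".join(rng.choice(aas, size=79))


def mutate(seq, n, rng):
    s = list(seq)
    for pos in rng.choice(np.arange(1, len(s)), size=n, replace=False):
        s[pos] = str(rng.choice(aas))
    return "".join(s)


panel = []
for i in range(3):
    panel.append(("famA", cs.ProteinRecord(f"A{i}", mutate(fam_a_root, 6, rng))))
    panel.append(("famB", cs.ProteinRecord(f"B{i}", mutate(fam_b_root, 6, rng))))

query = cs.ProteinRecord("query", mutate(fam_a_root, 10, rng))
fam = cs.assign_ortholog_group(query, panel)
print(f"query (a famA derivative) assigned to: {fam}")
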