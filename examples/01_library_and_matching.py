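"""Load the bundled torsion library and match its motifs against toy molecules.

Builds the small fixture hierarchy, validates it, and shows first-match
torsion assignment: every acyclic single bond goes to the highest-priority
SMARTS pattern that matches it, and all atom mappings on that bond are kept.
"""

import torsionprofiles as tp

lib = tp.fixture_library()
print(f"library: {len(lib)} patterns, per class: {lib.metadata['class_counts']}")

for record, expected in tp.make_toy_molecules():
    matches = tp.match_torsions(record, lib)
    print(f"\n{record.identifier}")
    for m in matches:
        print(f"  bond {m.central_bond} -> {m.pattern_id} ({len(m.mappings)} mapping(s))")
    if not matches:
        print("  no torsion motif matches")

# Filtering: drop the general fallback class and under-populated patterns.
counts = {p.pattern_id: 100 for p in lib}
kept = tp.filter_library(lib, counts, min_matches=50, drop_classes={"G-G"})
print(f"\nafter dropping G-G: {len(kept)} of {len(lib)} patterns remain")

# The printed match lines show which motif claims each rotatable bond; a
# symmetric motif reports several mappings, each contributing one angle.
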