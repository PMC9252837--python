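"""Curate a raw ATC index into the predictable level-4 dataset.

Builds a small synthetic ATC index that contains one specimen of every
pathology the curation rules exist for (a 'V' code, a drug combination, an
ambiguous structure, a structure-less entry, salts, a singleton group, an
'X' group) alongside clean records, runs the cascade and prints the audit.
"""

from pharmpred import FixtureSpec, curate, make_atc_toyset

records, expected = make_atc_toyset(FixtureSpec(seed=0))
dataset, audit = curate(records)

print(f"input records:  {audit.n_input}")
print(f"kept records:   {audit.n_output} in {len(dataset.groups)} level-4 groups")
print("removals by rule:")
for rule, n in audit.counts.items():
    print(f"  {rule:16s} {n}  (expected {expected.get(rule, 0)})")
print(f"conservation |in| = |out| + removals: {audit.check_conservation()}")

# The audit counts match the analytically planted ground truth, and the
# kept groups all have >= 2 members, no 'V' level-1 and no 'X' suffix —
# the invariants a trainable level-4 dataset must satisfy.
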