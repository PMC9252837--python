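"""Train the multi-class level-4 ATC model and predict a query.

Uses the scaffold-separable synthetic library (5 classes x 10 structures,
each class one ring scaffold with varied substituents), evaluates it by
leave-one-out cross-validation, then predicts a structure and renders the
traffic-light report.
"""

from pharmpred import (
    FixtureSpec,
    canonicalize,
    loocv,
    make_separable_library,
    predict,
    render_atc_report,
    train,
)

library = make_separable_library(FixtureSpec(seed=0))
report = loocv(library, seed=1)
print(f"LOOCV level-4 accuracy: {report.accuracy:.3f}")
print(f"LOOCV level-1 accuracy: {report.level1_accuracy:.3f}")

model = train(library, seed=1)

# a training structure: its class is both predicted and known
query = library.structures[0]
pred = predict(model, query, known_lookup=library.known_lookup())
print(f"\nquery: {query.canonical_smiles}")
for row in render_atc_report(pred):
    if row.known:
        print(f"  {row.label}  KNOWN (no score)")
    else:
        print(f"  {row.label}  p={row.probability:.3f}  [{row.color}]")

# a novel decoration of the same scaffold: predicted, not known
novel = canonicalize("c1ccc2ccccc2c1CCCCO")
pred = predict(model, novel, known_lookup=library.known_lookup())
print(f"\nnovel query: {novel.canonical_smiles}")
for row in render_atc_report(pred)[:3]:
    print(f"  {row.label}  p={row.probability:.3f}  [{row.color}]")
print("probabilities sum to", round(sum(pred.probabilities.values()), 9))

# The distribution always sums to 1: the model assumes one class per
# structure and splits 100% between the candidates; green means a
# confident single assignment.
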