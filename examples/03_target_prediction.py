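"""Bioactivity curation, per-target models and dual-score prediction.

Generates a synthetic assay table (strong binders on one scaffold,
non-binders on another, plus planted conflicts and untrusted records),
curates it into per-target binder/non-binder sets, trains the binary model
for the eligible target and predicts a query with both scores, expanding
the predicted target into its disease indications.
"""

from pharmpred import (
    FixtureSpec,
    IndicationMap,
    build_target_datasets,
    expand,
    make_assay_table,
    predict_targets,
    train_target_model,
)

activities, _ = make_assay_table(FixtureSpec(seed=0))
datasets, summary = build_target_datasets(activities)
print(f"activity records: {len(activities)}, dropped by trust filter: "
      f"{len(summary.drop_log)}")
print(f"strong relations: {summary.n_relations}, targets: {summary.n_targets}, "
      f"eligible: {summary.n_eligible_targets}")

target = next(d for d in datasets if d.eligible)
model = train_target_model(target, seed=1)
print(f"\n{model.target_id}: {model.n_binders} binders / {model.n_nonbinders} "
      f"non-binders, 10-fold CV accuracy {model.cv_accuracy:.3f}")

query = target.binders[0]
rows = predict_targets(query, [model],
                       binder_lookup={target.target_id: target.binder_smiles()})
for r in rows:
    print(f"query -> {r.target_id}: p={r.probability:.3f}, "
          f"model_accuracy={r.model_accuracy:.3f}, known_binder={r.known_binder}")

mapping = IndicationMap(rows=[
    (target.target_id, "bacterial skin infection", "synthetic"),
    (target.target_id, "urinary tract infection", "synthetic"),
])
print("\nindications (one row per target-indication pair):")
for row in expand(rows, mapping):
    print(f"  {row.target_id}  {row.indication_name}  p={row.probability:.3f}")

# Both scores travel together: the interaction probability for this query
# and the cross-validated accuracy of the model that produced it, so a
# high probability from a weak model is visible as such.
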