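# pharmpred

Fingerprint-based drug classification and ligand-based protein target
prediction for small molecules.

Given only a structure (SMILES or SDF), `pharmpred` answers two questions
medicinal chemists ask about an unknown compound:

1. **Which ATC class does it resemble?** The WHO Anatomical Therapeutic
   Chemical (ATC) system codes approved drugs hierarchically — level 1 is
   one letter (anatomical main group, e.g. `J` = antiinfectives), level 4
   five characters (chemical subgroup, e.g. `J01MA` = fluoroquinolones),
   level 5 a single substance (`J01MA24`). Predicting the level-4 group of
   a candidate hints at its therapeutic role.
2. **Which protein targets is it likely to bind?** Off-target binding
   drives side effects and repositioning opportunities alike; a ligand-based
   model trained on confirmed binders *and* confirmed non-binders gives a
   per-target interaction probability without needing a protein structure.

## Method

Structures are encoded as Morgan (circular substructure) fingerprints of
length 2048 and radius 2, computed from canonical isomeric SMILES with
RDKit, so the models key on functional groups and local substructure rather
than whole-molecule similarity.

**ATC classification.** A curated training table is built from a raw ATC
index by explicit rules: drop `V` ("various") codes, drug combinations,
structures carrying more than one ATC code, entries without a structure,
and salt records; then group by level 4 and prune singleton groups and the
structurally heterogeneous `X` ("other") groups. Every removal is logged,
and |input| = |output| + removals always holds. On the curated groups a
single multinomial logistic regression is trained; because class sizes are
wildly unequal, minority classes are randomly oversampled to the majority
size (re-drawn inside every cross-validation fold, never before
splitting). Predictions are a probability distribution that sums to 100%
across the classes — a structure that plausibly belongs to several groups
shows up as several high-probability classes. Codes already present in the
database for the exact structure (or a stereoisomer of it) are reported as
*known*, without a score.

**Target prediction.** Raw bioactivity records are reduced to trusted ones
(human assays, binding/functional type, target-mapping confidence ≥ 7,
IC50/EC50/Ki/Kd/Potency in nM, positive values, no "Outside typical range"
flag). Per (compound, target) pair: at least one activity ≤ 1000 nM with
relation `=`/`<` makes a *strong binder*; at least one ≥ 30 000 nM with
`=`/`>` makes a *non-binder*; pairs qualifying as both are conflicts and
enter neither set, so the sets stay disjoint. Targets with ≥ 20 binders and
≥ 20 non-binders each get a binary logistic-regression model, evaluated by
stratified 10-fold cross-validation. Every prediction carries **two
scores**: the interaction probability for the query and the CV accuracy of
the model that produced it. Predicted targets expand to one output row per
(target, indication) pair via a target→indication mapping table.

## Worked example

Everything runs on deterministic synthetic fixtures — no downloads. The
scripts in `examples/` are narrative versions of the three capabilities:

```bash
$ python examples/02_atc_prediction.py
LOOCV level-4 accuracy: 1.000
LOOCV level-1 accuracy: 1.000

query: COCCc1cccc2ccccc12
  J01MA  KNOWN (no score)
  J01MA  p=0.976  [green]

novel query: OCCCCc1cccc2ccccc12
  J01MA  p=0.977  [green]
probabilities sum to 1.0
```

The library here is five scaffold-defined classes of ten structures; the
model recovers every held-out structure's class (level-4 accuracy 1.000),
and a novel decoration of the naphthalene scaffold is confidently assigned
to the naphthalene class (`green` = probability ≥ 0.5). The first query is
a training structure, so its code is also reported as KNOWN, without a
probability.

```bash
$ python examples/03_target_prediction.py
activity records: 73, dropped by trust filter: 10
strong relations: 25, targets: 2, eligible: 1

T_SEP: 20 binders / 20 non-binders, 10-fold CV accuracy 1.000
query -> T_SEP: p=0.985, model_accuracy=1.000, known_binder=True
```

The same pipeline is available as a CLI (`pharmpred --help`) with
subcommands `make-fixtures`, `curate-atc`, `curate-bioactivity`,
`train-atc`, `loocv-atc`, `predict-atc`, `train-targets`,
`predict-targets` and `summarize-targets`; real WHO/ChEMBL/TTD-shaped TSV
exports can be fed to the curation commands in place of the fixtures.

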