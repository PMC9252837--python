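# Methods

## Structure handling

All identity decisions (deduplication, ambiguity, known-code lookup,
binder membership) use the RDKit canonical **isomeric** SMILES.
Stereochemistry is retained deliberately: enantiomers are different drugs
(they can carry different ATC codes), so stereoisomers must not collapse
into one record during curation. The report layer additionally performs a
second lookup on the stereo-stripped canonical form, so a query whose
stereoisomer is in the database is flagged `stereo_relative` rather than
silently treated as novel.

A record is a *salt* iff its SMILES has more than one disconnected
fragment, or it is itself a known counter-ion (configurable list). Salt
records are **dropped** during curation, not desalted: the free base is
usually present as its own record, and keeping a near-duplicate with only
the counter-ion differing would let validation see copies of training
structures. Query structures at prediction time are the one exception —
users paste salt forms, so the largest fragment is used there and the
reduction is logged.

Fingerprints are plain binary Morgan fingerprints, length 2048, radius 2
(the ECFP4-like setting the models were designed around). Bit collisions
are accepted; no count vectors.

## ATC curation

Stage order is fixed and matters: record-level rules (`V` codes →
combinations → ambiguity → missing structures → salts) run before
group-level pruning (singletons, then `X` groups). A two-member group whose
second member is a salt therefore loses the salt at the record stage and
its partner at the singleton stage — the audit shows both removals under
their own rules. Two pinned interpretation choices:

* the ambiguity census only sees records that survived the `V` and
  combination rules; a code removed for being a combination does not make
  its structure "ambiguous";
* exact duplicates (same code, same canonical structure) are merged before
  the census, so self-duplication is not ambiguity. Merges are logged under
  their own `duplicate` key so conservation stays exact.

Combination detection accepts an explicit flag from the input table and
falls back to name patterns ("… and …", "combinations", "comb.") that
mirror how combination products are named in ATC indexes.

## Binding-label semantics

Records must pass every trust predicate before pair classification
(organism, assay type B/F, confidence ≥ 7, activity type, nanomolar unit,
value > 0, no "Outside typical range" comment). The validity-comment
exclusion is applied as a record-level filter for simpler provenance; on
conflict-free data this is equivalent to excluding at the pair level.

Pair classification is deliberately conservative about relations: `<=` and
`>=` count as `<` and `>`, while `~` qualifies nothing in either
direction. A `<` on a large value is *not* evidence of non-binding, and a
`>` on a small value is *not* evidence of binding. Thresholds are
inclusive as written: 1000 nM with `=` is a strong binder, 30 000 nM with
`=` a non-binder. Conflicting pairs are excluded from both sets, which is
what makes binder/non-binder disjointness a construction invariant rather
than a post-hoc check. "Unique trusted relations" are counted as
(compound, target) pairs with a strong-binder label, not as raw records.

## Models

Both classifiers are L2-regularized logistic regressions (`C=1.0`,
`lbfgs`, `max_iter=2000` — defaults chosen for reliable convergence on
2048-bit binary inputs, all overridable). The multi-class ATC model is
multinomial: it distributes a total probability of 1 across the classes,
matching the curated dataset in which each structure carries exactly one
level-4 code. Argmax ties break lexicographically by label.

Random oversampling balances classes to the majority size by drawing
minority members uniformly with replacement; every original sample is
always retained. In every cross-validation fold (LOOCV for ATC, stratified
10-fold for targets) the oversampling is re-drawn *inside* the training
fold from a seed derived per fold via `numpy.random.SeedSequence`.
Oversampling before splitting would leak duplicates of held-out structures
into training and inflate accuracy; the per-fold choice is the leakage-safe
one and can legitimately score lower than a pre-split protocol on the same
data. 10-fold CV is stratified because unstratified folds on a 20/20
target set can be single-class, leaving fold accuracy undefined.

Level-1 accuracy is computed by truncating the level-4 prediction to its
first character. The model is optimized for level 4 only; truncation is
the only level-1 mechanism consistent with a single model, and it makes
level-1 accuracy ≥ level-4 accuracy an invariant.

Target-side class balancing (oversampling inside CV folds) is on by
default for consistency with the ATC pipeline and exposed as a switch;
eligible targets can still be imbalanced beyond the 20/20 floor.

## Reporting

Traffic-light bands are artifact choices, pinned in config: green ≥ 0.5,
yellow ≥ 0.2, red below; a query is highlighted as a multi-candidate case
when at least two classes clear the yellow band. Known codes always render
first, without score or colour — they are database facts, not predictions.
The predicted-targets table applies a display floor (default probability
≥ 0.5); machine-readable output always contains all scores.

## Synthetic data

The fixture generator emulates three properties of the real inputs:

* an ATC index containing every pathology the curation rules target, with
  analytically known removal counts (including the salt-then-singleton
  order-sensitivity case);
* compound libraries whose classes are defined by a conserved ring
  scaffold under varied substituents — the structural situation that makes
  substructure fingerprints informative. The default class scaffolds
  (naphthalene, decalin, 1,4-dioxane, 1,4-dithiane, quinuclidine) were
  chosen to be pairwise dissimilar in Morgan space, so an exhaustive
  Tanimoto nearest-neighbour search recovers the classes before any model
  is involved; substituents attach through chemistry-valid single bonds so
  every generated SMILES parses without repair;
* assay tables with planted STRONG / NON / CONFLICT / INDETERMINATE
  outcomes, one specimen of every trust-filter violation (each crafted so
  that it would flip a label if it slipped through), an eligible 20/20
  target and an ineligible 5/5 target. The conflict count is
  `round(assay_noise × (n_binders + n_nonbinders))`, default noise 0.1.

Everything is a pure function of the spec (seed included); regeneration is
byte-stable.

What passing on these fixtures does **not** show: real ATC classes are not
scaffold-pure, real bioactivity values are noisy and assay-dependent, and
real class counts are far larger (hundreds of groups, hundreds of targets).
The synthetic results validate the machinery — curation rules, label
semantics, leakage-safe evaluation, score plumbing — not the accuracy
attainable on WHO/ChEMBL-scale data. Fixture sizes (5×10 library, ~35 ATC
records, ~73 assay records, 20/20 per target, 20 permutation replicates)
are the package's chosen desk-scale study conditions; the same code paths
accept full-size tables.

## Degenerate inputs and numerical notes

* Invalid or empty SMILES raise a parse error naming the input; a
  zero-atom molecule is not a structure.
* A curation run that leaves no predictable group raises explicitly rather
  than returning an empty dataset.
* Training refuses single-class ATC datasets and ineligible targets (the
  refusal message carries the counts).
* Distributions are normalized by the multinomial model itself; the test
  suite asserts the 1e-9 normalization tolerance rather than re-normalizing.
* Determinism: identical (fixture, seed) gives byte-identical curation
  TSVs, LOOCV reports and prediction JSON; all fold/oversampling seeds
  derive from the single user seed.

## Known limitations

* Cross-toolkit canonical-SMILES equality is not guaranteed; identity is
  defined within RDKit.
* The ATC→structure mapping is taken as input; the package does not source
  structures for substances.
* "Potency" values are used as-is in nM with no standardization.
* The model-selection sweep over alternative algorithm families and
  fingerprint grids is out of scope; the pinned winner (logistic
  regression, Morgan 2048/r2) is the only trained configuration, with
  hyperparameters exposed.
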