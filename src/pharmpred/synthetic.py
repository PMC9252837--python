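"""Deterministic synthetic fixtures with analytically known ground truth.

Every pipeline stage can be exercised without any external download:

* :func:`make_atc_toyset` emits a small ATC index that triggers each
  curation rule at least once, together with the exact audit counts the
  curation must report.
* :func:`make_separable_library` builds a compound library whose classes
  are separable by construction — each class is one ring scaffold carrying
  varied substituents, so class membership is decided by a conserved
  substructure (the situation fingerprint models exploit in real data).
* :func:`make_assay_table` emits a bioactivity table covering every filter
  predicate and every binding-label outcome, with the planted labels
  returned alongside.

Everything is a pure function of the spec (seed included); regeneration is
byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atc import ATCRecord, CuratedATCDataset, parse_atc
from .bioactivity import ActivityRecord, BindingLabel
from .chem import Structure, canonicalize

__all__ = ["FixtureSpec", "make_atc_toyset", "make_separable_library", "make_assay_table"]

#: Ring scaffolds; appending a substituent SMILES bonds it to the atom that
#: closed the ring, which is valid for all of these. The first five (the
#: default class scaffolds) are pairwise dissimilar enough in Morgan space
#: that the conserved scaffold, not the substituents, decides similarity.
DEFAULT_SCAFFOLDS = (
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCC2CCCCC2C1",    # decalin
    "O1CCOCC1",          # 1,4-dioxane
    "S1CCSCC1",          # 1,4-dithiane
    "C1CN2CCC1CC2",      # quinuclidine
    "C1CCNCC1",          # piperidine
    "c1ccoc1",           # furan
    "C1CCCCC1",          # cyclohexane
)

#: Substituents valid as direct single-bond appendages to any scaffold above.
DEFAULT_DECORATIONS = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CO", "CCO", "CCCO",
    "CN", "CCN", "CCCN", "CCl", "CCCl", "CF", "CC(C)C", "C(C)C",
    "CC(C)O", "COC", "CCOC", "CS", "CCS", "C(F)(F)F", "CC#N", "CCF",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world.

    ``assay_noise`` is the proportion of deliberately conflicting
    (compound, target) pairs planted into the assay table, relative to the
    number of clean binder + non-binder pairs.
    """

    seed: int = 0
    n_classes: int = 5
    n_per_class: int = 10
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    decoration_alphabet: tuple[str, ...] = DEFAULT_DECORATIONS
    assay_noise: float = 0.1
    n_binders: int = 20
    n_nonbinders: int = 20

    def __post_init__(self) -> None:
        if len(set(self.scaffolds)) != len(self.scaffolds):
            raise ValueError("scaffolds must be pairwise distinct")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")


# level-4 labels for synthetic classes: distinct level-1 letters, no 'V',
# never ending in 'X'
_LABEL_POOL = ("J01MA", "D10AF", "A02BC", "C07AB", "L01CD", "N05BA", "R03DC", "M01AE")


def _decorated(scaffold: str, decorations: list[str]) -> list[Structure]:
    out, seen = [], set()
    for dec in decorations:
        s = canonicalize(scaffold + dec)
        if s.canonical_smiles not in seen:
            seen.add(s.canonical_smiles)
            out.append(s)
    return out


def make_separable_library(spec: FixtureSpec = FixtureSpec()) -> CuratedATCDataset:
    """Scaffold-separable compound library as a curated level-4 dataset.

    Class *k* consists of ``n_per_class`` decorations of scaffold *k*; every
    structure inside a class shares the scaffold's fingerprint bits, so a
    nearest-neighbour Tanimoto search already recovers the classes exactly.
    """
    if spec.n_classes > len(spec.scaffolds):
        raise ValueError("need at least as many scaffolds as classes")
    if spec.n_classes > len(_LABEL_POOL):
        raise ValueError(f"at most {len(_LABEL_POOL)} synthetic classes supported")
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[Structure, str]] = []
    for k in range(spec.n_classes):
        label = _LABEL_POOL[k]
        # validate scaffold early for a clear error
        canonicalize(spec.scaffolds[k])
        decs = list(spec.decoration_alphabet)
        rng.shuffle(decs)
        members = _decorated(spec.scaffolds[k], decs)[: spec.n_per_class]
        if len(members) < spec.n_per_class:
            raise ValueError(
                f"decoration alphabet too small for {spec.n_per_class} distinct "
                f"members of scaffold {spec.scaffolds[k]!r}"
            )
        for i, s in enumerate(members):
            sid = f"{label}{i + 1:02d}"
            records.append((Structure(s.input_smiles, s.canonical_smiles,
                                      s.n_fragments, id=sid), label))
    return CuratedATCDataset(records=records)


def make_atc_toyset(spec: FixtureSpec = FixtureSpec()) -> tuple[list[ATCRecord], dict[str, int]]:
    """ATC index records exercising every curation rule, plus expected counts.

    The returned dict maps rule name to the number of removals the curation
    audit must report; records not covered by any rule survive into the
    curated dataset. The fixture also plants the order-sensitivity case: a
    two-member group whose second member is a salt, so the survivor is
    removed later as a singleton.
    """
    lib = make_separable_library(
        FixtureSpec(seed=spec.seed, n_classes=min(5, spec.n_classes),
                    n_per_class=4, scaffolds=spec.scaffolds,
                    decoration_alphabet=spec.decoration_alphabet)
    )
    records: list[ATCRecord] = []
    expected = {
        "v_code": 0, "combination": 0, "ambiguous": 0, "no_structure": 0,
        "salt": 0, "singleton_group": 0, "x_group": 0,
    }

    # clean, survivable records (each label keeps all 4 members)
    for i, (s, label) in enumerate(lib.records):
        code = f"{label}{(i % 4) + 1:02d}"
        records.append(ATCRecord(atc=parse_atc(code), substance_name=f"clean-{i}",
                                 smiles=s.input_smiles))
    n_clean = len(records)

    # rule: 'V' codes (structures valid, still removed)
    records.append(ATCRecord(parse_atc("V03AB01"), "v-various-1", "CC(C)CO"))
    records.append(ATCRecord(parse_atc("V08CA02"), "v-various-2", "CC(C)CN"))
    expected["v_code"] += 2

    # rule: combinations — one via the explicit flag, one via naming
    records.append(ATCRecord(parse_atc("A02BD01"), "omeprazole, amoxicillin and metronidazole",
                             "CCCCCO"))
    records.append(ATCRecord(parse_atc("A02BD02"), "fixed combination", "CCCCCN",
                             is_combination=True))
    expected["combination"] += 2

    # rule: one structure carrying two distinct codes loses both
    records.append(ATCRecord(parse_atc("B01AC99"), "ambiguous-a", "OCCCCO"))
    records.append(ATCRecord(parse_atc("C01DA99"), "ambiguous-b", "OCCCCO"))
    expected["ambiguous"] += 2

    # rule: records without a usable structure
    records.append(ATCRecord(parse_atc("H02AB01"), "herbal extract", None))
    records.append(ATCRecord(parse_atc("H02AB02"), "bad-smiles", "C(("))
    expected["no_structure"] += 2

    # rule: salts (a pair so the group is not also a singleton)
    records.append(ATCRecord(parse_atc("S01AA01"), "sodium salt", "[Na+].CC(=O)[O-]"))
    records.append(ATCRecord(parse_atc("S01AA02"), "hydrochloride", "Cl.NCCc1ccccc1"))
    expected["salt"] += 2

    # order-sensitivity: a two-member group where one member is a salt —
    # the salt goes at the record stage, the partner becomes a singleton
    records.append(ATCRecord(parse_atc("G03CA01"), "partner", "OCC1CCCCC1O"))
    records.append(ATCRecord(parse_atc("G03CA02"), "partner-salt", "[K+].OC(=O)C1CCCCC1"))
    expected["salt"] += 1
    expected["singleton_group"] += 1

    # rule: a standalone singleton group
    records.append(ATCRecord(parse_atc("P01BA01"), "lonely", "NC1CCCCC1N"))
    expected["singleton_group"] += 1

    # rule: an 'X' level-4 group, fully populated yet excluded
    records.append(ATCRecord(parse_atc("J01MX01"), "x-group-1", "SCCCCO"))
    records.append(ATCRecord(parse_atc("J01MX02"), "x-group-2", "SCCCCN"))
    expected["x_group"] += 2

    assert len(records) == n_clean + sum(expected.values())
    return records, expected


def make_assay_table(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[list[ActivityRecord], dict[tuple[str, str], BindingLabel]]:
    """Bioactivity records with planted per-pair labels.

    Target ``T_SEP`` is the separable, eligible target: ``n_binders`` strong
    binders on one scaffold, ``n_nonbinders`` non-binders on another, plus
    ``round(assay_noise * (n_binders + n_nonbinders))`` conflicting pairs
    and two indeterminate pairs. Target ``T_SMALL`` is a deliberately
    ineligible 5/5 target. A block of records violating each trust filter is
    appended; none of them may influence any label. Expected labels are
    keyed by (target_id, compound_id).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ActivityRecord] = []
    expected: dict[tuple[str, str], BindingLabel] = {}

    def rec(cid, smiles, target, value, relation="=", organism="Homo sapiens",
            assay="B", conf=8, atype="IC50", unit="nM", comment=None):
        records.append(ActivityRecord(
            compound_id=cid, smiles=smiles, target_id=target, organism=organism,
            assay_type=assay, confidence=conf, activity_type=atype,
            relation=relation, value=float(value), unit=unit,
            validity_comment=comment,
        ))

    # enough distinct molecules: two scaffolds, decorations possibly doubled
    def molecules(scaffold: str, n: int, tag: str) -> list[tuple[str, str]]:
        decs = [d for d in spec.decoration_alphabet] + \
               [d + "C" for d in spec.decoration_alphabet]
        out, seen = [], set()
        for d in decs:
            s = canonicalize(scaffold + d)
            if s.canonical_smiles in seen:
                continue
            seen.add(s.canonical_smiles)
            out.append((f"{tag}{len(out) + 1:03d}", scaffold + d))
            if len(out) == n:
                return out
        raise ValueError("not enough distinct decorations")

    sep = "T_SEP"
    binders = molecules(spec.scaffolds[0], spec.n_binders, "BND")
    nonbinders = molecules(spec.scaffolds[1], spec.n_nonbinders, "NBD")
    for cid, smi in binders:
        rec(cid, smi, sep, rng.integers(10, 900), relation=rng.choice(["=", "<"]))
        expected[(sep, cid)] = BindingLabel.STRONG
    for cid, smi in nonbinders:
        rec(cid, smi, sep, rng.integers(35000, 90000), relation=rng.choice(["=", ">"]))
        expected[(sep, cid)] = BindingLabel.NON

    n_conflict = round(spec.assay_noise * (spec.n_binders + spec.n_nonbinders))
    conflicts = molecules(spec.scaffolds[2], n_conflict, "CFL") if n_conflict else []
    for cid, smi in conflicts:
        rec(cid, smi, sep, rng.integers(100, 900), relation="=")
        rec(cid, smi, sep, rng.integers(40000, 60000), relation="=")
        expected[(sep, cid)] = BindingLabel.CONFLICT

    for cid, smi in molecules(spec.scaffolds[3], 2, "IND"):
        rec(cid, smi, sep, rng.integers(2000, 20000), relation="=")
        expected[(sep, cid)] = BindingLabel.INDETERMINATE
    # directional-relation indeterminates: '<' on a high value, '>' on a low
    # value and '~' anywhere qualify nothing
    ind_extra = molecules(spec.scaffolds[4], 3, "INR")
    rec(*ind_extra[0], sep, 50000, relation="<")
    rec(*ind_extra[1], sep, 500, relation=">")
    rec(*ind_extra[2], sep, 500, relation="~")
    for cid, _ in ind_extra:
        expected[(sep, cid)] = BindingLabel.INDETERMINATE

    small = "T_SMALL"
    for cid, smi in molecules(spec.scaffolds[5], 5, "SB"):
        rec(cid, smi, small, rng.integers(10, 900))
        expected[(small, cid)] = BindingLabel.STRONG
    for cid, smi in molecules(spec.scaffolds[6], 5, "SN"):
        rec(cid, smi, small, rng.integers(35000, 90000))
        expected[(small, cid)] = BindingLabel.NON

    # records that must be dropped by the trust filter; each one would flip
    # or create a label if it slipped through
    nb1 = nonbinders[0]
    rec(nb1[0], nb1[1], sep, 100, organism="Rattus norvegicus")       # organism
    rec(nb1[0], nb1[1], sep, 100, assay="A")                          # assay type
    rec(nb1[0], nb1[1], sep, 100, conf=6)                             # confidence
    rec(nb1[0], nb1[1], sep, 100, atype="AC50")                       # activity type
    rec(nb1[0], nb1[1], sep, 0.1, unit="uM")                          # unit
    rec(nb1[0], nb1[1], sep, 0)                                       # zero value
    rec(nb1[0], nb1[1], sep, 100, comment="Outside typical range")    # validity
    b1 = binders[0]
    rec(b1[0], b1[1], sep, 90000, organism="Mus musculus")            # organism
    rec(b1[0], b1[1], sep, 90000, conf=0)                             # confidence
    rec(b1[0], b1[1], sep, 90000, comment="Outside typical range")    # validity

    return records, expected
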