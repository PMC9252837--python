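"""ATC code parsing and dataset curation.

The WHO Anatomical Therapeutic Chemical (ATC) system is strictly
hierarchical: level 1 is one letter (anatomical main group), level 4 five
characters (chemical subgroup, e.g. ``J01MA``), level 5 seven characters
(a single substance, e.g. ``J01MA24``). The curation here turns a raw ATC
index table into the "predictable" level-4 dataset: record-level filters
(drop 'V' codes, drug combinations, structurally ambiguous entries,
entries without a structure, salts) followed by group-level pruning
(singleton groups, heterogeneous 'X' groups). Every removal is logged so
the conservation identity |input| = |output| + removals always holds.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import Structure, canonicalize, is_salt, SmilesParseError

__all__ = [
    "ATCCode",
    "ATCRecord",
    "CuratedATCDataset",
    "AuditLog",
    "ATCValidationError",
    "EmptyDatasetError",
    "parse_atc",
    "ambiguity_key",
    "curate",
    "RULE_NAMES",
    "read_atc_table",
    "write_curated",
]

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: Stages in application order; audit counts are keyed by these names.
RULE_NAMES = (
    "v_code",          # level 1 is 'V' ("various")
    "combination",     # code denotes a combination of drugs
    "ambiguous",       # structure carries >1 distinct ATC code
    "no_structure",    # no SMILES / unparseable SMILES
    "salt",            # multi-component or counter-ion record
    "singleton_group", # level-4 group left with a single member
    "x_group",         # level-4 group ending in 'X' ("other")
)

_COMBINATION_NAME_RE = re.compile(r"(\bcombinations?\b|\band\b|\bcomb\.)", re.IGNORECASE)


class ATCValidationError(ValueError):
    pass


class EmptyDatasetError(RuntimeError):
    """Curation produced no predictable groups."""


@dataclass(frozen=True)
class ATCCode:
    """A level-5 ATC code with its five hierarchical prefixes."""

    code: str
    level1: str
    level2: str
    level3: str
    level4: str
    level5: str


def parse_atc(code: str) -> ATCCode:
    """Parse and validate a 7-character level-5 ATC code.

    >>> parse_atc("J01MA24").level4
    'J01MA'
    """
    code = code.strip()
    if not _ATC_RE.match(code):
        raise ATCValidationError(
            f"malformed ATC code {code!r}: expected 7 characters "
            "letter-digit-digit-letter-letter-digit-digit (level 5)"
        )
    return ATCCode(
        code=code,
        level1=code[:1],
        level2=code[:3],
        level3=code[:4],
        level4=code[:5],
        level5=code,
    )


@dataclass(frozen=True)
class ATCRecord:
    """One row of the ATC index: a code, its substance, optionally a SMILES."""

    atc: ATCCode
    substance_name: str
    smiles: str | None = None
    is_combination: bool = False


@dataclass
class CuratedATCDataset:
    """The predictable level-4 dataset: (structure, level-4 label) pairs."""

    records: list[tuple[Structure, str]]
    groups: dict[str, list[Structure]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            g: dict[str, list[Structure]] = defaultdict(list)
            for s, label in self.records:
                g[label].append(s)
            self.groups = dict(g)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.records]

    @property
    def structures(self) -> list[Structure]:
        return [s for s, _ in self.records]

    def known_lookup(self) -> dict[str, list[str]]:
        """canonical SMILES → level-4 labels present in the dataset."""
        out: dict[str, list[str]] = defaultdict(list)
        for s, label in self.records:
            if label not in out[s.canonical_smiles]:
                out[s.canonical_smiles].append(label)
        return dict(out)


@dataclass
class AuditLog:
    """Per-rule removal trail, in rule application order."""

    n_input: int = 0
    n_output: int = 0
    removals: list[tuple[str, str, str]] = field(default_factory=list)  # (rule, code, reason)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(rule for rule, _, _ in self.removals)
        out = {rule: c.get(rule, 0) for rule in RULE_NAMES}
        for rule in c:  # e.g. merged exact duplicates
            out.setdefault(rule, c[rule])
        return out

    @property
    def n_removed(self) -> int:
        return len(self.removals)

    def check_conservation(self) -> bool:
        return self.n_input == self.n_output + self.n_removed


def ambiguity_key(structure: Structure) -> str:
    """Identity key used to decide when two records are "the same structure".

    Canonical isomeric SMILES: stereoisomers get *different* keys, so an
    enantiomer pair never triggers ambiguity removal of each other's codes.
    """
    return structure.canonical_smiles


def is_combination_record(rec: ATCRecord) -> bool:
    """A record is a combination if flagged, or its name follows the WHO
    "X and Y" / "..., combinations" naming conventions."""
    if rec.is_combination:
        return True
    return bool(_COMBINATION_NAME_RE.search(rec.substance_name))


def curate(records: list[ATCRecord]) -> tuple[CuratedATCDataset, AuditLog]:
    """Apply the full curation cascade to a raw ATC record list.

    Stage order is fixed: 'V' codes → combinations → ambiguous structures →
    records without structures → salts → (group stage) singleton groups →
    'X' groups. The ambiguity stage only sees records that survived the
    first two stages, and exact duplicates under the same code are merged
    beforehand so self-duplication does not read as ambiguity.

    Returns the curated dataset plus an :class:`AuditLog` satisfying
    ``n_input == n_output + n_removed``.
    """
    log = AuditLog(n_input=len(records))

    def drop(rule: str, rec: ATCRecord, reason: str) -> None:
        log.removals.append((rule, rec.atc.code, reason))

    # Stage 1: 'V' ("various") codes.
    survivors: list[ATCRecord] = []
    for rec in records:
        if rec.atc.level1 == "V":
            drop("v_code", rec, "level 1 group 'V' (various)")
        else:
            survivors.append(rec)

    # Stage 2: combination products.
    stage2: list[ATCRecord] = []
    for rec in survivors:
        if is_combination_record(rec):
            drop("combination", rec, f"combination product: {rec.substance_name!r}")
        else:
            stage2.append(rec)

    # Parse structures once; records whose SMILES fails to parse are treated
    # as structure-less (they cannot be fingerprinted either way).
    parsed: dict[int, Structure | None] = {}
    for i, rec in enumerate(stage2):
        if rec.smiles is None or not rec.smiles.strip():
            parsed[i] = None
            continue
        try:
            parsed[i] = canonicalize(rec.smiles, id=rec.atc.code)
        except SmilesParseError:
            parsed[i] = None

    # Merge exact duplicates (same code, same structure key) before the
    # ambiguity census.
    seen: set[tuple[str, str | None]] = set()
    deduped: list[tuple[ATCRecord, Structure | None]] = []
    for i, rec in enumerate(stage2):
        s = parsed[i]
        key = (rec.atc.code, ambiguity_key(s) if s is not None else None)
        if key in seen:
            continue
        seen.add(key)
        deduped.append((rec, s))

    # Stage 3: structures associated with >1 distinct ATC code lose all
    # their codes. Only structure-bearing records can be ambiguous.
    codes_per_structure: dict[str, set[str]] = defaultdict(set)
    for rec, s in deduped:
        if s is not None:
            codes_per_structure[ambiguity_key(s)].add(rec.atc.code)
    ambiguous_keys = {k for k, codes in codes_per_structure.items() if len(codes) > 1}

    stage3: list[tuple[ATCRecord, Structure | None]] = []
    for rec, s in deduped:
        if s is not None and ambiguity_key(s) in ambiguous_keys:
            drop("ambiguous", rec, "structure maps to multiple ATC codes")
        else:
            stage3.append((rec, s))

    # Stage 4: records without a usable structure.
    stage4: list[tuple[ATCRecord, Structure]] = []
    for rec, s in stage3:
        if s is None:
            drop("no_structure", rec, "no SMILES / unparseable structure")
        else:
            stage4.append((rec, s))

    # Stage 5: salts.
    stage5: list[tuple[ATCRecord, Structure]] = []
    for rec, s in stage4:
        if is_salt(s):
            drop("salt", rec, "salt / multi-component record")
        else:
            stage5.append((rec, s))

    # Group stage: group by level 4, prune singletons, then 'X' groups.
    groups: dict[str, list[tuple[ATCRecord, Structure]]] = defaultdict(list)
    for rec, s in stage5:
        groups[rec.atc.level4].append((rec, s))

    kept: list[tuple[Structure, str]] = []
    for label in sorted(groups):
        members = groups[label]
        if len(members) < 2:
            for rec, _ in members:
                drop("singleton_group", rec, f"level-4 group {label} has one member")
            continue
        if label.endswith("X"):
            for rec, _ in members:
                drop("x_group", rec, f"level-4 group {label} is an 'X' (other) group")
            continue
        for rec, s in members:
            kept.append((s, label))

    log.n_output = len(kept)
    # Duplicates merged pre-ambiguity are neither output nor removals;
    # account for them so conservation holds.
    n_merged = len(stage2) - len(deduped)
    if n_merged:
        for _ in range(n_merged):
            log.removals.append(("duplicate", "", "exact duplicate of same code+structure"))

    if not kept:
        raise EmptyDatasetError("curation produced no predictable level-4 groups")
    return CuratedATCDataset(records=kept), log


# ---------------------------------------------------------------------------
# TSV I/O

def read_atc_table(path: str | Path) -> list[ATCRecord]:
    """Read an ATC index TSV: columns atc_code, name, smiles, is_combination."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        smiles = row.get("smiles", "") or None
        combo = str(row.get("is_combination", "0")).strip() in {"1", "true", "True"}
        records.append(
            ATCRecord(
                atc=parse_atc(row["atc_code"]),
                substance_name=row.get("name", ""),
                smiles=smiles,
                is_combination=combo,
            )
        )
    return records


def write_curated(dataset: CuratedATCDataset, log: AuditLog, out_dir: str | Path) -> None:
    """Write dataset TSV (canonical_smiles, level4_label) and audit TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(s.canonical_smiles, label) for s, label in dataset.records],
        columns=["canonical_smiles", "level4_label"],
    ).to_csv(out / "atc_dataset.tsv", sep="\t", index=False)
    pd.DataFrame(log.removals, columns=["rule", "atc_code", "reason"]).to_csv(
        out / "atc_audit.tsv", sep="\t", index=False
    )
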