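"""Bioactivity curation: trusted activities and binder / non-binder sets.

Raw assay tables (ChEMBL-style flat exports) are first reduced to trusted
records — human assays, binding (B) or functional (F) type, target-mapping
confidence >= 7, activity type in {IC50, EC50, Ki, Kd, Potency}, nanomolar
units, positive values, no "Outside typical range" flag — and then each
(compound, target) pair is classified:

* STRONG binder: at least one activity <= 1000 nM with relation '=' or '<',
  and no non-binding qualification;
* NON-binder: at least one activity >= 30000 nM with relation '=' or '>',
  and no binding qualification;
* CONFLICT: both qualifications present (the pair is excluded from both
  sets, which keeps binder and non-binder sets disjoint by construction);
* INDETERMINATE: neither.

A target becomes *eligible* for model training once it has at least 20
strong binders and 20 non-binders.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import Structure, canonicalize, SmilesParseError

__all__ = [
    "ActivityRecord",
    "BindingLabel",
    "CurationThresholds",
    "TargetDataset",
    "CurationSummary",
    "filter_activities",
    "classify_pair",
    "build_target_datasets",
    "read_activity_table",
    "write_target_datasets",
]


class BindingLabel(enum.Enum):
    STRONG = "STRONG"
    NON = "NON"
    INDETERMINATE = "INDETERMINATE"
    CONFLICT = "CONFLICT"


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement with every attribute the filter touches."""

    compound_id: str
    smiles: str
    target_id: str
    organism: str
    assay_type: str
    confidence: int
    activity_type: str
    relation: str  # one of = < > <= >= ~
    value: float
    unit: str
    validity_comment: str | None = None


@dataclass(frozen=True)
class CurationThresholds:
    """All cutoffs of the curation, with the published defaults."""

    strong_max_nm: float = 1000.0
    non_min_nm: float = 30000.0
    min_confidence: int = 7
    allowed_assay_types: frozenset[str] = frozenset({"B", "F"})
    allowed_activity_types: frozenset[str] = frozenset(
        {"IC50", "EC50", "Ki", "Kd", "Potency"}
    )
    organism: str = "Homo sapiens"
    min_binders: int = 20
    min_nonbinders: int = 20

    def __post_init__(self) -> None:
        if self.strong_max_nm >= self.non_min_nm:
            raise ValueError("strong_max_nm must be below non_min_nm")


@dataclass
class TargetDataset:
    """Disjoint strong-binder / non-binder structure sets for one target."""

    target_id: str
    binders: list[Structure]
    nonbinders: list[Structure]
    min_binders: int = 20
    min_nonbinders: int = 20

    @property
    def eligible(self) -> bool:
        return (
            len(self.binders) >= self.min_binders
            and len(self.nonbinders) >= self.min_nonbinders
        )

    def binder_smiles(self) -> set[str]:
        return {s.canonical_smiles for s in self.binders}


@dataclass
class CurationSummary:
    n_relations: int
    n_binder_structures: int
    n_targets: int
    n_eligible_targets: int
    drop_log: list[tuple[ActivityRecord, str]] = field(default_factory=list)


# nanomolar unit spellings accepted (the literature writes both nM and nm)
_NM_UNITS = {"nM", "nm", "NM"}
_EXCLUDED_COMMENT = "Outside typical range"


def _failed_predicate(rec: ActivityRecord, t: CurationThresholds) -> str | None:
    """Name of the first predicate the record fails, or None if trusted."""
    if rec.organism != t.organism:
        return "organism"
    if rec.assay_type not in t.allowed_assay_types:
        return "assay_type"
    if rec.confidence < t.min_confidence:
        return "confidence"
    if rec.activity_type not in t.allowed_activity_types:
        return "activity_type"
    if rec.unit not in _NM_UNITS:
        return "unit"
    if not rec.value > 0:
        return "zero_value"
    if rec.validity_comment == _EXCLUDED_COMMENT:
        return "validity_comment"
    return None


def filter_activities(
    records: list[ActivityRecord],
    t: CurationThresholds = CurationThresholds(),
    drop_log: list[tuple[ActivityRecord, str]] | None = None,
) -> list[ActivityRecord]:
    """Keep trusted records only; each drop is logged with its failed predicate."""
    kept = []
    for rec in records:
        why = _failed_predicate(rec, t)
        if why is None:
            kept.append(rec)
        elif drop_log is not None:
            drop_log.append((rec, why))
    return kept


def classify_pair(
    activities: list[ActivityRecord], t: CurationThresholds = CurationThresholds()
) -> BindingLabel:
    """Classify one (compound, target) pair from its trusted activities.

    Relations '<=' and '>=' count as '<' and '>'; '~' qualifies nothing.
    Threshold values are inclusive: 1000 nM with '=' is a strong binder,
    30000 nM with '=' is a non-binder.
    """
    if not activities:
        raise ValueError("classify_pair requires at least one activity record")
    strong = any(
        rec.value <= t.strong_max_nm and rec.relation in ("=", "<", "<=")
        for rec in activities
    )
    non = any(
        rec.value >= t.non_min_nm and rec.relation in ("=", ">", ">=")
        for rec in activities
    )
    if strong and non:
        return BindingLabel.CONFLICT
    if strong:
        return BindingLabel.STRONG
    if non:
        return BindingLabel.NON
    return BindingLabel.INDETERMINATE


def build_target_datasets(
    activities: list[ActivityRecord],
    t: CurationThresholds = CurationThresholds(),
    prefiltered: bool = False,
) -> tuple[list[TargetDataset], CurationSummary]:
    """Group trusted activities into per-target binder / non-binder sets.

    Compound identity within a target is the canonical SMILES; records whose
    SMILES does not parse are dropped and logged. Pairs labelled CONFLICT or
    INDETERMINATE enter neither set, so binders and non-binders are disjoint
    for every target.
    """
    drop_log: list[tuple[ActivityRecord, str]] = []
    trusted = activities if prefiltered else filter_activities(activities, t, drop_log)

    pairs: dict[tuple[str, str], list[ActivityRecord]] = defaultdict(list)
    structures: dict[str, Structure] = {}
    for rec in trusted:
        if rec.smiles not in structures:
            try:
                structures[rec.smiles] = canonicalize(rec.smiles, id=rec.compound_id)
            except SmilesParseError:
                drop_log.append((rec, "unparseable_smiles"))
                continue
        key = (rec.target_id, structures[rec.smiles].canonical_smiles)
        pairs[key].append(rec)

    by_target: dict[str, dict[str, list[Structure]]] = defaultdict(
        lambda: {"binders": [], "nonbinders": []}
    )
    n_strong_pairs = 0
    binder_structures: set[str] = set()
    targets_seen: set[str] = set()
    for (target_id, canon), recs in sorted(pairs.items()):
        targets_seen.add(target_id)
        label = classify_pair(recs, t)
        structure = canonicalize(canon)
        if label is BindingLabel.STRONG:
            by_target[target_id]["binders"].append(structure)
            n_strong_pairs += 1
            binder_structures.add(canon)
        elif label is BindingLabel.NON:
            by_target[target_id]["nonbinders"].append(structure)

    datasets = [
        TargetDataset(
            target_id=tid,
            binders=by_target[tid]["binders"],
            nonbinders=by_target[tid]["nonbinders"],
            min_binders=t.min_binders,
            min_nonbinders=t.min_nonbinders,
        )
        for tid in sorted(targets_seen)
    ]
    summary = CurationSummary(
        n_relations=n_strong_pairs,
        n_binder_structures=len(binder_structures),
        n_targets=len(targets_seen),
        n_eligible_targets=sum(d.eligible for d in datasets),
        drop_log=drop_log,
    )
    return datasets, summary


# ---------------------------------------------------------------------------
# TSV I/O

_DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "organism": "organism",
    "assay_type": "assay_type",
    "confidence": "confidence",
    "activity_type": "activity_type",
    "relation": "relation",
    "value": "value",
    "unit": "unit",
    "validity_comment": "validity_comment",
}


def read_activity_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[ActivityRecord]:
    """Read an activity TSV. ``column_map`` maps our field names to the
    file's column names so real database exports can be fed in unchanged."""
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        comment = row.get(cols["validity_comment"], "") or None
        records.append(
            ActivityRecord(
                compound_id=row[cols["compound_id"]],
                smiles=row[cols["smiles"]],
                target_id=row[cols["target_id"]],
                organism=row[cols["organism"]],
                assay_type=row[cols["assay_type"]],
                confidence=int(row[cols["confidence"]]),
                activity_type=row[cols["activity_type"]],
                relation=row[cols["relation"]],
                value=float(row[cols["value"]]),
                unit=row[cols["unit"]],
                validity_comment=comment,
            )
        )
    return records


def write_target_datasets(
    datasets: list[TargetDataset], summary: CurationSummary, out_dir: str | Path
) -> None:
    """Per-target binder/non-binder TSVs plus a summary TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in datasets:
        rows.append((d.target_id, len(d.binders), len(d.nonbinders), int(d.eligible)))
        pd.DataFrame(
            [(s.canonical_smiles, "binder") for s in d.binders]
            + [(s.canonical_smiles, "nonbinder") for s in d.nonbinders],
            columns=["canonical_smiles", "role"],
        ).to_csv(out / f"target_{d.target_id}.tsv", sep="\t", index=False)
    pd.DataFrame(
        rows, columns=["target_id", "n_binders", "n_nonbinders", "eligible"]
    ).to_csv(out / "target_summary.tsv", sep="\t", index=False)
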