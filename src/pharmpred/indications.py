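"""Target-to-indication expansion.

Predicted targets are joined against a pre-resolved target→indication
mapping table (the shape a Therapeutic Target Database export reduces to).
Each (target, indication) pair becomes its own output row so the table can
be searched by indication across targets; prediction scores pass through
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .target_models import TargetPrediction

__all__ = ["IndicationMap", "IndicationRow", "expand", "read_indication_map"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndicationRow:
    target_id: str
    indication_name: str
    probability: float
    model_accuracy: float


@dataclass
class IndicationMap:
    """Rows of (target_id, indication_name, source_annotation), deduplicated."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique = []
        for tid, name, src in self.rows:
            if (tid, name) not in seen:
                seen.add((tid, name))
                unique.append((tid, name, src))
        self.rows = unique

    def indications_for(self, target_id: str) -> list[str]:
        return [name for tid, name, _ in self.rows if tid == target_id]


def expand(
    predictions: list[TargetPrediction], mapping: IndicationMap
) -> list[IndicationRow]:
    """One row per (predicted target, indication).

    Targets without a mapping contribute zero rows (logged). Output is
    ordered by probability descending, then indication name.
    """
    if not predictions:
        raise ValueError("expand requires at least one prediction")
    out: list[IndicationRow] = []
    for pred in predictions:
        names = mapping.indications_for(pred.target_id)
        if not names:
            log.info("target %s has no indication mapping", pred.target_id)
            continue
        for name in sorted(names):
            out.append(
                IndicationRow(
                    target_id=pred.target_id,
                    indication_name=name,
                    probability=pred.probability,
                    model_accuracy=pred.model_accuracy,
                )
            )
    return sorted(out, key=lambda r: (-r.probability, r.indication_name))


def read_indication_map(path: str | Path) -> IndicationMap:
    """Load a mapping TSV with columns target_id, indication
    (optionally source_annotation)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = [
        (row["target_id"], row["indication"], row.get("source_annotation", ""))
        for _, row in df.iterrows()
    ]
    return IndicationMap(rows=rows)
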