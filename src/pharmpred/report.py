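"""Traffic-light report rendering for ATC and target predictions.

Known codes come first and carry no colour or score — they are database
facts, not predictions. Predicted codes are banded green / yellow / red by
probability, and a query is flagged as a multi-candidate case when at
least two classes clear the yellow band (the signature of a structure that
plausibly belongs to several groups).
"""

from __future__ import annotations

from dataclasses import dataclass

from .atc_model import ATCPrediction

__all__ = ["ColorBands", "ReportRow", "render_atc_report"]


@dataclass(frozen=True)
class ColorBands:
    """Probability cutoffs for the traffic-light colours (artifact defaults;
    green: confident single assignment, yellow: plausible candidate)."""

    green: float = 0.5
    yellow: float = 0.2

    def color(self, p: float) -> str:
        if p >= self.green:
            return "green"
        if p >= self.yellow:
            return "yellow"
        return "red"


@dataclass(frozen=True)
class ReportRow:
    label: str
    probability: float | None
    color: str | None
    known: bool
    highlight_multi: bool
    stereo_relative: bool = False


def render_atc_report(
    prediction: ATCPrediction,
    bands: ColorBands = ColorBands(),
    min_probability: float = 0.01,
) -> list[ReportRow]:
    """Render a prediction into report rows.

    Known rows first (no score, no colour), then the stereoisomer-known
    rows, then predicted classes above ``min_probability`` sorted by
    probability. Rendering is pure: same prediction and bands, same rows.
    """
    rows: list[ReportRow] = []
    n_candidates = sum(
        1 for p in prediction.probabilities.values() if p >= bands.yellow
    )
    multi = n_candidates >= 2
    for label in prediction.known_codes:
        rows.append(ReportRow(label, None, None, known=True, highlight_multi=False))
    for label in prediction.stereo_relative_codes:
        rows.append(ReportRow(label, None, None, known=True, highlight_multi=False,
                              stereo_relative=True))
    ranked = sorted(prediction.probabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    for label, p in ranked:
        if p < min_probability:
            continue
        rows.append(
            ReportRow(label, p, bands.color(p), known=False, highlight_multi=multi)
        )
    return rows
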