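"""Composite early-warning value (EWV) and five-grade classification.

The EWV of one region-year is the weighted sum P_i = sum_j w_j * y_ij of
its normalized indicator values; with weights summing to 1 and y in [0, 1]
the index lies in [0, 1], higher = safer. The five ecological safety levels
partition [0, 1) into half-open bands, lower bound inclusive:

    [0.0, 0.2)  I    Huge alarm
    [0.2, 0.4)  II   Moderate warning
    [0.4, 0.6)  III  Light warning
    [0.6, 0.8)  IV   Good
    [0.8, 1.0)  V    Excellent

Values at or above 1.0 clamp to grade V and values below 0 to grade I with a
logged warning — grey-model forecasts of a growing index can leave [0, 1].

Subsystem subscores use the type weights (renormalized within each PESN
subsystem), so each subscore also lies in [0, 1]; weighting the subscores by
their subsystem's share of comprehensive weight recomposes the EWV exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import CoverageError
from .panel import NormalizedPanel
from .registry import SUBSYSTEMS
from .weights import WeightTable

logger = logging.getLogger(__name__)

GRADE_BOUNDS = (0.2, 0.4, 0.6, 0.8)
GRADES = ("I", "II", "III", "IV", "V")
STATUS_LABELS = {
    "I": "Huge alarm",
    "II": "Moderate warning",
    "III": "Light warning",
    "IV": "Good",
    "V": "Excellent",
}


def classify_grade(value: float) -> tuple[str, str]:
    """Map an early-warning value onto its (grade, status label)."""
    if not math.isfinite(value):
        raise ValueError(f"cannot grade non-finite value {value!r}")
    if value < 0.0:
        logger.warning("value %.4f below 0; clamping to grade I", value)
        return "I", STATUS_LABELS["I"]
    if value >= 1.0:
        if value > 1.0:
            logger.warning("value %.4f above 1; clamping to grade V", value)
        return "V", STATUS_LABELS["V"]
    for bound, grade in zip(GRADE_BOUNDS, GRADES):
        if value < bound:
            return grade, STATUS_LABELS[grade]
    return "V", STATUS_LABELS["V"]


@dataclass
class EarlyWarningSeries:
    """Composite index, grade and subsystem subscores of one region over years."""

    region: str
    table: pd.DataFrame  # indexed by year; columns ewv, grade, status, p/e/s/n_score

    @property
    def years(self) -> list[int]:
        return list(self.table.index)

    @property
    def ewv(self) -> pd.Series:
        return self.table["ewv"]


def compute_ews(panel: NormalizedPanel, weights: WeightTable) -> list[EarlyWarningSeries]:
    """Score every region-year of a normalized panel under a weight table."""
    panel_codes = set(panel.indicators)
    weight_codes = set(weights.indicators)
    if weight_codes - panel_codes:
        raise CoverageError(f"weights cover indicators absent from panel: {sorted(weight_codes - panel_codes)}")
    if panel_codes - weight_codes:
        raise CoverageError(f"panel has unweighted indicators: {sorted(panel_codes - weight_codes)}")

    data = panel.data[weights.indicators]
    w = weights.comprehensive()
    ewv = data @ w

    scores = {}
    for sub in SUBSYSTEMS:
        tw = weights.type_weights(sub)
        scores[f"{sub.lower()}_score"] = data[tw.index] @ tw if len(tw) else pd.Series(0.0, index=data.index)

    out = []
    for region, group in data.groupby(level="region", sort=False):
        idx = group.index
        years = idx.get_level_values("year")
        graded = [classify_grade(v) for v in ewv.loc[idx]]
        table = pd.DataFrame(
            {
                "ewv": ewv.loc[idx].to_numpy(),
                "grade": [g for g, _ in graded],
                "status": [s for _, s in graded],
                **{k: v.loc[idx].to_numpy() for k, v in scores.items()},
            },
            index=pd.Index(years, name="year"),
        )
        out.append(EarlyWarningSeries(region=str(region), table=table))
    return out


def series_frame(series: list[EarlyWarningSeries]) -> pd.DataFrame:
    """Concatenate per-region series into one long frame for CSV output."""
    frames = []
    for s in series:
        block = s.table.reset_index()
        block.insert(0, "region", s.region)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def write_ews_csv(series: list[EarlyWarningSeries], path: str | Path) -> None:
    series_frame(series).to_csv(path, index=False)
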