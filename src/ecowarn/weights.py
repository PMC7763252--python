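"""Entropy weighting of normalized indicators.

The weight of an indicator is proportional to its information content: an
indicator whose normalized values are nearly uniform across the m pooled
observations carries entropy close to 1 and thus almost no weight, while a
dispersed indicator carries more. For indicator j with normalized column
y_ij over observations i = 1..m:

    f_ij = y_ij / sum_i y_ij            (relative frequencies)
    e_j  = -(1/ln m) * sum_i f_ij ln f_ij
    b_j  = 1 - e_j                      (difference coefficient)
    w_j  = b_j / sum_k b_k              (comprehensive weight)

Any f_ij that is exactly zero is replaced by 1e-4 before the entropy sum —
a fixed substitution, applied without renormalizing the vector; the induced
deviation of sum(f) from 1 is at most (number of zeros)·1e-4 and is logged.
Type weights renormalize the comprehensive weights within each PESN
subsystem, so each subsystem's type weights sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateColumnError, ZeroInformationError
from .panel import NormalizedPanel
from .registry import IndicatorRegistry

logger = logging.getLogger(__name__)

ZERO_FREQUENCY_SUBSTITUTE = 1e-4

WEIGHT_COLUMNS = ["subsystem", "entropy", "difference_coefficient", "comprehensive_weight", "type_weight"]


@dataclass
class WeightTable:
    """Per-indicator entropy, difference coefficient and weights."""

    data: pd.DataFrame  # indexed by indicator code, columns WEIGHT_COLUMNS

    def __post_init__(self) -> None:
        missing = set(WEIGHT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"weight table lacks columns: {sorted(missing)}")
        w = self.data["comprehensive_weight"]
        if (w < -1e-12).any():
            raise ValueError("comprehensive weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"comprehensive weights sum to {w.sum():.8f}, not 1")

    @property
    def indicators(self) -> list[str]:
        return list(self.data.index)

    def comprehensive(self) -> pd.Series:
        return self.data["comprehensive_weight"]

    def type_weights(self, subsystem: str) -> pd.Series:
        block = self.data[self.data["subsystem"] == subsystem]
        return block["type_weight"]

    def subsystem_share(self, subsystem: str) -> float:
        """Total comprehensive weight carried by one subsystem."""
        return float(
            self.data.loc[self.data["subsystem"] == subsystem, "comprehensive_weight"].sum()
        )

    def write_csv(self, path: str | Path) -> None:
        out = self.data.reset_index().rename(columns={"index": "indicator"})
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "WeightTable":
        frame = pd.read_csv(path).set_index("indicator")
        return cls(frame)

    @classmethod
    def from_fixed(cls, comprehensive: pd.Series, subsystems: pd.Series) -> "WeightTable":
        """Build a table from externally given comprehensive weights.

        Used to score observations under frozen (e.g. published) weights;
        entropies are unknown and set to NaN. The given weights are
        renormalized to sum exactly to 1 (published tables are rounded).
        """
        w = comprehensive / comprehensive.sum()
        sub_sum = w.groupby(subsystems).transform("sum")
        frame = pd.DataFrame(
            {
                "subsystem": subsystems,
                "entropy": np.nan,
                "difference_coefficient": np.nan,
                "comprehensive_weight": w,
                "type_weight": w / sub_sum,
            }
        )
        return cls(frame)


def relative_frequencies(column: np.ndarray) -> np.ndarray:
    """Proportional shares f_ij of one normalized column, with zero substitution.

    Zero entries become exactly 1e-4 *after* the division, without
    renormalizing, so the output may sum to slightly more than 1.
    """
    col = np.asarray(column, dtype=float)
    if (col < 0).any():
        raise ValueError("normalized column must be non-negative")
    total = col.sum()
    if total == 0:
        raise DegenerateColumnError("all-zero normalized column")
    freq = col / total
    n_zero = int((freq == 0).sum())
    if n_zero:
        logger.debug(
            "substituting %d zero frequencies by %.0e (sum deviates from 1 by <= %.1e)",
            n_zero, ZERO_FREQUENCY_SUBSTITUTE, n_zero * ZERO_FREQUENCY_SUBSTITUTE,
        )
        freq = np.where(freq == 0, ZERO_FREQUENCY_SUBSTITUTE, freq)
    return freq


def indicator_entropy(frequencies: np.ndarray, m: int | None = None) -> float:
    """Normalized Shannon entropy -(1/ln m) * sum f ln f of one column.

    Equals 1 for the uniform vector and approaches 0 as the mass concentrates
    on a single observation. ``m`` defaults to the vector length.
    """
    freq = np.asarray(frequencies, dtype=float)
    if m is None:
        m = len(freq)
    if m < 2:
        raise ValueError("entropy needs at least 2 observations")
    if (freq <= 0).any():
        raise ValueError("frequencies must be strictly positive (substitute zeros first)")
    return float(-(freq * np.log(freq)).sum() / np.log(m))


def compute_weights(panel: NormalizedPanel, registry: IndicatorRegistry) -> WeightTable:
    """Entropy-weight every registry indicator from a normalized panel."""
    missing = set(registry.codes) - set(panel.indicators)
    if missing:
        raise CoverageError(f"panel lacks indicators: {sorted(missing)}")
    data = panel.data[registry.codes]
    m = len(data)
    if m < 2:
        raise ValueError("need at least 2 observations to weight indicators")

    entropies = {}
    for code in registry.codes:
        freq = relative_frequencies(data[code].to_numpy())
        entropies[code] = indicator_entropy(freq, m)
    e = pd.Series(entropies)
    b = 1.0 - e
    if b.sum() <= 0:
        raise ZeroInformationError("every indicator has unit entropy; weights undefined")
    w = b / b.sum()

    subsystems = pd.Series({c: registry.subsystem(c) for c in registry.codes})
    sub_sum = w.groupby(subsystems).transform("sum")
    frame = pd.DataFrame(
        {
            "subsystem": subsystems,
            "entropy": e,
            "difference_coefficient": b,
            "comprehensive_weight": w,
            "type_weight": w / sub_sum,
        }
    ).loc[registry.codes]
    return WeightTable(frame)
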