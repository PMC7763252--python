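"""Entropy weights and composite early-warning index on the synthetic panel.

Normalizes the stage-01 panel (direction-aware min-max, pooled over all
region-years), computes entropy weights, scores every region-year and
classifies it into the five safety grades. Writes the weight table and the
graded index series.
"""

from pathlib import Path

from ecowarn import (
    compute_ews,
    compute_weights,
    default_registry,
    normalize_panel,
    read_panel,
)
from ecowarn.index import write_ews_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    registry = default_registry()
    panel = read_panel(RESULTS / "synthetic_panel.csv", registry)
    normalized = normalize_panel(panel, registry)
    weights = compute_weights(normalized, registry)
    weights.write_csv(RESULTS / "synthetic_weights.csv")
    series = compute_ews(normalized, weights)
    write_ews_csv(series, RESULTS / "synthetic_ewv_grades.csv")

    print(f"comprehensive weights sum: {weights.comprehensive().sum():.9f}")
    top = weights.comprehensive().nlargest(3)
    print("three most informative indicators:")
    for code, w in top.items():
        print(f"  {code}: {w:.4f}")
    for s in series:
        first, last = s.table.iloc[0], s.table.iloc[-1]
        print(
            f"  {s.region}: {first.ewv:.4f} ({first.grade}) -> {last.ewv:.4f} ({last.grade})"
        )


if __name__ == "__main__":
    main()
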