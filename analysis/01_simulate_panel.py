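"""Generate the study-shaped synthetic indicator panel.

Draws a 7-region x 8-year x 20-indicator panel (the shape of the real
yearbook data, which is not published) with region-specific monotone trends
and mild noise, and writes it where the later stages pick it up.
"""

from pathlib import Path

from ecowarn import SyntheticPanelConfig, generate_panel, write_panel

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    config = SyntheticPanelConfig(seed=SEED)
    panel = generate_panel(config)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "synthetic_panel.csv"
    write_panel(panel, out)
    print(
        f"wrote {panel.n_observations} observations "
        f"({len(panel.regions)} regions x {len(panel.years)} years) "
        f"x {len(panel.indicators)} indicators to {out}"
    )


if __name__ == "__main__":
    main()
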