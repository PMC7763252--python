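"""Synthetic indicator panels and grey series with known ground truth.

The panel generator emulates the structure of the study data — 7 regions
observed over 8 consecutive years on the 20-indicator PESN system — as
region-specific linear trends plus additive Gaussian noise:

    x(region, year, j) = baseline_rj + slope_rj * (year - start) + N(0, sigma_j)

truncated below at a small positive floor (1e-6) for determinism. Defaults
mirror the study conditions (R = 7, T = 8, the shipped 20-indicator
registry); trend signs are drawn so that the composite index tends to rise
over the window, the regime the grey model targets.

``generate_grey_series`` builds series that satisfy the grey difference
equation x(0)(k) + a z(1)(k) = b *exactly*, via the recursion

    x(0)(k) = (b - a x(1)(k-1)) / (1 + 0.5 a),

so least squares must recover (a, b) to machine precision — the package's
main parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PositivityError
from .gm11 import GreySeries
from .panel import IndicatorPanel
from .registry import IndicatorRegistry, default_registry

POSITIVE_FLOOR = 1e-6

DEFAULT_REGIONS = 7
DEFAULT_YEARS = 8
DEFAULT_START_YEAR = 2011
DEFAULT_NOISE_SCALE = 0.05  # relative to each indicator's baseline spread


@dataclass
class SyntheticPanelConfig:
    """Study-shaped panel: R regions x T consecutive years x registry indicators."""

    n_regions: int = DEFAULT_REGIONS
    start_year: int = DEFAULT_START_YEAR
    n_years: int = DEFAULT_YEARS
    registry: IndicatorRegistry = field(default_factory=default_registry)
    noise_scale: float = DEFAULT_NOISE_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        if self.n_years < 4:
            raise ValueError("need at least 4 years (grey model minimum)")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


def generate_panel(config: SyntheticPanelConfig) -> IndicatorPanel:
    """Draw a deterministic synthetic panel under the given config.

    One seeded generator governs every draw; identical configs give
    bit-identical panels. Baselines are indicator-specific (log-uniform over
    two decades, so units differ across indicators as in real yearbook
    data); slopes are region- and indicator-specific with a common sign per
    indicator, giving monotone region trends.
    """
    rng = np.random.default_rng(config.seed)
    codes = config.registry.codes
    regions = [f"R{i + 1:02d}" for i in range(config.n_regions)]
    years = np.arange(config.start_year, config.start_year + config.n_years)
    t = np.arange(config.n_years, dtype=float)

    baselines = 10.0 ** rng.uniform(-1, 1, size=len(codes))
    # improvement regime: positive indicators drift up, negative ones down
    trend_sign = np.array(
        [1.0 if config.registry.direction(c) == "positive" else -1.0 for c in codes]
    )

    blocks = []
    for _ in regions:
        region_slopes = trend_sign * baselines * rng.uniform(0.02, 0.10, size=len(codes))
        region_offsets = baselines * rng.uniform(0.8, 1.2, size=len(codes))
        noise = rng.normal(0.0, 1.0, size=(config.n_years, len(codes)))
        values = (
            region_offsets[None, :]
            + region_slopes[None, :] * t[:, None]
            + config.noise_scale * baselines[None, :] * noise
        )
        blocks.append(np.maximum(values, POSITIVE_FLOOR))

    if not all(np.isfinite(b).all() for b in blocks):
        raise ValueError("synthetic generation produced non-finite values")

    index = pd.MultiIndex.from_product([regions, years], names=["region", "year"])
    data = pd.DataFrame(np.vstack(blocks), index=index, columns=codes)
    return IndicatorPanel(data)


def exact_pipeline_panel(
    a: float = -0.05,
    b: float = 0.3,
    x0_1: float = 0.2,
    n_years: int = DEFAULT_YEARS,
    start_year: int = DEFAULT_START_YEAR,
    registry: IndicatorRegistry | None = None,
    target_region: str = "SYN",
) -> tuple[IndicatorPanel, GreySeries]:
    """A noise-free panel whose target region's composite index is an exact grey series.

    Construction: the target series g(k) is an exact grey-difference series
    in (0, 1); the target region's raw value for a positive indicator is
    g(k) and for a negative indicator 1 - g(k). A calibration region pins
    every pooled column min to 0 and max to 1, so min-max normalization is
    the identity on the target rows and the composite index equals g(k)
    exactly for *any* weight vector summing to 1. Running the full pipeline
    and refitting GM(1,1) on the target region must therefore recover (a, b)
    and fit with vanishing residuals.

    Returns the panel and the ground-truth target series.
    """
    if registry is None:
        registry = default_registry()
    g = generate_grey_series(a, b, x0_1, n_years, start_year=start_year)
    if g.values.min() <= 0 or g.values.max() >= 1:
        raise ValueError("target grey series must stay inside (0, 1); adjust (a, b, x0_1)")
    codes = registry.codes
    neg = np.array([registry.direction(c) == "negative" for c in codes])

    target = np.where(neg[None, :], 1.0 - g.values[:, None], g.values[:, None])
    # calibration rows: first year all 0, second all 1, rest mid-range
    cal = np.full((n_years, len(codes)), 0.5)
    cal[0, :], cal[1, :] = 0.0, 1.0

    years = list(range(start_year, start_year + n_years))
    index = pd.MultiIndex.from_product([["CAL", target_region], years], names=["region", "year"])
    data = pd.DataFrame(np.vstack([cal, target]), index=index, columns=codes)
    return IndicatorPanel(data), g


def generate_grey_series(
    a: float, b: float, x0_1: float, n: int, start_year: int = DEFAULT_START_YEAR
) -> GreySeries:
    """A series satisfying the grey difference equation exactly for (a, b)."""
    if abs(a) == 2:
        raise ValueError("a = +/-2 makes the recursion singular")
    if x0_1 <= 0:
        raise PositivityError("first value must be positive")
    if n < 4:
        raise ValueError("grey series needs n >= 4")
    x0 = np.empty(n)
    x0[0] = x0_1
    cum = x0_1
    for k in range(1, n):
        # z(1)(k) = cum + 0.5*x0[k]  =>  x0[k] = (b - a*cum) / (1 + 0.5a)
        x0[k] = (b - a * cum) / (1.0 + 0.5 * a)
        if x0[k] <= 0:
            raise PositivityError(
                f"generated value at position {k + 1} is not positive for "
                f"(a={a}, b={b}, x0_1={x0_1})"
            )
        cum += x0[k]
    return GreySeries(values=x0, years=list(range(start_year, start_year + n)))
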