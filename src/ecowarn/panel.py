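"""Raw and normalized indicator panels.

A panel holds one real value per (region, year, indicator). Internally it is
a pandas DataFrame with a (region, year) MultiIndex and one column per
indicator code; missing cells are NaN until interpolated. Normalization
rescales each indicator to [0, 1] by pooled min-max, with the direction of
the mapping decided by the indicator's registry entry:

* positive (developmental) indicators: ``y = (x - min) / (max - min)``
* negative (restrictive)   indicators: ``y = (max - x) / (max - min)``

so that larger normalized values always mean *safer* ecology. By default the
min and max are pooled over every (region, year) observation jointly, which
keeps normalized values — and hence the composite index — comparable across
years; a per-year pooling mode exists for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateIndicatorError,
    DuplicateObservationError,
    EndpointMissingError,
    MissingIndicatorError,
    PanelParseError,
)
from .registry import IndicatorRegistry

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("region", "year", "indicator", "value")


def _validate_index(data: pd.DataFrame) -> pd.DataFrame:
    if data.index.names != ["region", "year"]:
        raise ValueError("panel index must be a (region, year) MultiIndex")
    if data.index.duplicated().any():
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise DuplicateObservationError(f"duplicate (region, year) rows: {dupes}")
    data = data.sort_index()
    for region, group in data.groupby(level="region", sort=False):
        years = group.index.get_level_values("year").to_numpy()
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError(f"years for region {region!r} are not a contiguous run: {years.tolist()}")
    return data


@dataclass
class IndicatorPanel:
    """Raw indicator values keyed by (region, year, indicator)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_index(self.data.astype(float))

    @property
    def regions(self) -> list[str]:
        return list(self.data.index.get_level_values("region").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data.index.get_level_values("year").unique())

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.data.to_numpy()).all())


@dataclass
class NormalizedPanel:
    """Indicator panel rescaled to [0, 1]; same shape as its source."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_index(self.data.astype(float))
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("normalized panel contains non-finite values")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("normalized values must lie in [0, 1]")

    @property
    def regions(self) -> list[str]:
        return list(self.data.index.get_level_values("region").unique())

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns)


def _coerce_numeric(frame: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Convert string cells to float, naming the offending cell on failure."""
    out = frame.copy()
    for col in value_cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        # empty strings are legitimate missing cells, not parse errors
        raw = out[col].astype(str).str.strip()
        bad = converted.isna() & (raw != "") & raw.notna() & (raw.str.lower() != "nan")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = frame.iloc[i]
            if col == "value":  # long format: indicator is a cell, not the column
                raise PanelParseError(str(row["region"]), int(row["year"]), str(row["indicator"]), str(row[col]))
            raise PanelParseError(str(row["region"]), int(row["year"]), col, str(row[col]))
        out[col] = converted
    return out


def read_panel(path: str | Path, registry: IndicatorRegistry) -> IndicatorPanel:
    """Read a long- or wide-format CSV panel.

    Long format has columns (region, year, indicator, value); wide format has
    region, year and one column per indicator code. The returned panel
    contains exactly the registry's indicators, in registry order; extra
    columns are reported via logging, never silently dropped; registry
    indicators absent from the file raise :class:`MissingIndicatorError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    if not {"region", "year"} <= set(raw.columns):
        raise ValueError(f"{path}: panel file must have 'region' and 'year' columns")
    if raw.empty:
        raise ValueError(f"{path}: panel file contains no observations")
    raw["year"] = raw["year"].astype(int)

    if {"indicator", "value"} <= set(raw.columns):  # long format
        raw = _coerce_numeric(raw, ["value"])
        present = set(raw["indicator"].unique())
        unknown = present - set(registry.codes)
        if unknown:
            logger.warning("ignoring %d unknown indicators in %s: %s", len(unknown), path, sorted(unknown))
        missing = set(registry.codes) - present
        if missing:
            raise MissingIndicatorError(missing)
        dup = raw.duplicated(subset=["region", "year", "indicator"])
        if dup.any():
            raise DuplicateObservationError(
                f"duplicate (region, year, indicator) rows in {path}"
            )
        wide = raw.pivot(index=["region", "year"], columns="indicator", values="value")
        wide = wide[registry.codes]
        wide.columns.name = None
        return IndicatorPanel(wide)

    # wide format
    value_cols = [c for c in raw.columns if c not in ("region", "year")]
    unknown = set(value_cols) - set(registry.codes)
    if unknown:
        logger.warning("ignoring %d unknown columns in %s: %s", len(unknown), path, sorted(unknown))
    missing = set(registry.codes) - set(value_cols)
    if missing:
        raise MissingIndicatorError(missing)
    raw = _coerce_numeric(raw, [c for c in value_cols if c in registry.codes])
    raw = raw.replace({"": np.nan})
    wide = raw.set_index(["region", "year"])[registry.codes].astype(float)
    return IndicatorPanel(wide)


def write_panel(panel: IndicatorPanel, path: str | Path, fmt: str = "wide") -> None:
    """Write a panel as CSV (UTF-8, '.' decimal mark).

    Values are written with pandas' shortest round-tripping decimal
    representation, so ``read_panel(write_panel(p))`` reproduces every cell
    bit-exactly.
    """
    if fmt == "wide":
        panel.data.reset_index().to_csv(path, index=False)
    elif fmt == "long":
        long = panel.data.stack(future_stack=True).rename("value").reset_index()
        long.columns = list(LONG_COLUMNS)
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def interpolate_missing(panel: IndicatorPanel) -> IndicatorPanel:
    """Fill interior gaps of each (region, indicator) series linearly in year.

    Endpoint gaps are refused: interpolation is only defined between two
    observed neighbours, and no extrapolation rule is adopted.
    """
    filled = panel.data.copy()
    for region, group in panel.data.groupby(level="region", sort=False):
        block = group.droplevel("region")
        for code in block.columns:
            series = block[code]
            if series.notna().sum() == len(series):
                continue
            if series.notna().sum() < 2:
                raise EndpointMissingError(
                    f"series (region={region!r}, indicator={code!r}) has fewer than "
                    "two observed values"
                )
            if pd.isna(series.iloc[0]) or pd.isna(series.iloc[-1]):
                raise EndpointMissingError(
                    f"series (region={region!r}, indicator={code!r}) is missing an "
                    "endpoint year; refusing to extrapolate"
                )
            filled.loc[(region,), code] = series.interpolate(method="index").to_numpy()
    return IndicatorPanel(filled)


def normalize_panel(
    panel: IndicatorPanel,
    registry: IndicatorRegistry,
    pooling: str = "global",
    constant_policy: str = "error",
) -> NormalizedPanel:
    """Min-max rescale every indicator to [0, 1] by its direction.

    Parameters
    ----------
    pooling:
        ``"global"`` (default) pools min/max over all (region, year)
        observations jointly; ``"per-year"`` pools within each year.
    constant_policy:
        For an indicator with max == min over the pooled set: ``"error"``
        raises :class:`DegenerateIndicatorError`; ``"midpoint"`` assigns 0.5
        to every cell and logs the substitution.
    """
    if not panel.is_complete():
        raise ValueError("panel has missing cells; interpolate before normalizing")
    if pooling not in ("global", "per-year"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    missing = set(registry.codes) - set(panel.indicators)
    if missing:
        raise MissingIndicatorError(missing)

    data = panel.data[registry.codes]
    if pooling == "global":
        lo, hi = data.min(axis=0), data.max(axis=0)
    else:
        years = data.index.get_level_values("year")
        lo = data.groupby(years).transform("min")
        hi = data.groupby(years).transform("max")

    span = hi - lo
    degenerate = (span == 0) if pooling == "global" else (span == 0).any(axis=0)
    out = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
    for code in registry.codes:
        if bool(np.asarray(degenerate[code]).any()):
            if constant_policy == "error":
                raise DegenerateIndicatorError(code)
            logger.warning("indicator %r constant over pooled set; assigning 0.5", code)
            out[code] = 0.5
            continue
        scaled = (data[code] - lo[code]) / span[code]
        if registry.direction(code) == "negative":
            scaled = 1.0 - scaled
        out[code] = scaled
    return NormalizedPanel(out)
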