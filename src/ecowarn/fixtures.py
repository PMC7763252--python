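"""Packaged reference data.

Three small CSVs ship with the package:

``comprehensive_s44``
    The study-area-wide composite early-warning series, 2011-2018 — the
    worked-example input for the GM(1,1) grey model.
``table5_ewv``
    Per-county early-warning values and safety levels for the seven
    districts/counties (MH, PA, HZ, XH, HL, LD, HZh), 2011-2018.
``table4_weights``
    The published entropy weights of the 20-indicator PESN system
    (comprehensive weight and within-subsystem type weight).
``registry``
    The default 20-indicator catalogue (code, subsystem, direction, units).
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import pandas as pd

_FILES = {
    "comprehensive_s44": "comprehensive_ewv.csv",
    "table5_ewv": "county_ewv.csv",
    "table4_weights": "type_weights.csv",
    "registry": "registry.csv",
}


def _read(filename: str, **kwargs: Any) -> pd.DataFrame:
    ref = resources.files("ecowarn.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, **kwargs)


def load_fixture(name: str):
    """Return one of the packaged reference datasets.

    Parameters
    ----------
    name:
        One of ``comprehensive_s44`` (returns a :class:`~ecowarn.gm11.GreySeries`),
        ``table5_ewv`` (long DataFrame: region, year, ewv, esl),
        ``table4_weights`` (DataFrame indexed by indicator), or
        ``registry`` (:class:`~ecowarn.registry.IndicatorRegistry`).
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")

    if name == "comprehensive_s44":
        from .gm11 import GreySeries

        frame = _read(_FILES[name])
        return GreySeries(values=frame["ewv"].to_numpy(), years=frame["year"].tolist())
    if name == "table5_ewv":
        return _read(_FILES[name], dtype={"region": str, "year": int, "ewv": float, "esl": str})
    if name == "table4_weights":
        return _read(_FILES[name]).set_index("indicator")
    # registry
    from .registry import IndicatorRegistry

    return IndicatorRegistry.from_frame(_read(_FILES[name], dtype=str, keep_default_na=False))


def county_series(region: str):
    """The 2011-2018 early-warning series of one district/county as a GreySeries."""
    from .gm11 import GreySeries

    table = load_fixture("table5_ewv")
    rows = table[table["region"] == region].sort_values("year")
    if rows.empty:
        raise KeyError(f"unknown region {region!r}")
    return GreySeries(values=rows["ewv"].to_numpy(), years=rows["year"].tolist())
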