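"""Indicator catalogue: codes, names, subsystems and directions.

The default registry is the 20-indicator PESN system (Population,
Eco-environment, Socioeconomic, Natural resources) used throughout the
package, shipped as a CSV data file. Each indicator is either *positive*
(larger raw value = safer ecology) or *negative* (larger = worse), which
decides the min-max normalization formula applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

SUBSYSTEMS = ("P", "E", "S", "N")
DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator of the early-warning index system."""

    code: str
    name: str
    subsystem: str  # one of P, E, S, N
    direction: str  # "positive" or "negative"
    units: str = ""

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(f"unknown subsystem {self.subsystem!r} for {self.code!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r} for {self.code!r}")


@dataclass
class IndicatorRegistry:
    """Ordered collection of indicator specs with unique codes."""

    specs: list[IndicatorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [s.code for s in self.specs]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate indicator codes: {dupes}")

    def __iter__(self) -> Iterator[IndicatorSpec]:
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, code: str) -> IndicatorSpec:
        for s in self.specs:
            if s.code == code:
                return s
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(s.code == code for s in self.specs)

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.specs]

    def direction(self, code: str) -> str:
        return self[code].direction

    def subsystem(self, code: str) -> str:
        return self[code].subsystem

    def by_subsystem(self, subsystem: str) -> list[IndicatorSpec]:
        return [s for s in self.specs if s.subsystem == subsystem]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IndicatorRegistry":
        required = {"code", "name", "subsystem", "direction"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"registry file lacks columns: {sorted(missing)}")
        specs = [
            IndicatorSpec(
                code=str(r.code),
                name=str(r.name),
                subsystem=str(r.subsystem),
                direction=str(r.direction),
                units="" if pd.isna(getattr(r, "units", "")) else str(getattr(r, "units", "")),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(specs)

    @classmethod
    def read_csv(cls, path: str | Path) -> "IndicatorRegistry":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.code, s.name, s.subsystem, s.direction, s.units) for s in self.specs],
            columns=["code", "name", "subsystem", "direction", "units"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_registry() -> IndicatorRegistry:
    """The shipped 20-indicator PESN catalogue."""
    from .fixtures import load_fixture

    return load_fixture("registry")


def make_registry(specs: Iterable[IndicatorSpec]) -> IndicatorRegistry:
    return IndicatorRegistry(list(specs))
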