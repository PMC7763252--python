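"""Exception hierarchy for the early-warning pipeline.

Every error names the offending (region, year, indicator) coordinates where
it can, so a failed pipeline run points at the cell that caused it.
"""

from __future__ import annotations


class EcowarnError(Exception):
    """Base class for all package errors."""


class PanelParseError(EcowarnError):
    """A cell could not be parsed as a number."""

    def __init__(self, region: str, year: int | None, indicator: str, raw: str):
        self.region, self.year, self.indicator, self.raw = region, year, indicator, raw
        super().__init__(
            f"cannot parse value {raw!r} at (region={region!r}, year={year}, "
            f"indicator={indicator!r})"
        )


class MissingIndicatorError(EcowarnError):
    """An indicator required by the registry is absent from the input file."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"registry indicators missing from file: {self.codes}")


class DuplicateObservationError(EcowarnError):
    """The same (region, year) row appears more than once."""


class EndpointMissingError(EcowarnError):
    """A (region, indicator) series is missing its first or last value.

    Interior gaps are filled by linear interpolation between adjacent years;
    there is no extrapolation rule for endpoints, so this is refused.
    """


class DegenerateIndicatorError(EcowarnError):
    """An indicator is constant over all observations (max == min)."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(
            f"indicator {code!r} is constant across all observations; "
            "min-max normalization is undefined"
        )


class DegenerateColumnError(EcowarnError):
    """A normalized column is all zeros; relative frequencies are undefined."""


class ZeroInformationError(EcowarnError):
    """Every indicator has unit entropy, so entropy weights are undefined."""


class CoverageError(EcowarnError):
    """Weight table and panel do not cover the same indicator set."""


class PositivityError(EcowarnError):
    """A grey-model series contains a non-positive value."""


class DegenerateFitError(EcowarnError):
    """The GM(1,1) normal equations are singular (constant mean sequence)."""


class PipelineError(EcowarnError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
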