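"""GM(1,1) grey forecasting.

The grey model of first order in one variable fits a short positive series
x(0)(1..n), n >= 4, by smoothing it with the accumulated generating
operation (AGO, the running sum) and modelling the accumulated series as an
exponential. The fitting pipeline:

1. AGO:            x(1)(k) = x(1)(k-1) + x(0)(k),  x(1)(1) = x(0)(1)
2. mean sequence:  z(1)(k) = 0.5 x(1)(k) + 0.5 x(1)(k-1),  k = 2..n
3. grey difference equation x(0)(k) + a z(1)(k) = b, solved for (a, b) by
   ordinary least squares over k = 2..n with design rows (-z(1)(k), 1)
4. time response:  x̂(1)(k+1) = (x(0)(1) - b/a) e^{-ak} + b/a

``a`` is the development coefficient (negative a means a growing series),
``b`` the grey input. Fitted values on the original scale come back in
either of two ways, both pinning x̂(0)(1) = x(0)(1):

* ``difference`` — first differences of the time-response curve (inverse
  AGO); used for in-sample fitted values.
* ``derivative`` — x̂(0)(k+1) = -a (x(0)(1) - b/a) e^{-ak}, the whitening
  equation's derivative form; used for forecasting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, PositivityError

RESTORE_METHODS = ("difference", "derivative")


@dataclass
class GreySeries:
    """A positive, yearly-labelled series suitable for GM(1,1)."""

    values: np.ndarray
    years: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("series must be a non-empty 1-d array")
        if not np.isfinite(self.values).all():
            raise ValueError("series contains non-finite values")
        if (self.values <= 0).any():
            k = int(np.flatnonzero(self.values <= 0)[0])
            raise PositivityError(f"series value at position {k + 1} is not positive")
        if self.years is None:
            self.years = list(range(1, len(self.values) + 1))
        if len(self.years) != len(self.values):
            raise ValueError("year labels and values differ in length")

    def __len__(self) -> int:
        return len(self.values)


def ago(series: GreySeries | np.ndarray) -> np.ndarray:
    """Accumulated generating operation: the running sum x(1)."""
    values = series.values if isinstance(series, GreySeries) else np.asarray(series, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot accumulate an empty series")
    return np.cumsum(values)


def iago(x1: np.ndarray) -> np.ndarray:
    """Inverse AGO: first differences, keeping the first element."""
    x1 = np.asarray(x1, dtype=float)
    if len(x1) == 0:
        raise ValueError("cannot difference an empty series")
    return np.concatenate([x1[:1], np.diff(x1)])


def mean_sequence(x1: np.ndarray) -> np.ndarray:
    """Adjacent-pair means z(1)(k) = 0.5 x(1)(k) + 0.5 x(1)(k-1), k = 2..n."""
    x1 = np.asarray(x1, dtype=float)
    if len(x1) < 2:
        raise ValueError("mean sequence needs at least 2 accumulated values")
    return 0.5 * (x1[1:] + x1[:-1])


@dataclass
class Gm11Fit:
    """A fitted GM(1,1) model."""

    series: GreySeries
    a: float  # development coefficient
    b: float  # grey input
    x1: np.ndarray  # accumulated series
    z1: np.ndarray  # mean sequence, k = 2..n
    restore_method: str = "difference"
    fitted: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fitted = restore_fitted(self, self.restore_method)

    @property
    def c0(self) -> float:
        """Asymptote term b/a of the time-response function."""
        return self.b / self.a

    @property
    def c1(self) -> float:
        """Exponential coefficient x(0)(1) - b/a of the time-response function."""
        return float(self.series.values[0]) - self.b / self.a

    @property
    def derivative_multiplier(self) -> float:
        """Coefficient -a*(x(0)(1) - b/a) of the derivative-form prediction."""
        return -self.a * self.c1

    def time_response(self, k: np.ndarray | int) -> np.ndarray:
        """x̂(1)(k+1) = c1 e^{-ak} + b/a for integer offsets k >= 0."""
        return self.c1 * np.exp(-self.a * np.asarray(k, dtype=float)) + self.c0

    @property
    def residuals(self) -> np.ndarray:
        return self.series.values - self.fitted

    def to_frame(self) -> pd.DataFrame:
        obs = self.series.values
        eps = self.residuals
        return pd.DataFrame(
            {
                "year": self.series.years,
                "observed": obs,
                "fitted": self.fitted,
                "residual": eps,
                "relative_error": np.abs(eps) / obs,
            }
        )


def fit_gm11(series: GreySeries, restore: str = "difference") -> Gm11Fit:
    """Least-squares fit of the grey difference equation to a positive series.

    Raises :class:`DegenerateFitError` when the mean sequence is constant
    (the design matrix loses rank and (a, b) are not identifiable).
    """
    if len(series) < 4:
        raise ValueError(f"GM(1,1) needs at least 4 points, got {len(series)}")
    x1 = ago(series)
    z1 = mean_sequence(x1)
    if np.ptp(z1) == 0:
        raise DegenerateFitError("mean sequence is constant; (a, b) not identifiable")
    B = np.column_stack([-z1, np.ones_like(z1)])
    Y = series.values[1:]
    (a, b), *_ = np.linalg.lstsq(B, Y, rcond=None)
    return Gm11Fit(series=series, a=float(a), b=float(b), x1=x1, z1=z1, restore_method=restore)


def restore_fitted(fit: Gm11Fit, method: str = "difference") -> np.ndarray:
    """In-sample fitted values x̂(0)(1..n) on the original scale."""
    if method not in RESTORE_METHODS:
        raise ValueError(f"unknown restore method {method!r}; choose from {RESTORE_METHODS}")
    n = len(fit.series)
    k = np.arange(1, n)  # offsets for positions 2..n
    if method == "difference":
        x1hat = fit.time_response(np.arange(0, n))
        tail = np.diff(x1hat)
    else:
        tail = fit.derivative_multiplier * np.exp(-fit.a * k)
    return np.concatenate([fit.series.values[:1], tail])


def forecast(fit: Gm11Fit, horizon: int) -> pd.DataFrame:
    """Continue the restored sequence ``horizon`` steps past the sample.

    Uses the fit's restore method; rows are labelled by calendar years
    continuing the input run. Horizon 0 returns an empty frame.
    """
    if horizon < 0:
        raise ValueError("forecast horizon must be non-negative")
    n = len(fit.series)
    k = np.arange(n, n + horizon)  # offsets k for positions n+1 .. n+horizon
    if fit.restore_method == "difference":
        x1hat = fit.time_response(np.arange(n - 1, n + horizon))
        values = np.diff(x1hat)
    else:
        values = fit.derivative_multiplier * np.exp(-fit.a * k)
    last_year = fit.series.years[-1]
    years = [last_year + i for i in range(1, horizon + 1)]
    return pd.DataFrame({"year": years, "predicted": values})
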