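"""Double accuracy testing of a fitted GM(1,1) model.

Two complementary checks gate a fit before it is used for forecasting:

*Posterior-error test.* With residuals ε(k) = x(0)(k) - x̂(0)(k),

    S1 = population std of the observed series,
    S2 = population std of the residuals,
    C  = S2 / S1                       (posterior error ratio)
    p  = fraction of k with |ε(k) - ε̄| < 0.6745 S1   (small-error probability)

graded against the standard four-level table:

    Excellent   p >= 0.95      C <= 0.35
    Good        0.80 <= p < 0.95   0.35 < C <= 0.50
    Accepted    0.70 <= p < 0.80   0.50 < C <= 0.65
    Failed      p < 0.70       C > 0.65

with the overall verdict the worse of the two grades.

*Residual test.* Per-point relative errors Φ(k) = |ε(k)|/x(0)(k) (pass:
mean below 20%) and the stage-ratio deviation

    ρ(k) = |1 - ((1 - 0.5a)/(1 + 0.5a)) · λ(k)|,   λ(k) = x(0)(k-1)/x(0)(k)

which measures how far the observed consecutive-value ratios sit from the
geometric decay implied by the fitted development coefficient (pass: max
below 0.2).

All statistics are evaluated over k = 2..n: the first residual is
structurally zero (x̂(0)(1) = x(0)(1) by construction) and would only dilute
them. Standard deviations are population (divide-by-count) ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gm11 import Gm11Fit, GreySeries

SMALL_ERROR_FACTOR = 0.6745
RELATIVE_ERROR_PASS = 0.20  # mean relative error threshold (fraction)
STAGE_RATIO_PASS = 0.20  # max |rho| threshold

#: (label, p lower bound, C upper bound), checked best-to-worst
ACCURACY_LEVELS = (
    ("Excellent", 0.95, 0.35),
    ("Good", 0.80, 0.50),
    ("Accepted", 0.70, 0.65),
)
VERDICT_ORDER = ("Excellent", "Good", "Accepted", "Failed")


def residual_stats(observed: GreySeries, fitted: np.ndarray) -> pd.DataFrame:
    """Residuals ε, absolute errors Δ and relative errors Φ, per point."""
    fitted = np.asarray(fitted, dtype=float)
    if len(fitted) != len(observed):
        raise ValueError("observed and fitted series differ in length")
    eps = observed.values - fitted
    delta = np.abs(eps)
    return pd.DataFrame(
        {
            "year": observed.years,
            "observed": observed.values,
            "fitted": fitted,
            "residual": eps,
            "absolute_error": delta,
            "relative_error": delta / observed.values,
        }
    )


def posterior_error_test(observed: GreySeries, residuals: np.ndarray) -> tuple[float, float]:
    """Posterior error ratio C and small-error probability p over k = 2..n."""
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(observed):
        raise ValueError("observed series and residuals differ in length")
    eps = residuals[1:]
    obs = observed.values[1:]
    if len(eps) < 3:
        raise ValueError("posterior-error test needs at least 3 residual points")
    s1 = float(np.std(obs))  # population std
    if s1 == 0:
        raise ZeroDivisionError("observed series constant over k=2..n; C undefined")
    s2 = float(np.std(eps))
    c = s2 / s1
    p = float(np.mean(np.abs(eps - eps.mean()) < SMALL_ERROR_FACTOR * s1))
    return c, p


def stage_ratio_deviation(observed: GreySeries, a: float) -> np.ndarray:
    """Stage-ratio deviations ρ(k), k = 2..n, for development coefficient a."""
    if a == -2.0:
        raise ZeroDivisionError("a = -2 makes the smoothing factor singular")
    x = observed.values
    if len(x) < 2:
        raise ValueError("stage ratios need at least 2 points")
    lam = x[:-1] / x[1:]
    return np.abs(1.0 - (1.0 - 0.5 * a) / (1.0 + 0.5 * a) * lam)


def _grade_p(p: float) -> str:
    for label, p_lo, _ in ACCURACY_LEVELS:
        if p >= p_lo:
            return label
    return "Failed"


def _grade_c(c: float) -> str:
    for label, _, c_hi in ACCURACY_LEVELS:
        if c <= c_hi:
            return label
    return "Failed"


def accuracy_verdict(
    c: float, p: float, relative_errors: np.ndarray, rho: np.ndarray
) -> dict:
    """Grade C and p individually and combine into the overall verdict.

    The verdict is the worse of grade(C) and grade(p); the residual checks
    (mean relative error, max stage-ratio deviation) are reported as
    pass/fail flags alongside, not folded into the verdict label.
    """
    grade_c, grade_p = _grade_c(c), _grade_p(p)
    verdict = max(grade_c, grade_p, key=VERDICT_ORDER.index)
    rel = np.asarray(relative_errors, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return {
        "grade_C": grade_c,
        "grade_p": grade_p,
        "verdict": verdict,
        "relative_error_pass": bool(rel.mean() < RELATIVE_ERROR_PASS),
        "stage_ratio_pass": bool(rho.max() < STAGE_RATIO_PASS),
    }


@dataclass
class DiagnosticsReport:
    """Full double-accuracy-test report for one fitted model."""

    region: str
    a: float
    b: float
    C: float
    p: float
    mean_rel_err: float  # fraction, over k=2..n
    max_rel_err: float
    mean_rho: float
    max_rho: float
    grade_C: str
    grade_p: str
    verdict: str
    relative_error_pass: bool
    stage_ratio_pass: bool
    table: pd.DataFrame  # per-point residual statistics

    @property
    def usable_for_forecast(self) -> bool:
        return self.verdict != "Failed"

    def to_row(self) -> dict:
        return {
            "region": self.region,
            "a": self.a,
            "b": self.b,
            "C": self.C,
            "p": self.p,
            "mean_rel_err_pct": 100.0 * self.mean_rel_err,
            "max_rel_err_pct": 100.0 * self.max_rel_err,
            "mean_rho": self.mean_rho,
            "max_rho": self.max_rho,
            "grade_C": self.grade_C,
            "grade_p": self.grade_p,
            "verdict": self.verdict,
        }


def diagnose(fit: Gm11Fit, region: str = "") -> DiagnosticsReport:
    """Run both accuracy tests on a fitted model."""
    table = residual_stats(fit.series, fit.fitted)
    c, p = posterior_error_test(fit.series, fit.residuals)
    rho = stage_ratio_deviation(fit.series, fit.a)
    rel = table["relative_error"].to_numpy()[1:]  # k = 2..n
    verdict = accuracy_verdict(c, p, rel, rho)
    return DiagnosticsReport(
        region=region,
        a=fit.a,
        b=fit.b,
        C=c,
        p=p,
        mean_rel_err=float(rel.mean()),
        max_rel_err=float(rel.max()),
        mean_rho=float(rho.mean()),
        max_rho=float(rho.max()),
        table=table,
        **verdict,
    )
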