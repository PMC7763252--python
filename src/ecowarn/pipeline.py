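"""Full-analysis orchestration: panel -> weights -> index -> grey forecast.

``run_pipeline`` drives the whole chain on a raw indicator panel;
``run_from_ewv`` enters at the grey-model stage with precomputed
early-warning series (one positive series per region). Both write plain
CSV tables (no timestamps, fixed column order), so identical inputs and
config give byte-identical outputs.

Regions whose double accuracy test verdict is "Failed" still get fit and
diagnostics rows — they are worth inspecting — but are excluded from the
forecast table: the accuracy tests gate the prediction step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .diagnostics import DiagnosticsReport, diagnose
from .errors import DuplicateObservationError, PipelineError, PositivityError
from .gm11 import Gm11Fit, GreySeries, fit_gm11, forecast
from .index import EarlyWarningSeries, classify_grade, compute_ews, series_frame
from .panel import IndicatorPanel, interpolate_missing, normalize_panel, read_panel
from .registry import IndicatorRegistry, default_registry
from .weights import WeightTable, compute_weights

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the YAML config file."""

    panel_path: str | Path | None = None
    registry_path: str | Path | None = None
    output_dir: str | Path = "ecowarn_out"
    pooling: str = "global"  # min-max pooling scope: "global" | "per-year"
    restore_method: str = "difference"  # in-sample restoration variant
    forecast_restore: str = "derivative"  # restoration variant used to forecast
    horizon: int = 3
    frozen_weights_path: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("forecast horizon must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """All artifacts of one run, in memory; files land in the output dir."""

    weights: WeightTable | None
    series: list[EarlyWarningSeries]
    fits: dict[str, Gm11Fit]
    diagnostics: dict[str, DiagnosticsReport]
    forecasts: pd.DataFrame
    output_dir: Path | None = None


def _log_conventions(config: PipelineConfig) -> None:
    logger.info(
        "conventions: pooling=%s, in-sample restore=%s, forecast restore=%s, "
        "diagnostics over k=2..n with population std",
        config.pooling, config.restore_method, config.forecast_restore,
    )


def _grey_stage(
    series_by_region: dict[str, GreySeries], config: PipelineConfig
) -> tuple[dict[str, Gm11Fit], dict[str, DiagnosticsReport], pd.DataFrame]:
    fits: dict[str, Gm11Fit] = {}
    reports: dict[str, DiagnosticsReport] = {}
    forecast_rows = []
    for region, gs in series_by_region.items():
        try:
            fit = fit_gm11(gs, restore=config.restore_method)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError("grey-fit", f"region {region!r}: {exc}") from exc
        fits[region] = fit
        reports[region] = diagnose(fit, region=region)
        if not reports[region].usable_for_forecast:
            logger.warning("region %r failed the accuracy test; no forecast emitted", region)
            continue
        fc_fit = fit_gm11(gs, restore=config.forecast_restore)
        fc = forecast(fc_fit, config.horizon)
        fc.insert(0, "region", region)
        graded = [classify_grade(v) for v in fc["predicted"]]
        fc["grade"] = [g for g, _ in graded]
        fc["status"] = [s for _, s in graded]
        forecast_rows.append(fc)
    forecasts = (
        pd.concat(forecast_rows, ignore_index=True)
        if forecast_rows
        else pd.DataFrame(columns=["region", "year", "predicted", "grade", "status"])
    )
    return fits, reports, forecasts


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.weights is not None:
        result.weights.write_csv(out_dir / "weights.csv")
    if result.series:
        series_frame(result.series).to_csv(out_dir / "ewv_grades.csv", index=False)
    if result.fits:
        fit_frames = []
        for region, fit in result.fits.items():
            block = fit.to_frame()
            block.insert(0, "region", region)
            fit_frames.append(block)
        pd.concat(fit_frames, ignore_index=True).to_csv(out_dir / "gm11_fits.csv", index=False)
        pd.DataFrame([r.to_row() for r in result.diagnostics.values()]).to_csv(
            out_dir / "diagnostics.csv", index=False
        )
    result.forecasts.to_csv(out_dir / "forecasts.csv", index=False)
    lines = ["ecological-security early-warning pipeline summary", ""]
    for region, rep in result.diagnostics.items():
        lines.append(
            f"{region}: a={rep.a:+.6f} C={rep.C:.4f} p={rep.p:.4f} "
            f"mean_rel_err={100 * rep.mean_rel_err:.1f}% verdict={rep.verdict}"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(
    config: PipelineConfig,
    panel: IndicatorPanel | None = None,
    registry: IndicatorRegistry | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full analysis; pass a panel in memory or via config paths."""
    _log_conventions(config)
    if registry is None:
        registry = (
            IndicatorRegistry.read_csv(config.registry_path)
            if config.registry_path
            else default_registry()
        )
    if panel is None:
        if config.panel_path is None:
            raise PipelineError("input", "no panel given (in memory or via panel_path)")
        try:
            panel = read_panel(config.panel_path, registry)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("input", str(exc)) from exc

    try:
        panel = interpolate_missing(panel)
        normalized = normalize_panel(panel, registry, pooling=config.pooling)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalize", str(exc)) from exc

    try:
        if config.frozen_weights_path:
            weights = WeightTable.read_csv(config.frozen_weights_path)
            logger.info("scoring under frozen weights from %s", config.frozen_weights_path)
        else:
            weights = compute_weights(normalized, registry)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("weights", str(exc)) from exc

    try:
        series = compute_ews(normalized, weights)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("score", str(exc)) from exc

    grey_input = {
        s.region: GreySeries(values=s.ewv.to_numpy(), years=list(s.years)) for s in series
    }
    fits, reports, forecasts = _grey_stage(grey_input, config)

    result = PipelineResult(
        weights=weights, series=series, fits=fits, diagnostics=reports, forecasts=forecasts
    )
    if write:
        out_dir = Path(config.output_dir)
        _write_outputs(result, out_dir)
        result.output_dir = out_dir
    return result


def read_ewv_series(path: str | Path) -> dict[str, GreySeries]:
    """Read precomputed early-warning series (long CSV: region, year, ewv)."""
    frame = pd.read_csv(path)
    required = {"region", "year", "ewv"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: series file needs columns {sorted(required)}")
    if frame.duplicated(subset=["region", "year"]).any():
        raise DuplicateObservationError(f"duplicate (region, year) rows in {path}")
    out = {}
    for region, group in frame.groupby("region", sort=False):
        group = group.sort_values("year")
        values = group["ewv"].to_numpy()
        if (values <= 0).any():
            raise PositivityError(f"region {region!r} has non-positive early-warning values")
        out[str(region)] = GreySeries(values=values, years=group["year"].astype(int).tolist())
    return out


def run_from_ewv(
    series: dict[str, GreySeries] | str | Path,
    config: PipelineConfig | None = None,
    write: bool = False,
) -> PipelineResult:
    """Grey-model tail of the pipeline on precomputed index series."""
    if config is None:
        config = PipelineConfig()
    _log_conventions(config)
    if not isinstance(series, dict):
        series = read_ewv_series(series)
    fits, reports, forecasts = _grey_stage(series, config)
    result = PipelineResult(
        weights=None, series=[], fits=fits, diagnostics=reports, forecasts=forecasts
    )
    if write:
        out_dir = Path(config.output_dir)
        _write_outputs(result, out_dir)
        result.output_dir = out_dir
    return result
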