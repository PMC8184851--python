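"""End-to-end orchestration: data -> cutoff -> forecasts -> variation ->
fragmentation profiles -> VIF -> four association models -> mediated impact.

Every stage is a pure function of (inputs, config, seed); re-running with the
same config and seed reproduces all numeric outputs byte for byte. Stage
failures abort with the stage name (and station id where applicable) in the
message, leaving partial outputs plus a FAILED marker in the output
directory. Stations whose SARIMAX grid never converges are dropped from the
association fits and listed in the manifest instead of aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import fragno2
from fragno2 import dtw as dtw_mod
from fragno2 import gam as gam_mod
from fragno2 import landscape as landscape_mod
from fragno2 import synthetic as synth_mod
from fragno2.forecast import (
    AllOrdersFailedError,
    CounterfactualForecaster,
    SarimaxOrder,
    select_training_cutoff,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and station)."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable).

    In synthetic mode the scenario is generated from ``scenario``; in
    user-data mode ``panels_path``, ``rasters_path`` and ``controls_path``
    must exist.
    """

    mode: str = "synthetic"
    scenario: synth_mod.ScenarioConfig = field(default_factory=synth_mod.ScenarioConfig)
    panels_path: str | None = None
    rasters_path: str | None = None
    controls_path: str | None = None
    # forecasting
    order_grid: list[tuple[int, int, int, int, int, int]] | None = None
    seasonal_period: int = 7
    fourier_annual: bool = True
    cutoff_candidates: list[str] | None = None
    # windows
    lockdown_date: str | None = None  # defaults to the scenario's
    # metrics
    buffer_radius: float = 3000.0
    ed_denominator: str = "class"
    boundary_as_edge: bool = True
    # gam
    alpha_grid: list[float] | None = None
    log_transform_response: bool = False
    # run control
    out_dir: str = "fragno2_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = synth_mod.ScenarioConfig(**d["scenario"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved_order_grid(self) -> list[SarimaxOrder] | None:
        if self.order_grid is None:
            return None
        return [SarimaxOrder(*o, s=self.seasonal_period) if len(o) == 6 else SarimaxOrder(*o)
                for o in self.order_grid]


def _stage(name: str, out: Path):
    """Context wrapper turning stage exceptions into PipelineError and
    dropping a FAILED marker."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                if not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the output tables and writes CSVs
    plus a run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    scenario_cfg = dataclasses.replace(config.scenario, seed=config.seed)
    lockdown = pd.Timestamp(config.lockdown_date or scenario_cfg.lockdown_date)
    end_date = pd.Timestamp(scenario_cfg.end_date)
    forecast_start = pd.Timestamp(scenario_cfg.forecast_start)

    # -- stage 1: data ------------------------------------------------------
    with _stage("data", out):
        if config.mode == "synthetic":
            scenario = synth_mod.generate_scenario(scenario_cfg)
            synth_mod.write_scenario(scenario, out / "scenario")
            panels = scenario.panels
            rasters = scenario.rasters
            controls = scenario.controls
        elif config.mode == "user-data":
            for label, p in (("panels", config.panels_path),
                             ("rasters", config.rasters_path),
                             ("controls", config.controls_path)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{label} path missing or not found: {p}")
            panels = synth_mod.read_panels(config.panels_path)
            rasters = synth_mod.read_rasters(config.rasters_path)
            controls = synth_mod.read_controls(config.controls_path)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

    order_grid = config.resolved_order_grid()

    # -- stage 2: training cutoff -------------------------------------------
    with _stage("cutoff-selection", out):
        if config.cutoff_candidates:
            report = select_training_cutoff(
                panels,
                config.cutoff_candidates,
                end_date,
                order_grid=order_grid,
                seasonal_period=config.seasonal_period,
                fourier_annual=config.fourier_annual,
            )
            train_end = report.selected
            report.table.assign(cutoff=report.table["cutoff"].dt.strftime("%Y-%m-%d")).to_csv(
                out / "cutoff_report.csv", index=False, float_format="%.10g"
            )
        else:
            train_end = forecast_start

    # -- stage 3: per-station forecasts -------------------------------------
    forecasts = {}
    excluded: list[str] = []
    fc_dir = out / "forecasts"
    fc_dir.mkdir(exist_ok=True)
    with _stage("forecast", out):
        for panel in panels:
            forecaster = CounterfactualForecaster(
                order_grid=order_grid,
                seasonal_period=config.seasonal_period,
                fourier_annual=config.fourier_annual,
            )
            try:
                fc = forecaster.fit(panel, train_end).predict(end_date)
            except AllOrdersFailedError:
                logger.warning("station %s excluded: no convergent order", panel.station_id)
                excluded.append(str(panel.station_id))
                continue
            except Exception as exc:
                raise PipelineError(
                    f"stage forecast failed at station {panel.station_id}: {exc}"
                ) from exc
            forecasts[str(panel.station_id)] = fc
            obs = pd.Series(panel.no2_observed, index=panel.dates)
            fc.to_frame(observed=obs).to_csv(
                fc_dir / f"{panel.station_id}.csv", index=False, float_format="%.10g"
            )
        if not forecasts:
            raise AllOrdersFailedError("every station failed to forecast")

    # -- stage 4: variation scoring ------------------------------------------
    with _stage("variation", out):
        variations = []
        for panel in panels:
            sid = str(panel.station_id)
            if sid not in forecasts:
                continue
            try:
                variations.append(dtw_mod.score_variation(panel, forecasts[sid], lockdown))
            except Exception as exc:
                raise PipelineError(
                    f"stage variation failed at station {sid}: {exc}"
                ) from exc
        variation_table = dtw_mod.variation_table(variations)
        variation_table.to_csv(out / "variation.csv", index=False, float_format="%.10g")

    # -- stage 5: fragmentation profiles -------------------------------------
    with _stage("fragmentation-metrics", out):
        rows = []
        for sid, raster in sorted(rasters.items()):
            center = (raster.shape[0] // 2, raster.shape[1] // 2)
            prof = landscape_mod.fragmentation_profile(
                raster,
                center,
                config.buffer_radius,
                boundary_as_edge=config.boundary_as_edge,
                ed_denominator=config.ed_denominator,
            )
            rows.append({"station_id": str(sid), **prof.as_dict()})
        profile_table = pd.DataFrame(rows)
        profile_table.to_csv(out / "profiles.csv", index=False, float_format="%.10g")

    # -- stage 6: VIF screen --------------------------------------------------
    with _stage("vif", out):
        vif_input = profile_table.dropna()[["station_id", *gam_mod.FRAG_COLUMNS]]
        vif_report = gam_mod.compute_vif(vif_input)
        vif_report.to_frame().to_csv(out / "vif.csv", index=False, float_format="%.10g")

    # -- stage 7: association models ------------------------------------------
    fits = {}
    with _stage("association-models", out):
        gam_kwargs = {"log_transform_response": config.log_transform_response}
        if config.alpha_grid is not None:
            gam_kwargs["alpha_grid"] = tuple(config.alpha_grid)
        for variant in gam_mod.VARIANTS:
            spec = gam_mod.ModelSpec(variant)
            fits[variant] = gam_mod.fit_association_model(
                variation_table, profile_table, controls, spec, **gam_kwargs
            )
        coef = pd.concat([f.coefficient_table() for f in fits.values()], ignore_index=True)
        coef.to_csv(out / "coefficients.csv", index=False, float_format="%.10g")
        evaluation = pd.DataFrame(
            {
                "variant": list(fits),
                "r2": [f.r_squared for f in fits.values()],
                "deviance_explained": [f.deviance_explained for f in fits.values()],
                "aic": [f.aic for f in fits.values()],
                "n": [f.n for f in fits.values()],
            }
        )
        evaluation.to_csv(out / "evaluation.csv", index=False, float_format="%.10g")

    # -- stage 8: mediated impact ----------------------------------------------
    with _stage("mediated-impact", out):
        mediated = gam_mod.mediated_impact_table(fits["UFCB"], fits["UFCD"])
        mediated.to_csv(out / "mediated_impact.csv", index=False, float_format="%.10g")

    manifest = {
        "package": "fragno2",
        "version": fragno2.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "train_end": str(pd.Timestamp(train_end).date()),
        "lockdown_date": str(lockdown.date()),
        "excluded_stations": excluded,
        "config": _jsonable(dataclasses.asdict(config)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    return {
        "variation": variation_table,
        "profiles": profile_table,
        "vif": vif_report,
        "fits": fits,
        "mediated_impact": mediated,
        "evaluation": evaluation,
        "train_end": pd.Timestamp(train_end),
        "excluded": excluded,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return str(obj)
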