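"""Readers/writers for the package's delimited-text tables and structured
configs, plus the end-to-end pipeline runner.

All tables are comma-separated with ISO dates and unit-bearing column headers
(prcp_mm, tn_mg_per_L, loss_kgN_per_ha, ...) so units cannot silently drift.
Every artifact written by the pipeline carries a comment header with the
package version, the run seed, and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    CalibSpec,
    CalibrationResult,
    calibrate,
    evaluate,
    normalized_rmse_objective,
)
from .management import FertEvent, ManagementSchedule
from .nitrogen import NRateParams, simulate_season
from .scenario import (
    TREATMENTS,
    classify_scenario_years,
    run_scenarios,
    summarize_by_year_type,
)
from .synth import PROFILES, generate_observations, make_site
from .water import IrrigationPolicy, SoilHydroParams
from .weather import generate_weather

__all__ = [
    "read_weather",
    "write_weather",
    "read_observations",
    "write_observations",
    "load_site_config",
    "dump_site_config",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_WEATHER_COLS = {"date": "date", "prcp_mm": "prcp", "tmax_C": "tmax",
                 "tmin_C": "tmin", "sunshine_h": "sunshine", "et0_mm": "et0"}


class SchemaError(ValueError):
    """Malformed table or configuration."""


def read_weather(path) -> pd.DataFrame:
    """Read a daily weather table; validates dates and precipitation.

    Expects columns date, prcp_mm, tmax_C, tmin_C and optionally sunshine_h,
    et0_mm; returns internal names (prcp, tmax, ...).
    """
    try:
        raw = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise SchemaError(f"cannot parse weather table {path}: {exc}") from exc
    missing = {"date", "prcp_mm"} - set(raw.columns)
    if missing:
        raise SchemaError(f"weather table missing required columns: {sorted(missing)}")
    df = raw.rename(columns={k: v for k, v in _WEATHER_COLS.items() if k in raw.columns})
    try:
        df["date"] = pd.to_datetime(df["date"])
    except Exception as exc:
        raise SchemaError(f"unparseable date in weather table: {exc}") from exc
    if df["date"].duplicated().any() or not df["date"].is_monotonic_increasing:
        raise SchemaError("weather dates must be strictly increasing")
    bad = df.index[df["prcp"] < 0]
    if len(bad):
        raise SchemaError(f"negative precipitation at data row {int(bad[0]) + 1}")
    if "tmax" in df and "tmin" in df:
        both = df["tmax"].notna() & df["tmin"].notna()
        viol = df.index[both & (df["tmax"] < df["tmin"])]
        if len(viol):
            raise SchemaError(f"tmax < tmin at data row {int(viol[0]) + 1}")
    gaps = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1]).difference(df["date"])
    if len(gaps):
        logger.warning("weather gaps on %d dates, first %s", len(gaps), gaps[0].date())
    return df


def write_weather(df: pd.DataFrame, path, header: str | None = None) -> None:
    out = df.rename(columns={v: k for k, v in _WEATHER_COLS.items()})
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    _write_table(out, path, header)


def _write_table(df: pd.DataFrame, path, header: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"series_name", "dat", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"observations table missing columns: {sorted(missing)}")
    return df


def write_observations(df: pd.DataFrame, path, header: str | None = None) -> None:
    _write_table(df, path, header)


def load_site_config(path) -> dict:
    """Load a site config (YAML): soil, policy, dates, latitude, fertilization."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    soil = SoilHydroParams(**cfg.get("soil", {}))
    policy_cfg = cfg.get("policy", {})
    windows = tuple(tuple(w) for w in policy_cfg.pop("drainage_windows", ()))
    policy = IrrigationPolicy(drainage_windows=windows, **policy_cfg)
    fert = tuple(FertEvent(**e) for e in cfg.get("fertilization", []))
    dates = cfg.get("dates", {})
    schedule = ManagementSchedule(
        transplant=dates["transplant"], harvest=dates["harvest"],
        fert_events=fert, policy=policy,
    )
    rates = NRateParams(**cfg.get("rates", {}))
    return {
        "soil": soil,
        "schedule": schedule,
        "rates": rates,
        "latitude": float(cfg.get("latitude", 30.0)),
    }


def dump_site_config(soil, schedule, rates, latitude, path) -> None:
    cfg = {
        "latitude": latitude,
        "soil": {"perc_rate": soil.perc_rate, "pd_max": soil.pd_max, "kc": soil.kc},
        "policy": {
            "pd_lower": schedule.policy.pd_lower,
            "pd_target": schedule.policy.pd_target,
            "pd_upper": schedule.policy.pd_upper,
            "drainage_windows": [list(w) for w in schedule.policy.drainage_windows],
        },
        "dates": {"transplant": str(schedule.transplant), "harvest": str(schedule.harvest)},
        "fertilization": [
            {"day": e.day, "n_amount": e.n_amount, "kind": e.kind, "f_surf": e.f_surf}
            for e in schedule.fert_events
        ],
        "rates": dataclasses.asdict(rates),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    profile: str = "default"
    seed: int = 0
    n_years: int = 50
    out_dir: str = "paddyn_out"
    treatments: tuple[str, ...] = ()
    calibrate: bool = True

    def resolved_treatments(self) -> tuple[str, ...]:
        if not self.treatments:
            logger.info("no treatment list in config; defaulting to FR, FRS, MR, MRS")
            return tuple(TREATMENTS)
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise SchemaError(f"unknown treatments: {sorted(unknown)}")
        return self.treatments


def _artifact_header(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # hash the scientific config, not the path
    blob = json.dumps(payload, sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"paddyn v{__version__}\nseed: {config.seed}\nconfig: {digest}"


def run_pipeline(config: RunConfig) -> dict:
    """Run synth → weather → (calibrate) → scenario, writing all artifacts.

    Deterministic given the config seed; returns the in-memory artifact set.
    """
    out = Path(config.out_dir)
    header = _artifact_header(config)
    truth = make_site(config.profile, seed=config.seed)
    logger.info("stage synth: profile=%s seed=%d", config.profile, config.seed)
    obs = generate_observations(truth)
    write_weather(obs["weather"], out / "weather_observed.csv", header)
    write_observations(
        pd.concat([obs["ponding"], obs["runoff"], obs["concentrations"]]),
        out / "observations.csv", header,
    )
    dump_site_config(
        truth.soil, truth.schedule, truth.rates, truth.latitude, out / "site.yaml"
    )

    fitted_soil, fitted_rates, fitted_sched = truth.soil, truth.rates, truth.schedule
    if config.calibrate:
        logger.info("stage calibrate")
        result = calibrate_site(truth, obs)
        fitted_soil = dataclasses.replace(truth.soil, perc_rate=result.params["perc_rate"])
        fitted_rates = dataclasses.replace(truth.rates, k_nh4=result.params["k_nh4"])
        fitted_sched = truth.schedule.with_f_surf(result.params["f_surf"])
        metrics_rows = [
            {"series": name, "rmse": m.rmse, "d": m.d, "e": m.e}
            for name, m in result.metrics.items()
        ]
        _write_table(pd.DataFrame(metrics_rows), out / "calibration_metrics.csv", header)
        with open(out / "fitted_params.json", "w") as fh:
            json.dump(result.params, fh, indent=2)

    logger.info("stage scenario: %d years", config.n_years)
    truth_fitted = dataclasses.replace(
        truth, soil=fitted_soil, rates=fitted_rates, schedule=fitted_sched
    )
    year0 = pd.Timestamp(truth.schedule.transplant).year
    weather50 = generate_weather(
        truth.weather_params, config.n_years, np.random.default_rng(config.seed + 7),
        temperature_model=truth.temperature, start_year=year0,
    )
    prof = PROFILES[config.profile]
    treatments = [TREATMENTS[t] for t in config.resolved_treatments()]
    losses = run_scenarios(truth_fitted, weather50, treatments)
    classes = classify_scenario_years(weather50, prof.transplant, prof.harvest)
    summary = summarize_by_year_type(losses, classes, seed=config.seed)
    _write_table(losses, out / "scenario_losses.csv", header)
    _write_table(summary.summary, out / "scenario_summary.csv", header)
    _write_table(
        summary.reductions, out / "scenario_reductions.csv",
        header + f"\nprocedure: {summary.procedure}",
    )
    return {
        "truth": truth,
        "observations": obs,
        "losses": losses,
        "classes": classes,
        "summary": summary,
    }


def calibrate_site(
    truth,
    obs,
    hydro_spec: CalibSpec | None = None,
    n_spec: CalibSpec | None = None,
):
    """Fit perc_rate, k_nh4 and f_surf to the observation tables of a site
    (conventional-fertilization data), per-series metrics included.

    Calibration is staged the way paddy models are tuned in practice: the
    hydraulic parameter is fitted first against the ponding-depth and runoff
    series (whose response is independent of the N parameters, but rugged —
    shifting an irrigation or drainage day jumps the error — hence a dense
    grid), then the N-transformation parameters against the concentration
    series on a smooth surface.
    """
    if hydro_spec is None:
        hydro_spec = CalibSpec(
            bounds={"perc_rate": (2.0, 15.0)},
            n_rounds=6, n_grid=61, shrink=0.1, seed=truth.seed,
        )
    if n_spec is None:
        n_spec = CalibSpec(
            bounds={"k_nh4": (0.1, 0.8), "f_surf": (0.1, 0.6)},
            seed=truth.seed,
        )
    weather = obs["weather"]
    sample_days = obs["sample_days"]

    def simulate(params: dict[str, float]):
        soil = dataclasses.replace(truth.soil, perc_rate=params.get("perc_rate", truth.soil.perc_rate))
        rates = dataclasses.replace(truth.rates, k_nh4=params.get("k_nh4", truth.rates.k_nh4))
        sched = truth.schedule
        if "f_surf" in params:
            sched = sched.with_f_surf(params["f_surf"])
        return simulate_season(weather, soil, sched, rates, latitude=truth.latitude)

    water_obs = {
        "ponding_depth": (
            obs["ponding"]["value"].to_numpy(),
            lambda sim: sim.water["pd"].to_numpy(),
        ),
        "runoff": (
            obs["runoff"]["value"].to_numpy(),
            lambda sim: sim.water["rf"].to_numpy(),
        ),
    }
    def _conc_extractor(form: str):
        def extract(sim):
            return sim.nitrogen.set_index("day").loc[sample_days, form].to_numpy()
        return extract

    # concentrations carry multiplicative noise, so they are fitted on a
    # log1p scale; reported metrics stay on the measured scale
    conc_obs_raw = {
        form: (
            obs["concentrations"].query(f"series_name == '{form}'")["value"].to_numpy(),
            _conc_extractor(form),
        )
        for form in ("c_tn", "c_din")
    }
    conc_obs = {
        form: (np.log1p(o), (lambda ex: lambda sim: np.log1p(ex(sim)))(ex))
        for form, (o, ex) in conc_obs_raw.items()
    }

    stage1 = calibrate(hydro_spec, normalized_rmse_objective(water_obs, simulate))
    fixed = dict(stage1.params)

    def simulate_stage2(params: dict[str, float]):
        return simulate({**fixed, **params})

    stage2 = calibrate(
        n_spec, normalized_rmse_objective(conc_obs, simulate_stage2)
    )
    params = {**fixed, **stage2.params}
    result = CalibrationResult(
        params=params,
        objective=stage2.objective,
        trace=stage1.trace + stage2.trace,
        n_evaluations=stage1.n_evaluations + stage2.n_evaluations,
    )
    final = simulate(params)
    for name, (o, extract) in {**water_obs, **conc_obs_raw}.items():
        result.metrics[name] = evaluate(o, extract(final))
    return result
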