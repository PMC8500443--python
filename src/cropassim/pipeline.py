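"""End-to-end pipeline: synthetic twin -> localized run -> per-treatment
assimilation -> localized-vs-assimilated validation of LAI and yield.

The "localized" model is the shipped default parameter set — the crop
model adjusted to the region before any observation-driven optimization.
Assimilation re-fits only the five sensitive parameters per treatment.
Every artifact records the seed, and a rerun with the same configuration
is byte-identical.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assimilation import AssimilationResult, OptimizationConfig, cost, optimize
from .crop_model import (
    CropParameters,
    StateTrajectory,
    WeatherSeries,
    default_parameters,
    extract_lai,
    run_simulation,
)
from .errors import ConfigurationError, CropAssimError
from .evaluation import PairedSeries, compare_runs, evaluate
from .synthetic import (
    ObservationSet,
    TreatmentDesign,
    generate_experiment,
    write_observations_csv,
    write_truth_sidecar,
    write_yields_csv,
)

log = logging.getLogger("cropassim")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"                 # synthetic | external
    seasons: tuple[str, ...] = ("2015-2016",)
    seed: int = 0
    noise_cv: float = 0.10
    out_dir: Path | None = None
    n_restarts: int = 12
    # external mode inputs
    weather_path: Path | None = None
    observations_path: Path | None = None
    yields_path: Path | None = None
    params_path: Path | None = None
    sowing_date: dt.date | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "external"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "external":
            for name in ("weather_path", "observations_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"external mode requires existing {name}: {p}")
            if self.sowing_date is None:
                raise ConfigurationError("external mode requires a sowing date")


# ---------------------------------------------------------------------------
# Observation file I/O (external-data path; schema shared with synthetic)
# ---------------------------------------------------------------------------

def read_observations(path) -> list[ObservationSet]:
    """Read `treatment_id,date,lai_uav` rows grouped by treatment."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"treatment_id", "date", "lai_uav"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"observations CSV must have columns {sorted(required)}")
    if len(df) == 0:
        raise ConfigurationError(f"observations file {path} is empty")
    out = []
    for tid, grp in df.groupby("treatment_id", sort=False):
        dates = []
        for lineno, raw in zip(grp.index, grp["date"]):
            try:
                dates.append(dt.date.fromisoformat(str(raw)))
            except ValueError as exc:
                raise ConfigurationError(
                    f"malformed date {raw!r} at row {lineno + 2} of {path}"
                ) from exc
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ConfigurationError(
                f"non-monotone observation dates for treatment {tid!r} in {path}"
            )
        out.append(
            ObservationSet(
                treatment_id=str(tid),
                dates=tuple(dates),
                lai_uav=grp["lai_uav"].to_numpy(float),
            )
        )
    return out


def read_yields(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return {str(t): float(y) for t, y in zip(df["treatment_id"], df["yield_kg_hm2"])}


def write_summary(summary: dict, path) -> None:
    """Deterministic JSON (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class TreatmentOutcome:
    treatment_id: str
    season: str
    assimilation: AssimilationResult | None
    localized_cost: float
    lai_obs: np.ndarray
    lai_localized: np.ndarray
    lai_assimilated: np.ndarray | None
    measured_yield: float | None
    yield_localized: float | None
    yield_assimilated: float | None
    truth_params: CropParameters | None = None
    truth_trajectory: StateTrajectory | None = None
    error: str | None = None


def _season_bundles(config: PipelineConfig, base: CropParameters):
    """Yield (season_label, design/sowing, weather, observation sets, yields)."""
    if config.mode == "synthetic":
        for si, label in enumerate(config.seasons):
            design = TreatmentDesign.for_season(label)
            obs_sets, weather = generate_experiment(
                design, base, noise_cv=config.noise_cv, seed=config.seed + 10_000 * si
            )
            yields = {
                o.treatment_id: o.measured_yield
                for o in obs_sets
                if o.measured_yield is not None
            }
            yield label, design.sowing_date, design.observation_dates, weather, obs_sets, yields
    else:
        weather = WeatherSeries.from_csv(config.weather_path)
        obs_sets = read_observations(config.observations_path)
        yields = read_yields(config.yields_path) if config.yields_path else {}
        dates = obs_sets[0].dates
        yield "external", config.sowing_date, dates, weather, obs_sets, yields


def run_pipeline(config: PipelineConfig, base_params: CropParameters | None = None) -> dict:
    """Run the full experiment and return the summary dictionary.

    Per treatment: evaluate the localized model, assimilate the five
    sensitive parameters against the treatment's LAI observations, and
    re-simulate. Aggregated over treatments, LAI (at the observation
    dates) and yield are each validated against the measurements for both
    model variants, and the side-by-side comparison is reported. Failures
    in one treatment are recorded and the pipeline continues.
    """
    config.validate()
    logging.basicConfig(level=config.log_level, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    base = base_params if base_params is not None else default_parameters()
    if config.mode == "external" and config.params_path:
        base = CropParameters.from_yaml(config.params_path)

    outcomes: list[TreatmentOutcome] = []
    for season, sowing, _obs_dates, weather, obs_sets, yields in _season_bundles(config, base):
        traj_loc = run_simulation(base, weather, sowing, require_maturity=False)
        for k, obs in enumerate(obs_sets):
            log.info("assimilating %s", obs.treatment_id)
            lai_loc = extract_lai(traj_loc, obs.dates)
            loc_cost = cost(base, obs, weather, sowing)
            try:
                opt_cfg = OptimizationConfig(
                    seed=config.seed + 31 * (len(outcomes) + 1),
                    n_restarts=config.n_restarts,
                )
                result = optimize(obs, weather, base, opt_cfg, sowing_date=sowing)
                traj_asm = run_simulation(
                    result.optimized_params, weather, sowing, require_maturity=False
                )
                lai_asm = extract_lai(traj_asm, obs.dates)
                y_asm = traj_asm.yield_kg_per_hm2
                err = None
            except CropAssimError as exc:
                log.error("stage assimilate failed for %s: %s", obs.treatment_id, exc)
                result, lai_asm, y_asm = None, None, None
                err = f"assimilate: {exc}"
            outcomes.append(
                TreatmentOutcome(
                    treatment_id=obs.treatment_id,
                    season=season,
                    assimilation=result,
                    localized_cost=loc_cost,
                    lai_obs=np.asarray(obs.lai_uav, float),
                    lai_localized=lai_loc,
                    lai_assimilated=lai_asm,
                    measured_yield=yields.get(obs.treatment_id),
                    yield_localized=traj_loc.yield_kg_per_hm2,
                    yield_assimilated=y_asm,
                    truth_params=obs.truth_params,
                    truth_trajectory=obs.truth_trajectory,
                    error=err,
                )
            )
    return summarize(config, outcomes)


def summarize(config: PipelineConfig, outcomes: list[TreatmentOutcome]) -> dict:
    ok = [o for o in outcomes if o.error is None]
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "noise_cv": config.noise_cv,
        "seasons": list(config.seasons),
        "n_treatments": len(outcomes),
        "n_failed": len(outcomes) - len(ok),
        "partial": len(ok) < len(outcomes),
        "treatments": {},
    }
    for o in outcomes:
        entry = {
            "season": o.season,
            "localized_cost": o.localized_cost,
            "measured_yield": o.measured_yield,
            "yield_localized": o.yield_localized,
            "yield_assimilated": o.yield_assimilated,
            "error": o.error,
        }
        if o.assimilation is not None:
            entry["assimilation"] = o.assimilation.to_dict()
            # per-treatment NRMSE of LAI at the observation dates
            loc = PairedSeries(o.lai_localized, o.lai_obs, label="lai", units="-")
            asm = PairedSeries(o.lai_assimilated, o.lai_obs, label="lai", units="-")
            entry["lai_nrmse_localized"] = evaluate(loc).nrmse
            entry["lai_nrmse_assimilated"] = evaluate(asm).nrmse
        summary["treatments"][o.treatment_id] = entry

    # pooled LAI validation over all observation points
    if ok:
        lai_obs = np.concatenate([o.lai_obs for o in ok])
        lai_loc = np.concatenate([o.lai_localized for o in ok])
        lai_asm = np.concatenate([o.lai_assimilated for o in ok])
        rep_loc = evaluate(PairedSeries(lai_loc, lai_obs, label="lai", units="-"))
        rep_asm = evaluate(PairedSeries(lai_asm, lai_obs, label="lai", units="-"))
        summary["lai"] = {
            "localized": rep_loc.to_dict(),
            "assimilated": rep_asm.to_dict(),
            "comparison": compare_runs(rep_loc, rep_asm).to_dict(),
        }
        with_yield = [
            o for o in ok if o.measured_yield is not None and o.yield_assimilated is not None
        ]
        if len(with_yield) >= 2:
            ym = np.array([o.measured_yield for o in with_yield])
            yl = np.array([o.yield_localized for o in with_yield])
            ya = np.array([o.yield_assimilated for o in with_yield])
            yrep_loc = evaluate(PairedSeries(yl, ym, label="yield", units="kg/hm2"))
            yrep_asm = evaluate(PairedSeries(ya, ym, label="yield", units="kg/hm2"))
            summary["yield"] = {
                "localized": yrep_loc.to_dict(),
                "assimilated": yrep_asm.to_dict(),
                "comparison": compare_runs(yrep_loc, yrep_asm).to_dict(),
            }
    return summary


def run_and_write(config: PipelineConfig, base_params: CropParameters | None = None) -> dict:
    """Run the pipeline and write summary JSON + per-treatment CSV."""
    summary = run_pipeline(config, base_params)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary(summary, out / "summary.json")
        rows = []
        for tid, entry in summary["treatments"].items():
            rows.append(
                {
                    "treatment_id": tid,
                    "season": entry["season"],
                    "localized_cost": entry["localized_cost"],
                    "final_cost": entry.get("assimilation", {}).get("final_cost"),
                    "termination_reason": entry.get("assimilation", {}).get(
                        "termination_reason"
                    ),
                    "lai_nrmse_localized": entry.get("lai_nrmse_localized"),
                    "lai_nrmse_assimilated": entry.get("lai_nrmse_assimilated"),
                    "measured_yield": entry["measured_yield"],
                    "yield_localized": entry["yield_localized"],
                    "yield_assimilated": entry["yield_assimilated"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "treatments.csv", index=False)
    return summary


def export_synthetic(config: PipelineConfig, out_dir: Path) -> None:
    """Write the synthetic campaign to CSV (observations, yields, weather,
    truth sidecar) without running any assimilation."""
    base = default_parameters()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for si, label in enumerate(config.seasons):
        design = TreatmentDesign.for_season(label)
        obs_sets, weather = generate_experiment(
            design, base, noise_cv=config.noise_cv, seed=config.seed + 10_000 * si
        )
        tag = label.replace("/", "-")
        weather.to_csv(out_dir / f"weather_{tag}.csv")
        write_observations_csv(obs_sets, out_dir / f"observations_{tag}.csv")
        write_yields_csv(obs_sets, out_dir / f"yields_{tag}.csv")
        write_truth_sidecar(obs_sets, out_dir / f"truth_{tag}.yaml")
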