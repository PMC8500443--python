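"""Synthetic twin of the field/UAV campaigns.

Generates everything the assimilation pipeline consumes when no real data
are available: a seeded daily weather series for a lower-Yangtze winter
wheat season, a 3 sowing-density x 4 nitrogen-level factorial of treatments
with known ("truth") parameter sets, noisy UAV-style LAI observations at
five dates per season, and plot-scale measured yields.

The observation-noise model is deliberately simple: the UAV retrieval step
is represented by multiplicative Gaussian noise on the true LAI with a
configurable coefficient of variation (default 10%), and yields carry 5%
CV measurement noise. Treatment effects enter through the parameter
vector: nitrogen scales the maximum-assimilation table upward with a
saturating response, and sowing density scales the initial LAI
proportionally; both are then clipped into the assimilation bounds.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crop_model import (
    CropParameters,
    StateTrajectory,
    WeatherSeries,
    extract_lai,
    run_simulation,
)
from .errors import ConfigurationError

# Factorial treatment structure of the field campaigns: sowing densities
# (plants m-2) M1-M3 crossed with nitrogen doses (kg ha-1) N1-N4.
DENSITY_LEVELS = (150.0, 225.0, 300.0)
NITROGEN_LEVELS = (0.0, 180.0, 240.0, 300.0)
REFERENCE_DENSITY = 225.0

# Observation calendars of the two seasons (five LAI dates each).
SEASON_CALENDARS = {
    "2015-2016": {
        "sowing": dt.date(2015, 11, 2),
        "observations": (
            dt.date(2016, 1, 7),
            dt.date(2016, 3, 7),
            dt.date(2016, 3, 27),
            dt.date(2016, 4, 12),
            dt.date(2016, 5, 30),
        ),
    },
    "2016-2017": {
        "sowing": dt.date(2016, 11, 14),
        "observations": (
            dt.date(2017, 1, 6),
            dt.date(2017, 2, 28),
            dt.date(2017, 3, 14),
            dt.date(2017, 4, 24),
            dt.date(2017, 5, 19),
        ),
    },
}


@dataclass(frozen=True)
class SeasonSpec:
    """Climate specification for one synthetic growing season.

    Defaults approximate a lower-Yangtze (~32 N) winter-wheat season:
    annual mean temperature 15 degC with 12.5 degC amplitude (coldest in
    mid-January), clear-sky radiation 6.5-19.5 MJ m-2 d-1, AR(1)
    temperature noise and multiplicative cloudiness on radiation.
    """

    start: dt.date
    end: dt.date
    tmean_annual: float = 15.0
    tmean_amplitude: float = 12.5
    coldest_doy: int = 15
    rad_annual: float = 13.0
    rad_amplitude: float = 6.5
    temp_noise_sd: float = 2.0
    temp_noise_rho: float = 0.7
    cloud_fraction: float = 0.6

    def __post_init__(self):
        if self.end < self.start:
            raise ConfigurationError(f"season end {self.end} before start {self.start}")


def season_spec_for(label: str, pad_days: int = 75) -> SeasonSpec:
    """Season spec covering sowing through well past expected maturity."""
    cal = SEASON_CALENDARS[label]
    return SeasonSpec(
        start=cal["sowing"] - dt.timedelta(days=1),
        end=cal["observations"][-1] + dt.timedelta(days=pad_days),
    )


def generate_weather(spec: SeasonSpec, seed: int) -> WeatherSeries:
    """Seeded synthetic daily weather: seasonal sinusoids plus noise.

    Temperature is an annual sinusoid with AR(1) noise; radiation is a
    seasonal sinusoid damped by uniform cloudiness, floored at zero.
    """
    rng = np.random.default_rng(seed)
    n = (spec.end - spec.start).days + 1
    dates = tuple(spec.start + dt.timedelta(days=i) for i in range(n))
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    phase = 2.0 * math.pi * (doy - spec.coldest_doy) / 365.0

    tmean_clim = spec.tmean_annual - spec.tmean_amplitude * np.cos(phase)
    ar = np.zeros(n)
    if spec.temp_noise_sd > 0:
        eps = rng.normal(0.0, spec.temp_noise_sd, size=n)
        for i in range(1, n):
            ar[i] = spec.temp_noise_rho * ar[i - 1] + eps[i]
        ar[0] = eps[0]
    tmean = tmean_clim + ar

    rad_clear = spec.rad_annual - spec.rad_amplitude * np.cos(phase)
    if spec.cloud_fraction > 0:
        cloud = rng.uniform(0.0, spec.cloud_fraction, size=n)
    else:
        cloud = np.zeros(n)
    radiation = np.maximum(0.0, rad_clear * (1.0 - cloud))
    return WeatherSeries(dates=dates, tmean=tmean, radiation=radiation)


@dataclass(frozen=True)
class TreatmentDesign:
    """One season of the factorial field experiment."""

    densities: tuple[float, ...] = DENSITY_LEVELS
    nitrogen_levels: tuple[float, ...] = NITROGEN_LEVELS
    sowing_date: dt.date = SEASON_CALENDARS["2015-2016"]["sowing"]
    observation_dates: tuple[dt.date, ...] = SEASON_CALENDARS["2015-2016"]["observations"]
    season_label: str = "2015-2016"

    def __post_init__(self):
        obs = self.observation_dates
        if any(b <= a for a, b in zip(obs, obs[1:])):
            raise ConfigurationError("observation dates must be strictly increasing")
        if obs and obs[0] <= self.sowing_date:
            raise ConfigurationError("observation dates must follow the sowing date")

    @classmethod
    def for_season(cls, label: str) -> "TreatmentDesign":
        cal = SEASON_CALENDARS[label]
        return cls(
            sowing_date=cal["sowing"],
            observation_dates=cal["observations"],
            season_label=label,
        )

    def treatments(self) -> list[tuple[str, float, float]]:
        """Full factorial as (treatment_id, density, nitrogen) tuples."""
        out = []
        for mi, density in enumerate(self.densities, start=1):
            for ni, nitrogen in enumerate(self.nitrogen_levels, start=1):
                out.append((f"{self.season_label}/M{mi}N{ni}", density, nitrogen))
        return out


@dataclass(frozen=True)
class ObservationSet:
    """Dated UAV-style LAI observations for one treatment, with the
    measured yield and (in synthetic mode) the generating truth."""

    treatment_id: str
    dates: tuple[dt.date, ...]
    lai_uav: np.ndarray
    measured_yield: float | None = None
    truth_params: CropParameters | None = None
    truth_trajectory: StateTrajectory | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.dates) != len(self.lai_uav):
            raise ConfigurationError("observation dates and values differ in length")
        if np.any(self.lai_uav < 0):
            raise ConfigurationError("lai_uav must be >= 0")

    def __len__(self) -> int:
        return len(self.dates)


def nitrogen_amax_multiplier(nitrogen: float) -> float:
    """Saturating nitrogen response applied to the AMAXTB knots.

    0.85 at zero nitrogen rising toward ~1.03 at 300 kg ha-1, so the
    unfertilised plots assimilate visibly less while heavy fertilisation
    saturates.
    """
    return 0.85 + 0.25 * nitrogen / (nitrogen + 120.0)


def make_truth_parameters(
    base: CropParameters,
    density: float,
    nitrogen: float,
    seed: int,
    jitter_cv: float = 0.04,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> CropParameters:
    """Treatment-specific "true" parameter set.

    Deterministic treatment effects (nitrogen scales AMAXTB upward with a
    saturating response; density scales the initial LAI proportionally)
    plus a small seeded log-normal jitter on the five sensitive
    parameters, clipped into the assimilation bounds.
    """
    if bounds is None:
        from .assimilation import DEFAULT_BOUNDS

        bounds = DEFAULT_BOUNDS
    rng = np.random.default_rng(seed)
    sens = base.sensitive_values()
    mult_n = nitrogen_amax_multiplier(nitrogen)
    targets = dict(sens)
    targets["amaxtb1"] = sens["amaxtb1"] * mult_n
    targets["amaxtb1.3"] = sens["amaxtb1.3"] * mult_n
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2)) if jitter_cv > 0 else 0.0
    out = {}
    for key in ("slatb0", "slatb0.5", "slatb2", "amaxtb1", "amaxtb1.3"):
        jitter = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
        lo, hi = bounds[key]
        out[key] = float(np.clip(targets[key] * jitter, lo, hi))
    params = base.with_sensitive(out)
    lai_init = base.lai_init * density / REFERENCE_DENSITY
    from dataclasses import replace

    return replace(params, lai_init=lai_init)


def simulate_observations(
    trajectory: StateTrajectory,
    dates,
    noise_cv: float,
    seed: int,
    truth_params: CropParameters | None = None,
    treatment_id: str = "synthetic",
    yield_noise_cv: float = 0.05,
) -> ObservationSet:
    """Noisy UAV-style observations of a simulated trajectory.

    lai_uav = lai_true * (1 + eps), eps ~ N(0, noise_cv), floored at 0;
    measured yield gets the same multiplicative treatment at
    ``yield_noise_cv``.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    lai_true = extract_lai(trajectory, dates)
    eps = rng.normal(0.0, noise_cv, size=len(lai_true)) if noise_cv > 0 else np.zeros(len(lai_true))
    lai_uav = np.maximum(0.0, lai_true * (1.0 + eps))
    measured_yield = None
    if trajectory.yield_kg_per_hm2 is not None:
        y_eps = rng.normal(0.0, yield_noise_cv) if yield_noise_cv > 0 else 0.0
        measured_yield = max(0.0, trajectory.yield_kg_per_hm2 * (1.0 + y_eps))
    return ObservationSet(
        treatment_id=treatment_id,
        dates=tuple(dates),
        lai_uav=lai_uav,
        measured_yield=measured_yield,
        truth_params=truth_params,
        truth_trajectory=trajectory,
    )


def generate_experiment(
    design: TreatmentDesign,
    base: CropParameters,
    noise_cv: float,
    seed: int,
    weather: WeatherSeries | None = None,
) -> tuple[list[ObservationSet], WeatherSeries]:
    """One full synthetic season: weather plus the 3x4 factorial of
    treatments, each with truth parameters, a truth trajectory, five noisy
    LAI observations and a measured yield."""
    if weather is None:
        weather = generate_weather(season_spec_for(design.season_label), seed=seed)
    obs_sets = []
    for k, (tid, density, nitrogen) in enumerate(design.treatments()):
        truth = make_truth_parameters(base, density, nitrogen, seed=seed + 1000 + k)
        traj = run_simulation(truth, weather, design.sowing_date)
        obs = simulate_observations(
            traj,
            design.observation_dates,
            noise_cv=noise_cv,
            seed=seed + 2000 + k,
            truth_params=truth,
            treatment_id=tid,
        )
        obs_sets.append(obs)
    return obs_sets, weather


# ---------------------------------------------------------------------------
# CSV round trip (schemas shared with the external-data path)
# ---------------------------------------------------------------------------

def write_observations_csv(obs_sets: list[ObservationSet], path) -> None:
    """Write `treatment_id,date,lai_uav` rows; floats use shortest
    round-trip repr so read-back is exact."""
    rows = [
        {"treatment_id": o.treatment_id, "date": d.isoformat(), "lai_uav": repr(float(v))}
        for o in obs_sets
        for d, v in zip(o.dates, o.lai_uav)
    ]
    pd.DataFrame(rows, columns=["treatment_id", "date", "lai_uav"]).to_csv(path, index=False)


def write_yields_csv(obs_sets: list[ObservationSet], path) -> None:
    rows = [
        {"treatment_id": o.treatment_id, "yield_kg_hm2": repr(float(o.measured_yield))}
        for o in obs_sets
        if o.measured_yield is not None
    ]
    pd.DataFrame(rows, columns=["treatment_id", "yield_kg_hm2"]).to_csv(path, index=False)


def write_truth_sidecar(obs_sets: list[ObservationSet], path) -> None:
    """Per-treatment truth parameters (synthetic mode only)."""
    import yaml

    payload = {
        o.treatment_id: o.truth_params.to_dict()
        for o in obs_sets
        if o.truth_params is not None
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
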