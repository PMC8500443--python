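"""Reduced WOFOST-style winter-wheat growth model.

A deterministic, daily-time-step simulator of potential (light- and
temperature-limited) winter-wheat growth. The model keeps the WOFOST state
conventions — development stage DVS on a 0 (emergence) to 1 (anthesis) to
2 (maturity) scale, leaf area index (LAI), and dry-mass pools per organ in
kg/ha — and exposes the WOFOST parameters that matter for LAI
assimilation: the specific-leaf-area table SLATB (ha/kg vs DVS), the
maximum-gross-assimilation table AMAXTB (kg CO2/ha/h vs DVS), the
thermal-time constants TSUMEM/TSUM1/TSUM2 and the assimilate conversion
efficiency CVS.

The daily carbon budget is deliberately compact: gross assimilation from
Beer-law light interception with a radiation limitation, Q10 maintenance
respiration, conversion to structural dry matter by CVS, DVS-indexed
partitioning over root/leaf/stem/storage, SLA-driven leaf-area growth, and
a post-anthesis relative death rate for leaves. Integration is explicit
Euler at a one-day step with state floors at zero, WOFOST's own convention.
There is no photoperiod, vernalization, water balance or nutrient dynamics;
treatment effects enter through the parameter vector.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, IncompleteSeasonError, OutOfRangeDateError

#: kg CH2O formed per kg CO2 assimilated (molar mass ratio 30/44).
CH2O_PER_CO2 = 30.0 / 44.0

ORGANS = ("leaf", "stem", "storage", "root")


# ---------------------------------------------------------------------------
# Parameter tables (AFGEN convention)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterTable:
    """A piecewise-linear parameter-vs-DVS table (the AFGEN convention).

    Knots are ``(dvs, value)`` pairs, strictly ascending in DVS; lookups
    interpolate linearly between bracketing knots and clamp to the end
    values outside the knot range.
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.knots) == 0:
            raise ConfigurationError("parameter table has no knots")
        dvs = [k[0] for k in self.knots]
        vals = [k[1] for k in self.knots]
        if any(not math.isfinite(d) or not math.isfinite(v) for d, v in self.knots):
            raise ConfigurationError("parameter table contains non-finite entries")
        if any(b <= a for a, b in zip(dvs, dvs[1:])):
            raise ConfigurationError("parameter table knots must be strictly ascending in DVS")
        if any(v < 0 for v in vals):
            raise ConfigurationError("parameter table values must be >= 0")

    def __call__(self, dvs: float) -> float:
        return afgen_interp(self, dvs)

    def value_at(self, dvs: float) -> float:
        """Exact table value at a knot DVS (raises if ``dvs`` is not a knot)."""
        for d, v in self.knots:
            if d == dvs:
                return v
        raise KeyError(f"no knot at DVS {dvs}")

    def with_value_at(self, dvs: float, value: float) -> "ParameterTable":
        """Return a copy with the knot at ``dvs`` replaced by ``value``."""
        if all(d != dvs for d, _ in self.knots):
            raise KeyError(f"no knot at DVS {dvs}")
        return ParameterTable(tuple((d, value if d == dvs else v) for d, v in self.knots))


def afgen_interp(table: ParameterTable, dvs: float) -> float:
    """Piecewise-linear table lookup with clamped extrapolation."""
    if not math.isfinite(dvs):
        raise ConfigurationError(f"non-finite DVS {dvs!r} in table lookup")
    knots = table.knots
    if dvs <= knots[0][0]:
        return knots[0][1]
    if dvs >= knots[-1][0]:
        return knots[-1][1]
    for (d0, v0), (d1, v1) in zip(knots, knots[1:]):
        if d0 <= dvs <= d1:
            return v0 + (v1 - v0) * (dvs - d0) / (d1 - d0)
    raise AssertionError("unreachable: knots are ascending")  # pragma: no cover


# ---------------------------------------------------------------------------
# Crop parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropParameters:
    """The full tunable parameter vector of the reduced model.

    The five assimilation-sensitive parameters live in ``slatb`` (knots at
    DVS 0, 0.5, 2) and ``amaxtb`` (knots at DVS 1, 1.3); everything else is
    auxiliary (phenology constants, conversion efficiency, canopy and
    respiration constants, partitioning tables).
    """

    slatb: ParameterTable            # specific leaf area, ha leaf kg-1 leaf
    amaxtb: ParameterTable           # max gross CO2 assimilation, kg CO2 ha-1 h-1
    tsumem: float                    # deg C d, sowing -> emergence
    tsum1: float                     # deg C d, emergence -> anthesis
    tsum2: float                     # deg C d, anthesis -> maturity
    cvs: float                       # kg DM per kg CH2O, (0, 1]
    k_ext: float = 0.6               # canopy light extinction coefficient
    partition_tables: dict[str, ParameterTable] = field(default_factory=dict)
    rdr_base: float = 0.025          # base relative leaf death rate, d-1
    lai_init: float = 0.05           # LAI at emergence
    t_base: float = 0.0              # base temperature for thermal time, deg C
    f_day: float = 12.0              # effective assimilating hours per day
    r_ref: float = 15.0              # radiation saturation level, MJ m-2 d-1
    q10: float = 2.0
    t_ref: float = 25.0              # reference temperature for maintenance, deg C
    stem_trans_rate: float = 0.0     # post-anthesis stem->storage translocation, d-1
    maint_coefs: dict[str, float] = field(
        default_factory=lambda: {"leaf": 0.03, "stem": 0.015, "storage": 0.01, "root": 0.01}
    )

    def __post_init__(self):
        if not (self.tsumem > 0 and self.tsum1 > 0 and self.tsum2 > 0):
            raise ConfigurationError("tsumem, tsum1, tsum2 must all be positive")
        if not (0 < self.cvs <= 1):
            raise ConfigurationError(f"cvs must be in (0, 1], got {self.cvs}")
        if self.lai_init <= 0:
            raise ConfigurationError("lai_init must be positive")
        if set(self.partition_tables) != set(ORGANS):
            raise ConfigurationError(f"partition_tables must have keys {ORGANS}")
        for dvs in np.linspace(0.0, 2.0, 201):
            fracs = [self.partition_tables[o](float(dvs)) for o in ORGANS]
            if any(f < -1e-12 or f > 1 + 1e-12 for f in fracs):
                raise ConfigurationError(f"partition fraction outside [0,1] at DVS {dvs}")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"partition fractions sum to {sum(fracs)} != 1 at DVS {dvs}"
                )

    # -- the five sensitive parameters -------------------------------------

    def sensitive_values(self) -> dict[str, float]:
        """Current values of SLATB0, SLATB0.5, SLATB2, AMAXTB1, AMAXTB1.3."""
        return {
            "slatb0": self.slatb.value_at(0.0),
            "slatb0.5": self.slatb.value_at(0.5),
            "slatb2": self.slatb.value_at(2.0),
            "amaxtb1": self.amaxtb.value_at(1.0),
            "amaxtb1.3": self.amaxtb.value_at(1.3),
        }

    def with_sensitive(self, values: dict[str, float]) -> "CropParameters":
        """Return a copy with some of the five sensitive parameters replaced."""
        slatb, amaxtb = self.slatb, self.amaxtb
        stage = {"slatb0": 0.0, "slatb0.5": 0.5, "slatb2": 2.0}
        for key, val in values.items():
            if key in stage:
                slatb = slatb.with_value_at(stage[key], val)
            elif key == "amaxtb1":
                amaxtb = amaxtb.with_value_at(1.0, val)
            elif key == "amaxtb1.3":
                amaxtb = amaxtb.with_value_at(1.3, val)
            else:
                raise KeyError(f"unknown sensitive parameter {key!r}")
        return replace(self, slatb=slatb, amaxtb=amaxtb)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "slatb": [[k, v] for k, v in self.slatb.knots],
            "amaxtb": [[k, v] for k, v in self.amaxtb.knots],
            "tsumem": self.tsumem,
            "tsum1": self.tsum1,
            "tsum2": self.tsum2,
            "cvs": self.cvs,
            "k_ext": self.k_ext,
            "rdr_base": self.rdr_base,
            "lai_init": self.lai_init,
            "t_base": self.t_base,
            "f_day": self.f_day,
            "r_ref": self.r_ref,
            "q10": self.q10,
            "t_ref": self.t_ref,
            "stem_trans_rate": self.stem_trans_rate,
        }
        dvs_grid = [k for k, _ in self.partition_tables["leaf"].knots]
        d["partition_dvs"] = dvs_grid
        for organ in ORGANS:
            d[f"partition_{organ}"] = [v for _, v in self.partition_tables[organ].knots]
        for organ in ORGANS:
            d[f"maint_{organ}"] = self.maint_coefs[organ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CropParameters":
        try:
            dvs_grid = d["partition_dvs"]
            partition = {
                organ: ParameterTable(
                    tuple(zip(map(float, dvs_grid), map(float, d[f"partition_{organ}"])))
                )
                for organ in ORGANS
            }
            return cls(
                slatb=ParameterTable(tuple((float(a), float(b)) for a, b in d["slatb"])),
                amaxtb=ParameterTable(tuple((float(a), float(b)) for a, b in d["amaxtb"])),
                tsumem=float(d["tsumem"]),
                tsum1=float(d["tsum1"]),
                tsum2=float(d["tsum2"]),
                cvs=float(d["cvs"]),
                k_ext=float(d["k_ext"]),
                partition_tables=partition,
                rdr_base=float(d["rdr_base"]),
                lai_init=float(d["lai_init"]),
                t_base=float(d["t_base"]),
                f_day=float(d["f_day"]),
                r_ref=float(d["r_ref"]),
                q10=float(d["q10"]),
                t_ref=float(d["t_ref"]),
                stem_trans_rate=float(d.get("stem_trans_rate", 0.0)),
                maint_coefs={o: float(d[f"maint_{o}"]) for o in ORGANS},
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing crop parameter key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "CropParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_parameters() -> CropParameters:
    """The localized winter-wheat parameter set shipped with the package."""
    text = resources.files("cropassim.data").joinpath("winter_wheat.yaml").read_text()
    return CropParameters.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Weather forcing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherSeries:
    """Daily weather forcing: date, mean temperature (deg C), global radiation
    (MJ m-2 d-1). Dates are consecutive with no gaps."""

    dates: tuple[dt.date, ...]
    tmean: np.ndarray
    radiation: np.ndarray

    def __post_init__(self):
        if len(self.dates) == 0:
            raise ConfigurationError("weather series is empty")
        if len(self.dates) != len(self.tmean) or len(self.dates) != len(self.radiation):
            raise ConfigurationError("weather columns have unequal lengths")
        for a, b in zip(self.dates, self.dates[1:]):
            if (b - a).days != 1:
                raise ConfigurationError(f"weather dates not consecutive at {a} -> {b}")
        if np.any(self.radiation < 0):
            raise ConfigurationError("radiation must be >= 0")

    def __len__(self) -> int:
        return len(self.dates)

    def index_of(self, date: dt.date) -> int:
        offset = (date - self.dates[0]).days
        if offset < 0 or offset >= len(self.dates):
            raise OutOfRangeDateError(f"date {date} outside weather span")
        return offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": list(self.dates), "tmean_c": self.tmean, "radiation_mj_m2": self.radiation}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = [d.isoformat() for d in df["date"]]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"date", "tmean_c", "radiation_mj_m2"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"weather CSV must have columns {sorted(required)}")
        dates = tuple(dt.date.fromisoformat(str(d)) for d in df["date"])
        return cls(
            dates=dates,
            tmean=df["tmean_c"].to_numpy(float),
            radiation=df["radiation_mj_m2"].to_numpy(float),
        )


# ---------------------------------------------------------------------------
# State and trajectory
# ---------------------------------------------------------------------------

@dataclass
class CropState:
    """Mutable daily state advanced by the step functions."""

    dvs: float = 0.0
    tsum_pre: float = 0.0            # thermal time accumulated toward emergence
    emerged: bool = False
    lai: float = 0.0
    w_leaf: float = 0.0
    w_stem: float = 0.0
    w_storage: float = 0.0
    w_root: float = 0.0

    @property
    def tagp(self) -> float:
        """Total above-ground production: leaf + stem + storage pools."""
        return self.w_leaf + self.w_stem + self.w_storage


@dataclass(frozen=True)
class StateTrajectory:
    """Daily simulated state from sowing through the end of the forcing.

    ``yield_kg_per_hm2`` is the storage-organ mass on the maturity date
    (kg per hectare), or ``None`` if maturity was not reached.
    """

    dates: tuple[dt.date, ...]
    dvs: np.ndarray
    lai: np.ndarray
    w_leaf: np.ndarray
    w_stem: np.ndarray
    w_storage: np.ndarray
    w_root: np.ndarray
    tagp: np.ndarray
    emergence_date: dt.date | None
    anthesis_date: dt.date | None
    maturity_date: dt.date | None
    yield_kg_per_hm2: float | None
    complete: bool = True

    def index_of(self, date: dt.date) -> int:
        offset = (date - self.dates[0]).days
        if offset < 0 or offset >= len(self.dates):
            raise OutOfRangeDateError(
                f"date {date} outside simulated span {self.dates[0]}..{self.dates[-1]}"
            )
        return offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": list(self.dates),
                "dvs": self.dvs,
                "lai": self.lai,
                "w_leaf": self.w_leaf,
                "w_stem": self.w_stem,
                "w_storage": self.w_storage,
                "w_root": self.w_root,
                "tagp": self.tagp,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = [d.isoformat() for d in df["date"]]
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Step functions
# ---------------------------------------------------------------------------

def step_phenology(state: CropState, tmean: float, params: CropParameters) -> CropState:
    """Advance thermal-time phenology by one day (in place; returns state).

    Effective temperature max(0, tmean - t_base) accumulates toward TSUMEM
    before emergence; after emergence DVS advances at eff/TSUM1 below
    anthesis and eff/TSUM2 between anthesis and maturity, capped at 2.
    """
    eff = max(0.0, tmean - params.t_base)
    if not state.emerged:
        state.tsum_pre += eff
        if state.tsum_pre >= params.tsumem:
            state.emerged = True
            state.lai = params.lai_init
            state.w_leaf = params.lai_init / params.slatb(0.0)
        return state
    if state.dvs < 1.0:
        state.dvs = min(2.0, state.dvs + eff / params.tsum1)
    elif state.dvs < 2.0:
        state.dvs = min(2.0, state.dvs + eff / params.tsum2)
    return state


def step_growth(
    state: CropState, tmean: float, radiation: float, params: CropParameters
) -> CropState:
    """Advance the daily carbon budget by one day (in place; returns state).

    Gross assimilation follows Beer-law light interception scaled by an
    effective day length and a radiation limitation min(1, R/R_ref);
    maintenance respiration has a Q10 temperature response; positive net
    assimilate is converted by CVS and partitioned by the DVS-indexed
    tables. Leaf area grows as SLA(DVS) x leaf-mass increment (SLA in
    ha kg-1 against mass in kg ha-1, hence dimensionless LAI) and senesces
    post-anthesis at rdr_base x max(0, DVS - 1).
    """
    if not state.emerged:
        return state
    dvs = state.dvs
    growing = dvs < 2.0
    if growing:
        amax = params.amaxtb(dvs)
        f_rad = min(1.0, radiation / params.r_ref)
        a_co2 = amax * params.f_day * (1.0 - math.exp(-params.k_ext * state.lai)) * f_rad
        a_ch2o = a_co2 * CH2O_PER_CO2
        maint = (params.q10 ** ((tmean - params.t_ref) / 10.0)) * (
            params.maint_coefs["leaf"] * state.w_leaf
            + params.maint_coefs["stem"] * state.w_stem
            + params.maint_coefs["storage"] * state.w_storage
            + params.maint_coefs["root"] * state.w_root
        )
        growth = params.cvs * max(0.0, a_ch2o - maint)
        d_leaf = growth * params.partition_tables["leaf"](dvs)
        d_stem = growth * params.partition_tables["stem"](dvs)
        d_storage = growth * params.partition_tables["storage"](dvs)
        d_root = growth * params.partition_tables["root"](dvs)
        dlai_growth = params.slatb(dvs) * d_leaf
    else:
        d_leaf = d_stem = d_storage = d_root = 0.0
        dlai_growth = 0.0

    rdr = params.rdr_base * max(0.0, dvs - 1.0)
    rdr = min(rdr, 1.0)  # death never exceeds the available pool
    dlai_death = rdr * state.lai
    dw_leaf_death = rdr * state.w_leaf

    # post-anthesis remobilisation of stem reserves into the storage organ
    # (mass-conserving transfer, a large sink for wheat grain fill)
    trans = 0.0
    if growing and dvs > 1.0:
        trans = min(params.stem_trans_rate, 1.0) * state.w_stem

    state.lai = max(0.0, state.lai + dlai_growth - dlai_death)
    state.w_leaf = max(0.0, state.w_leaf + d_leaf - dw_leaf_death)
    state.w_stem += d_stem - trans
    state.w_storage += d_storage + trans
    state.w_root += d_root
    return state


def run_simulation(
    params: CropParameters,
    weather: WeatherSeries,
    sowing_date: dt.date,
    require_maturity: bool = True,
) -> StateTrajectory:
    """Run the model from sowing through the end of the weather forcing.

    Deterministic: identical inputs give bit-identical trajectories. Raises
    :class:`IncompleteSeasonError` (carrying the partial trajectory) if the
    forcing ends before maturity and ``require_maturity`` is true.
    """
    try:
        start = weather.index_of(sowing_date)
    except OutOfRangeDateError as exc:
        raise ConfigurationError(f"sowing date {sowing_date} outside weather span") from exc

    n = len(weather) - start
    dates = weather.dates[start:]
    dvs = np.empty(n)
    lai = np.empty(n)
    w_leaf = np.empty(n)
    w_stem = np.empty(n)
    w_storage = np.empty(n)
    w_root = np.empty(n)
    tagp = np.empty(n)

    state = CropState()
    emergence_date = anthesis_date = maturity_date = None
    yield_value = None

    for i in range(n):
        t = float(weather.tmean[start + i])
        r = float(weather.radiation[start + i])
        was_emerged = state.emerged
        pre_dvs = state.dvs
        if state.emerged:
            step_growth(state, t, r, params)
        step_phenology(state, t, params)
        if state.emerged and not was_emerged:
            emergence_date = dates[i]
        if was_emerged and pre_dvs < 1.0 <= state.dvs and anthesis_date is None:
            anthesis_date = dates[i]
        if was_emerged and pre_dvs < 2.0 <= state.dvs and maturity_date is None:
            maturity_date = dates[i]
            yield_value = state.w_storage
        dvs[i] = state.dvs
        lai[i] = state.lai
        w_leaf[i] = state.w_leaf
        w_stem[i] = state.w_stem
        w_storage[i] = state.w_storage
        w_root[i] = state.w_root
        tagp[i] = state.tagp

    complete = maturity_date is not None
    traj = StateTrajectory(
        dates=tuple(dates),
        dvs=dvs,
        lai=lai,
        w_leaf=w_leaf,
        w_stem=w_stem,
        w_storage=w_storage,
        w_root=w_root,
        tagp=tagp,
        emergence_date=emergence_date,
        anthesis_date=anthesis_date,
        maturity_date=maturity_date,
        yield_kg_per_hm2=yield_value,
        complete=complete,
    )
    if require_maturity and not complete:
        raise IncompleteSeasonError(
            f"weather forcing ends {weather.dates[-1]} before maturity "
            f"(final DVS {state.dvs:.3f})",
            partial_trajectory=traj,
        )
    return traj


def extract_lai(trajectory: StateTrajectory, dates: Sequence[dt.date]) -> np.ndarray:
    """Simulated LAI at the requested dates, order preserved."""
    return np.array([trajectory.lai[trajectory.index_of(d)] for d in dates])
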