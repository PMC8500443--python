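"""Least-squares assimilation of LAI observations into the crop model.

The cost function is the sum of squared differences between model LAI and
UAV-retrieved LAI at the observation dates,

    F(I1..I5) = sum_i (LAI_M,i - LAI_UAV,i)^2 ,

minimised over the five sensitive parameters SLATB0, SLATB0.5, SLATB2,
AMAXTB1 and AMAXTB1.3 inside fixed bounds, all other crop parameters held
at their localized values. The search is a multi-start bounded
least-squares: the localized values seed the first start, the remaining
starts are drawn uniformly from the initial-value ranges, and each start
is refined by a trust-region-reflective minimisation that honours the
bounds. The search stops when the first of three conditions fires:

1. the best cost has not improved by at least 0.0001% (relative) over
   five consecutive cycles;
2. the cumulative number of forward-model evaluations exceeds 10000;
3. the five optimized parameters all sit at a bound.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .crop_model import CropParameters, WeatherSeries, extract_lai, run_simulation
from .errors import ConfigurationError, CropAssimError, OptimizationFailureError
from .synthetic import ObservationSet

SENSITIVE_NAMES = ("slatb0", "slatb0.5", "slatb2", "amaxtb1", "amaxtb1.3")

# Search bounds: the union of the published initial-value and
# optimized-value ranges per parameter. AMAXTB1 has a single initial value
# (38.83), so its search range is the optimized 35-45.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "slatb0": (0.001, 0.00212),
    "slatb0.5": (0.0011, 0.00215),
    "slatb2": (0.0007, 0.0012),
    "amaxtb1": (35.0, 45.0),
    "amaxtb1.3": (30.0, 60.0),
}

# Uniform sampling ranges for the starts: the initial-value ranges
# (AMAXTB1's single value is a degenerate range).
DEFAULT_START_RANGES: dict[str, tuple[float, float]] = {
    "slatb0": (0.001, 0.00212),
    "slatb0.5": (0.00125, 0.00215),
    "slatb2": (0.0007, 0.0012),
    "amaxtb1": (38.83, 38.83),
    "amaxtb1.3": (30.0, 60.0),
}

BOUND_TOL = 1e-9


@dataclass(frozen=True)
class OptimizationConfig:
    """Bounds, sampling ranges and termination settings for the search."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    start_sampling: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_START_RANGES)
    )
    improvement_tol: float = 1e-6       # 0.0001% relative improvement
    patience: int = 5                   # consecutive non-improving cycles
    max_iterations: int = 10000         # cumulative forward-model evaluations
    max_nfev_per_cycle: int = 60        # trust-region iterations per start
    n_restarts: int = 40                # hard cap on start cycles
    seed: int = 0
    shape_policy: str = "warn"          # see enforce_shape
    record_candidates: bool = False

    def __post_init__(self):
        for name in SENSITIVE_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ConfigurationError(f"bounds for {name} must satisfy lower < upper")
        if self.improvement_tol <= 0:
            raise ConfigurationError("improvement_tol must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class AssimilationResult:
    optimized_params: CropParameters
    sensitive_values: dict[str, float]
    final_cost: float
    termination_reason: str             # converged_patience | max_iterations | all_at_bounds
    iteration_trace: list[tuple[int, float]]   # (cycle, best cost so far)
    n_obs_used: int
    n_evaluations: int
    n_cycles: int
    shape_ok: bool
    evaluated_candidates: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "sensitive_values": dict(self.sensitive_values),
            "final_cost": self.final_cost,
            "termination_reason": self.termination_reason,
            "n_obs_used": self.n_obs_used,
            "n_evaluations": self.n_evaluations,
            "n_cycles": self.n_cycles,
            "shape_ok": self.shape_ok,
            "iteration_trace": [[c, v] for c, v in self.iteration_trace],
        }


class ShapeWarning(UserWarning):
    """Candidate SLATB values violate the expected decrease with DVS."""


def enforce_shape(
    slatb0: float, slatb05: float, slatb2: float, policy: str = "warn"
) -> tuple[tuple[float, float, float], bool]:
    """Check the agronomic shape constraint slatb2 <= slatb0.5 and
    slatb2 <= slatb0 (specific leaf area falls as the crop matures).

    Values are never modified: under ``policy='warn'`` a violation emits a
    :class:`ShapeWarning`; under ``policy='reject'`` it raises.
    Returns the triple unchanged plus a validity flag.
    """
    ok = slatb2 <= slatb05 and slatb2 <= slatb0
    if not ok:
        msg = (
            f"SLATB shape violation: slatb2={slatb2} exceeds "
            f"slatb0={slatb0} or slatb0.5={slatb05}"
        )
        if policy == "reject":
            raise CropAssimError(msg)
        warnings.warn(msg, ShapeWarning, stacklevel=2)
    return (slatb0, slatb05, slatb2), ok


def cost_from_series(lai_m: np.ndarray, lai_uav: np.ndarray) -> float:
    """Sum of squared differences between simulated and observed LAI."""
    lai_m = np.asarray(lai_m, dtype=float)
    lai_uav = np.asarray(lai_uav, dtype=float)
    if lai_m.shape != lai_uav.shape:
        raise ConfigurationError("LAI series must have equal length")
    d = lai_m - lai_uav
    return float(np.sum(d * d))


def cost(
    params: CropParameters,
    obs: ObservationSet,
    weather: WeatherSeries,
    sowing_date: dt.date,
) -> float:
    """Evaluate the cost function by running the crop model."""
    try:
        traj = run_simulation(params, weather, sowing_date, require_maturity=False)
        lai_m = extract_lai(traj, obs.dates)
    except CropAssimError as exc:
        raise CropAssimError(
            f"simulation failed for treatment {obs.treatment_id!r}: {exc}"
        ) from exc
    return cost_from_series(lai_m, obs.lai_uav)


def _embed(base: CropParameters, x: np.ndarray) -> CropParameters:
    return base.with_sensitive(dict(zip(SENSITIVE_NAMES, map(float, x))))


def optimize(
    obs: ObservationSet,
    weather: WeatherSeries,
    base_params: CropParameters,
    config: OptimizationConfig | None = None,
    sowing_date: dt.date | None = None,
) -> AssimilationResult:
    """Multi-start bounded minimisation of the LAI cost function.

    ``sowing_date`` defaults to the start of the weather series. The
    localized (base) values seed the first cycle, so the assimilated cost
    never exceeds the localized cost; subsequent cycles start from uniform
    draws over the configured sampling ranges.
    """
    if config is None:
        config = OptimizationConfig()
    if sowing_date is None:
        sowing_date = weather.dates[0]
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.bounds[k][0] for k in SENSITIVE_NAMES])
    hi = np.array([config.bounds[k][1] for k in SENSITIVE_NAMES])
    obs_vec = np.asarray(obs.lai_uav, dtype=float)

    n_eval = 0
    candidates: list[np.ndarray] = []

    def residual(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        if config.record_candidates:
            candidates.append(np.array(x))
        traj = run_simulation(_embed(base_params, x), weather, sowing_date,
                              require_maturity=False)
        return extract_lai(traj, obs.dates) - obs_vec

    def draw_start() -> np.ndarray:
        x = np.empty(len(SENSITIVE_NAMES))
        for i, name in enumerate(SENSITIVE_NAMES):
            a, b = config.start_sampling[name]
            x[i] = a if a == b else rng.uniform(a, b)
        return np.clip(x, lo, hi)

    base_x = np.array([base_params.sensitive_values()[k] for k in SENSITIVE_NAMES])
    starts_exhausted = False

    best_cost = np.inf
    best_x: np.ndarray | None = None
    trace: list[tuple[int, float]] = []
    no_improve = 0
    cycle = 0
    reason = None
    any_success = False

    while reason is None:
        cycle += 1
        x0 = np.clip(base_x, lo, hi) if cycle == 1 else draw_start()
        budget = config.max_iterations - n_eval
        prev_best = best_cost
        if budget >= 1:
            try:
                res = least_squares(
                    residual,
                    x0,
                    bounds=(lo, hi),
                    x_scale=hi - lo,
                    diff_step=1e-4,
                    ftol=config.improvement_tol,
                    xtol=1e-10,
                    gtol=1e-12,
                    max_nfev=min(budget, config.max_nfev_per_cycle),
                )
                any_success = True
                c = 2.0 * float(res.cost)  # scipy cost is 0.5 * sum r^2
                # a later start displaces the incumbent only when it beats it
                # by at least the improvement tolerance, so near-degenerate
                # ties do not swap in unconstrained parameter combinations
                if best_x is None or c < best_cost * (1.0 - config.improvement_tol):
                    best_cost = c
                    best_x = np.clip(res.x, lo, hi)
            except CropAssimError:
                pass
        trace.append((cycle, best_cost))

        # termination conditions, in the order they are listed above but
        # with the hard iteration cap checked first so a tiny budget is
        # reported as such
        if n_eval >= config.max_iterations:
            reason = "max_iterations"
            break
        if best_x is not None and np.all(
            (best_x - lo <= BOUND_TOL) | (hi - best_x <= BOUND_TOL)
        ):
            reason = "all_at_bounds"
            break
        if not np.isfinite(prev_best):
            improved = np.isfinite(best_cost)  # first accepted solution
        else:
            improved = (
                prev_best > 0
                and (prev_best - best_cost) / prev_best >= config.improvement_tol
            )
        no_improve = 0 if improved else no_improve + 1
        if no_improve >= config.patience:
            reason = "converged_patience"
            break
        if cycle >= config.n_restarts:
            # sampling budget exhausted without further improvement
            reason = "converged_patience"
            break

    if best_x is None or not any_success:
        raise OptimizationFailureError(
            f"all {cycle} optimization starts failed for treatment {obs.treatment_id!r}"
        )

    # tie-break among (near-)equal-cost optima: parameters the observations do
    # not constrain at the solution are returned to their localized values,
    # one at a time, whenever doing so leaves the cost unchanged within the
    # improvement tolerance
    base_clipped = np.clip(base_x, lo, hi)
    for i in range(len(best_x)):
        if best_x[i] == base_clipped[i]:
            continue
        x_try = best_x.copy()
        x_try[i] = base_clipped[i]
        try:
            c_try = float(np.sum(residual(x_try) ** 2))
        except CropAssimError:
            continue
        if c_try <= best_cost + max(abs(best_cost) * config.improvement_tol, 1e-15):
            best_x = x_try
            best_cost = min(best_cost, c_try)
    trace.append((cycle + 1, best_cost))

    sens = dict(zip(SENSITIVE_NAMES, map(float, best_x)))
    _, shape_ok = enforce_shape(
        sens["slatb0"], sens["slatb0.5"], sens["slatb2"], policy=config.shape_policy
    )
    return AssimilationResult(
        optimized_params=_embed(base_params, best_x),
        sensitive_values=sens,
        final_cost=best_cost,
        termination_reason=reason,
        iteration_trace=trace,
        n_obs_used=len(obs),
        n_evaluations=n_eval,
        n_cycles=cycle,
        shape_ok=shape_ok,
        evaluated_candidates=np.array(candidates) if config.record_candidates else None,
    )
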