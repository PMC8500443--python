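"""Validation statistics for paired simulated/measured series.

Four statistics are used throughout: the coefficient of determination
about the 1:1 line, R2 = 1 - SSE/SST with SSE = sum (Y_i - X_i)^2 and
SST = sum (X_i - Xbar)^2 (this measures agreement with the measurements
directly and can be negative, unlike regression R2); the coefficient of
residual mass CRM = (sum Y - sum X)/sum X, positive when the model
overestimates; RMSE; and NRMSE = RMSE/Xbar x 100%, with the accuracy
classes <=10% extremely high, <=20% high, <=30% medium, >30% low.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError


class AccuracyClass(str, Enum):
    EXTREMELY_HIGH = "extremely_high"
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


@dataclass(frozen=True)
class PairedSeries:
    """Simulated values Y_i paired with measured values X_i."""

    simulated: np.ndarray
    measured: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        sim = np.asarray(self.simulated, dtype=float)
        meas = np.asarray(self.measured, dtype=float)
        object.__setattr__(self, "simulated", sim)
        object.__setattr__(self, "measured", meas)
        if sim.shape != meas.shape or sim.ndim != 1:
            raise ConfigurationError("paired series must be 1-D and equal length")
        if len(sim) < 2:
            raise ConfigurationError("paired series needs at least 2 points")
        if not (np.all(np.isfinite(sim)) and np.all(np.isfinite(meas))):
            raise ConfigurationError("paired series contains non-finite values")

    def __len__(self) -> int:
        return len(self.simulated)


@dataclass(frozen=True)
class EvaluationReport:
    r2: float
    crm: float
    rmse: float
    nrmse: float                    # percent
    accuracy_class: AccuracyClass
    n: int
    label: str = ""
    units: str = ""

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "crm": self.crm,
            "rmse": self.rmse,
            "nrmse_pct": self.nrmse,
            "accuracy_class": self.accuracy_class.value,
            "n": self.n,
            "label": self.label,
            "units": self.units,
        }


def r_squared(pairs: PairedSeries) -> float:
    """1 - SSE/SST about the 1:1 line; may be negative."""
    x, y = pairs.measured, pairs.simulated
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError("R2 undefined: measured series is constant")
    sse = float(np.sum((y - x) ** 2))
    return 1.0 - sse / sst


def regression_r_squared(pairs: PairedSeries) -> float:
    """Ordinary least-squares regression R2 (for scatter plots only)."""
    x, y = pairs.measured, pairs.simulated
    if np.all(x == x[0]):
        raise UndefinedStatisticError("regression R2 undefined: measured series is constant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def crm(pairs: PairedSeries) -> float:
    """(sum Y - sum X)/sum X; positive means overestimation."""
    sx = float(np.sum(pairs.measured))
    if sx == 0.0:
        raise UndefinedStatisticError("CRM undefined: measured values sum to zero")
    return (float(np.sum(pairs.simulated)) - sx) / sx


def rmse(pairs: PairedSeries) -> float:
    d = pairs.simulated - pairs.measured
    return float(np.sqrt(np.mean(d * d)))


def nrmse(pairs: PairedSeries) -> float:
    """RMSE normalised by the measured mean, in percent."""
    xbar = float(np.mean(pairs.measured))
    if xbar <= 0.0:
        raise UndefinedStatisticError(f"NRMSE undefined: measured mean {xbar} <= 0")
    return rmse(pairs) / xbar * 100.0


def classify_accuracy(nrmse_pct: float) -> AccuracyClass:
    """Map an NRMSE percentage to its accuracy class (boundaries 10/20/30%
    belong to the better class)."""
    if nrmse_pct < 0:
        raise UndefinedStatisticError(f"NRMSE cannot be negative, got {nrmse_pct}")
    if nrmse_pct <= 10.0:
        return AccuracyClass.EXTREMELY_HIGH
    if nrmse_pct <= 20.0:
        return AccuracyClass.HIGH
    if nrmse_pct <= 30.0:
        return AccuracyClass.MEDIUM
    return AccuracyClass.LOW


def evaluate(pairs: PairedSeries) -> EvaluationReport:
    """All four statistics plus the accuracy class for one paired series."""
    n = nrmse(pairs)
    return EvaluationReport(
        r2=r_squared(pairs),
        crm=crm(pairs),
        rmse=rmse(pairs),
        nrmse=n,
        accuracy_class=classify_accuracy(n),
        n=len(pairs),
        label=pairs.label,
        units=pairs.units,
    )


@dataclass(frozen=True)
class RunComparison:
    """Deltas (assimilated minus localized) for the four statistics."""

    label: str
    d_r2: float
    d_crm: float
    d_rmse: float
    d_nrmse: float
    improved: bool                  # NRMSE decreased

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "delta_r2": self.d_r2,
            "delta_crm": self.d_crm,
            "delta_rmse": self.d_rmse,
            "delta_nrmse": self.d_nrmse,
            "improved": self.improved,
        }


def compare_runs(localized: EvaluationReport, assimilated: EvaluationReport) -> RunComparison:
    """Assimilated-vs-localized comparison for the same variable."""
    if (localized.label, localized.units, localized.n) != (
        assimilated.label,
        assimilated.units,
        assimilated.n,
    ):
        raise ConfigurationError(
            "cannot compare reports for different variables/units/sample sizes: "
            f"{(localized.label, localized.units, localized.n)} vs "
            f"{(assimilated.label, assimilated.units, assimilated.n)}"
        )
    return RunComparison(
        label=localized.label,
        d_r2=assimilated.r2 - localized.r2,
        d_crm=assimilated.crm - localized.crm,
        d_rmse=assimilated.rmse - localized.rmse,
        d_nrmse=assimilated.nrmse - localized.nrmse,
        improved=assimilated.nrmse < localized.nrmse,
    )
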