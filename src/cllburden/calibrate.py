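"""Calibration of designated free parameters to observable targets.

The original model was calibrated with a spreadsheet solver so that the
warm-up produced a population matching real-world observations
(prevalence at a reference time, drug utilization).  Here the same step
is a bounded derivative-free minimization of the weighted relative
squared error

    sum_i  w_i * ((model_i - target_i) / target_i)^2

over a named subset of the calibrated probabilities, evaluated against
the warm-up phase only.  Relative error keeps counts (prevalence,
deaths) and proportions (on-drug share) commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .context import ModelContext, run_warmup
from .policy import FIXED

OBSERVABLES = ("prevalence_at_year", "on_drug_share_at_year", "deaths_in_year")

#: parameters eligible for calibration, with default search bounds
FREE_PARAMETERS: dict[str, tuple[float, float]] = {
    "p_ww_to_tx_per_cycle": (1e-4, 0.2),
    "p_discontinue_1L_per_cycle": (0.0, 0.1),
    "p_discontinue_2L_per_cycle": (0.0, 0.1),
    "p_background_death_per_cycle": (1e-4, 0.05),
}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationTarget:
    observable: str
    year: int
    value: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise CalibrationError(
                f"unknown observable {self.observable!r}; expected one of "
                f"{OBSERVABLES}"
            )
        if self.weight < 0:
            raise CalibrationError("target weight must be non-negative")

    def to_dict(self) -> dict:
        return {"observable": self.observable, "year": int(self.year),
                "value": float(self.value), "weight": float(self.weight)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationTarget":
        return cls(d["observable"], int(d["year"]), float(d["value"]),
                   float(d.get("weight", 1.0)))


def observable_from_trace(trace: pd.DataFrame, observable: str,
                          year: int) -> float:
    """Read one calibration observable off an annual trace."""
    if year not in trace.index:
        raise CalibrationError(f"trace does not cover year {year}")
    row = trace.loc[year]
    if observable == "prevalence_at_year":
        return float(row["prevalence"])
    if observable == "on_drug_share_at_year":
        return float(row["on_drug"] / row["prevalence"]) if row["prevalence"] else 0.0
    if observable == "deaths_in_year":
        return float(row["deaths"])
    raise CalibrationError(f"unknown observable {observable!r}")


@dataclass
class CalibrationResult:
    fitted: dict[str, float]
    residuals: pd.DataFrame        # per-target model value and relative residual
    objective: float
    start_objective: float
    converged: bool
    n_evaluations: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "fitted": {k: float(v) for k, v in self.fitted.items()},
            "objective": float(self.objective),
            "start_objective": float(self.start_objective),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
            "message": self.message,
            "residuals": self.residuals.to_dict(orient="records"),
        }


def _objective(
    x: np.ndarray,
    names: Sequence[str],
    targets: Sequence[CalibrationTarget],
    ctx: ModelContext,
    scenario: str,
) -> tuple[float, list[dict]]:
    trial = ctx.copy()
    trial.params = trial.params.copy(**{n: float(v) for n, v in zip(names, x)})
    trace = run_warmup(trial, scenario).trace
    total = 0.0
    rows = []
    for t in targets:
        model = observable_from_trace(trace, t.observable, t.year)
        denom = t.value if t.value != 0 else 1.0
        rel = (model - t.value) / denom
        total += t.weight * rel * rel
        rows.append({"observable": t.observable, "year": t.year,
                     "target": t.value, "model": model,
                     "relative_residual": rel, "weight": t.weight})
    return total, rows


def calibrate(
    targets: Sequence[CalibrationTarget],
    free: Mapping[str, tuple[float, float]],
    ctx: ModelContext,
    scenario: str = FIXED,
    method: str = "Nelder-Mead",
    maxiter: int = 400,
    objective_tol: float = 1e-6,
) -> CalibrationResult:
    """Fit ``free`` parameters (name -> bounds) to ``targets``.

    Deterministic: fixed start at the current parameter values, no
    stochastic restarts.  Non-convergence returns the best point found,
    flagged, never silently.
    """
    if not targets:
        raise CalibrationError("at least one calibration target is required")
    names = list(free)
    for name in names:
        if name not in FREE_PARAMETERS:
            raise CalibrationError(
                f"{name!r} is not a calibratable parameter; choose from "
                f"{sorted(FREE_PARAMETERS)}"
            )
    bounds = []
    for name in names:
        lo, hi = free[name]
        if not (0.0 <= lo <= hi <= 1.0):
            raise CalibrationError(f"bounds for {name} must lie within [0, 1]")
        bounds.append((lo, hi))
    x0 = np.array([getattr(ctx.params, n) for n in names], dtype=float)

    n_eval = 0

    def fun(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return _objective(x, names, targets, ctx, scenario)[0]

    start_obj = fun(x0)
    res = minimize(
        fun, x0, method=method, bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-12}
        if method == "Nelder-Mead" else {"maxiter": maxiter},
    )
    best_x, best_f = (res.x, float(res.fun))
    if start_obj < best_f:  # never report worse than the start
        best_x, best_f = x0, start_obj
    final_obj, rows = _objective(best_x, names, targets, ctx, scenario)
    return CalibrationResult(
        fitted={n: float(v) for n, v in zip(names, best_x)},
        residuals=pd.DataFrame(rows),
        objective=final_obj,
        start_objective=start_obj,
        converged=bool(res.success) and final_obj <= objective_tol,
        n_evaluations=n_eval,
        message=str(res.message),
    )
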