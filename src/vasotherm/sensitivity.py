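"""One-at-a-time (OAT) normalized sensitivity of the temperature field.

Each input parameter x is scaled by (1 + delta) in turn and the model
re-solved.  Per thermal unknown i the normalized coefficient is

    X_i = ((theta'_i - theta_i) / theta_i) / delta,

where theta_i = T_i - T_inf is the temperature offset above ambient
(making the coefficient independent of the temperature unit), and the
reported value is the arithmetic mean over the included unknowns.
Unknowns whose baseline offset magnitude falls below a configurable
floor are excluded (the ratio diverges as theta -> 0) and counted.

The inlet-temperature row perturbs the offset itself
(T_in' = T_inf + (1 + delta) (T_in - T_inf)); by linearity of the steady
thermal system with zero metabolic generation its mean coefficient is
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pipeline import Problem, solve_problem

__all__ = ["SensitivityResult", "relative_sensitivity", "oat_analysis",
           "DEFAULT_PARAMETERS"]

#: Parameters analyzed by default: the inlet offset, ambient film
#: coefficient, compartmental perfusion, the two permeabilities, the two
#: virtual-network conductances, and the wall film coefficient.
DEFAULT_PARAMETERS = (
    "theta_in", "h_inf", "alpha", "k_a", "k_v", "gamma_a", "gamma_v", "h_b",
)

#: Parameters that require a new flow solve.
_FLOW_PARAMS = {"alpha", "k_a", "k_v", "gamma_a", "gamma_v", "mu"}


@dataclass
class SensitivityResult:
    parameter: str
    delta: float
    X: np.ndarray | None        # per-unknown coefficients (included only)
    X_mean: float
    n_included: int
    n_excluded: int
    error: str | None = None


def relative_sensitivity(
    theta_base: np.ndarray,
    theta_pert: np.ndarray,
    delta: float,
    floor: float = 1e-9,
) -> tuple[np.ndarray, float, int]:
    """Per-unknown coefficients and their mean.

    Returns ``(X over included unknowns, mean, excluded count)``;
    unknowns with |theta_base| <= floor are excluded.
    """
    if delta <= 0:
        raise ConfigurationError("delta must be > 0")
    tb = np.asarray(theta_base, dtype=float)
    tp = np.asarray(theta_pert, dtype=float)
    if tb.shape != tp.shape:
        raise ConfigurationError("baseline/perturbed shapes differ")
    include = np.abs(tb) > floor
    if not include.any():
        raise ConfigurationError(
            "all baseline offsets are (near) zero: sensitivity undefined"
        )
    X = ((tp[include] - tb[include]) / tb[include]) / delta
    return X, float(X.mean()), int((~include).sum())


def _thetas(result, T_inf: float, include_elements: bool) -> np.ndarray:
    temps = result.heat.all_temperatures()
    if not include_elements:
        temps = temps[: result.heat.system.tissue_linear.size]
    return temps - T_inf


def oat_analysis(
    problem: Problem,
    parameters=DEFAULT_PARAMETERS,
    delta: float = 0.01,
    floor: float = 1e-9,
    include_elements: bool = True,
    tol: float = 1e-8,
    method: str = "auto",
    keep_fields: bool = False,
) -> list[SensitivityResult]:
    """Run the OAT study around ``problem``'s parameter point.

    Flow-only parameters re-solve the flow stage and rebuild the
    advection graph; purely thermal parameters re-use the cached flow
    solution.  A failed perturbed solve is recorded in its row and the
    analysis continues.
    """
    base = solve_problem(problem, tol=tol, method=method)
    theta0 = _thetas(base, problem.thermal_params.T_inf, include_elements)

    results: list[SensitivityResult] = []
    for name in parameters:
        try:
            pert = _solve_perturbed(problem, base, name, delta, tol, method)
            theta1 = _thetas(pert, problem.thermal_params.T_inf, include_elements)
            X, mean, excluded = relative_sensitivity(theta0, theta1, delta, floor)
            results.append(SensitivityResult(
                name, delta, X if keep_fields else None, mean,
                int(X.size), excluded,
            ))
        except Exception as exc:  # record per-row, keep going
            results.append(SensitivityResult(name, delta, None, np.nan, 0, 0,
                                             error=str(exc)))
    return results


def _solve_perturbed(problem, base, name, delta, tol, method):
    fp, tp = problem.flow_params, problem.thermal_params
    if name == "theta_in":
        theta_in = tp.T_in - tp.T_inf
        tp2 = replace(tp, T_in=tp.T_inf + (1.0 + delta) * theta_in)
        return _resolve_heat_only(problem, base, tp2, tol, method)
    if hasattr(tp, name) and name not in _FLOW_PARAMS:
        tp2 = replace(tp, **{name: getattr(tp, name) * (1.0 + delta)})
        return _resolve_heat_only(problem, base, tp2, tol, method)
    if hasattr(fp, name):
        fp2 = replace(fp, **{name: getattr(fp, name) * (1.0 + delta)})
        prob2 = problem.with_params(flow_params=fp2)
        return solve_problem(prob2, tol=tol, method=method, coupling=base.coupling)
    raise ConfigurationError(f"unknown parameter {name!r}")


def _resolve_heat_only(problem, base, tp2, tol, method):
    """Re-solve only the thermal stage with cached flow/coupling."""
    prob2 = problem.with_params(thermal_params=tp2)
    return solve_problem(prob2, tol=tol, method=method,
                         coupling=base.coupling, flow=base.flow)


def to_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    """Tabulate an OAT study for export."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "delta": r.delta,
                "X_mean": r.X_mean,
                "n_included": r.n_included,
                "n_excluded": r.n_excluded,
                "error": r.error or "",
            }
            for r in results
        ]
    )
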