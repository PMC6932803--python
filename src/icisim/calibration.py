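"""Model calibration against a tumor-load series.

The fit minimizes a root-mean-square error between simulated and observed
total tumor load, augmented with penalties for parameter-bound violations
and for clinically infeasible behaviour (the untreated counterpart of the
candidate patient must progress: at least a 20% load increase over 12
untreated weeks).  Patient-specific parameters move in wide (default
0.28-3.5 fold) boxes, general parameters in narrow (+-20%) boxes.

The optimizer is a seeded hybrid of global exploration and local refinement:
annealed log-space perturbations of the incumbent alternate with uniform
restarts over the box and derivative-free (Nelder-Mead) polishing, all under
a fixed evaluation budget.  Confidence intervals come from profiling the
error surface and thresholding at a chi-square quantile under a
Gaussian-error approximation; a flat profile above the optimum is reported
as a saturated (one-sided) interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .model import (
    DoseSchedule, GeneralParameters, SpecificParameters, SimulationError,
    TumorLoadSeries, initial_state, simulate, tumor_load,
)
from .synthetic import REFERENCE_SCENARIO, ReferenceScenario, WEEK_H

__all__ = [
    "FitConfig", "FitResult", "ProfileCI", "cost", "fit", "profile_ci",
    "WIDE_FOLD_RANGE", "NARROW_FOLD_RANGE",
]

#: Default fold-range for patient-specific parameters.
WIDE_FOLD_RANGE = (0.28, 3.5)
#: Default fold-range for general parameters (narrow, +-20%).
NARROW_FOLD_RANGE = (0.8, 1.2)

_SPECIFIC_NAMES = ("p_C", "kE0", "rho_D", "kC03", "kC04",
                   "a_SCM", "a_CM", "a_EM", "a_EFF")


@dataclass
class FitConfig:
    """Configuration of a calibration run.

    ``free_specific`` / ``free_general`` name the parameters allowed to move;
    bounds are fold-ranges around the reference values (wide for specific,
    narrow for general parameters).  ``lambda_bound`` weights squared
    bound violations, ``lambda_trend`` the untreated-progression penalty.
    """

    free_specific: tuple[str, ...] = ("kE0", "p_C")
    free_general: tuple[str, ...] = ()
    sp_ref: SpecificParameters = field(default_factory=SpecificParameters)
    gp_ref: GeneralParameters = field(default_factory=GeneralParameters)
    scenario: ReferenceScenario = REFERENCE_SCENARIO
    wide_range: tuple[float, float] = WIDE_FOLD_RANGE
    narrow_range: tuple[float, float] = NARROW_FOLD_RANGE
    lambda_bound: float = 1e3
    lambda_trend: float = 1e2
    budget: int = 2000
    seed: int = 0
    dose_mg: float = 120.0
    #: Untreated pre-screen: load(12 wk) must reach this fold of baseline.
    progression_fold: float = 1.2

    def __post_init__(self) -> None:
        for name in (*self.free_specific, *self.free_general):
            if name in self.free_specific and name not in _SPECIFIC_NAMES:
                raise ValueError(f"unknown specific parameter {name!r}")
        if self.budget < 1:
            raise ValueError("budget must be positive")
        for lo, hi in (self.wide_range, self.narrow_range):
            if not 0 < lo < hi:
                raise ValueError("fold ranges must be ordered and positive")

    @property
    def param_names(self) -> tuple[str, ...]:
        return (*self.free_specific, *self.free_general)

    def bounds(self) -> dict[str, tuple[float, float]]:
        """Absolute box bounds per free parameter."""
        out: dict[str, tuple[float, float]] = {}
        for name in self.free_specific:
            ref = getattr(self.sp_ref, name)
            out[name] = (ref * self.wide_range[0], ref * self.wide_range[1])
        for name in self.free_general:
            ref = getattr(self.gp_ref, name)
            out[name] = (ref * self.narrow_range[0], ref * self.narrow_range[1])
        return out

    def build_params(self, values: dict[str, float]
                     ) -> tuple[SpecificParameters, GeneralParameters]:
        sp_over = {k: v for k, v in values.items() if k in _SPECIFIC_NAMES}
        gp_over = {k: v for k, v in values.items() if k not in _SPECIFIC_NAMES}
        sp = replace(self.sp_ref, **sp_over) if sp_over else self.sp_ref
        gp = replace(self.gp_ref, **gp_over) if gp_over else self.gp_ref
        return sp, gp


@dataclass
class ProfileCI:
    """Profile interval for one parameter (absolute units)."""

    param: str
    level: float
    lower: float
    upper: float
    saturated_lower: bool = False
    saturated_upper: bool = False


@dataclass
class FitResult:
    """Outcome of :func:`fit`."""

    best_params: dict[str, float]
    best_cost: float
    cost_trace: np.ndarray
    n_eval: int
    config: FitConfig
    budget_exhausted: bool = False
    profiles: dict[str, ProfileCI] = field(default_factory=dict)


def _simulate_loads(sp: SpecificParameters, gp: GeneralParameters,
                    scenario: ReferenceScenario, weeks: np.ndarray,
                    dose_mg: float, drug_off: bool = False) -> np.ndarray:
    t_end = max(float(weeks[-1]) * WEEK_H, 6.0)
    sched = DoseSchedule.none() if drug_off else DoseSchedule.q3w(dose_mg, t_end)
    init = initial_state(scenario.total_T,
                         scenario.baseline_load_cm3 * gp.cells_per_cm3,
                         scenario.dc0, gp)
    traj = simulate(sp, gp, sched, t_end, init, drug_off=drug_off)
    series = tumor_load(traj)
    return np.interp(weeks, series.weeks, series.load_cm3)


def cost(values: dict[str, float], data: TumorLoadSeries,
         config: FitConfig) -> float:
    """RMSE-plus-penalty calibration cost.

    RMSE between simulated and observed load at the data weeks, plus
    ``lambda_bound`` times the summed squared bound violations, plus
    ``lambda_trend`` if the same patient simulated *without* drug fails to
    progress (untreated 12-week load below ``progression_fold`` times
    baseline).  Simulation failures map to +inf.
    """
    penalty = 0.0
    bounds = config.bounds()
    clipped = dict(values)
    for name, v in values.items():
        lo, hi = bounds[name]
        if v < lo:
            penalty += config.lambda_bound * (lo - v) ** 2
            clipped[name] = lo
        elif v > hi:
            penalty += config.lambda_bound * (v - hi) ** 2
            clipped[name] = hi
    scenario = config.scenario
    try:
        sp, gp = config.build_params(clipped)
        sim = _simulate_loads(sp, gp, scenario, data.weeks, config.dose_mg)
        rmse = float(np.sqrt(np.mean((sim - data.load_cm3) ** 2)))
        untreated = _simulate_loads(
            sp, gp, scenario, np.array([0.0, 12.0]), config.dose_mg,
            drug_off=True)
        if untreated[-1] < config.progression_fold * untreated[0]:
            penalty += config.lambda_trend
    except (SimulationError, ValueError):
        return math.inf
    return rmse + penalty


def _to_unit(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))


def _from_unit(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.exp(np.log(lo) + np.clip(u, 0.0, 1.0) * (np.log(hi) - np.log(lo)))


def fit(data: TumorLoadSeries, config: FitConfig,
        x0: dict[str, float] | None = None) -> FitResult:
    """Hybrid global/local calibration under a fixed evaluation budget.

    Seeded and reproducible: identical inputs give an identical result.  The
    search works in log-space on the bounded box, alternating annealed
    perturbations of the incumbent and uniform restarts with Nelder-Mead
    refinement; the best-ever point is returned with its evaluation trace.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 data points to calibrate")
    names = config.param_names
    if not names:
        raise ValueError("no free parameters configured")
    bounds = config.bounds()
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    rng = np.random.default_rng(config.seed)

    trace: list[float] = []
    state = {"n": 0, "best_u": None, "best_c": math.inf}

    def eval_u(u: np.ndarray) -> float:
        if state["n"] >= config.budget:
            return math.inf
        state["n"] += 1
        x = _from_unit(np.asarray(u), lo, hi)
        c = cost(dict(zip(names, x)), data, config)
        if c < state["best_c"]:
            state["best_c"] = c
            state["best_u"] = np.clip(np.asarray(u, dtype=float), 0, 1).copy()
        trace.append(state["best_c"])
        return c

    # initial guess: reference values (centre of fold-space) unless given
    if x0 is not None:
        u0 = _to_unit(np.array([x0[n] for n in names]), lo, hi)
    else:
        ref = np.array([getattr(config.sp_ref, n, None)
                        if n in _SPECIFIC_NAMES else getattr(config.gp_ref, n)
                        for n in names], dtype=float)
        u0 = _to_unit(np.clip(ref, lo, hi), lo, hi)
    eval_u(u0)

    k = len(names)
    while state["n"] < config.budget:
        frac = state["n"] / config.budget
        temp = 0.5 * (1.0 - frac) + 0.02          # annealed step size
        r = rng.random()
        if r < 0.45:
            # annealed perturbation of the incumbent (simulated-annealing move)
            u = state["best_u"] + rng.normal(scale=temp, size=k)
            eval_u(np.clip(u, 0, 1))
        elif r < 0.65:
            # global restart: uniform draw over the box
            eval_u(rng.random(k))
        else:
            # local refinement of the incumbent (derivative-free descent)
            maxfev = min(20 * k, config.budget - state["n"])
            if maxfev <= 0:
                break
            optimize.minimize(
                eval_u, state["best_u"], method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-10})

    x_best = _from_unit(state["best_u"], lo, hi)
    return FitResult(
        best_params=dict(zip(names, x_best)),
        best_cost=float(state["best_c"]),
        cost_trace=np.asarray(trace),
        n_eval=state["n"],
        config=config,
        budget_exhausted=state["n"] >= config.budget,
    )


def interval_from_profile(grid: np.ndarray, costs: np.ndarray,
                          threshold: float,
                          flat_tol: float = 1e-3
                          ) -> tuple[float, float, bool, bool]:
    """Interval where a profiled cost stays at or below a threshold.

    ``grid`` is increasing and brackets the optimum (the grid minimum).
    Crossings are located by linear interpolation; if the profile never
    exceeds the threshold on a side, or is flat on that side (relative slope
    below ``flat_tol``), the interval extends to the grid end and the side
    is flagged as saturated.
    """
    grid = np.asarray(grid, dtype=float)
    costs = np.asarray(costs, dtype=float)
    i0 = int(np.argmin(costs))
    c0 = costs[i0]

    def crossing(idx: np.ndarray) -> tuple[float, bool]:
        for a, b in zip(idx[:-1], idx[1:]):
            if costs[b] > threshold >= costs[a]:
                t = (threshold - costs[a]) / (costs[b] - costs[a])
                return float(grid[a] + t * (grid[b] - grid[a])), False
        return float(grid[idx[-1]]), True

    upper, sat_up = crossing(np.arange(i0, grid.size))
    lower, sat_lo = crossing(np.arange(i0, -1, -1))
    # flatness check: a saturated side whose profile barely rises is flat
    span = max(abs(costs[-1] - c0), abs(costs[0] - c0), threshold - c0, 1e-300)
    if sat_up and (costs[-1] - c0) < flat_tol * span:
        sat_up = True
    return lower, upper, sat_lo, sat_up


def profile_ci(fit_result: FitResult, data: TumorLoadSeries, param_name: str,
               level: float = 0.90, n_grid: int = 17,
               refine_budget: int = 0) -> ProfileCI:
    """Profile-likelihood confidence interval for one fitted parameter.

    The cost is profiled over a log-spaced grid spanning the parameter's box;
    at each grid point the remaining free parameters are either held at the
    optimum (``refine_budget=0``) or re-optimized with a small local budget.
    The squared-error surface is thresholded at
    ``SSR* * (1 + chi2_1(level) / (n - p))`` (single-parameter chi-square
    quantile under Gaussian errors).  A profile that stays below threshold up
    to a box edge yields a one-sided interval with a saturation flag — e.g. a
    cost surface that is flat above the optimum reports
    ``[lower crossing, upper box bound]``.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    config = fit_result.config
    names = config.param_names
    if param_name not in names:
        raise ValueError(f"{param_name!r} was not a free parameter of the fit")
    bounds = config.bounds()
    lo, hi = bounds[param_name]
    best = dict(fit_result.best_params)
    theta_star = best[param_name]

    n = len(data)
    p = len(names)
    ssr_star = n * fit_result.best_cost ** 2
    if level == 0.0:
        return ProfileCI(param_name, level, theta_star, theta_star)
    q = stats.chi2.ppf(level, df=1)
    dof = max(n - p, 1)
    thr_ssr = ssr_star * (1.0 + q / dof) + 1e-12

    grid = np.unique(np.concatenate([
        np.geomspace(lo, hi, n_grid), [theta_star]]))
    others = [nm for nm in names if nm != param_name]
    prof = np.empty(grid.size)
    for i, theta in enumerate(grid):
        values = dict(best)
        values[param_name] = float(theta)
        if others and refine_budget > 0:
            sub = replace(
                config,
                free_specific=tuple(nm for nm in config.free_specific
                                    if nm != param_name),
                free_general=tuple(nm for nm in config.free_general
                                   if nm != param_name),
                budget=refine_budget, seed=config.seed + 1)
            # pin the profiled parameter by moving the reference
            if param_name in _SPECIFIC_NAMES:
                sub.sp_ref = replace(config.sp_ref,
                                     **{param_name: float(theta)})
            else:
                sub.gp_ref = replace(config.gp_ref,
                                     **{param_name: float(theta)})
            res = fit(data, sub, x0={nm: best[nm] for nm in others})
            prof[i] = res.best_cost
        else:
            prof[i] = cost(values, data, config)
    ssr_prof = n * prof ** 2
    lower, upper, sat_lo, sat_up = interval_from_profile(grid, ssr_prof,
                                                         thr_ssr)
    return ProfileCI(param_name, level, lower, upper, sat_lo, sat_up)
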