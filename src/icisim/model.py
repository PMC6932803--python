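"""Core tumor–immune–drug ODE model.

The model couples three arms:

* **Cellular immunity** — antigen-specific CD8+ T cells on a differentiation ×
  senescence grid.  Differentiation compartments (index ``i``) are T memory
  stem cells (SCM), central memory (CM), effector memory (EM), effector (EFF)
  and fully exhausted (EXH) cells; the senescence index ``j`` counts cumulative
  divisions of a lineage and division ceases at ``j = m`` (replicative
  senescence).  Each division sends both daughters one senescence step up;
  with probability ``a_i`` a daughter self-renews (stays in compartment ``i``),
  otherwise it differentiates to ``i + 1``.  Activated/mature dendritic cells
  (DCs) transduce tumor antigen into naive-cell recruitment and boost SCM/CM
  division.
* **Tumor** — total melanoma burden ``C`` (cells) growing by a power law
  ``dC/dt = p_C * C**(2/3)`` and killed by EM/EFF cells with saturating,
  PD-1-modulated cytotoxicity.
* **Drug** — one-compartment pembrolizumab pharmacokinetics with bolus IV
  dosing; receptor blockade ``B = P/(P + EC50)`` annuls the PD-1/PD-L1
  inhibitory signal proportionally.

PD-1 signalling enters through a single dimensionless pressure
``g(C, B, j) = (j/m) * C/(C + K_PD) * (1 - B)`` — inhibitory-receptor
expression grows with the division index, ligation saturates in tumor burden,
and blockade scales the whole signal down.  The pressure impairs EM/EFF
division and killing and drives PD-1-mediated apoptosis at compartment
specific rates (``kC03`` on EM, ``kC04`` on EFF).

All internal times are hours and cell quantities are absolute counts; tumor
burden converts to lesion volume via ``cells_per_cm3`` (default 1e9 cells per
cm^3) for clinical I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SCM", "CM", "EM", "EFF", "EXH", "N_COMPARTMENTS",
    "SpecificParameters", "GeneralParameters", "StateVector", "DoseSchedule",
    "Trajectory", "TumorLoadSeries", "SimulationError",
    "initial_state", "blocked_fraction", "pd1_pressure", "division_rates",
    "rhs", "simulate", "tumor_load", "reinvigoration_percent",
    "reinvigoration_series",
]

# Differentiation compartment indices, ordered by increasing differentiation.
SCM, CM, EM, EFF, EXH = 0, 1, 2, 3, 4
N_COMPARTMENTS = 5
COMPARTMENT_NAMES = ("SCM", "CM", "EM", "EFF", "EXH")

# Compartments that divide (EXH is terminally inert).
_DIVIDING = (SCM, CM, EM, EFF)


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails or produces an invalid state."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificParameters:
    """Patient-specific rate constants.

    These are the parameters that cannot be pinned down from literature alone
    and are instead estimated per patient from the tumor-load time course.
    Defaults are the reference-patient best-fit values.

    Attributes
    ----------
    p_C : float
        Intrinsic tumor growth coefficient of the power law
        ``dC/dt = p_C * C**(2/3)`` (cells^(1/3)/h).
    kE0 : float
        Baseline effector cytotoxicity (per effector cell, 1/h, before
        PD-1 impairment and tumor-saturation scaling).
    rho_D : float
        Tumor immunogenicity: maximal DC activation rate (cells/h).
    kC03 : float
        PD-1-mediated apoptosis coefficient acting on EM cells (1/h).
    kC04 : float
        PD-1-mediated apoptosis coefficient acting on EFF cells (1/h).
    a_SCM, a_CM, a_EM, a_EFF : float
        Self-renewal probabilities per dividing compartment (dimensionless,
        in [0, 1]): probability that a daughter cell stays in its mother's
        compartment rather than differentiating onward.
    """

    p_C: float = 1.828
    kE0: float = 0.00603
    rho_D: float = 0.95
    kC03: float = 0.0058
    kC04: float = 0.00535
    a_SCM: float = 0.05
    a_CM: float = 0.9
    a_EM: float = 0.03
    a_EFF: float = 0.92

    def __post_init__(self) -> None:
        for name in ("p_C", "kE0", "rho_D", "kC03", "kC04"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("a_SCM", "a_CM", "a_EM", "a_EFF"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def self_renewal(self) -> np.ndarray:
        """Self-renewal probabilities indexed by compartment (SCM..EFF)."""
        return np.array([self.a_SCM, self.a_CM, self.a_EM, self.a_EFF])


@dataclass(frozen=True)
class GeneralParameters:
    """Population-level ("general") model parameters.

    Defaults were calibrated once, together with the reference-patient
    specific parameters, so that the default parameterization reproduces the
    reference double-peak tumor-load trajectory under 120 mg q3w dosing (see
    the methods note).  All rates are per hour; cell quantities are counts.
    """

    #: Maximal divisions per lineage; division ceases at senescence index m.
    m: int = 25
    #: Intrinsic division rates (1/h) for SCM, CM, EM, EFF; strictly
    #: decreasing with differentiation.
    p_div: tuple[float, float, float, float] = (0.02, 0.0158, 0.0129, 0.01)
    #: Death rates (1/h) for SCM, CM, EM, EFF, EXH; non-decreasing.
    mu: tuple[float, float, float, float, float] = (
        1e-4, 2e-4, 5e-4, 1.5e-3, 5e-3)
    #: Naive -> SCM activation influx coefficient (cells/h at DC saturation).
    sigma_N: float = 213.0
    #: Maximal DC-driven fold-boost of SCM/CM division (dimensionless).
    s_max: float = 2.0
    #: DC half-saturation for naive recruitment and division boost (cells).
    K_D: float = 20.0
    #: Tumor half-saturation for DC activation (cells).
    K_Cdc: float = 2e9
    #: DC migration, activation-state death and mature-DC death rates (1/h).
    m_DC: float = 0.03
    d_act: float = 0.02
    d_m: float = 0.01
    #: Tumor half-saturation for PD-1 ligation (cells).
    K_PD: float = 5e9
    #: Maximal fractional impairment of killing / EM-EFF division by PD-1.
    eps_kill: float = 0.95
    eps_div: float = 0.9
    #: EM cytotoxicity as a fraction of kE0.
    phi_EM: float = 0.5
    #: Tumor half-saturation of the killing term (cells).
    K_kill: float = 4e11
    #: Drug elimination half-life (h); ~22 days for pembrolizumab.
    t_half: float = 528.0
    #: Drug volume of distribution (L).
    V_d: float = 7.7
    #: Drug concentration at half receptor blockade (mg/L).
    EC50: float = 12.0
    #: Reinvigoration time constant (h): average overall division time.
    tau: float = 24.0
    #: Tumor cell-to-volume conversion (cells per cm^3).
    cells_per_cm3: float = 1e9

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        scalars = ("sigma_N", "s_max", "K_D", "K_Cdc", "m_DC", "d_act", "d_m",
                   "K_PD", "K_kill", "t_half", "V_d", "EC50", "tau",
                   "cells_per_cm3")
        for name in scalars:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        pd = np.asarray(self.p_div, dtype=float)
        if pd.shape != (4,) or np.any(pd <= 0) or np.any(np.diff(pd) >= 0):
            raise ValueError("p_div must be 4 positive rates, strictly "
                             "decreasing from SCM to EFF")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (5,) or np.any(mu <= 0) or np.any(np.diff(mu) < 0):
            raise ValueError("mu must be 5 positive, non-decreasing rates")
        for name in ("eps_kill", "eps_div", "phi_EM"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_levels(self) -> int:
        """Number of senescence levels, ``m + 1``."""
        return self.m + 1


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class StateVector:
    """Full system state.

    Attributes
    ----------
    T : ndarray, shape (5, m+1)
        Cell counts per (differentiation compartment, senescence level).
    D_act : float
        Tumor-activated dendritic cells.
    D_m : float
        Mature (lymph-node) dendritic cells.
    C : float
        Tumor burden (cells).
    P : float
        Drug plasma concentration (mg/L).
    """

    T: np.ndarray
    D_act: float
    D_m: float
    C: float
    P: float

    def validate(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state contains non-finite entries")
        if np.any(arr < 0):
            raise ValueError("state contains negative entries")

    def to_array(self) -> np.ndarray:
        """Flatten to the solver layout ``[T.ravel(), D_act, D_m, C, P]``."""
        return np.concatenate(
            [np.asarray(self.T, dtype=float).ravel(),
             [self.D_act, self.D_m, self.C, self.P]])

    @classmethod
    def from_array(cls, y: np.ndarray, m: int) -> "StateVector":
        n = N_COMPARTMENTS * (m + 1)
        T = np.asarray(y[:n], dtype=float).reshape(N_COMPARTMENTS, m + 1)
        return cls(T=T, D_act=float(y[n]), D_m=float(y[n + 1]),
                   C=float(y[n + 2]), P=float(y[n + 3]))

    @property
    def total_T(self) -> float:
        """Total CD8+ T-cell count over all compartments and levels."""
        return float(np.sum(self.T))


def initial_state(total_T: float, tumor0: float, dc0: float,
                  gp: GeneralParameters | None = None) -> StateVector:
    """Uniform initial condition.

    ``total_T`` cells are spread equally over all ``5 * (m+1)`` grid bins
    (the conventional pre-treatment initial condition for this model);
    activated and mature DC pools both start at ``dc0``; no drug on board.
    """
    gp = gp or GeneralParameters()
    if total_T < 0 or tumor0 < 0 or dc0 < 0:
        raise ValueError("initial_state arguments must be non-negative")
    n_bins = N_COMPARTMENTS * gp.n_levels
    T = np.full((N_COMPARTMENTS, gp.n_levels), total_T / n_bins)
    return StateVector(T=T, D_act=float(dc0), D_m=float(dc0),
                       C=float(tumor0), P=0.0)


# ---------------------------------------------------------------------------
# Dosing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseSchedule:
    """IV bolus dosing schedule: ``dose_amounts[k]`` mg at ``dose_times[k]`` h."""

    dose_times: tuple[float, ...]
    dose_amounts: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.dose_times, dtype=float)
        a = np.asarray(self.dose_amounts, dtype=float)
        if t.shape != a.shape:
            raise ValueError("dose_times and dose_amounts must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("dose_times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("dose_amounts must be non-negative")

    @classmethod
    def q3w(cls, dose_mg: float = 120.0, t_end_h: float = 12 * 7 * 24.0,
            interval_h: float = 504.0) -> "DoseSchedule":
        """Standard pembrolizumab schedule: ``dose_mg`` at t=0 and every 3 weeks."""
        times = tuple(np.arange(0.0, t_end_h, interval_h))
        return cls(dose_times=times, dose_amounts=(dose_mg,) * len(times))

    @classmethod
    def none(cls) -> "DoseSchedule":
        """No treatment."""
        return cls(dose_times=(), dose_amounts=())


# ---------------------------------------------------------------------------
# Elementary signals
# ---------------------------------------------------------------------------

def blocked_fraction(P: float, EC50: float) -> float:
    """Fraction of PD-1 receptors blocked at drug concentration ``P``.

    ``B = P / (P + EC50)``; saturating, in [0, 1).
    """
    if EC50 <= 0:
        raise ValueError("EC50 must be positive")
    if P < 0:
        raise ValueError("drug concentration must be non-negative")
    return P / (P + EC50)


def pd1_pressure(C: float, B: float, j, gp: GeneralParameters):
    """Dimensionless PD-1 inhibitory pressure on a cell at senescence ``j``.

    ``g = (j/m) * C/(C + K_PD) * (1 - B)``: inhibitory-receptor expression
    rises linearly with the division index, PD-L1 ligation saturates in tumor
    burden, and receptor blockade ``B`` scales the signal down.  Vectorized
    over ``j``.
    """
    if C < 0:
        raise ValueError("tumor burden must be non-negative")
    if not 0.0 <= B <= 1.0:
        raise ValueError("blocked fraction must lie in [0, 1]")
    j = np.asarray(j, dtype=float)
    if np.any(j < 0) or np.any(j > gp.m):
        raise ValueError("senescence index out of range")
    return (j / gp.m) * (C / (C + gp.K_PD)) * (1.0 - B)


def division_rates(state: StateVector, sp: SpecificParameters,
                   gp: GeneralParameters, drug_off: bool = False) -> np.ndarray:
    """Effective division rates r[i, j] (1/h) at the current state.

    SCM/CM rates are boosted by mature DCs; EM/EFF rates are impaired by the
    PD-1 pressure; EXH cells and the terminal senescence row ``j = m`` do not
    divide.
    """
    B = 0.0 if drug_off else blocked_fraction(state.P, gp.EC50)
    j = np.arange(gp.n_levels)
    g = pd1_pressure(max(state.C, 0.0), B, j, gp)
    dsat = state.D_m / (gp.K_D + state.D_m) if state.D_m > 0 else 0.0
    r = np.zeros((N_COMPARTMENTS, gp.n_levels))
    boost = 1.0 + gp.s_max * dsat
    r[SCM] = gp.p_div[SCM] * boost
    r[CM] = gp.p_div[CM] * boost
    r[EM] = gp.p_div[EM] * (1.0 - gp.eps_div * g)
    r[EFF] = gp.p_div[EFF] * (1.0 - gp.eps_div * g)
    r[:, gp.m] = 0.0
    return r


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _rhs_flat(t: float, y: np.ndarray, sp: SpecificParameters,
              gp: GeneralParameters, drug_off: bool,
              killing_off: bool) -> np.ndarray:
    """Flat-array right-hand side used by the solver (no validation)."""
    nl = gp.n_levels
    nT = N_COMPARTMENTS * nl
    T = y[:nT].reshape(N_COMPARTMENTS, nl)
    D_act, D_m, C, P = y[nT], y[nT + 1], y[nT + 2], y[nT + 3]
    Cpos = C if C > 0 else 0.0

    B = P / (P + gp.EC50) if (not drug_off and P > 0) else 0.0
    jfrac = np.arange(nl) / gp.m
    csat_pd = Cpos / (Cpos + gp.K_PD)
    g = jfrac * (csat_pd * (1.0 - B))
    dsat = D_m / (gp.K_D + D_m) if D_m > 0 else 0.0

    # Effective division rates per (compartment, senescence level).
    boost = 1.0 + gp.s_max * dsat
    r = np.empty((N_COMPARTMENTS, nl))
    r[SCM] = gp.p_div[SCM] * boost
    r[CM] = gp.p_div[CM] * boost
    one_minus = 1.0 - gp.eps_div * g
    r[EM] = gp.p_div[EM] * one_minus
    r[EFF] = gp.p_div[EFF] * one_minus
    r[EXH] = 0.0
    r[:, -1] = 0.0

    rT = r * T
    dT = -rT
    mu = np.asarray(gp.mu)
    dT -= mu[:, None] * T
    a = sp.self_renewal
    # Both daughters advance one senescence step; expected routing splits
    # them between self-renewal (stay in i) and differentiation (i -> i+1).
    for i in _DIVIDING:
        flux = rT[i, :-1]
        dT[i, 1:] += 2.0 * a[i] * flux
        dT[i + 1, 1:] += 2.0 * (1.0 - a[i]) * flux
    # PD-1-driven apoptosis on EM/EFF (scaled by the same pressure g).
    dT[EM] -= sp.kC03 * g * T[EM]
    dT[EFF] -= sp.kC04 * g * T[EFF]
    # Naive-cell recruitment into the youngest SCM bin.
    dT[SCM, 0] += gp.sigma_N * dsat

    # Dendritic cells.
    dD_act = sp.rho_D * Cpos / (Cpos + gp.K_Cdc) - (gp.m_DC + gp.d_act) * D_act
    dD_m = gp.m_DC * D_act - gp.d_m * D_m

    # Tumor: power-law growth minus saturating, PD-1-impaired killing.
    dC = sp.p_C * Cpos ** (2.0 / 3.0)
    if not killing_off:
        killers = T[EFF].sum() + gp.phi_EM * T[EM].sum()
        pool = T[EFF].sum() + T[EM].sum()
        if pool > 0 and killers > 0:
            jbar = float((np.arange(nl) * (T[EM] + T[EFF])).sum()) / pool
            ghat = (jbar / gp.m) * csat_pd * (1.0 - B)
            dC -= (Cpos / (Cpos + gp.K_kill)) * (1.0 - gp.eps_kill * ghat) \
                * sp.kE0 * killers

    dP = -(math.log(2.0) / gp.t_half) * P

    dy = np.empty_like(y)
    dy[:nT] = dT.ravel()
    dy[nT] = dD_act
    dy[nT + 1] = dD_m
    dy[nT + 2] = dC
    dy[nT + 3] = dP
    return dy


def rhs(t: float, state: StateVector, sp: SpecificParameters,
        gp: GeneralParameters, drug_off: bool = False,
        killing_off: bool = False) -> StateVector:
    """Time derivative of the full state (validated, structured interface).

    ``drug_off`` forces the blocked fraction to zero (PK decay still applies);
    ``killing_off`` removes the immune kill term from the tumor equation.
    Both exist for ablation in tests and the untreated pre-screen.
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise SimulationError("state contains non-finite entries")
    if np.any(y < 0):
        raise SimulationError("state contains negative entries")
    dy = _rhs_flat(t, y, sp, gp, drug_off, killing_off)
    return StateVector.from_array(dy, gp.m)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Simulated time course with full provenance.

    ``states[k]`` is the flat state at ``times[k]`` (hours); use
    :meth:`state_at` for the structured view.
    """

    times: np.ndarray
    states: np.ndarray
    sp: SpecificParameters
    gp: GeneralParameters
    schedule: DoseSchedule
    drug_off: bool = False
    killing_off: bool = False

    def state_at(self, k: int) -> StateVector:
        return StateVector.from_array(self.states[k], self.gp.m)

    @property
    def tumor_cells(self) -> np.ndarray:
        return self.states[:, -2]

    @property
    def drug_conc(self) -> np.ndarray:
        return self.states[:, -1]


@dataclass(frozen=True)
class TumorLoadSeries:
    """Clinical (or synthetic) total tumor-load measurements.

    ``weeks`` are measurement times, ``load_cm3`` total lesion volumes and
    ``err_cm3`` optional per-point measurement errors.
    """

    weeks: np.ndarray
    load_cm3: np.ndarray
    err_cm3: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=float)
        v = np.asarray(self.load_cm3, dtype=float)
        object.__setattr__(self, "weeks", w)
        object.__setattr__(self, "load_cm3", v)
        if self.err_cm3 is not None:
            e = np.asarray(self.err_cm3, dtype=float)
            object.__setattr__(self, "err_cm3", e)
            if e.shape != w.shape:
                raise ValueError("err_cm3 length mismatch")
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("weeks and load_cm3 must be equal-length 1-D")
        if w.size > 1 and np.any(np.diff(w) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("loads must be non-negative")

    def __len__(self) -> int:
        return self.weeks.size


_NEG_REL_TOL = 1e-9  # relative clip threshold for solver negativity excursions


def simulate(sp: SpecificParameters, gp: GeneralParameters,
             schedule: DoseSchedule, t_span: float, init: StateVector,
             drug_off: bool = False, killing_off: bool = False,
             grid_h: float = 6.0, rtol: float = 1e-6,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model over ``[0, t_span]`` hours.

    Doses are applied as instantaneous boluses (``P += dose / V_d``) at their
    scheduled times; the ODE is solved piecewise between dose events with a
    stiff-capable method and sampled on a uniform grid (default 6 h).  Tiny
    negative excursions (< 1e-9 of the state scale) are clipped to zero;
    anything larger raises :class:`SimulationError`.
    """
    if t_span <= 0:
        raise ValueError("t_span must be positive")
    init.validate()
    t_grid = np.arange(0.0, t_span + 0.5 * grid_h, grid_h)
    t_grid[-1] = min(t_grid[-1], t_span)

    events = [] if drug_off else [
        (t, d) for t, d in zip(schedule.dose_times, schedule.dose_amounts)
        if t <= t_span]
    breaks = sorted({0.0, t_span, *(t for t, _ in events)})
    dose_at = {t: d for t, d in events}

    y = init.to_array()
    out = np.empty((t_grid.size, y.size))
    filled = np.zeros(t_grid.size, dtype=bool)
    if 0.0 in dose_at:
        y[-1] += dose_at[0.0] / gp.V_d

    # Cell counts span many orders of magnitude; scale the absolute tolerance
    # to the problem so the solver does not chase sub-cell noise.
    scale = max(1.0, float(np.max(np.abs(y))))
    atol = max(1e-9, 1e-12 * scale)

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        mask = (t_grid >= t0 - 1e-9) & (t_grid <= t1 + 1e-9) & ~filled
        grid_idx = np.where(mask)[0]
        t_eval = np.unique(np.concatenate(
            [np.clip(t_grid[grid_idx], t0, t1), [t1]]))
        sol = solve_ivp(
            _rhs_flat, (t0, t1), y, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval, args=(sp, gp, drug_off, killing_off))
        if not sol.success:
            raise SimulationError(
                f"integration failed in [{t0:.1f}, {t1:.1f}] h: {sol.message}")
        pos = np.searchsorted(sol.t, np.clip(t_grid[grid_idx], t0, t1))
        out[grid_idx] = sol.y[:, pos].T
        filled[grid_idx] = True
        y = sol.y[:, -1].copy()
        scale = max(1.0, float(np.max(np.abs(y))))
        neg = y < 0
        if np.any(y < -_NEG_REL_TOL * scale):
            raise SimulationError(
                f"state went negative beyond tolerance at t={t1:.1f} h "
                f"(min {y.min():.3e}, scale {scale:.3e})")
        y[neg] = 0.0
        if t1 in dose_at and t1 != 0.0:
            y[-1] += dose_at[t1] / gp.V_d

    out_scale = np.maximum(1.0, np.max(np.abs(out), axis=1, keepdims=True))
    bad = out < -_NEG_REL_TOL * out_scale
    if np.any(bad):
        raise SimulationError("sampled state negative beyond tolerance")
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=t_grid, states=out, sp=sp, gp=gp,
                      schedule=schedule, drug_off=drug_off,
                      killing_off=killing_off)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def tumor_load(traj: Trajectory, gp: GeneralParameters | None = None
               ) -> TumorLoadSeries:
    """Tumor load in cm^3 against time in weeks along a trajectory."""
    gp = gp or traj.gp
    return TumorLoadSeries(weeks=traj.times / (7 * 24.0),
                           load_cm3=traj.tumor_cells / gp.cells_per_cm3)


def reinvigoration_percent(state: StateVector, sp: SpecificParameters,
                           gp: GeneralParameters,
                           drug_off: bool = False) -> float:
    """Percentage of CD8+ T cells actively dividing (Ki67+ proxy).

    Computed as ``100 * tau * sum(r_ij * T_ij) / sum(T_ij)`` with ``r_ij``
    the current effective division rates (EXH rows divide at rate 0) and
    ``tau`` the average division time; capped at 100.
    """
    total = state.total_T
    if total <= 0:
        raise ValueError("reinvigoration undefined for zero T cells")
    r = division_rates(state, sp, gp, drug_off=drug_off)
    pct = 100.0 * gp.tau * float(np.sum(r * state.T)) / total
    return min(pct, 100.0)


def reinvigoration_series(traj: Trajectory) -> np.ndarray:
    """Reinvigoration percentage at every sampled time of a trajectory."""
    out = np.empty(traj.times.size)
    for k in range(traj.times.size):
        state = traj.state_at(k)
        if state.total_T <= 0:
            out[k] = 0.0
        else:
            out[k] = reinvigoration_percent(state, traj.sp, traj.gp,
                                            drug_off=traj.drug_off)
    return out
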