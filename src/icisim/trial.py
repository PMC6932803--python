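"""Virtual patient populations and in-silico pembrolizumab trials.

Four populations (VP0-VP3) probe which sources of inter-patient variation
reproduce the clinically observed link between response and the
reinvigoration-to-baseline-tumor-load ratio:

* **VP0** — patients differ only in baseline tumor load and lesion count;
* **VP1** — additionally, effector cytotoxicity ``kE0`` and tumor growth
  rate ``p_C`` are patient-specific (log-uniform in a 0.28-3.5 fold range);
* **VP2** — as VP1, but ``p_C`` is strictly (rank-one) correlated with the
  baseline tumor load through a deterministic log-linear map;
* **VP3** — as VP2, plus independent 0.5-2 fold scalings of the intrinsic
  T-cell division rates.

Every candidate patient is screened for untreated progression (≥20% load
increase over 12 untreated weeks) before enrolment; screened patients then
receive 120 mg q3w for 12 weeks.  Response is classified on the total
tumor burden by immune-related RECIST classes (CR/PR/SD/PD) and CR/PR
patients count as responders.  The reinvigoration summary per patient is
the maximum Ki67+ percentage over the first six treatment weeks, and the
classifier under study thresholds the ratio reinvigoration / baseline load,
scored by balanced (class-weighted) accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DoseSchedule, GeneralParameters, SimulationError, SpecificParameters,
    initial_state, reinvigoration_series, simulate,
)
from .synthetic import REFERENCE_SCENARIO, ReferenceScenario, WEEK_H

__all__ = [
    "PopulationSpec", "VirtualPatient", "sample_population",
    "screen_progressors", "build_screened_population", "run_trial",
    "classify_irRECIST", "weighted_accuracy", "trial_accuracy",
]

_POPULATIONS = ("VP0", "VP1", "VP2", "VP3")


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of one virtual population.

    ``name`` selects which parameters vary (see module docstring);
    fold-ranges are relative to the reference patient's values.
    """

    name: str
    n_patients: int = 125
    seed: int = 0
    fold_range: tuple[float, float] = (0.28, 3.5)
    p_div_fold: tuple[float, float] = (0.5, 2.0)
    baseline_range_cm3: tuple[float, float] = (1.0, 300.0)
    lesion_range: tuple[int, int] = (1, 10)

    def __post_init__(self) -> None:
        if self.name not in _POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}; "
                             f"expected one of {_POPULATIONS}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for lo, hi in (self.fold_range, self.p_div_fold,
                       self.baseline_range_cm3):
            if not 0 < lo <= hi:
                raise ValueError("fold ranges must be ordered and positive")


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated patient: parameters plus baseline disease burden."""

    id: int
    sp: SpecificParameters
    gp: GeneralParameters
    baseline_load_cm3: float
    n_lesions: int

    def __post_init__(self) -> None:
        if self.baseline_load_cm3 <= 0:
            raise ValueError("baseline load must be positive")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float,
                 size=None) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _correlated_p_C(load_cm3: float, base_p_C: float,
                    spec: PopulationSpec) -> float:
    """Deterministic log-linear map tying p_C to baseline load.

    Maps the log of the baseline-load range onto the log of the p_C
    fold-range, so the rank order of p_C equals the rank order of load
    exactly (a strictly monotone association).
    """
    llo, lhi = np.log(spec.baseline_range_cm3)
    flo, fhi = np.log(spec.fold_range)
    t = (np.log(load_cm3) - llo) / (lhi - llo)
    return float(base_p_C * np.exp(flo + np.clip(t, 0.0, 1.0) * (fhi - flo)))


def _sample_p_div(rng: np.random.Generator, base: tuple[float, ...],
                  fold: tuple[float, float]) -> tuple[float, ...]:
    """Independent fold-scalings of the division rates.

    The division-rate hierarchy (strictly decreasing with differentiation)
    is a structural model assumption, so draws violating it are rejected and
    redrawn.
    """
    base_arr = np.asarray(base)
    for _ in range(1000):
        scaled = base_arr * _log_uniform(rng, *fold, size=len(base))
        if np.all(np.diff(scaled) < 0):
            return tuple(float(v) for v in scaled)
    raise RuntimeError("could not sample a decreasing division-rate profile")


def sample_population(spec: PopulationSpec,
                      base_sp: SpecificParameters | None = None,
                      base_gp: GeneralParameters | None = None,
                      rng: np.random.Generator | None = None
                      ) -> list[VirtualPatient]:
    """Draw ``spec.n_patients`` virtual patients (unscreened).

    All stochastic parameters are log-uniform in their fold-ranges; baseline
    loads are log-uniform in ``baseline_range_cm3`` and lesion counts
    uniform integers in ``lesion_range``.
    """
    base_sp = base_sp or SpecificParameters()
    base_gp = base_gp or GeneralParameters()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n_patients):
        load = float(_log_uniform(rng, *spec.baseline_range_cm3))
        lesions = int(rng.integers(spec.lesion_range[0],
                                   spec.lesion_range[1] + 1))
        sp = base_sp
        gp = base_gp
        if spec.name in ("VP1", "VP2", "VP3"):
            kE0 = float(base_sp.kE0 * _log_uniform(rng, *spec.fold_range))
            if spec.name == "VP1":
                p_C = float(base_sp.p_C * _log_uniform(rng, *spec.fold_range))
            else:
                p_C = _correlated_p_C(load, base_sp.p_C, spec)
            sp = replace(base_sp, kE0=kE0, p_C=p_C)
        if spec.name == "VP3":
            gp = replace(base_gp, p_div=_sample_p_div(rng, base_gp.p_div,
                                                      spec.p_div_fold))
        patients.append(VirtualPatient(id=i, sp=sp, gp=gp,
                                       baseline_load_cm3=load,
                                       n_lesions=lesions))
    return patients


def _simulate_patient(patient: VirtualPatient, schedule: DoseSchedule,
                      weeks: float, scenario: ReferenceScenario,
                      drug_off: bool = False):
    gp = patient.gp
    init = initial_state(scenario.total_T,
                         patient.baseline_load_cm3 * gp.cells_per_cm3,
                         scenario.dc0, gp)
    return simulate(patient.sp, gp, schedule, weeks * WEEK_H, init,
                    drug_off=drug_off)


def untreated_progresses(patient: VirtualPatient, weeks: float = 12.0,
                         fold: float = 1.2,
                         scenario: ReferenceScenario = REFERENCE_SCENARIO
                         ) -> bool:
    """Whether the untreated patient's load grows by ``fold`` over ``weeks``."""
    traj = _simulate_patient(patient, DoseSchedule.none(), weeks, scenario,
                             drug_off=True)
    return traj.tumor_cells[-1] >= fold * traj.tumor_cells[0]


def screen_progressors(patients: Sequence[VirtualPatient],
                       weeks: float = 12.0, fold: float = 1.2,
                       scenario: ReferenceScenario = REFERENCE_SCENARIO
                       ) -> list[VirtualPatient]:
    """Keep only patients whose disease progresses without treatment."""
    return [p for p in patients
            if untreated_progresses(p, weeks, fold, scenario)]


def build_screened_population(spec: PopulationSpec,
                              base_sp: SpecificParameters | None = None,
                              base_gp: GeneralParameters | None = None,
                              scenario: ReferenceScenario = REFERENCE_SCENARIO,
                              max_batches: int = 40
                              ) -> list[VirtualPatient]:
    """Sample-and-screen until ``spec.n_patients`` progressors are retained.

    Candidates are drawn from a single seeded stream in batches; retention
    below 1% aborts with a diagnostic.
    """
    rng = np.random.default_rng(spec.seed)
    kept: list[VirtualPatient] = []
    drawn = 0
    for _ in range(max_batches):
        if len(kept) >= spec.n_patients:
            break
        batch = sample_population(spec, base_sp, base_gp, rng=rng)
        drawn += len(batch)
        kept.extend(screen_progressors(batch, scenario=scenario))
        if drawn >= 100 * max(spec.n_patients, 1) and not kept:
            break
    if spec.n_patients and drawn and len(kept) / drawn < 0.01:
        raise RuntimeError(
            f"untreated-progression retention {len(kept)}/{drawn} below 1%")
    if len(kept) < spec.n_patients:
        raise RuntimeError(
            f"could not retain {spec.n_patients} progressors "
            f"({len(kept)}/{drawn} kept)")
    kept = kept[:spec.n_patients]
    return [replace(p, id=i) for i, p in enumerate(kept)]


def classify_irRECIST(baseline_cm3: float, week12_cm3: float,
                      cr_floor_cm3: float = 0.01) -> str:
    """Immune-related RECIST class on total tumor burden.

    CR below an absolute detectability floor, PR at >=30% shrinkage, PD at
    >=20% growth, SD otherwise.
    """
    if baseline_cm3 <= 0:
        raise ValueError("baseline load must be positive")
    if week12_cm3 < 0:
        raise ValueError("follow-up load must be non-negative")
    if week12_cm3 < cr_floor_cm3:
        return "CR"
    if week12_cm3 <= 0.70 * baseline_cm3:
        return "PR"
    if week12_cm3 >= 1.20 * baseline_cm3:
        return "PD"
    return "SD"


def run_trial(patients: Sequence[VirtualPatient],
              schedule: DoseSchedule | None = None, weeks: float = 12.0,
              reinvig_window_weeks: float = 6.0,
              scenario: ReferenceScenario = REFERENCE_SCENARIO
              ) -> pd.DataFrame:
    """Simulate a q3w pembrolizumab trial and classify every patient.

    Returns one row per patient: baseline and week-12 loads, the maximal
    reinvigoration percentage over the first ``reinvig_window_weeks``, the
    irRECIST class and the responder flag (CR or PR).  Patients whose
    simulation fails are excluded and reported in the ``failed`` attribute.
    """
    if schedule is None:
        schedule = DoseSchedule.q3w(120.0, weeks * WEEK_H)
    rows = []
    failed: list[int] = []
    for p in patients:
        try:
            traj = _simulate_patient(p, schedule, weeks, scenario)
        except SimulationError:
            failed.append(p.id)
            continue
        loads = traj.tumor_cells / p.gp.cells_per_cm3
        week12 = float(loads[-1])
        window = traj.times <= reinvig_window_weeks * WEEK_H
        reinvig = reinvigoration_series(traj)
        reinvig_max = float(np.max(reinvig[window]))
        klass = classify_irRECIST(p.baseline_load_cm3, week12)
        rows.append({
            "id": p.id,
            "baseline_cm3": p.baseline_load_cm3,
            "n_lesions": p.n_lesions,
            "week12_cm3": week12,
            "reinvigoration_pct": reinvig_max,
            "irrecist": klass,
            "responder": klass in ("CR", "PR"),
        })
    df = pd.DataFrame(rows, columns=["id", "baseline_cm3", "n_lesions",
                                     "week12_cm3", "reinvigoration_pct",
                                     "irrecist", "responder"])
    df.attrs["failed"] = failed
    return df


def weighted_accuracy(ratios: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, float]:
    """Best threshold on a score and its balanced accuracy.

    Predicts "responder" for ``ratio >= threshold`` and scores with the mean
    of sensitivity and specificity; every midpoint between adjacent sorted
    scores (plus both outer extremes) is tried and ties resolve to the
    lowest threshold.  Requires both classes to be present.
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if ratios.shape != labels.shape or ratios.ndim != 1:
        raise ValueError("ratios and labels must be equal-length 1-D")
    if ratios.size < 2 or labels.all() or not labels.any():
        raise ValueError("both classes must be present to score a classifier")
    order = np.argsort(ratios, kind="stable")
    sorted_r = ratios[order]
    mids = (sorted_r[:-1] + sorted_r[1:]) / 2.0
    candidates = np.concatenate([[sorted_r[0] - 1.0], mids,
                                 [sorted_r[-1] + 1.0]])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        pred = ratios >= thr
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        acc = 0.5 * (sens + spec)
        if acc > best_acc + 1e-12:
            best_acc, best_thr = acc, thr
    return float(best_thr), float(best_acc)


def trial_accuracy(result: pd.DataFrame) -> tuple[float, float]:
    """Balanced accuracy of the reinvigoration/baseline-load ratio classifier."""
    ratios = (result["reinvigoration_pct"] /
              result["baseline_cm3"]).to_numpy()
    labels = result["responder"].to_numpy()
    return weighted_accuracy(ratios, labels)
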