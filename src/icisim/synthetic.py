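"""Synthetic tumor-load measurement series.

Real PET/CT tumor-load series are sums of per-lesion volumes, each derived
from three orthogonal caliper axes with a bounded per-axis measurement error
(up to 3 mm for a standard CT read).  This module forward-simulates the
model, samples the tumor load at clinic visits, and perturbs each sample
through that geometric error model; it also ships a deterministic
reference-patient series (a pembrolizumab-treated advanced-melanoma course
with two tumor-load maxima and long-term response) used for calibration and
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DoseSchedule, GeneralParameters, SpecificParameters, TumorLoadSeries,
    initial_state, simulate, tumor_load,
)

__all__ = [
    "NoiseModel", "ReferenceScenario", "REFERENCE_SCENARIO",
    "generate_series", "patient_o_fixture", "FIXTURE_SAMPLE_WEEKS",
]

WEEK_H = 7 * 24.0


@dataclass(frozen=True)
class NoiseModel:
    """CT axis-error model for lesion volumetry.

    Each lesion is treated as an ellipsoid measured along ``n_axes``
    orthogonal axes; every axis reading carries an independent uniform error
    in ``[-axis_err_mm, +axis_err_mm]`` (the 3 mm default is the maximal
    error of a standard CT measurement, read as the half-width of a uniform
    distribution).  The emitted per-point error bar is the first-order
    volume error under identical errors along all axes.
    """

    axis_err_mm: float = 3.0
    n_axes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_err_mm < 0:
            raise ValueError("axis_err_mm must be non-negative")
        if self.n_axes < 1:
            raise ValueError("n_axes must be >= 1")


@dataclass(frozen=True)
class ReferenceScenario:
    """Initial conditions of the reference-patient simulation."""

    baseline_load_cm3: float = 10.0
    total_T: float = 1e7
    dc0: float = 10.0
    n_lesions: int = 1


#: Calibrated reference scenario: with the default specific and general
#: parameters it reproduces the double-peak treated course.
REFERENCE_SCENARIO = ReferenceScenario()

#: Clinic-visit schedule of the shipped fixture: denser surveillance over
#: the first cycle (weeks 0, 3, 6), then every 9 weeks to week 162.
FIXTURE_SAMPLE_WEEKS = (0.0, 3.0, 6.0) + tuple(
    float(w) for w in range(9, 163, 9))


def _perturb_volumes(load_cm3: np.ndarray, n_lesions: int,
                     noise: NoiseModel, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Perturb sampled loads through the per-lesion axis-error model.

    The total load is split into ``n_lesions`` equal spherical lesions of
    diameter ``d``; each axis of each lesion is perturbed independently and
    the volume recomputed, so the perturbation is exactly unbiased.  Returns
    (noisy loads, first-order error bars), both in cm^3.
    """
    delta_cm = noise.axis_err_mm / 10.0
    noisy = np.empty_like(load_cm3)
    err = np.empty_like(load_cm3)
    for k, v in enumerate(load_cm3):
        v_les = max(v, 0.0) / n_lesions
        d = (6.0 * v_les / np.pi) ** (1.0 / 3.0)
        axes = d + rng.uniform(-delta_cm, delta_cm,
                               size=(n_lesions, noise.n_axes))
        axes = np.clip(axes, 0.0, None)
        # ellipsoid volume from n axes (diameters): (pi/6) * prod(axes)
        # for n_axes != 3 the remaining axes keep the unperturbed diameter
        prod = np.prod(axes, axis=1) * d ** (3 - noise.n_axes)
        noisy[k] = float(np.sum(np.pi / 6.0 * prod))
        err[k] = n_lesions * (np.pi / 6.0) * noise.n_axes * d ** 2 * delta_cm
    return noisy, err


def generate_series(sp: SpecificParameters, gp: GeneralParameters,
                    schedule: DoseSchedule, sample_weeks,
                    noise: NoiseModel | None = None,
                    scenario: ReferenceScenario = REFERENCE_SCENARIO,
                    anchor_t0: bool = False) -> TumorLoadSeries:
    """Simulate and sample a synthetic clinical tumor-load series.

    The model is integrated over the sampling horizon from the scenario's
    uniform initial state, the load is read off at ``sample_weeks``, and each
    sample is perturbed through the CT axis-error model (``noise=None`` or
    ``axis_err_mm=0`` yields the noiseless model output).  With
    ``anchor_t0`` the week-0 sample is pinned to the exact simulated
    baseline, mirroring the convention that the baseline load is known.
    """
    weeks = np.asarray(sample_weeks, dtype=float)
    if weeks.ndim != 1 or weeks.size == 0:
        raise ValueError("sample_weeks must be a non-empty 1-D sequence")
    t_end = float(weeks[-1]) * WEEK_H
    init = initial_state(scenario.total_T,
                         scenario.baseline_load_cm3 * gp.cells_per_cm3,
                         scenario.dc0, gp)
    traj = simulate(sp, gp, schedule, max(t_end, 6.0), init)
    series = tumor_load(traj)
    clean = np.interp(weeks, series.weeks, series.load_cm3)

    if noise is None or noise.axis_err_mm == 0:
        return TumorLoadSeries(weeks=weeks, load_cm3=clean,
                               err_cm3=np.zeros_like(clean))
    rng = np.random.default_rng(noise.seed)
    noisy, err = _perturb_volumes(clean, scenario.n_lesions, noise, rng)
    if anchor_t0 and weeks[0] == 0.0:
        noisy[0] = clean[0]
    return TumorLoadSeries(weeks=weeks, load_cm3=noisy, err_cm3=err)


def patient_o_fixture() -> TumorLoadSeries:
    """Deterministic reference-patient measurement series.

    Generated from the default (best-fit) specific parameters and calibrated
    general defaults under 120 mg q3w dosing, sampled every 9 weeks to week
    162 with the 3 mm axis-error model at noise seed 0; the week-0 point is
    anchored to the exact baseline load.  Regeneration is bit-stable, and the
    repository ships the same series as ``fixtures/patient_o_like.csv``.

    This is a synthetic stand-in for an unavailable clinical lesion table,
    emulating a treated course with tumor-load maxima near weeks 3-5 and
    45-52 and a final load below 30% of baseline.
    """
    sp = SpecificParameters()
    gp = GeneralParameters()
    t_end = FIXTURE_SAMPLE_WEEKS[-1] * WEEK_H
    schedule = DoseSchedule.q3w(120.0, t_end)
    return generate_series(sp, gp, schedule, FIXTURE_SAMPLE_WEEKS,
                           noise=NoiseModel(axis_err_mm=3.0, seed=0),
                           scenario=REFERENCE_SCENARIO, anchor_t0=True)
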