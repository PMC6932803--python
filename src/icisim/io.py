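"""CSV/JSON/YAML readers-writers, parameter scans and plotting.

File conventions:

* tumor-load series CSV: columns ``week,load_cm3[,err_cm3]``;
* trajectory export CSV: ``week,tumor_load_cm3,reinvigoration_pct,
  drug_mg_per_L``;
* parameter files (YAML or JSON): top-level sections ``specific`` and
  ``general`` whose keys must match the corresponding parameter fields
  exactly (unknown keys are rejected);
* every CLI run writes a JSON manifest (parameters, seed, package version)
  sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    DoseSchedule, GeneralParameters, SpecificParameters, Trajectory,
    TumorLoadSeries, initial_state, reinvigoration_series, simulate,
    tumor_load,
)
from .synthetic import REFERENCE_SCENARIO, ReferenceScenario, WEEK_H

__all__ = [
    "load_series", "save_series", "load_params", "save_params",
    "trajectory_frame", "save_trajectory", "scan_parameter",
    "load_curve_maxima", "save_results", "write_manifest",
    "plot_trajectory", "plot_trial_scatter",
]


def load_curve_maxima(weeks, loads, smooth_weeks: float = 1.5,
                      min_separation_weeks: float = 4.0) -> list[float]:
    """Weeks of the local maxima of a tumor-load curve.

    The curve is smoothed with a moving average of half-width
    ``smooth_weeks`` before peak detection, so the ~3-week dosing ripple
    does not register as a maximum; maxima closer together than
    ``min_separation_weeks`` are merged (keeping the larger).
    """
    weeks = np.asarray(weeks, dtype=float)
    loads = np.asarray(loads, dtype=float)
    if weeks.size < 3:
        return []
    dt = np.median(np.diff(weeks))
    half = max(int(round(smooth_weeks / dt)), 1)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    padded = np.concatenate([np.full(half, loads[0]), loads,
                             np.full(half, loads[-1])])
    sm = np.convolve(padded, kernel, mode="valid")
    idx = [k for k in range(1, sm.size - 1)
           if sm[k] >= sm[k - 1] and sm[k] > sm[k + 1]]
    merged: list[int] = []
    for k in idx:
        if merged and weeks[k] - weeks[merged[-1]] < min_separation_weeks:
            if sm[k] > sm[merged[-1]]:
                merged[-1] = k
        else:
            merged.append(k)
    return [float(weeks[k]) for k in merged]


# ---------------------------------------------------------------------------
# Tumor-load series
# ---------------------------------------------------------------------------

def load_series(path) -> TumorLoadSeries:
    """Read a ``week,load_cm3[,err_cm3]`` CSV into a TumorLoadSeries."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty series file") from None
    required = {"week", "load_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    weeks = df["week"].to_numpy(dtype=float)
    if weeks.size == 0:
        raise ValueError(f"{path}: series contains no rows")
    bad = np.where(np.diff(weeks) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: weeks not strictly increasing at row {bad[0] + 1} "
            f"(week {weeks[bad[0] + 1]} after {weeks[bad[0]]})")
    err = df["err_cm3"].to_numpy(dtype=float) if "err_cm3" in df else None
    return TumorLoadSeries(weeks=weeks,
                           load_cm3=df["load_cm3"].to_numpy(dtype=float),
                           err_cm3=err)


def save_series(series: TumorLoadSeries, path) -> None:
    """Write a TumorLoadSeries as CSV (full float precision round-trip)."""
    cols = {"week": series.weeks, "load_cm3": series.load_cm3}
    if series.err_cm3 is not None:
        cols["err_cm3"] = series.err_cm3
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    section = {k: tuple(v) if isinstance(v, list) else v
               for k, v in section.items()}
    return cls(**section)


def load_params(path) -> tuple[SpecificParameters, GeneralParameters]:
    """Read specific/general parameters from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(data) - {"specific", "general"}
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    sp = _build(SpecificParameters, data.get("specific", {}), "specific")
    gp = _build(GeneralParameters, data.get("general", {}), "general")
    return sp, gp


def save_params(sp: SpecificParameters, gp: GeneralParameters, path) -> None:
    path = Path(path)
    data = {"specific": dataclasses.asdict(sp),
            "general": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(gp).items()}}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Trajectories and scans
# ---------------------------------------------------------------------------

def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tabulate a trajectory: load, reinvigoration and drug level per week."""
    series = tumor_load(traj)
    return pd.DataFrame({
        "week": series.weeks,
        "tumor_load_cm3": series.load_cm3,
        "reinvigoration_pct": reinvigoration_series(traj),
        "drug_mg_per_L": traj.drug_conc,
    })


def save_trajectory(traj: Trajectory, path) -> None:
    trajectory_frame(traj).to_csv(path, index=False, float_format="%.10g")


def scan_parameter(sp: SpecificParameters, gp: GeneralParameters,
                   param_name: str, n_steps: int = 10, step: float = 1.05,
                   months: float = 28.0, dose_mg: float = 120.0,
                   scenario: ReferenceScenario = REFERENCE_SCENARIO,
                   grid_h: float = 24.0) -> pd.DataFrame:
    """Tumor-load curves over a geometric grid of one parameter.

    The parameter is multiplied by ``step**k`` for ``k`` in ``[-n_steps,
    n_steps]`` (default 1.05**10, a 1.63-fold range either way) and each
    variant is simulated under q3w dosing for ``months`` months.  Returns a
    long-format frame with columns ``fold, param_value, week, load_cm3``.
    """
    if step <= 1.0:
        raise ValueError("step must exceed 1")
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    is_specific = hasattr(sp, param_name)
    base = getattr(sp if is_specific else gp, param_name)
    t_end = months * 30.4375 * 24.0
    sched = DoseSchedule.q3w(dose_mg, t_end)
    frames = []
    for k in range(-n_steps, n_steps + 1):
        fold = step ** k
        if is_specific:
            sp_k, gp_k = dataclasses.replace(sp, **{param_name: base * fold}), gp
        else:
            sp_k, gp_k = sp, dataclasses.replace(gp, **{param_name: base * fold})
        init = initial_state(scenario.total_T,
                             scenario.baseline_load_cm3 * gp_k.cells_per_cm3,
                             scenario.dc0, gp_k)
        traj = simulate(sp_k, gp_k, sched, t_end, init, grid_h=grid_h)
        series = tumor_load(traj)
        frames.append(pd.DataFrame({
            "fold": fold, "param_value": base * fold,
            "week": series.weeks, "load_cm3": series.load_cm3}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Results and manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_results(obj, path) -> None:
    """Serialize a (possibly nested, numpy-bearing) result object to JSON."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def write_manifest(path, command: str, seed: int | None,
                   sp: SpecificParameters, gp: GeneralParameters,
                   extra: dict | None = None) -> None:
    """Record everything needed to reproduce a CLI run."""
    from . import __version__
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "specific": _jsonable(sp),
        "general": _jsonable(gp),
    }
    if extra:
        manifest.update(_jsonable(extra))
    Path(path).write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_trajectory(traj: Trajectory, path, title: str = "") -> None:
    """Tumor load (cm^3, log scale) against weeks, with dose ticks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = trajectory_frame(traj)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(frame["week"], frame["tumor_load_cm3"], lw=1.5)
    ax.set_xlabel("weeks of treatment")
    ax.set_ylabel("tumor load (cm$^3$)")
    ax.set_yscale("log")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trial_scatter(result: pd.DataFrame, path, title: str = "") -> None:
    """Baseline load vs reinvigoration, coloured by irRECIST class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"CR": "tab:green", "PR": "tab:blue", "SD": "black",
              "PD": "tab:red"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for klass, sub in result.groupby("irrecist"):
        filled = klass != "SD"
        ax.scatter(sub["baseline_cm3"], sub["reinvigoration_pct"],
                   label=klass, s=28,
                   facecolors=colors.get(klass, "grey") if filled else "none",
                   edgecolors=colors.get(klass, "grey"))
    ax.set_xscale("log")
    ax.set_xlabel("baseline tumor load (cm$^3$)")
    ax.set_ylabel("reinvigoration (max % Ki67$^+$, weeks 0-6)")
    ax.legend(title="irRECIST")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
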