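"""Simulation experiment design: condition/rate sweeps over seeds, tracked-
cell summaries, and the perimeter/circularity signature that separates the
two constriction regimes.

The published experiment ramps ten tracked cells from sts 20 onward under
either a contractility increase (rates c = [0, 1, 2.5, 5, 7.5]e-7 per
iteration) or a resting-area decrease (r = [0, 0.5, 1, 2.5, 3.5]e-4 per
iteration) and compares tracked perimeter and circularity against a
control.  A purse-string-like (tension-driven) constriction shrinks the
perimeter while the cell rounds up; a resting-area-driven constriction
shrinks the perimeter while circularity falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mc_dynamics import RateSchedule, run_simulation, scale_rate
from .vertex_core import ModelParams, build_initial_tissue, select_tracked_cells

__all__ = [
    "Preset",
    "PRESETS",
    "CONTRACTILITY_RATES",
    "RESTING_AREA_RATES",
    "SweepResult",
    "run_sweep",
    "regime_signature",
]

# per-iteration ramp rates of the published sweep (full-scale iteration count)
CONTRACTILITY_RATES: Tuple[float, ...] = (0.0, 1.0e-7, 2.5e-7, 5.0e-7, 7.5e-7)
RESTING_AREA_RATES: Tuple[float, ...] = (0.0, 0.5e-4, 1.0e-4, 2.5e-4, 3.5e-4)

FULL_ITERATIONS_PER_STS = 130_000


@dataclass(frozen=True)
class Preset:
    """Problem-size preset.

    ``paper`` matches the published setup (1141 cells, 130,000 iterations
    per sts).  ``small`` is a desk-scale preset (300 cells, 13,000
    iterations per sts) whose per-iteration ramp rates are rescaled so the
    per-sts ramp factor equals the full-scale one.
    """

    name: str
    n_cells: int
    iterations_per_sts: int
    n_tracked: int = 10
    ramp_start_sts: int = 20
    total_sts: int = 50

    def params(self, base: Optional[ModelParams] = None) -> ModelParams:
        base = base or ModelParams()
        return base.with_(iterations_per_sts=self.iterations_per_sts)

    def scaled_rate(self, full_scale_rate: float) -> float:
        """Rescale a published per-iteration rate to this preset's
        iteration count, preserving the per-sts ramp factor."""
        return scale_rate(
            full_scale_rate, FULL_ITERATIONS_PER_STS, self.iterations_per_sts
        )


PRESETS: Dict[str, Preset] = {
    "paper": Preset("paper", 1141, 130_000),
    "small": Preset("small", 300, 13_000),
}


@dataclass
class SweepResult:
    """Tidy per-sts results for every (condition, rate, seed) run.

    ``summaries`` columns: condition, rate (full-scale units), seed, sts,
    mean_P, sem_P, mean_C, sem_C, mean_A (mean +/- SEM over the tracked
    cells).  ``trajectories`` holds the per-cell observables with the same
    keying columns.  ``failures`` records runs that raised, without
    aborting the sweep.
    """

    summaries: pd.DataFrame
    trajectories: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: Dict = field(default_factory=dict)
    failures: List[Dict] = field(default_factory=list)

    def _select(self, df, condition: str, rate: float, seed: int) -> pd.DataFrame:
        m = (
            (df["condition"] == condition)
            & np.isclose(df["rate"], rate)
            & (df["seed"] == seed)
        )
        return df[m]

    def get(self, condition: str, rate: float, seed: int) -> pd.DataFrame:
        return self._select(self.summaries, condition, rate, seed).set_index("sts")

    def get_trajectory(self, condition: str, rate: float, seed: int) -> pd.DataFrame:
        return self._select(self.trajectories, condition, rate, seed)


def run_sweep(
    conditions: Sequence[str] = ("control", "contractility", "resting_area"),
    contractility_rates: Sequence[float] = CONTRACTILITY_RATES,
    resting_area_rates: Sequence[float] = RESTING_AREA_RATES,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    preset: Preset | str = "small",
    params: Optional[ModelParams] = None,
    lloyd_steps: int = 3,
    initial_area_ratio: float = 3.7,
) -> SweepResult:
    """One run per (condition, rate, seed), paired by seed.

    For a given seed, every condition starts from the identical initial
    mesh and tracked-cell set, so trajectories are identical up to the
    ramp onset and rate-zero runs coincide with the control.  Rates are
    given in full-scale (130,000 iterations/sts) units and rescaled to the
    preset; the ``rate`` column keeps the full-scale value.  A failed run
    is recorded in ``failures`` and the sweep continues.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    params = preset.params(params)

    grid: List[Tuple[str, float]] = []
    for cond in conditions:
        if cond == "control":
            grid.append(("control", 0.0))
        elif cond == "contractility":
            grid += [("contractility", r) for r in contractility_rates]
        elif cond == "resting_area":
            grid += [("resting_area", r) for r in resting_area_rates]
        else:
            raise ValueError(f"unknown condition {cond!r}")

    rows = []
    traj_rows = []
    failures: List[Dict] = []
    for seed in seeds:
        mesh = build_initial_tissue(
            preset.n_cells,
            seed,
            lloyd_steps=lloyd_steps,
            initial_area_ratio=initial_area_ratio,
        )
        tracked = tuple(
            select_tracked_cells(mesh, preset.n_tracked, seed + 10_000)
        )
        for cond, rate in grid:
            schedule = RateSchedule(
                cond,
                preset.scaled_rate(rate),
                preset.ramp_start_sts,
                preset.total_sts,
                tracked,
            )
            try:
                res = run_simulation(mesh, params, schedule, seed=seed)
            except Exception as exc:  # record and continue
                failures.append(
                    {"condition": cond, "rate": rate, "seed": seed, "error": str(exc)}
                )
                continue
            for df, sink in ((res.summary, rows), (res.trajectory, traj_rows)):
                d = df.copy()
                d.insert(0, "seed", seed)
                d.insert(0, "rate", rate)
                d.insert(0, "condition", cond)
                sink.append(d)
    summaries = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    trajectories = pd.concat(traj_rows, ignore_index=True) if traj_rows else pd.DataFrame()
    meta = {
        "preset": preset.name,
        "n_cells": preset.n_cells,
        "iterations_per_sts": preset.iterations_per_sts,
        "seeds": list(seeds),
        "initial_area_ratio": initial_area_ratio,
    }
    return SweepResult(summaries, trajectories, meta, failures)


def window_changes(
    trajectory: pd.DataFrame,
    window: Tuple[int, int] = (20, 40),
    endpoint_halfwidth: int = 2,
) -> pd.DataFrame:
    """Per-cell paired change of perimeter and circularity over an sts
    window.

    Endpoint values are averaged over ``+/- endpoint_halfwidth`` sts
    (clipped to the available range) to suppress single-snapshot noise.
    Returns one row per tracked cell with columns dP and dC.
    """
    lo, hi = window
    smax = int(trajectory["sts"].max())
    if lo > smax or hi > smax:
        raise ValueError(f"trajectory does not span sts window {window}")
    out = {}
    for col, name in (("perimeter", "dP"), ("circularity", "dC")):
        t = trajectory.pivot_table(index="cell_id", columns="sts", values=col)
        ends = []
        for anchor in (lo, hi):
            cols = [
                s
                for s in range(anchor - endpoint_halfwidth, anchor + endpoint_halfwidth + 1)
                if s in t.columns
            ]
            ends.append(t[cols].mean(axis=1))
        out[name] = ends[1] - ends[0]
    return pd.DataFrame(out)


def regime_signature(
    run: pd.DataFrame,
    window: Tuple[int, int] = (20, 40),
    sem_multiplier: float = 2.0,
) -> str:
    """Classify one run's constriction regime.

    ``run`` is a per-cell trajectory (columns sts, cell_id, perimeter,
    circularity).  Over the sts ``window``: 'tension-like' when the
    tracked perimeter decreases while circularity increases,
    'resting-area-like' when the perimeter decreases while circularity
    decreases, 'none' otherwise.  Changes are per-cell paired differences;
    each must exceed ``sem_multiplier`` times its SEM over the cells to
    count as a change (set ``sem_multiplier=0`` for a pure sign
    classification).
    """
    ch = window_changes(run, window)
    n = len(ch)
    dP, dC = ch["dP"].mean(), ch["dC"].mean()
    semP = ch["dP"].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    semC = ch["dC"].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    if dP < -sem_multiplier * semP and dC > sem_multiplier * semC:
        return "tension-like"
    if dP < -sem_multiplier * semP and dC < -sem_multiplier * semC:
        return "resting-area-like"
    return "none"


def dose_response(
    sweep: SweepResult, condition: str, at_sts: int = 40
) -> pd.DataFrame:
    """Tracked mean perimeter at ``at_sts`` per (rate, seed) for one
    condition, with the rate-zero control included."""
    s = sweep.summaries
    rows = []
    for (cond, rate, seed), grp in s.groupby(["condition", "rate", "seed"]):
        if cond not in (condition, "control"):
            continue
        g = grp.set_index("sts")
        if at_sts not in g.index:
            continue
        rows.append(
            {"rate": rate, "seed": seed, "mean_P": g.loc[at_sts, "mean_P"], "condition": cond}
        )
    df = pd.DataFrame(rows)
    # a control run stands in for the rate-zero grid point when absent
    if not df.empty and not np.isclose(df[df.condition == condition]["rate"], 0).any():
        ctrl = df[df.condition == "control"].copy()
        ctrl["condition"] = condition
        df = pd.concat([df[df.condition == condition], ctrl], ignore_index=True)
    else:
        df = df[df.condition == condition]
    return df.sort_values(["rate", "seed"]).reset_index(drop=True)
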