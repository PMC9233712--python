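"""Synthetic inputs with the statistical structure the analysis assumes.

Each generator returns both the data and a machine-readable ground-truth
record, so every pipeline stage (onset detection, alignment, pulse
metrics, coupling lag, contraction yield, kymographs, duration
statistics) can be scored against known values without any imaging data.

What is emulated: pulsatile myosin-like intensity traces coupled to
perimeter constriction with a tunable frame lag and a yield change at a
known onset; perimeter traces with a plateau -> constriction change
point; radial intensity fields with a junctional ring and a medial pool
dropping at a known time; and cohorts of cells with jittered onsets and
ends.  Noise is additive Gaussian by default (a Poisson option exists for
intensities); the post-onset decline is linear, matching the near-linear
published mean constriction curves over the final ~20 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .trace_analysis import TraceSeries

__all__ = [
    "SynthCohortSpec",
    "gen_extrusion_trace",
    "gen_pulsatile_pair",
    "gen_radial_stack",
    "gen_cohort",
]


@dataclass(frozen=True)
class SynthCohortSpec:
    """Parameters of a synthetic extruding-cell cohort.

    Times are minutes; the default frame interval of 1 min and ~30-min
    extrusion duration match the live-imaging setting the pipeline
    targets.  ``pulse_rate`` is the Poisson rate of myosin pulses per
    minute, ``coupling_lag_frames`` the (integer) delay between a myosin
    fluctuation and the constriction it drives, ``yield_multiplier`` the
    factor by which deformation per unit myosin rises after the onset.
    """

    n_cells: int = 20
    frame_interval: float = 1.0
    duration_min: float = 120.0
    plateau: float = 100.0
    plateau_sd: float = 5.0
    onset_min: float = 80.0
    onset_jitter_min: float = 10.0
    constriction_slope: float = -2.0  # units/min after the onset
    pulse_rate: float = 0.1  # pulses/min
    pulse_min_gap_min: float = 0.0  # refractory gap between pulses (0 = Poisson)
    pulse_amplitude: float = 10.0
    pulse_sigma_min: float = 2.0
    myosin_baseline: float = 20.0
    coupling_gain: float = 0.1
    coupling_lag_frames: int = 3
    yield_multiplier: float = 1.0
    noise_sd: float = 1.0
    noise_model: str = "gaussian"  # or "poisson" for intensities
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plateau_sd", "onset_jitter_min", "pulse_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coupling_lag_frames != int(self.coupling_lag_frames):
            raise ValueError("coupling_lag_frames must be an integer")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _noise(rng: np.random.Generator, spec: SynthCohortSpec, base: np.ndarray) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.zeros_like(base)
    if spec.noise_model == "poisson":
        lam = np.clip(base, 0, None)
        return rng.poisson(lam) - lam
    return rng.normal(0, spec.noise_sd, size=base.shape)


def gen_extrusion_trace(
    spec: SynthCohortSpec, stream: int = 0
) -> Tuple[TraceSeries, Dict]:
    """A perimeter trace: noisy plateau, then a linear decline to zero.

    Truth record: onset (min), end (min, where the noiseless trace hits
    zero, capped at the trace end), duration, plateau, slope.
    """
    if spec.constriction_slope == 0:
        raise ValueError("constriction_slope must be nonzero")
    rng = spec.rng(stream)
    dt = spec.frame_interval
    times = np.arange(0.0, spec.duration_min + dt / 2, dt)
    plateau = spec.plateau + rng.normal(0, spec.plateau_sd)
    clean = np.where(
        times < spec.onset_min,
        plateau,
        plateau + spec.constriction_slope * (times - spec.onset_min),
    )
    end = spec.onset_min + plateau / abs(spec.constriction_slope)
    completes = end <= float(times[-1])
    end = min(end, float(times[-1]))
    # the measurement stops when the apical surface is gone
    keep = times <= end + dt / 2
    times = times[keep]
    clean = np.clip(clean[keep], 0.0, None)
    values = clean + rng.normal(0, spec.noise_sd, size=clean.shape)
    if completes:
        # at termination the apical perimeter is 0 by definition
        end = float(times[-1])
        values[-1] = 0.0
    trace = TraceSeries(times, values, channel="perimeter", cell_id=f"synth{stream}")
    truth = {
        "onset": spec.onset_min,
        "end": end,
        "duration": end - spec.onset_min,
        "plateau": plateau,
        "slope": spec.constriction_slope,
    }
    return trace, truth


def gen_pulsatile_pair(
    spec: SynthCohortSpec, stream: int = 0
) -> Tuple[TraceSeries, TraceSeries, Dict]:
    """Coupled (myosin, perimeter) traces.

    Myosin is a baseline plus Poisson-timed Gaussian pulses plus noise.
    The contraction rate is ``gain * pulses(t - lag)``, with the gain
    multiplied by ``yield_multiplier`` from the onset on; the perimeter
    integrates the negative contraction rate from the plateau.  Truth
    stores pulse times/amplitudes, the lag (frames and minutes), the
    yield multiplier and the onset.
    """
    rng = spec.rng(stream + 1_000)
    dt = spec.frame_interval
    times = np.arange(0.0, spec.duration_min + dt / 2, dt)
    n = len(times)
    lag = int(spec.coupling_lag_frames)
    if lag >= n:
        raise ValueError("coupling lag exceeds the trace length")

    if spec.pulse_min_gap_min > 0:
        # renewal process with a refractory gap; mean rate stays pulse_rate
        mean_gap = 1.0 / spec.pulse_rate
        if spec.pulse_min_gap_min >= mean_gap:
            raise ValueError("pulse_min_gap_min must be below 1/pulse_rate")
        exp_mean = mean_gap - spec.pulse_min_gap_min
        pts = []
        t = float(times[0]) + rng.exponential(exp_mean)
        while t < times[-1]:
            pts.append(t)
            t += spec.pulse_min_gap_min + rng.exponential(exp_mean)
        pulse_times = np.array(pts)
    else:
        n_pulses = rng.poisson(spec.pulse_rate * spec.duration_min)
        pulse_times = np.sort(rng.uniform(times[0], times[-1], size=n_pulses))
    n_pulses = len(pulse_times)
    amps = spec.pulse_amplitude * rng.uniform(0.8, 1.2, size=n_pulses)
    pulses = np.zeros(n)
    for t0, a in zip(pulse_times, amps):
        pulses += a * np.exp(-0.5 * ((times - t0) / spec.pulse_sigma_min) ** 2)
    myosin_clean = spec.myosin_baseline + pulses
    myosin = myosin_clean + _noise(rng, spec, myosin_clean)

    shifted = np.concatenate([np.zeros(lag), pulses[: n - lag]])
    gain = np.where(
        times >= spec.onset_min,
        spec.coupling_gain * spec.yield_multiplier,
        spec.coupling_gain,
    )
    rate = gain * shifted  # positive = constriction
    perimeter = spec.plateau - np.concatenate([[0.0], np.cumsum(rate[:-1]) * dt])
    perimeter = perimeter + rng.normal(0, spec.noise_sd * 0.1, size=n)

    cid = f"synthpair{stream}"
    truth = {
        "pulse_times": pulse_times,
        "pulse_amplitudes": amps,
        "lag_frames": lag,
        "lag_min": lag * dt,
        "onset": spec.onset_min,
        "yield_multiplier": spec.yield_multiplier,
        "gain": spec.coupling_gain,
    }
    return (
        TraceSeries(times, myosin, channel="myosin", cell_id=cid),
        TraceSeries(times, perimeter, channel="perimeter", cell_id=cid),
        truth,
    )


def gen_radial_stack(
    ring_radius_schedule,
    medial_level_schedule=None,
    image_size: int = 64,
    ring_intensity: float = 10.0,
    ring_thickness: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """(junction stack, signal stack) of a shrinking bright ring plus a
    medial pool.

    Per frame t, the junction channel is a ring of the scheduled radius
    (Gaussian cross-section of width ``ring_thickness`` px) and the
    signal channel a medial disk at the scheduled level inside that ring.
    Truth stores the radius and medial level per frame.
    """
    radii = np.asarray(ring_radius_schedule, dtype=float)
    if not np.all(np.isfinite(radii)):
        raise ValueError("ring radius schedule must be finite")
    if np.any(radii >= image_size / 2):
        raise ValueError("ring radius must stay inside the image half-size")
    T = len(radii)
    medial = (
        np.full(T, 5.0)
        if medial_level_schedule is None
        else np.asarray(medial_level_schedule, dtype=float)
    )
    if len(medial) != T:
        raise ValueError("medial schedule must match the radius schedule")
    rng = np.random.default_rng(seed)
    c = (image_size - 1) / 2
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    rr = np.hypot(yy - c, xx - c)
    junction = np.empty((T, image_size, image_size))
    sig = np.empty_like(junction)
    for t in range(T):
        ring = ring_intensity * np.exp(-0.5 * ((rr - radii[t]) / ring_thickness) ** 2)
        junction[t] = ring
        sig[t] = medial[t] * (rr < radii[t] - ring_thickness) + 0.2 * ring
        if noise_sd > 0:
            junction[t] += rng.normal(0, noise_sd, rr.shape)
            sig[t] += rng.normal(0, noise_sd, rr.shape)
    truth = {"radii": radii, "medial_levels": medial, "centre": (c, c)}
    return junction, sig, truth


def gen_cohort(
    spec: SynthCohortSpec,
    duration_multiplier: float = 1.0,
) -> Tuple[List[TraceSeries], pd.DataFrame]:
    """A cohort of extrusion perimeter traces with jittered onsets.

    Onsets are drawn uniformly in ``onset_min +/- onset_jitter_min``; the
    constriction slope is divided by ``duration_multiplier`` so cohorts
    with slowed extrusion (e.g. a 3x duration) can be generated from the
    same spec.  Truth table: one row per cell with cell_id, onset, end,
    duration.
    """
    rng = spec.rng(77)
    traces: List[TraceSeries] = []
    rows = []
    for i in range(spec.n_cells):
        onset = spec.onset_min + rng.uniform(-1, 1) * spec.onset_jitter_min
        cell_spec = SynthCohortSpec(
            **{
                **spec.__dict__,
                "onset_min": onset,
                "constriction_slope": spec.constriction_slope / duration_multiplier,
                "duration_min": spec.duration_min * max(duration_multiplier, 1.0),
                "seed": spec.seed,
            }
        )
        trace, truth = gen_extrusion_trace(cell_spec, stream=10_000 + i)
        trace.cell_id = f"cell{i:03d}"
        traces.append(trace)
        rows.append({"cell_id": trace.cell_id, **truth})
    return traces, pd.DataFrame(rows)
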