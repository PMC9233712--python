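"""Quantification pipeline for per-cell time series and simple image grids.

Implements the measurements used to characterise apical constriction and
cell extrusion from live imaging: trace smoothing, constriction-onset
(inflection) detection by a two-segment linear fit, end/onset alignment
and normalisation of cell cohorts, derivatives and normalised
cross-correlation, myosin pulse metrics (time, amplitude, half-max width,
prominence, frequency), the contraction yield (constriction rate per unit
myosin at contraction peaks, binned in 5-min windows around the onset),
radial averaged kymographs around the cell centre, region mean intensities
(medial / junctional / total), apicobasal intensity profiles, perimeter
fold changes, extrusion durations, cell-elimination proportions with exact
binomial statistics, and a normality-gated two-sample test dispatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage.morphology import binary_dilation, binary_erosion, disk
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TraceSeries",
    "AlignedEnsemble",
    "Pulse",
    "PulseSet",
    "Kymograph",
    "EliminationCounts",
    "OnsetResult",
    "smooth_trace",
    "detect_onset",
    "align_normalize",
    "rate_of_change",
    "contraction_rate",
    "xcorr_normalized",
    "coupling_lag",
    "detect_pulses",
    "pulse_frequency",
    "contraction_yield",
    "yield_ratio",
    "radial_kymograph",
    "region_intensities",
    "apicobasal_profile",
    "perimeter_fold_change",
    "extrusion_duration",
    "duration_histogram",
    "fisher_exact_two_sided",
    "elimination_stats",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class TraceSeries:
    """A per-cell time series on a uniform grid of minutes."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan

    def __len__(self) -> int:
        return len(self.times)

    def with_values(self, values: np.ndarray) -> "TraceSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def interpolate_gaps(self, max_gap: int = 2) -> "TraceSeries":
        """Linearly fill runs of <= max_gap missing frames; raises when a
        longer gap remains (the cell should then be excluded upstream)."""
        v = self.values.copy()
        isnan = np.isnan(v)
        if not isnan.any():
            return self
        runs = []
        start = None
        for i, m in enumerate(isnan):
            if m and start is None:
                start = i
            elif not m and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(v)))
        for s, e in runs:
            if e - s > max_gap or s == 0 or e == len(v):
                raise ValueError(
                    f"trace {self.cell_id!r} has an unfillable gap of {e - s} frames"
                )
        good = ~isnan
        v[isnan] = np.interp(self.times[isnan], self.times[good], v[good])
        return self.with_values(v)


@dataclass
class AlignedEnsemble:
    """Traces resampled on a common relative-time axis (reference at 0)."""

    rel_times: np.ndarray
    matrix: np.ndarray  # (n_members, n_times), NaN where a member is absent
    mode: str
    norm_constants: np.ndarray
    members: List[str] = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.n
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nanstd(self.matrix, axis=0, ddof=1) / np.sqrt(n)

    @property
    def n(self) -> np.ndarray:
        return np.sum(~np.isnan(self.matrix), axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_time_min": self.rel_times, "mean": self.mean, "sem": self.sem, "n": self.n}
        )


@dataclass(frozen=True)
class Pulse:
    t_peak: float  # minutes
    a_peak: float  # amplitude above the higher flanking minimum (= prominence)
    w_peak: float  # width at half amplitude, minutes
    prominence: float


@dataclass
class PulseSet:
    pulses: List[Pulse]

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t_peak for p in self.pulses])


@dataclass
class Kymograph:
    """time x radial-bin mean-intensity grid with a per-time contour radius."""

    grid: np.ndarray  # (n_times, n_bins)
    bin_centers: np.ndarray  # px
    times: np.ndarray
    contour_radius: np.ndarray  # px, argmax of the junction channel per time
    counts: np.ndarray  # pixels per (time, bin)
    ring_width: float = 3.0


@dataclass(frozen=True)
class EliminationCounts:
    compartment: str
    extrusions: int
    cells: int
    window_min: float = np.nan

    def __post_init__(self) -> None:
        if not (0 <= self.extrusions <= self.cells):
            raise ValueError("need 0 <= extrusions <= cells")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def _moving_average_shrink(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at the
    ends (so the first/last points use windows of 1, 3, ... samples)."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def smooth_trace(
    trace: TraceSeries,
    method: str = "loess",
    span_or_window: float = 0.07,
) -> TraceSeries:
    """Smooth a trace for noise suppression.

    ``moving_average``: centered boxcar of ``span_or_window`` samples (odd),
    shrinking symmetrically at the endpoints — the default window of 5
    samples matches the onset-detection pipeline.  ``loess``: locally
    weighted linear regression with span ``span_or_window`` given as a
    fraction of the trace length (floored at 3 points).
    """
    if method == "moving_average":
        window = int(span_or_window)
        if window < 1:
            raise ValueError("moving-average window must be >= 1 sample")
        if len(trace) < window:
            raise ValueError("trace shorter than the smoothing window")
        return trace.with_values(_moving_average_shrink(trace.values, window))
    if method == "loess":
        span = float(span_or_window)
        if span <= 0:
            raise ValueError("loess span must be positive")
        frac = max(span, 3.0 / max(len(trace), 1))
        frac = min(frac, 1.0)
        sm = lowess(
            trace.values, trace.times, frac=frac, it=0, return_sorted=False
        )
        return trace.with_values(sm)
    raise ValueError(f"unknown smoothing method {method!r}")


# ---------------------------------------------------------------------------
# Onset (inflection-point) detection
# ---------------------------------------------------------------------------


@dataclass
class OnsetResult:
    index: Optional[int]  # sample index of the breakpoint (None when flat)
    time: Optional[float]  # minutes
    no_constriction: bool
    error_curve: np.ndarray  # total SSE per candidate breakpoint
    candidates: np.ndarray  # candidate indices
    slopes: Tuple[float, float]  # fitted slopes left/right of the breakpoint


def _segment_sse_slope(x, y) -> Tuple[float, float]:
    """Least-squares line fit; returns (SSE, slope)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        return float(np.sum((y - ym) ** 2)), 0.0
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    resid = y - (ym + slope * (x - xm))
    return float(np.sum(resid**2)), slope


def detect_onset(
    perimeter: TraceSeries,
    min_segment: int = 5,
    smooth_window: int = 5,
    slope_min: float = 0.01,
    presmoothed: bool = False,
) -> OnsetResult:
    """Constriction-onset detection by a two-segment linear fit.

    The trace is smoothed (5-point moving average), then every interior
    breakpoint with at least ``min_segment`` points on each side is scored
    by the summed squared error of one line fitted left and one right of
    it; the breakpoint minimising the total error is the inflection point
    (left segment = samples before the breakpoint, right segment = from
    the breakpoint on).  When the fitted slope drop across the breakpoint
    is smaller than ``slope_min`` (units/min) the trace is flagged
    ``no_constriction`` — a plateau or a single straight line has no
    inflection.
    """
    n = len(perimeter)
    if n < 2 * min_segment + 1:
        raise ValueError(
            f"trace of {n} samples cannot hold two segments of {min_segment}"
        )
    sm = perimeter if presmoothed else smooth_trace(
        perimeter, "moving_average", smooth_window
    )
    x, y = sm.times, sm.values
    candidates = np.arange(min_segment, n - min_segment + 1)
    sse = np.empty(len(candidates))
    slopes = np.empty((len(candidates), 2))
    for k, b in enumerate(candidates):
        e1, s1 = _segment_sse_slope(x[:b], y[:b])
        e2, s2 = _segment_sse_slope(x[b:], y[b:])
        sse[k] = e1 + e2
        slopes[k] = (s1, s2)
    k_best = int(np.argmin(sse))
    b = int(candidates[k_best])
    s1, s2 = slopes[k_best]
    flat = (s2 - s1) > -slope_min
    return OnsetResult(
        index=None if flat else b,
        time=None if flat else float(perimeter.times[b]),
        no_constriction=bool(flat),
        error_curve=sse,
        candidates=candidates,
        slopes=(float(s1), float(s2)),
    )


# ---------------------------------------------------------------------------
# Alignment and normalisation
# ---------------------------------------------------------------------------


def align_normalize(
    traces: Sequence[TraceSeries],
    mode: str = "end",
    norm: str = "first5_mean",
    references: Optional[Sequence[int]] = None,
) -> AlignedEnsemble:
    """Align traces on a per-cell reference frame and normalise each.

    ``mode='end'`` aligns on the last sample (extrusion termination);
    ``mode='onset'`` aligns on the supplied per-trace reference indices
    (e.g. detected inflection points).  Normalisation divides each trace
    by the mean of its first five samples, its pre-reference mean, or
    nothing.  Traces whose normalisation constant is 0 are excluded.
    The ensemble mean/SEM at each relative time uses only the members
    present there.
    """
    if mode not in ("end", "onset"):
        raise ValueError("mode must be 'end' or 'onset'")
    if mode == "onset":
        if references is None:
            raise ValueError("mode='onset' requires per-trace reference indices")
    else:
        references = [len(t) - 1 for t in traces]
    if len(references) != len(traces):
        raise ValueError("one reference index per trace required")
    dts = {round(t.dt, 9) for t in traces}
    if len(dts) != 1:
        raise ValueError("all traces must share the frame interval")
    dt = dts.pop()

    kept, consts, rels = [], [], []
    for t, ref in zip(traces, references):
        if norm == "first5_mean":
            c = float(np.nanmean(t.values[:5]))
        elif norm == "pre_onset_mean":
            c = float(np.nanmean(t.values[: max(ref, 1)]))
        elif norm == "none":
            c = 1.0
        else:
            raise ValueError(f"unknown norm {norm!r}")
        if c == 0 or not np.isfinite(c):
            continue
        kept.append((t, ref))
        consts.append(c)
        rels.append((np.arange(len(t)) - ref) * dt)
    if not kept:
        raise ValueError("no traces left after normalisation")
    lo = min(r[0] for r in rels)
    hi = max(r[-1] for r in rels)
    n_steps = int(round((hi - lo) / dt)) + 1
    rel_axis = lo + dt * np.arange(n_steps)
    matrix = np.full((len(kept), n_steps), np.nan)
    for row, ((t, ref), c, r) in enumerate(zip(kept, consts, rels)):
        start = int(round((r[0] - lo) / dt))
        matrix[row, start : start + len(t)] = t.values / c
    return AlignedEnsemble(
        rel_axis,
        matrix,
        mode,
        np.asarray(consts),
        [t.cell_id for t, _ in kept],
    )


# ---------------------------------------------------------------------------
# Derivatives and cross-correlation
# ---------------------------------------------------------------------------


def rate_of_change(trace: TraceSeries, negate: bool = False) -> TraceSeries:
    """Finite-difference derivative per minute, at interval midpoints
    (length n-1).  ``negate=True`` flips the sign (used for the
    contraction rate, where positive means a shrinking perimeter)."""
    if len(trace) < 2:
        raise ValueError("need at least two samples")
    dv = np.diff(trace.values) / trace.dt
    if negate:
        dv = -dv
    mid = trace.times[:-1] + trace.dt / 2
    return TraceSeries(mid, dv, channel=trace.channel + "_rate", cell_id=trace.cell_id)


def contraction_rate(perimeter: TraceSeries) -> TraceSeries:
    """-d(perimeter)/dt: positive while the apical perimeter constricts."""
    return rate_of_change(perimeter, negate=True)


def xcorr_normalized(
    a: TraceSeries, b: TraceSeries, max_lag: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Normalised cross-correlation after mean subtraction.

    coefficient(L) = sum_t a'(t) b'(t+L) / sqrt(sum a'^2 sum b'^2), the
    zero-normalised form whose value at lag 0 for a == b is 1.  Returns
    (lags in minutes, coefficients, argmax lag in minutes); ``max_lag``
    is in frames (default: a third of the trace length).
    """
    if len(a) != len(b):
        raise ValueError("traces must have equal length")
    if not math.isclose(a.dt, b.dt, rel_tol=1e-9):
        raise ValueError("traces must share the frame interval")
    av = a.values - a.values.mean()
    bv = b.values - b.values.mean()
    denom = math.sqrt(float(np.sum(av**2)) * float(np.sum(bv**2)))
    if denom == 0:
        raise ValueError("cross-correlation undefined for zero-variance input")
    n = len(av)
    if max_lag is None:
        max_lag = max(n // 3, 1)
    full = signal.correlate(bv, av, mode="full") / denom  # index n-1 = lag 0
    lags_f = np.arange(-max_lag, max_lag + 1)
    coefs = full[n - 1 + lags_f[0] : n + lags_f[-1]]
    lags = lags_f * a.dt
    best = float(lags[int(np.argmax(coefs))])
    return lags, coefs, best


def coupling_lag(
    myosin: TraceSeries,
    perimeter: TraceSeries,
    max_lag: Optional[int] = None,
    smooth_span: float = 0.07,
) -> float:
    """Lag (minutes) at which myosin best anticipates the contraction
    rate: argmax of xcorr(myosin, -dP/dt), both series loess-smoothed
    first as in the rest of the pipeline.  A positive value means the
    constriction follows the myosin signal."""
    if smooth_span:
        myosin = smooth_trace(myosin, "loess", smooth_span)
        perimeter = smooth_trace(perimeter, "loess", smooth_span)
    rate = contraction_rate(perimeter)
    m = TraceSeries(rate.times, myosin.values[:-1], myosin.channel, myosin.cell_id)
    _, _, best = xcorr_normalized(m, rate, max_lag=max_lag)
    return best


# ---------------------------------------------------------------------------
# Pulse detection and metrics
# ---------------------------------------------------------------------------


def detect_pulses(trace: TraceSeries, min_prominence: float = 7.0) -> PulseSet:
    """Local maxima with topographic prominence >= ``min_prominence``.

    The published pipeline filters myosin pulses with a prominence
    threshold of 7 (raw mean-pixel-intensity units).  Per pulse: the time
    at the maximum, the amplitude above the higher flanking minimum
    (the prominence), and the width at half that amplitude, in minutes.
    """
    idx, props = signal.find_peaks(trace.values, prominence=min_prominence)
    if len(idx) == 0:
        return PulseSet([])
    widths, _, _, _ = signal.peak_widths(trace.values, idx, rel_height=0.5)
    pulses = [
        Pulse(
            t_peak=float(trace.times[i]),
            a_peak=float(p),
            w_peak=float(w * trace.dt),
            prominence=float(p),
        )
        for i, p, w in zip(idx, props["prominences"], widths)
    ]
    return PulseSet(sorted(pulses, key=lambda p: p.t_peak))


def pulse_frequency(
    pulses: PulseSet, onset_time: float, trace_span: Tuple[float, float]
) -> Tuple[float, float]:
    """Pulse count per minute strictly before vs. at/after the onset."""
    t0, t1 = trace_span
    if not (t0 <= onset_time <= t1):
        raise ValueError("onset must lie within the trace span")
    dur_before = onset_time - t0
    dur_after = t1 - onset_time
    if dur_before <= 0 or dur_after <= 0:
        raise ValueError("zero-length window on one side of the onset")
    times = pulses.times
    n_before = int(np.sum(times < onset_time)) if len(times) else 0
    n_after = len(times) - n_before
    return n_before / dur_before, n_after / dur_after


# ---------------------------------------------------------------------------
# Contraction yield
# ---------------------------------------------------------------------------


def contraction_yield(
    perimeter: TraceSeries,
    myosin: TraceSeries,
    onset_time: float,
    bin_width: float = 5.0,
    min_prominence: float = 7.0,
    smooth_span: float = 0.07,
) -> pd.DataFrame:
    """Yield per contraction peak: constriction rate at the peak divided
    by the myosin intensity there, keyed to ``bin_width``-minute windows
    relative to the onset.

    Both traces are loess-smoothed; contraction peaks are detected on the
    contraction-rate series with the given prominence threshold.  Peaks
    where the myosin intensity is 0 are skipped.  Columns: t_peak,
    rel_time, yield, bin_left.
    """
    p_s = smooth_trace(perimeter, "loess", smooth_span)
    m_s = smooth_trace(myosin, "loess", smooth_span)
    rate = contraction_rate(p_s)
    peaks = detect_pulses(rate, min_prominence)
    rows = []
    for p in peaks:
        m_at = float(np.interp(p.t_peak, m_s.times, m_s.values))
        r_at = float(np.interp(p.t_peak, rate.times, rate.values))
        if m_at == 0:
            continue
        rel = p.t_peak - onset_time
        rows.append(
            {
                "t_peak": p.t_peak,
                "rel_time": rel,
                "yield": r_at / m_at,
                "bin_left": math.floor(rel / bin_width) * bin_width,
            }
        )
    return pd.DataFrame(rows, columns=["t_peak", "rel_time", "yield", "bin_left"])


def yield_ratio(yields: pd.DataFrame) -> float:
    """Mean post-onset yield over mean pre-onset yield for one cell."""
    pre = yields[yields["rel_time"] < 0]["yield"]
    post = yields[yields["rel_time"] >= 0]["yield"]
    if len(pre) == 0 or len(post) == 0:
        return np.nan
    return float(post.mean() / pre.mean())


def binned_yield_table(per_cell_yields: Iterable[pd.DataFrame], bin_width: float = 5.0) -> pd.DataFrame:
    """Mean +/- SEM of the yield per relative-time bin across cells
    (cell-level means first, so every cell counts once per bin)."""
    cell_means = []
    for i, df in enumerate(per_cell_yields):
        if df.empty:
            continue
        g = df.groupby("bin_left")["yield"].mean()
        g.name = i
        cell_means.append(g)
    if not cell_means:
        return pd.DataFrame(columns=["bin_left", "mean", "sem", "n"])
    wide = pd.concat(cell_means, axis=1)
    out = pd.DataFrame(
        {
            "bin_left": wide.index,
            "mean": wide.mean(axis=1),
            "sem": wide.std(axis=1, ddof=1) / np.sqrt(wide.notna().sum(axis=1)),
            "n": wide.notna().sum(axis=1),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Radial kymographs and region intensities
# ---------------------------------------------------------------------------


def radial_kymograph(
    frames: np.ndarray,
    centre_per_frame: np.ndarray,
    junction_channel: Optional[np.ndarray] = None,
    ring_width: float = 3.0,
    times: Optional[np.ndarray] = None,
) -> Kymograph:
    """Mean intensity on concentric rings around a per-frame centre.

    ``frames`` is (T, H, W) for the signal channel; ``junction_channel``
    (same shape; defaults to the signal) defines the per-frame contour
    radius as the ring of maximal mean intensity.  Rings are
    ``ring_width``-px annuli [k*w, (k+1)*w).  Frames whose centre lies
    outside the image are skipped (grid row NaN).
    """
    frames = np.asarray(frames, dtype=float)
    if junction_channel is None:
        junction_channel = frames
    T, H, W = frames.shape
    centre_per_frame = np.asarray(centre_per_frame, dtype=float)
    if centre_per_frame.shape == (2,):
        centre_per_frame = np.tile(centre_per_frame, (T, 1))
    max_r = math.hypot(H, W) / 2
    n_bins = int(math.ceil(max_r / ring_width))
    grid = np.full((T, n_bins), np.nan)
    jgrid = np.full((T, n_bins), np.nan)
    counts = np.zeros((T, n_bins), dtype=int)
    yy, xx = np.mgrid[0:H, 0:W]
    contour = np.full(T, np.nan)
    for t in range(T):
        cy, cx = centre_per_frame[t]
        if not (0 <= cy < H and 0 <= cx < W):
            continue
        rr = np.hypot(yy - cy, xx - cx)
        bins = (rr / ring_width).astype(int)
        valid = bins < n_bins
        b = bins[valid]
        counts[t] = np.bincount(b, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            grid[t] = np.bincount(b, weights=frames[t][valid], minlength=n_bins) / counts[t]
            jgrid[t] = (
                np.bincount(b, weights=junction_channel[t][valid], minlength=n_bins)
                / counts[t]
            )
        row = jgrid[t]
        if np.any(np.isfinite(row)):
            contour[t] = (np.nanargmax(row) + 0.5) * ring_width
    bin_centers = (np.arange(n_bins) + 0.5) * ring_width
    if times is None:
        times = np.arange(T, dtype=float)
    return Kymograph(grid, bin_centers, np.asarray(times, float), contour, counts, ring_width)


def region_intensities(
    cell_mask: np.ndarray,
    image: np.ndarray,
    erode_px: int = 3,
    dilate_px: int = 3,
    band_px: int = 6,
    background_roi: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Medial, total and junctional mean intensities of one cell.

    medial: mask eroded by ``erode_px``; total: mask dilated by
    ``dilate_px``; junctional: the ``band_px``-wide band straddling the
    contour (dilation minus erosion by band_px/2 each).  When
    ``background_roi`` (a boolean mask or an image patch such as a 20x20
    region outside the tissue) is given, its mean is subtracted.
    An emptied medial region yields NaN.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    image = np.asarray(image, dtype=float)
    if not mask.any():
        raise ValueError("empty cell mask")
    bg = 0.0
    if background_roi is not None:
        roi = np.asarray(background_roi)
        bg = float(image[roi].mean()) if roi.dtype == bool else float(roi.mean())
    half = band_px // 2
    medial_mask = binary_erosion(mask, disk(erode_px))
    total_mask = binary_dilation(mask, disk(dilate_px))
    band_mask = binary_dilation(mask, disk(half)) & ~binary_erosion(mask, disk(half))
    out = {
        "medial": float(image[medial_mask].mean() - bg) if medial_mask.any() else np.nan,
        "total": float(image[total_mask].mean() - bg),
        "junctional": float(image[band_mask].mean() - bg) if band_mask.any() else np.nan,
    }
    return out


# ---------------------------------------------------------------------------
# Apicobasal profiles
# ---------------------------------------------------------------------------


def apicobasal_profile(
    reference_profiles: Sequence[np.ndarray],
    signal_profiles: Sequence[np.ndarray],
    background: float = 0.0,
) -> pd.DataFrame:
    """Align per-cell z-profiles on the reference-channel maximum and
    min-max normalise each.

    Each profile is a per-plane mean intensity (index 0 = most apical).
    The plane of the reference maximum maps to relative z = 0 (ties break
    toward the most apical plane); after background removal each signal
    profile is scaled to [0, 1].  Returns the ensemble mean +/- SEM on the
    common relative-z grid (columns rel_z, mean, sem, n).
    """
    if len(reference_profiles) != len(signal_profiles):
        raise ValueError("one reference profile per signal profile required")
    aligned: List[Tuple[np.ndarray, int]] = []
    for ref, sig in zip(reference_profiles, signal_profiles):
        ref = np.asarray(ref, float)
        sig = np.asarray(sig, float) - background
        if len(ref) < 3 or len(ref) != len(sig):
            raise ValueError("profiles need >= 3 matching planes")
        zmax = int(np.argmax(ref))  # argmax takes the first (most apical) tie
        lo, hi = float(np.min(sig)), float(np.max(sig))
        norm = (sig - lo) / (hi - lo) if hi > lo else np.zeros_like(sig)
        aligned.append((norm, zmax))
    z_lo = min(-z for _, z in aligned)
    z_hi = max(len(p) - 1 - z for p, z in aligned)
    axis = np.arange(z_lo, z_hi + 1)
    mat = np.full((len(aligned), len(axis)), np.nan)
    for row, (p, z) in enumerate(aligned):
        start = -z - z_lo
        mat[row, start : start + len(p)] = p
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame(
        {"rel_z": axis, "mean": np.nanmean(mat, axis=0), "sem": sem, "n": n}
    )


# ---------------------------------------------------------------------------
# Fold change, durations
# ---------------------------------------------------------------------------


def perimeter_fold_change(perimeter_t0: float, perimeter_t1: float) -> float:
    if perimeter_t0 <= 0:
        raise ValueError("fold change undefined for a non-positive baseline")
    return perimeter_t1 / perimeter_t0


def extrusion_duration(onset_time: float, end_time: float) -> float:
    """Minutes between the constriction onset (inflection) and the end of
    extrusion (apical area gone)."""
    if not onset_time < end_time:
        raise ValueError("onset must precede the end of extrusion")
    return end_time - onset_time


def duration_histogram(durations: Sequence[float], bin_width: float = 10.0) -> pd.DataFrame:
    """Distribution of extrusion durations normalised to fractions
    (columns bin_left, fraction; fractions sum to 1)."""
    d = np.asarray(durations, float)
    if len(d) == 0:
        raise ValueError("no durations")
    left = np.floor(d / bin_width) * bin_width
    counts = pd.Series(left).value_counts().sort_index()
    return pd.DataFrame(
        {"bin_left": counts.index, "fraction": counts.values / len(d)}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Elimination statistics
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by exact hypergeometric
    enumeration (integer arithmetic; no floating-point distribution calls).

    With margins fixed, the probability of the table with top-left entry k
    is C(r1, k) C(r2, c1-k) / C(N, c1); the two-sided p sums the
    probabilities of all tables no more probable than the observed one.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)
    }
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return num / math.comb(n, c1)


def _binomial_ci(k: int, n: int, method: str = "clopper-pearson", alpha: float = 0.05):
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return lo, hi
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        p = k / n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown CI method {method!r}")


def elimination_stats(
    counts: Sequence[EliminationCounts],
    ci_method: str = "clopper-pearson",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-compartment extrusion proportions with 95% CIs, plus two-sided
    Fisher exact p-values for every pairwise comparison.

    Returns a tidy frame with one row per compartment (proportion,
    ci_low, ci_high) and the pairwise p-values in the attribute
    ``.attrs['fisher_p']`` keyed by compartment pairs.
    """
    rows = []
    for ct in counts:
        if ct.cells == 0:
            rows.append(
                {"compartment": ct.compartment, "extrusions": ct.extrusions,
                 "cells": 0, "proportion": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        lo, hi = _binomial_ci(ct.extrusions, ct.cells, ci_method, alpha)
        rows.append(
            {
                "compartment": ct.compartment,
                "extrusions": ct.extrusions,
                "cells": ct.cells,
                "proportion": ct.extrusions / ct.cells,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    df = pd.DataFrame(rows)
    pvals = {}
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            a, b = counts[i], counts[j]
            if a.cells == 0 or b.cells == 0:
                continue
            tbl = [
                [a.extrusions, a.cells - a.extrusions],
                [b.extrusions, b.cells - b.extrusions],
            ]
            pvals[(a.compartment, b.compartment)] = fisher_exact_two_sided(tbl)
    df.attrs["fisher_p"] = pvals
    return df


# ---------------------------------------------------------------------------
# Two-sample test dispatch
# ---------------------------------------------------------------------------


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    design: str = "unpaired",
    alpha_normality: float = 0.05,
) -> Dict[str, object]:
    """Normality-gated two-sample comparison.

    Shapiro–Wilk on both samples; if both pass at ``alpha_normality`` the
    comparison is a t test (paired or unpaired per ``design``), otherwise
    a rank test (Mann–Whitney U, or Wilcoxon signed-rank for a paired
    design).  Returns the test name, the p-value and the per-sample
    normality p-values; constant samples are flagged
    ``degenerate_variance`` and dispatched to the rank path.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if design == "paired" and len(a) != len(b):
        raise ValueError("paired design requires equal sample sizes")
    degenerate = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if degenerate:
        norm_p = (np.nan, np.nan)
        normal = False
    else:
        pa = float(stats.shapiro(a).pvalue)
        pb = float(stats.shapiro(b).pvalue)
        norm_p = (pa, pb)
        normal = pa > alpha_normality and pb > alpha_normality
    if normal:
        if design == "paired":
            res = stats.ttest_rel(a, b)
            test = "paired t"
        else:
            res = stats.ttest_ind(a, b)
            test = "t"
        p = float(res.pvalue)
    else:
        if design == "paired":
            diffs = a - b
            if np.all(diffs == 0):
                test, p = "wilcoxon signed-rank", 1.0
            else:
                res = stats.wilcoxon(a, b)
                test, p = "wilcoxon signed-rank", float(res.pvalue)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test, p = "mann-whitney", float(res.pvalue)
    return {
        "test": test,
        "p_value": p,
        "normality_p": norm_p,
        "degenerate_variance": degenerate,
    }
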