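"""Per-beat deformational kinematics of annular geometry time series.

Given a geometric metric sampled through time (MAA, ACI or NPA) and beat
windows from the hemodynamic layer, this module computes:

* maximal cyclical reduction Δr — the within-beat max-to-min excursion,
  expressed in percent of the maximum (MAA, NPA) or as an absolute
  difference (ACI);
* average deformational velocity v̄ — the mean magnitude of the first time
  derivative over the descending segments of the cyclical curve;
* time-normalised cyclical curves (linear interpolation onto [0, 1]);
* fractional change relative to the previous beat's end-systolic value;
* three-beat mean ± SE aggregation.

Derivatives use central differences after a short moving-average smoothing
so that sampling noise at the 117 Hz acquisition rate does not masquerade as
descending deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .beats import MIN_BEAT_SAMPLES, BeatWindow

__all__ = [
    "KinematicsError",
    "BeatSeries",
    "BeatKinematics",
    "KinematicsSummary",
    "segment_beats",
    "cyclical_reduction",
    "deformation_velocity",
    "normalize_beat",
    "fractional_change",
    "aggregate_beats",
    "analyze_metric",
]

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_RUN = 3
DEFAULT_NORMALIZED_POINTS = 100


class KinematicsError(ValueError):
    """Invalid input to a kinematic computation."""


@dataclass(frozen=True)
class BeatSeries:
    """One beat's slice of a geometry time series."""

    times: np.ndarray
    values: np.ndarray
    window: BeatWindow


@dataclass(frozen=True)
class BeatKinematics:
    """Per-beat kinematic summary for one metric."""

    beat_id: int
    delta_r: float
    v_bar: float
    t_norm: np.ndarray
    normalized_curve: np.ndarray
    fractional_change_curve: np.ndarray | None  # None for the first beat

    @property
    def valid(self) -> bool:
        return np.isfinite(self.delta_r) and np.isfinite(self.v_bar)


@dataclass(frozen=True)
class KinematicsSummary:
    """Mean ± SE kinematics over ``n_beats_averaged`` consecutive beats."""

    metric: str
    mode: str
    delta_r: float
    delta_r_se: float
    v_bar: float
    v_bar_se: float
    t_norm: np.ndarray
    curve_mean: np.ndarray
    curve_se: np.ndarray
    frac_curve_mean: np.ndarray | None
    n_beats_averaged: int
    beats: tuple[BeatKinematics, ...] = field(repr=False, default=())


# ---------------------------------------------------------------------------


def segment_beats(
    times: np.ndarray, values: np.ndarray, windows: list[BeatWindow]
) -> list[BeatSeries]:
    """Slice a geometry series into ED-to-ED beats.

    Windows are half-open ``[start, end)`` so adjacent beats partition the
    record without losing or duplicating samples.  Beats shorter than
    :data:`~annulokin.beats.MIN_BEAT_SAMPLES` samples are discarded with a
    warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise KinematicsError("times and values must have identical shape")
    if not windows:
        raise KinematicsError("empty beat annotation list")
    n = times.size
    out: list[BeatSeries] = []
    for w in windows:
        if w.end <= 0 or w.start >= n:
            continue
        if w.end > n:
            continue
        if w.n_samples < MIN_BEAT_SAMPLES:
            warnings.warn(
                f"discarding beat [{w.start}, {w.end}) with only {w.n_samples} samples",
                stacklevel=2,
            )
            continue
        out.append(BeatSeries(times=times[w.start : w.end], values=values[w.start : w.end], window=w))
    if not out:
        raise KinematicsError("no overlap between beat annotations and geometry series")
    return out


def cyclical_reduction(values: np.ndarray, mode: str = "percent") -> float:
    """Maximal cyclical reduction Δr of one beat.

    ``percent`` mode: ``100 * (max - min) / max`` (used for MAA and NPA);
    ``absolute`` mode: ``max - min`` (used for ACI).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise KinematicsError("need at least 2 samples for cyclical reduction")
    if np.all(np.isnan(values)):
        raise KinematicsError("all-NaN beat series")
    vmax = float(np.nanmax(values))
    vmin = float(np.nanmin(values))
    if mode == "absolute":
        return vmax - vmin
    if mode == "percent":
        if vmax == 0.0:
            raise KinematicsError("percent-mode Δr undefined for zero maximum")
        return 100.0 * (vmax - vmin) / vmax
    raise KinematicsError(f"unknown Δr mode {mode!r}")


def _descending_runs(mask: np.ndarray, min_len: int) -> list[slice]:
    runs: list[slice] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append(slice(start, i))
            start = None
    if start is not None and mask.size - start >= min_len:
        runs.append(slice(start, mask.size))
    return runs


def _parabolic_extremum(times: np.ndarray, values: np.ndarray, j: int) -> tuple[float, float]:
    """Vertex (t, v) of the parabola through samples j-1, j, j+1 (edges: the sample)."""
    if j <= 0 or j >= values.size - 1:
        return float(times[j]), float(values[j])
    y0, y1, y2 = values[j - 1], values[j], values[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-30:
        return float(times[j]), float(values[j])
    delta = 0.5 * (y0 - y2) / denom  # in samples, |delta| <= 1 at a genuine extremum
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = times[j + 1] - times[j] if delta >= 0 else times[j] - times[j - 1]
    v = y1 - 0.25 * (y0 - y2) * delta
    return float(times[j] + delta * dt), float(v)


def deformation_velocity(
    times: np.ndarray,
    values: np.ndarray,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
) -> float:
    """Average deformational velocity v̄ over descending segments.

    Descending segments are runs of at least ``min_run`` consecutive samples
    with negative central-difference derivative of the
    ``smooth_window``-sample moving-average of the series.  v̄ is the average
    first derivative over those segments, evaluated as the net drop divided
    by the elapsed time between the bracketing local extremum of each run
    (extremum time and value refined by a three-point parabolic fit of the
    raw series, which keeps the estimate insensitive to how the run
    boundaries fall on the sampling grid).  Returned as a positive magnitude
    (metric units per second); NaN with a warning when the beat contains no
    descending segment.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < max(min_run + 1, 3):
        raise KinematicsError("series too short for velocity estimation")
    smooth = uniform_filter1d(values, size=smooth_window, mode="nearest")
    deriv = np.gradient(smooth, times)
    runs = _descending_runs(deriv < 0.0, min_run)
    total_drop = 0.0
    total_time = 0.0
    half = max(smooth_window // 2, 1)
    n = values.size
    for r in runs:
        i0, i1 = r.start, r.stop  # [i0, i1) have negative smoothed derivative
        lo = max(i0 - half, 0)
        j0 = lo + int(np.argmax(values[lo : min(i0 + 2, n)]))
        hi = min(i1 + half, n)
        j1 = max(i1 - 2, 0) + int(np.argmin(values[max(i1 - 2, 0) : hi]))
        t0, v0 = _parabolic_extremum(times, values, j0)
        t1, v1 = _parabolic_extremum(times, values, j1)
        if t1 > t0 and v0 > v1:
            total_drop += v0 - v1
            total_time += t1 - t0
    if total_time <= 0.0:
        warnings.warn("no descending segment in beat; v̄ undefined", stacklevel=2)
        return float("nan")
    return float(total_drop / total_time)


def normalize_beat(
    times: np.ndarray, values: np.ndarray, k: int = DEFAULT_NORMALIZED_POINTS
) -> tuple[np.ndarray, np.ndarray]:
    """Linear temporal interpolation onto ``k`` equispaced normalised times.

    Endpoints are preserved exactly; linear signals are reproduced to
    machine precision.
    """
    if k < 2:
        raise KinematicsError(f"need at least 2 normalized points, got {k}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 2:
        raise KinematicsError("need at least 2 samples to normalise a beat")
    span = times[-1] - times[0]
    if span <= 0.0:
        raise KinematicsError("beat has non-positive duration")
    t_norm = np.linspace(0.0, 1.0, k)
    resampled = np.interp(t_norm, (times - times[0]) / span, values)
    resampled[0] = values[0]
    resampled[-1] = values[-1]
    return t_norm, resampled


def fractional_change(values: np.ndarray, previous_es_value: float) -> np.ndarray:
    """Percent change of each sample relative to the previous beat's ES value."""
    if not np.isfinite(previous_es_value) or previous_es_value <= 0.0:
        raise KinematicsError("previous end-systolic value must be positive")
    values = np.asarray(values, dtype=float)
    return 100.0 * (values - previous_es_value) / previous_es_value


def aggregate_beats(beats: list[BeatKinematics], n: int = 3) -> KinematicsSummary:
    """Mean ± SE of Δr, v̄ and the normalised curves over ``n`` consecutive beats.

    The first run of ``n`` consecutive valid beats is used; fewer raises.
    SE is the sample standard deviation (ddof=1) divided by sqrt(n).
    """
    run: list[BeatKinematics] = []
    for b in beats:
        if b.valid:
            run.append(b)
            if len(run) == n:
                break
        else:
            run = []
    if len(run) < n:
        raise KinematicsError(f"need {n} consecutive valid beats, found at most {len(run)}")

    def _mean_se(x: np.ndarray, axis=0):
        mean = np.mean(x, axis=axis)
        se = np.std(x, axis=axis, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        return mean, se

    dr_mean, dr_se = _mean_se(np.array([b.delta_r for b in run]))
    vb_mean, vb_se = _mean_se(np.array([b.v_bar for b in run]))
    curves = np.stack([b.normalized_curve for b in run])
    curve_mean, curve_se = _mean_se(curves)
    fracs = [b.fractional_change_curve for b in run if b.fractional_change_curve is not None]
    frac_mean = np.mean(np.stack(fracs), axis=0) if fracs else None
    return KinematicsSummary(
        metric="",
        mode="",
        delta_r=float(dr_mean),
        delta_r_se=float(dr_se),
        v_bar=float(vb_mean),
        v_bar_se=float(vb_se),
        t_norm=run[0].t_norm,
        curve_mean=curve_mean,
        curve_se=curve_se,
        frac_curve_mean=frac_mean,
        n_beats_averaged=n,
        beats=tuple(run),
    )


def analyze_metric(
    times: np.ndarray,
    values: np.ndarray,
    windows: list[BeatWindow],
    mode: str = "percent",
    metric: str = "",
    k: int = DEFAULT_NORMALIZED_POINTS,
    n_average: int = 3,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> KinematicsSummary:
    """End-to-end kinematics for one metric: segment, per-beat stats, aggregate.

    The fractional-change curve of beat ``i`` is referenced to the metric
    value at beat ``i-1``'s end-systolic sample; it is undefined (None) for
    the first beat of a record.
    """
    beat_series = segment_beats(times, values, windows)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    per_beat: list[BeatKinematics] = []
    prev_es_value: float | None = None
    for i, bs in enumerate(beat_series):
        dr = cyclical_reduction(bs.values, mode=mode)
        # a few pre-window samples let an extremum sitting exactly on the
        # beat boundary be located and refined properly
        pad = max(bs.window.start - smooth_window, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vb = deformation_velocity(
                times[pad : bs.window.end],
                values[pad : bs.window.end],
                smooth_window=smooth_window,
            )
        t_norm, curve = normalize_beat(bs.times, bs.values, k=k)
        frac = None
        if prev_es_value is not None and prev_es_value > 0:
            frac = fractional_change(curve, prev_es_value)
        per_beat.append(
            BeatKinematics(
                beat_id=i,
                delta_r=dr,
                v_bar=vb,
                t_norm=t_norm,
                normalized_curve=curve,
                fractional_change_curve=frac,
            )
        )
        prev_es_value = float(values[bs.window.es])
    summary = aggregate_beats(per_beat, n=n_average)
    return KinematicsSummary(
        metric=metric,
        mode=mode,
        delta_r=summary.delta_r,
        delta_r_se=summary.delta_r_se,
        v_bar=summary.v_bar,
        v_bar_se=summary.v_bar_se,
        t_norm=summary.t_norm,
        curve_mean=summary.curve_mean,
        curve_se=summary.curve_se,
        frac_curve_mean=summary.frac_curve_mean,
        n_beats_averaged=summary.n_beats_averaged,
        beats=summary.beats,
    )
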