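"""LV volumes, cardiac-cycle event detection and contractility (E_es).

Volumes come from a two-axis ellipsoid model, V = (pi/6) * D^2 * L, with the
epicardial short (D) and long (L) axes corrected for wall thickness.  Beats
are delimited at end-diastole (onset of the dP/dt upstroke, coinciding with
the lower-right corner of the PV loop) and end-systole (minimum LV volume,
upper-left corner).  Contractility is the slope E_es of an ordinary
least-squares line through the end-systolic pressure-volume points of up to
10 sequential beats acquired during caval constriction (ESPVR).  Volume and
area indices are normalised to body surface area via the porcine Kelley
formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .beats import MIN_BEAT_SAMPLES, BeatWindow

__all__ = [
    "HemodynamicsError",
    "BodyMetrics",
    "PVBeat",
    "HemodynamicSummary",
    "EesEstimate",
    "bsa_kelley",
    "lv_volume_ellipsoid",
    "correct_for_wall_thickness",
    "interpolate_wall_thickness",
    "volume_from_dimensions",
    "detect_ed_es",
    "pv_beats",
    "summarize_state",
    "select_icc_beat",
    "select_ao_beat",
    "estimate_ees",
]

DEFAULT_DPDT_THRESHOLD_FRAC = 0.10
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_PLATEAU_FRAC = 0.02
VOLUME_CORNER_TOL = 0.02
CORNER_WINDOW_SAMPLES = 5


class HemodynamicsError(ValueError):
    """Invalid input to a hemodynamic computation."""


@dataclass(frozen=True)
class BodyMetrics:
    """Body weight (kg) and the derived body surface area (m^2)."""

    bw_kg: float
    bsa_m2: float

    @classmethod
    def from_weight(cls, bw_kg: float) -> "BodyMetrics":
        return cls(bw_kg=bw_kg, bsa_m2=bsa_kelley(bw_kg))


@dataclass(frozen=True)
class PVBeat:
    """Pressure-volume indices of one beat."""

    window: BeatWindow
    edp: float
    esp: float
    sp_max: float
    dpdt_max: float
    dpdt_min: float
    edv: float
    esv: float
    duration: float
    flag_non_ejecting: bool = False

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return 100.0 * self.sv / self.edv if self.edv > 0 else float("nan")


@dataclass(frozen=True)
class HemodynamicSummary:
    """Table-style state summary (three-beat averages, BSA-indexed)."""

    hr_bpm: float
    edp: float
    sp_max: float
    esp: float
    dpdt_max: float
    dpdt_min: float
    edv_i: float
    esv_i: float
    sv_i: float
    ef: float
    ci: float  # cardiac index, L min^-1 m^-2
    n_beats: int
    body: BodyMetrics


@dataclass(frozen=True)
class EesEstimate:
    """ESPVR regression: ESP = E_es * (ESV - V0)."""

    slope: float  # E_es, mmHg mL^-1
    v0: float  # volume-axis intercept, mL
    r_squared: float
    n_beats: int


# ---------------------------------------------------------------------------
# scalar formulas


def bsa_kelley(bw_kg: float) -> float:
    """Porcine body surface area (m^2) from body weight: 734 * BW^0.656.

    The formula yields cm^2 for physiologic weights and is divided by 1e4.
    """
    if bw_kg <= 0:
        raise HemodynamicsError(f"body weight must be positive, got {bw_kg}")
    return 734.0 * bw_kg**0.656 / 1e4


def lv_volume_ellipsoid(d_mm, l_mm):
    """Two-axis ellipsoid LV volume (mL): V = pi/6 * D^2 * L (D, L in mm)."""
    d = np.asarray(d_mm, dtype=float)
    ln = np.asarray(l_mm, dtype=float)
    if np.any(d < 0) or np.any(ln < 0):
        raise HemodynamicsError("ellipsoid axes must be non-negative")
    v = np.pi / 6.0 * d**2 * ln / 1000.0  # mm^3 -> mL
    return float(v) if np.isscalar(d_mm) and np.isscalar(l_mm) else v


def correct_for_wall_thickness(d_epi, l_epi, wt_equatorial, wt_apical):
    """Endocardial axes from epicardial ones: D - 2*wt_eq and L - wt_apical."""
    d = np.asarray(d_epi, dtype=float) - 2.0 * np.asarray(wt_equatorial, dtype=float)
    ln = np.asarray(l_epi, dtype=float) - np.asarray(wt_apical, dtype=float)
    if np.any(d <= 0) or np.any(ln <= 0):
        raise HemodynamicsError("wall-thickness correction produced non-positive dimension")
    scalar = np.isscalar(d_epi) and np.isscalar(l_epi)
    return (float(d), float(ln)) if scalar else (d, ln)


def interpolate_wall_thickness(phase, wt_ed: float, wt_es: float):
    """Within-beat wall thickness, linear in the ED->ES fraction ``phase``.

    ``phase`` = 0 at end-diastole, 1 at end-systole; intermediate values
    follow the contraction state (the emptying fraction of the cavity).
    """
    return wt_ed + (wt_es - wt_ed) * np.asarray(phase, dtype=float)


def volume_from_dimensions(
    d_epi: np.ndarray,
    l_epi: np.ndarray,
    wt_ed: float,
    wt_es: float,
    wt_apical: float,
    windows: list[BeatWindow] | None = None,
    n_iter: int = 4,
) -> np.ndarray:
    """Sample-wise endocardial LV volume trace from epicardial dimensions.

    Without beat windows the mean of the ED and ES equatorial wall thickness
    is applied uniformly (bootstrap pass; a constant-thickness correction is
    a monotone map of the epicardial diameter, so ED/ES sample positions are
    already trustworthy).  With windows, thickness is linearly interpolated
    between the ED and ES values along the contraction state — the fraction
    of the beat's emptying, (V - ESV)/(EDV - ESV) — which thickens the wall
    as the cavity empties; the interpolation is solved by fixed-point
    iteration since the fraction depends on the volume being computed.
    """
    d_epi = np.asarray(d_epi, dtype=float)
    l_epi = np.asarray(l_epi, dtype=float)
    wt_mean = np.full_like(d_epi, 0.5 * (wt_ed + wt_es))
    d_endo, l_endo = correct_for_wall_thickness(d_epi, l_epi, wt_mean, wt_apical)
    volume = lv_volume_ellipsoid(d_endo, l_endo)
    if not windows:
        return volume
    for _ in range(n_iter):
        wt = wt_mean.copy()
        for w in windows:
            sl = slice(w.start, w.end)
            edv_k, esv_k = volume[w.start], volume[w.es]
            span = edv_k - esv_k
            if span <= 1e-9:
                continue
            phase = 1.0 - np.clip((volume[sl] - esv_k) / span, 0.0, 1.0)
            wt[sl] = interpolate_wall_thickness(phase, wt_ed, wt_es)
        wt[: windows[0].start] = wt[windows[0].start]
        if windows[-1].end < wt.size:
            wt[windows[-1].end :] = wt[windows[-1].end - 1]
        d_endo, l_endo = correct_for_wall_thickness(d_epi, l_epi, wt, wt_apical)
        volume = lv_volume_ellipsoid(d_endo, l_endo)
    return volume


# ---------------------------------------------------------------------------
# event detection


def detect_ed_es(
    times: np.ndarray,
    pressure: np.ndarray,
    volume: np.ndarray,
    threshold_frac: float = DEFAULT_DPDT_THRESHOLD_FRAC,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[BeatWindow]:
    """Delimit beats at ED (dP/dt upstroke) and locate ES and SP_max.

    Beats are localised where the smoothed dP/dt crosses ``threshold_frac``
    of the within-beat dP/dt maximum; ED is then refined to the volume
    maximum near the crossing — the lower-right corner of the PV loop, with
    which the dP/dt upstroke must coincide.  When the corner and the
    crossing disagree by more than :data:`CORNER_WINDOW_SAMPLES` samples
    (or the ED volume sits >2% below its local maximum) the window is
    flagged with a warning and the crossing is used.  ES is the volume
    minimum within each ED-to-ED window, SP_max the pressure maximum.
    """
    times = np.asarray(times, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if not (times.size == pressure.size == volume.size):
        raise HemodynamicsError("times, pressure and volume must be equally long")
    if not np.all(np.isfinite(pressure)):
        raise HemodynamicsError("non-finite pressure sample")
    if float(np.ptp(pressure)) < 1e-9:
        raise HemodynamicsError("constant pressure trace: no cardiac cycles to detect")

    p_smooth = uniform_filter1d(pressure, size=smooth_window, mode="nearest")
    dpdt = np.gradient(p_smooth, times)
    if dpdt.max() <= 0:
        raise HemodynamicsError("pressure never rises: no dP/dt threshold crossings")

    def _upcrossings(signal: np.ndarray, thr: float, lo: int, hi: int) -> np.ndarray:
        seg = signal[lo:hi]
        up = np.nonzero((seg[:-1] < thr) & (seg[1:] >= thr))[0]
        return up + 1 + lo

    # pass 1: provisional EDs from a global threshold; a genuine crossing is
    # followed immediately by a steep systolic upstroke, which noise blips
    # near the threshold are not
    thr0 = threshold_frac * float(dpdt.max())
    provisional = _upcrossings(dpdt, thr0, 0, dpdt.size)
    provisional = np.array(
        [i for i in provisional if float(dpdt[i : i + 6].max()) >= 2.5 * thr0], dtype=int
    )
    if provisional.size == 0:
        raise HemodynamicsError("no dP/dt threshold crossings found")
    # keep the first crossing of each upstroke (suppress re-crossings within a beat)
    min_gap = (
        max(MIN_BEAT_SAMPLES, int(0.5 * np.median(np.diff(provisional))))
        if provisional.size > 1
        else MIN_BEAT_SAMPLES
    )
    eds = [int(provisional[0])]
    for i in provisional[1:]:
        if i - eds[-1] >= min_gap:
            eds.append(int(i))

    # pass 2: interpolate each crossing against the within-beat dP/dt
    # maximum, then snap ED onto the volume corner next to it
    refined: list[int] = []
    flags: list[bool] = []
    bounds = eds + [dpdt.size]
    for k, ed in enumerate(eds):
        lo = max(ed - smooth_window, 0)
        hi = bounds[k + 1]
        thr_k = threshold_frac * float(dpdt[lo:hi].max())
        ups = _upcrossings(dpdt, thr_k, lo, hi)
        crossing = ed
        if ups.size:
            i = int(ups[0])
            frac = (thr_k - dpdt[i - 1]) / (dpdt[i] - dpdt[i - 1]) if dpdt[i] != dpdt[i - 1] else 1.0
            crossing = int(round(i - 1 + frac))
        c_lo = max(crossing - 2 * CORNER_WINDOW_SAMPLES, 0)
        c_hi = min(crossing + min_gap + 1, volume.size)
        corner = c_lo + int(np.argmax(volume[c_lo:c_hi]))
        # a genuine corner is an interior maximum of the search window (the
        # isovolumic plateau may be bit-identical, so test position not value)
        interior = c_lo < corner < c_hi - 1
        mismatch = abs(corner - crossing) > CORNER_WINDOW_SAMPLES
        if mismatch or not interior:
            warnings.warn(
                f"dP/dt upstroke at sample {crossing} disagrees with the volume corner "
                f"(sample {corner})",
                stacklevel=2,
            )
        refined.append(corner if interior else crossing)
        flags.append(mismatch or not interior)

    windows: list[BeatWindow] = []
    for (a, flag), b in zip(zip(refined[:-1], flags[:-1]), refined[1:]):
        if b - a < MIN_BEAT_SAMPLES:
            continue
        es = a + int(np.argmin(volume[a:b]))
        sp = a + int(np.argmax(pressure[a:b]))
        if not (a < es < b):
            continue
        windows.append(BeatWindow(start=a, end=b, es=es, sp_max=sp, flag_corner_mismatch=flag))
    if not windows:
        raise HemodynamicsError("no complete ED-to-ED beat found")
    return windows


# ---------------------------------------------------------------------------
# per-beat and per-state summaries


def pv_beats(
    times: np.ndarray,
    pressure: np.ndarray,
    volume: np.ndarray,
    windows: list[BeatWindow],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[PVBeat]:
    """Pressure-volume indices per detected beat."""
    times = np.asarray(times, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    volume = np.asarray(volume, dtype=float)
    p_smooth = uniform_filter1d(pressure, size=smooth_window, mode="nearest")
    dpdt = np.gradient(p_smooth, times)
    dt = float(np.median(np.diff(times)))
    beats = []
    for w in windows:
        sl = slice(w.start, w.end)
        edv = float(volume[w.start])
        esv = float(volume[w.es])
        non_ejecting = edv <= esv
        if non_ejecting:
            warnings.warn(f"non-ejecting beat at sample {w.start} (EDV <= ESV)", stacklevel=2)
        beats.append(
            PVBeat(
                window=w,
                edp=float(pressure[w.start]),
                esp=float(pressure[w.es]),
                sp_max=float(pressure[w.sp_max]),
                dpdt_max=float(dpdt[sl].max()),
                dpdt_min=float(dpdt[sl].min()),
                edv=edv,
                esv=esv,
                duration=w.n_samples * dt,
                flag_non_ejecting=non_ejecting,
            )
        )
    return beats


def summarize_state(
    beats: list[PVBeat],
    body: BodyMetrics,
    n_average: int = 3,
    start_beat: int = 0,
) -> HemodynamicSummary:
    """Three-beat mean of the per-beat indices, indexed to BSA.

    ``start_beat`` selects where the averaged run begins (e.g. the beat
    satisfying a state criterion).  CI = HR * SV_i / 1000 (L min^-1 m^-2).
    """
    run = beats[start_beat : start_beat + n_average]
    if len(run) < n_average:
        raise HemodynamicsError(
            f"need {n_average} consecutive beats from beat {start_beat}, have {len(run)}"
        )
    mean = lambda attr: float(np.mean([getattr(b, attr) for b in run]))
    duration = mean("duration")
    hr = 60.0 / duration
    sv_i = mean("sv") / body.bsa_m2
    return HemodynamicSummary(
        hr_bpm=hr,
        edp=mean("edp"),
        sp_max=mean("sp_max"),
        esp=mean("esp"),
        dpdt_max=mean("dpdt_max"),
        dpdt_min=mean("dpdt_min"),
        edv_i=mean("edv") / body.bsa_m2,
        esv_i=mean("esv") / body.bsa_m2,
        sv_i=sv_i,
        ef=mean("ef"),
        ci=hr * sv_i / 1000.0,
        n_beats=n_average,
        body=body,
    )


def select_icc_beat(beats: list[PVBeat], baseline_edp: float, drop_frac: float = 0.2) -> int:
    """Index of the first caval-constriction beat at >= ``drop_frac`` EDP drop."""
    if baseline_edp <= 0:
        raise HemodynamicsError("baseline EDP must be positive")
    target = (1.0 - drop_frac) * baseline_edp
    for i, b in enumerate(beats):
        if b.edp <= target:
            return i
    raise HemodynamicsError(
        f"no beat reached a {100 * drop_frac:.0f}% EDP drop (target <= {target:.2f} mmHg)"
    )


def select_ao_beat(beats: list[PVBeat], plateau_frac: float = DEFAULT_PLATEAU_FRAC) -> int:
    """Index of the first beat after the SP_max plateau during aortic occlusion.

    Plateau: consecutive-beat |ΔSP_max| below ``plateau_frac`` of the
    previous beat's SP_max.
    """
    for i in range(1, len(beats)):
        prev = beats[i - 1].sp_max
        if prev > 0 and abs(beats[i].sp_max - prev) < plateau_frac * prev:
            return i
    raise HemodynamicsError(
        f"SP_max never plateaued (consecutive change always >= {100 * plateau_frac:.0f}%)"
    )


def estimate_ees(
    esv: np.ndarray, esp: np.ndarray, max_beats: int = 10
) -> EesEstimate:
    """OLS slope of the end-systolic pressure-volume relationship.

    ESP is regressed on ESV over up to ``max_beats`` sequential beats;
    the slope is E_es (mmHg mL^-1) and the volume-axis intercept V0.
    """
    esv = np.asarray(esv, dtype=float)[:max_beats]
    esp = np.asarray(esp, dtype=float)[:max_beats]
    if esv.size != esp.size:
        raise HemodynamicsError("ESV and ESP arrays must be equally long")
    if esv.size < 3:
        raise HemodynamicsError(f"need at least 3 beats for the ESPVR, got {esv.size}")
    if float(np.ptp(esv)) <= 0.0:
        raise HemodynamicsError("zero ESV variance: ESPVR slope undefined")
    fit = stats.linregress(esv, esp)
    slope = float(fit.slope)
    if not np.isfinite(slope):
        raise HemodynamicsError("non-finite ESPVR slope")
    return EesEstimate(
        slope=slope,
        v0=float(-fit.intercept / slope) if slope != 0 else float("nan"),
        r_squared=float(fit.rvalue**2),
        n_beats=int(esv.size),
    )
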