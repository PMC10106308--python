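"""Ground-truthed synthetic data: saddle-annulus motion and elastance PV loops.

The generator reproduces the statistical structure the analysis assumes,
with every derived quantity known in closed form:

* **Annulus**: eight crystals sit at equidistant angular stations on the
  deforming saddle ellipse ``x = a(t) cos(theta)``, ``y = b(t) sin(theta)``,
  ``z = -h(t) cos(2 theta)`` (horns on the septolateral axis high,
  commissures low).  Area, circularity and non-planarity waveforms are
  prescribed directly — MAA = pi*a*b, ACI = b/a and NPA =
  ``acos((h^2-b^2)/(h^2+b^2))`` exactly — and the semi-axes are solved from
  them, so the recorded ground truth is internally consistent.  Optional
  i.i.d. Gaussian positional noise, rigid-body motion and angular placement
  jitter emulate acquisition imperfections.
* **Ventricle**: a time-varying elastance model ``P = E(t) (V - V0)`` with a
  raised-cosine activation between E_min and E_max, a resistive valve into a
  two-element windkessel afterload, and resistive filling from a constant
  venous pressure.  With a small valve resistance the end-systolic PV points
  fall on the line ``ESP = E_max (ESV - V0)`` to within 1%.
* **Protocols**: baseline; inferior caval constriction (ICC, geometric
  beat-to-beat preload decay at fixed E_max, so the simulated ESPVR is
  exactly linear); aortic occlusion (AO, afterload ramp until the peak
  systolic pressure plateaus, with annular dilation and saddle flattening).

Default parameter values are the study conditions of the emulated porcine
preparation: HR 135 min^-1, 8.53 ms sampling, indexed annular area
607 mm^2 m^-2 at a BSA of 1.053 m^2 (58 kg), ACI 0.71, NPA 169 deg, cyclical
drops of 21.2% (MAA), 0.12 (ACI) and 10.3% (NPA), E_es 2.66 mmHg mL^-1,
V0 15 mL, EDV 120 mL, EDP 9.8 mmHg.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beats import BeatWindow
from .hemodynamics import bsa_kelley

__all__ = [
    "SAMPLE_INTERVAL_S",
    "SimulationError",
    "AnnulusSimConfig",
    "LVSimConfig",
    "AnnulusTruth",
    "PVTruth",
    "SimulatedDataset",
    "saddle_semi_axes",
    "npa_closed_form",
    "saddle_height_for_npa",
    "simulate_annulus",
    "simulate_pv",
    "simulate_protocol",
]

#: sonomicrometry acquisition interval (s)
SAMPLE_INTERVAL_S = 0.00853

#: reference body weight (kg) and derived BSA used for indexed defaults
REFERENCE_BW_KG = 58.0
REFERENCE_BSA_M2 = bsa_kelley(REFERENCE_BW_KG)


class SimulationError(ValueError):
    """Invalid simulator configuration or non-physiologic parameterisation."""


# ---------------------------------------------------------------------------
# closed forms


def npa_closed_form(b_mm: float, h_mm: float) -> float:
    """NPA (deg) of the symmetric saddle: horns (0, +-b, h), juncture origin."""
    c = (h_mm**2 - b_mm**2) / (h_mm**2 + b_mm**2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def saddle_height_for_npa(b_mm, npa_deg):
    """Saddle height h giving the requested NPA for septolateral semi-axis b."""
    c = np.cos(np.radians(np.asarray(npa_deg, dtype=float)))
    return np.asarray(b_mm, dtype=float) * np.sqrt((1.0 + c) / (1.0 - c))


def saddle_semi_axes(maa_mm2, aci):
    """Semi-axes (a, b) of the ellipse with area MAA and circularity b/a."""
    maa = np.asarray(maa_mm2, dtype=float)
    aci = np.asarray(aci, dtype=float)
    b = np.sqrt(maa * aci / np.pi)
    return b / aci, b


def _hermite(u: np.ndarray, y0: float, y1: float, m0: float, m1: float) -> np.ndarray:
    h00 = (1.0 + 2.0 * u) * (1.0 - u) ** 2
    h10 = u * (1.0 - u) ** 2
    h01 = u**2 * (3.0 - 2.0 * u)
    h11 = u**2 * (u - 1.0)
    return h00 * y0 + h10 * m0 + h01 * y1 + h11 * m1


def _bump(phi: np.ndarray, f: float) -> np.ndarray:
    """C2 periodic bump: 0 at phase 0, 1 at phase ``f``, 0 again at 1.

    Built as (1 - cos(2 pi g)) / 2 with a monotone C1 time-warp ``g`` whose
    slope matches across phases 0, f and 1, so the waveform has continuous
    curvature everywhere — including at its extrema, like a physiological
    signal.
    """
    phi = np.asarray(phi, dtype=float) % 1.0
    s_end, s_mid = 0.8, 1.0  # warp slopes at the extrema / at phase f
    u1 = np.clip(phi / f, 0.0, 1.0)
    g_rise = _hermite(u1, 0.0, 0.5, s_end * f, s_mid * f)
    u2 = np.clip((phi - f) / (1.0 - f), 0.0, 1.0)
    g_fall = _hermite(u2, 0.5, 1.0, s_mid * (1.0 - f), s_end * (1.0 - f))
    g = np.where(phi < f, g_rise, g_fall)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * g))


# ---------------------------------------------------------------------------
# configurations


def _default_geometry() -> tuple[float, float, float]:
    maa_ed = 607.0 * REFERENCE_BSA_M2  # mm^2, from the indexed end-diastolic area
    a0, b0 = saddle_semi_axes(maa_ed, 0.71)
    h0 = float(saddle_height_for_npa(b0, 169.0))
    return float(a0), float(b0), h0


_A0, _B0, _H0 = _default_geometry()


@dataclass(frozen=True)
class AnnulusSimConfig:
    """Saddle-annulus generator parameters (defaults = study baseline)."""

    a0: float = _A0  # intercommissural semi-axis at ED, mm
    b0: float = _B0  # septolateral semi-axis at ED, mm
    h0: float = _H0  # saddle height at ED, mm (NPA 169 deg)
    maa_drop_frac: float = 0.212  # prescribed (max-min)/max of MAA
    aci_drop_abs: float = 0.12  # prescribed max-min of ACI
    npa_drop_frac: float = 0.103  # prescribed (max-min)/max of NPA
    systolic_frac: float = 0.35  # phase of the cyclical minimum (ES timing)
    hr_bpm: float = 135.0
    n_beats: int = 12
    dt_s: float = SAMPLE_INTERVAL_S
    theta0_deg: float = 0.0  # angular station of crystal 1
    placement_jitter_deg: float = 0.0  # SD of per-crystal angular jitter
    noise_sd_mm: float = 0.0  # i.i.d. Gaussian positional noise
    rigid_rot_deg: float = 0.0  # amplitude of slow rigid rotation
    rigid_trans_mm: float = 0.0  # amplitude of slow rigid translation
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.a0 >= self.b0 > 0):
            raise SimulationError("require a0 >= b0 > 0")
        if self.h0 < 0:
            raise SimulationError("saddle height must be non-negative")
        period = 60.0 / self.hr_bpm
        if not (0 < self.dt_s < period):
            raise SimulationError("sample interval must be positive and below the beat duration")
        if not (0 < self.systolic_frac < 1):
            raise SimulationError("systolic fraction must be in (0, 1)")
        if not (0 <= self.maa_drop_frac < 1 and 0 <= self.npa_drop_frac < 1):
            raise SimulationError("fractional drops must be in [0, 1)")

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_bpm

    @property
    def maa_ed(self) -> float:
        return float(np.pi * self.a0 * self.b0)

    @property
    def aci_ed(self) -> float:
        return self.b0 / self.a0

    @property
    def npa_ed(self) -> float:
        return npa_closed_form(self.b0, self.h0)


@dataclass(frozen=True)
class LVSimConfig:
    """Time-varying elastance generator parameters (defaults = study baseline)."""

    e_max: float = 2.66  # mmHg mL^-1 (ESPVR slope)
    e_min: float = 2.66 / 28.5  # mmHg mL^-1; gives EDP 9.8 at EDV 120
    v0: float = 15.0  # mL, ESPVR volume intercept
    edv: float = 120.0  # mL, target end-diastolic volume
    hr_bpm: float = 135.0
    systolic_frac: float = 0.35  # activation peaks here; zero again at 2x
    r_valve: float = 0.004  # mmHg s mL^-1, aortic valve resistance
    r_periph: float = 0.39  # mmHg s mL^-1, windkessel runoff
    c_art: float = 4.0  # mL mmHg^-1, windkessel compliance
    r_fill: float = 0.002  # mmHg s mL^-1, filling resistance
    dt_s: float = SAMPLE_INTERVAL_S
    n_beats: int = 12
    n_warmup: int = 8  # beats discarded while the windkessel settles
    substeps: int = 40
    p_art_init: float = 76.0  # mmHg
    noise_sd_p: float = 0.0  # mmHg, additive pressure noise
    # wall geometry used to emit epicardial dimension traces
    l_endo_mm: float = 80.0
    wt_ed_mm: float = 9.0
    wt_es_mm: float = 13.0
    wt_apical_mm: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise SimulationError("require E_max > E_min > 0")
        if self.edv <= self.v0:
            raise SimulationError("require EDV > V0")
        period = 60.0 / self.hr_bpm
        if not (0 < self.dt_s < period):
            raise SimulationError("sample interval must be positive and below the beat duration")

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_bpm

    @property
    def p_ven(self) -> float:
        """Venous filling pressure yielding the target EDV at equilibrium."""
        return self.e_min * (self.edv - self.v0)


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class AnnulusTruth:
    """Analytic per-frame and per-beat geometric ground truth."""

    maa: np.ndarray
    aci: np.ndarray
    npa: np.ndarray
    beat_starts: np.ndarray  # first sample index of each beat
    delta_r: dict[str, np.ndarray]  # per-beat prescribed Δr (percent / abs)
    v_bar: dict[str, np.ndarray]  # per-beat analytic mean |d/dt| on descent


@dataclass(frozen=True)
class PVTruth:
    """Elastance-model ground truth events and ESPVR points."""

    windows: list[BeatWindow]
    edv: np.ndarray
    esv: np.ndarray
    esp: np.ndarray
    edp: np.ndarray
    sp_max: np.ndarray
    espvr_esv: np.ndarray  # volume at peak elastance (exactly on the E_max line)
    espvr_esp: np.ndarray


@dataclass
class SimulatedDataset:
    """Crystal trajectories + PV traces + full ground truth for one protocol."""

    protocol: str
    times: np.ndarray
    crystals: np.ndarray  # (T, 8, 3) mm
    pressure: np.ndarray  # mmHg
    volume: np.ndarray  # mL (endocardial truth)
    d_epi: np.ndarray  # mm
    l_epi: np.ndarray  # mm
    annulus_truth: AnnulusTruth
    pv_truth: PVTruth
    annulus_config: AnnulusSimConfig
    lv_config: LVSimConfig
    seed: int | None = None

    def write(self, out_dir: str | Path) -> None:
        """Write the CSV dialects the analysis reads, plus truth.json."""
        from . import io as akio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        akio.write_crystals_csv(out / "xyz.csv", self.times, self.crystals)
        akio.write_pressure_csv(out / "pressure.csv", self.times, self.pressure)
        akio.write_dimensions_csv(out / "dims.csv", self.times, self.d_epi, self.l_epi)
        truth = {
            "protocol": self.protocol,
            "seed": self.seed,
            "annulus_config": dataclasses.asdict(self.annulus_config),
            "lv_config": dataclasses.asdict(self.lv_config),
            "per_frame": {
                "maa_mm2": self.annulus_truth.maa.tolist(),
                "aci": self.annulus_truth.aci.tolist(),
                "npa_deg": self.annulus_truth.npa.tolist(),
            },
            "per_beat": {
                "beat_starts": self.annulus_truth.beat_starts.tolist(),
                "delta_r": {k: v.tolist() for k, v in self.annulus_truth.delta_r.items()},
                "v_bar": {k: v.tolist() for k, v in self.annulus_truth.v_bar.items()},
                "edv_ml": self.pv_truth.edv.tolist(),
                "esv_ml": self.pv_truth.esv.tolist(),
                "esp_mmhg": self.pv_truth.esp.tolist(),
                "edp_mmhg": self.pv_truth.edp.tolist(),
                "sp_max_mmhg": self.pv_truth.sp_max.tolist(),
                "espvr_esv_ml": self.pv_truth.espvr_esv.tolist(),
                "espvr_esp_mmhg": self.pv_truth.espvr_esp.tolist(),
            },
            "events": [
                {"start": w.start, "es": w.es, "sp_max": w.sp_max, "end": w.end}
                for w in self.pv_truth.windows
            ],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# annulus generator


def _rotation_matrix(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def simulate_annulus(
    config: AnnulusSimConfig,
    maa_scale: np.ndarray | None = None,
    npa_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, AnnulusTruth]:
    """Crystal trajectories on the prescribed deforming saddle.

    ``maa_scale``/``npa_scale`` optionally scale the end-diastolic MAA and
    NPA per beat (protocol hooks).  Returns ``(times, crystals, truth)``.
    """
    period = config.period_s
    n_samples = int(np.floor(config.n_beats * period / config.dt_s))
    times = np.arange(n_samples) * config.dt_s
    beat_idx = np.minimum((times / period).astype(int), config.n_beats - 1)
    phase = times / period - beat_idx

    maa_scale = np.ones(config.n_beats) if maa_scale is None else np.asarray(maa_scale, dtype=float)
    npa_scale = np.ones(config.n_beats) if npa_scale is None else np.asarray(npa_scale, dtype=float)
    if maa_scale.size != config.n_beats or npa_scale.size != config.n_beats:
        raise SimulationError("per-beat scale arrays must have length n_beats")

    f = config.systolic_frac
    bump = _bump(phase, f)
    maa_ed_t = config.maa_ed * maa_scale[beat_idx]
    npa_ed_t = np.minimum(config.npa_ed * npa_scale[beat_idx], 179.5)
    maa = maa_ed_t * (1.0 - config.maa_drop_frac * bump)
    aci = config.aci_ed - config.aci_drop_abs * bump
    npa = npa_ed_t * (1.0 - config.npa_drop_frac * bump)

    a, b = saddle_semi_axes(maa, aci)
    h = saddle_height_for_npa(b, npa)

    rng = np.random.default_rng(config.seed)
    theta = np.radians(config.theta0_deg) + 2.0 * np.pi * np.arange(8) / 8.0
    if config.placement_jitter_deg > 0:
        theta = theta + np.radians(rng.normal(0.0, config.placement_jitter_deg, size=8))

    cos_t, sin_t, cos_2t = np.cos(theta), np.sin(theta), np.cos(2.0 * theta)
    crystals = np.empty((n_samples, 8, 3))
    crystals[:, :, 0] = a[:, None] * cos_t
    crystals[:, :, 1] = b[:, None] * sin_t
    crystals[:, :, 2] = -h[:, None] * cos_2t

    if config.rigid_rot_deg > 0 or config.rigid_trans_mm > 0:
        # slow, smooth whole-heart motion (incommensurate with the beat)
        w1 = 2.0 * np.pi / (1.7 * period)
        w2 = 2.0 * np.pi / (2.3 * period)
        amp = np.radians(config.rigid_rot_deg)
        trans = config.rigid_trans_mm * np.stack(
            [np.sin(w1 * times), np.sin(w2 * times + 1.0), np.cos(w1 * times + 2.0)], axis=1
        )
        for i, t in enumerate(times):
            R = _rotation_matrix(amp * np.sin(w1 * t), amp * np.sin(w2 * t + 0.5), amp * np.cos(w1 * t))
            crystals[i] = crystals[i] @ R.T + trans[i]

    if config.noise_sd_mm > 0:
        crystals = crystals + rng.normal(0.0, config.noise_sd_mm, size=crystals.shape)

    beat_starts = np.searchsorted(times / period, np.arange(config.n_beats), side="left")
    desc_time = f * period
    truth = AnnulusTruth(
        maa=maa,
        aci=aci,
        npa=npa,
        beat_starts=beat_starts,
        delta_r={
            "maa": np.full(config.n_beats, 100.0 * config.maa_drop_frac),
            "aci": np.full(config.n_beats, config.aci_drop_abs),
            "npa": np.full(config.n_beats, 100.0 * config.npa_drop_frac),
        },
        v_bar={
            "maa": config.maa_drop_frac * config.maa_ed * maa_scale / desc_time,
            "aci": np.full(config.n_beats, config.aci_drop_abs / desc_time),
            "npa": config.npa_drop_frac * config.npa_ed * npa_scale / desc_time,
        },
    )
    return times, crystals, truth


# ---------------------------------------------------------------------------
# ventricle generator


def _elastance(phase: float, cfg: LVSimConfig) -> float:
    f_act = 2.0 * cfg.systolic_frac
    if phase < f_act:
        act = np.sin(np.pi * phase / f_act) ** 2
    else:
        act = 0.0
    return cfg.e_min + (cfg.e_max - cfg.e_min) * act


def simulate_pv(
    config: LVSimConfig,
    pven_scale: np.ndarray | None = None,
    rp_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], PVTruth]:
    """Elastance-model pressure/volume record with ground-truth events.

    Per-beat ``pven_scale`` scales the venous filling pressure (preload) and
    ``rp_scale`` the windkessel runoff resistance (afterload).  Warm-up beats
    let the windkessel settle and are discarded.  Returns
    ``(times, traces, truth)`` where ``traces`` holds pressure, volume and
    the epicardial dimension traces.
    """
    period = config.period_s
    n_total = config.n_warmup + config.n_beats
    pven_scale = np.ones(config.n_beats) if pven_scale is None else np.asarray(pven_scale, dtype=float)
    rp_scale = np.ones(config.n_beats) if rp_scale is None else np.asarray(rp_scale, dtype=float)
    if pven_scale.size != config.n_beats or rp_scale.size != config.n_beats:
        raise SimulationError("per-beat scale arrays must have length n_beats")
    pv_beat = np.concatenate([np.ones(config.n_warmup), pven_scale])
    rp_beat = np.concatenate([np.ones(config.n_warmup), rp_scale])

    n_samples = int(np.floor(n_total * period / config.dt_s))
    dt_sub = config.dt_s / config.substeps

    v = config.edv
    p_art = config.p_art_init
    times_all = np.arange(n_samples) * config.dt_s
    pressure = np.empty(n_samples)
    volume = np.empty(n_samples)
    # exact peak-elastance PV points per beat (on the E_max line by construction)
    espvr_v = np.full(n_total, np.nan)
    # volume at the exact start of each beat (activation onset, E = E_min)
    ed_v_exact = np.full(n_total, np.nan)
    ed_v_exact[0] = v
    peak_phase = config.systolic_frac

    t = 0.0
    for i in range(n_samples):
        e_now = _elastance((t / period) % 1.0, config)
        pressure[i] = e_now * (v - config.v0)
        volume[i] = v
        for _ in range(config.substeps):
            beat = min(int(t / period), n_total - 1)
            phase = t / period - beat
            e = _elastance(phase, config)
            p_lv = e * (v - config.v0)
            q_out = max(0.0, (p_lv - p_art) / config.r_valve)
            p_ven = config.p_ven * pv_beat[beat]
            q_in = max(0.0, (p_ven - p_lv) / config.r_fill)
            r_p = config.r_periph * rp_beat[beat]
            v += (q_in - q_out) * dt_sub
            p_art += (q_out - p_art / r_p) / config.c_art * dt_sub
            prev_phase = phase
            t += dt_sub
            phase_next = (t / period) - beat
            if prev_phase < peak_phase <= phase_next and np.isnan(espvr_v[beat]):
                espvr_v[beat] = v
            if phase_next >= 1.0 and beat + 1 < n_total and np.isnan(ed_v_exact[beat + 1]):
                ed_v_exact[beat + 1] = v
        if v <= config.v0:
            raise SimulationError("ventricle emptied below V0: non-physiologic parameterisation")

    # discard warm-up
    first = int(np.searchsorted(times_all / period, config.n_warmup, side="left"))
    times = times_all[first:] - times_all[first]
    pressure = pressure[first:]
    volume = volume[first:]
    n = times.size

    # truth events per recorded beat
    beat_of = np.minimum(((times_all[first:]) / period).astype(int), n_total - 1) - config.n_warmup
    windows: list[BeatWindow] = []
    edv_l, esv_l, esp_l, edp_l, sp_l, lin_v, lin_p = [], [], [], [], [], [], []
    for k in range(config.n_beats):
        in_beat = np.nonzero(beat_of == k)[0]
        if in_beat.size < 2:
            continue
        start = int(in_beat[0])
        end = int(in_beat[-1]) + 1
        if k == config.n_beats - 1 and end < n:
            end = n
        if end >= n and in_beat.size < int(0.9 * period / config.dt_s):
            break  # trailing partial beat
        es = start + int(np.argmin(volume[start:end]))
        sp = start + int(np.argmax(pressure[start:end]))
        if not (start < es < end):
            continue
        windows.append(BeatWindow(start=start, end=min(end, n), es=es, sp_max=sp))
        v_ed = ed_v_exact[config.n_warmup + k]
        edv_l.append(v_ed)
        esv_l.append(volume[es])
        esp_l.append(pressure[es])
        edp_l.append(config.e_min * (v_ed - config.v0))
        sp_l.append(pressure[sp])
        vv = espvr_v[config.n_warmup + k]
        lin_v.append(vv)
        lin_p.append(config.e_max * (vv - config.v0))

    if not windows:
        raise SimulationError("record too short: no complete beat")
    if volume[windows[0].start] <= volume[windows[0].es]:
        raise SimulationError("non-ejecting parameterisation (SV <= 0)")

    if config.noise_sd_p > 0:
        rng = np.random.default_rng(config.seed)
        pressure = pressure + rng.normal(0.0, config.noise_sd_p, size=pressure.shape)

    # epicardial dimension traces consistent with the volume (ellipsoid
    # model); the wall thickens as the cavity empties (incompressible
    # myocardium), linear between the ED and ES values within each beat
    d_endo = np.sqrt(6.0 * volume * 1000.0 / (np.pi * config.l_endo_mm))
    wt = np.full(n, 0.5 * (config.wt_ed_mm + config.wt_es_mm))
    for w in windows:
        sl = slice(w.start, w.end)
        edv_k, esv_k = volume[w.start], volume[w.es]
        span = max(edv_k - esv_k, 1e-9)
        f = np.clip((volume[sl] - esv_k) / span, 0.0, 1.0)  # 1 at ED, 0 at ES
        wt[sl] = config.wt_es_mm + (config.wt_ed_mm - config.wt_es_mm) * f
    wt[: windows[0].start] = wt[windows[0].start]
    wt[windows[-1].end :] = wt[windows[-1].end - 1] if windows[-1].end <= n else wt[-1]
    d_epi = d_endo + 2.0 * wt
    l_epi = np.full(n, config.l_endo_mm + config.wt_apical_mm)

    truth = PVTruth(
        windows=windows,
        edv=np.array(edv_l),
        esv=np.array(esv_l),
        esp=np.array(esp_l),
        edp=np.array(edp_l),
        sp_max=np.array(sp_l),
        espvr_esv=np.array(lin_v),
        espvr_esp=np.array(lin_p),
    )
    traces = {"pressure": pressure, "volume": volume, "d_epi": d_epi, "l_epi": l_epi}
    return times, traces, truth


# ---------------------------------------------------------------------------
# protocols


PROTOCOLS = ("baseline", "icc", "ao")

ICC_PRELOAD_DECAY = 0.93  # per-beat venous-pressure factor during constriction
ICC_RAMP_START = 1  # the snare bites from the second beat on
AO_RP_GAIN = 5.0  # max fractional increase of runoff resistance
AO_RAMP_RATE = 0.65  # per-beat approach factor of the afterload ramp


def simulate_protocol(
    annulus_cfg: AnnulusSimConfig,
    lv_cfg: LVSimConfig,
    protocol: str = "baseline",
) -> SimulatedDataset:
    """Coupled annulus + ventricle record under one loading protocol."""
    protocol = protocol.lower()
    if protocol not in PROTOCOLS:
        raise SimulationError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if abs(annulus_cfg.hr_bpm - lv_cfg.hr_bpm) > 1e-9:
        raise SimulationError("annulus and ventricle heart rates must match")

    nb = lv_cfg.n_beats
    if annulus_cfg.n_beats != nb:
        annulus_cfg = dataclasses.replace(annulus_cfg, n_beats=nb)

    k = np.arange(nb)
    if protocol == "baseline":
        pven = rp = None
        maa_s = npa_s = None
    elif protocol == "icc":
        steps = np.maximum(k - ICC_RAMP_START + 1, 0)
        pven = ICC_PRELOAD_DECAY**steps
        rp = None
        # annular area shrinks with the falling preload; saddle shape unchanged
        maa_s = pven**0.15
        npa_s = None
    else:  # ao
        pven = None
        ramp = 1.0 - AO_RAMP_RATE ** np.maximum(k, 0).astype(float)
        rp = 1.0 + AO_RP_GAIN * ramp
        # annular dilation and saddle flattening with the rising afterload
        maa_s = 1.0 + 0.08 * ramp
        npa_s = 1.0 + (171.0 / annulus_cfg.npa_ed - 1.0) * ramp

    times_g, crystals, ann_truth = simulate_annulus(annulus_cfg, maa_scale=maa_s, npa_scale=npa_s)
    times_p, traces, pv_truth = simulate_pv(lv_cfg, pven_scale=pven, rp_scale=rp)

    n = min(times_g.size, times_p.size)
    return SimulatedDataset(
        protocol=protocol,
        times=times_g[:n],
        crystals=crystals[:n],
        pressure=traces["pressure"][:n],
        volume=traces["volume"][:n],
        d_epi=traces["d_epi"][:n],
        l_epi=traces["l_epi"][:n],
        annulus_truth=ann_truth,
        pv_truth=pv_truth,
        annulus_config=annulus_cfg,
        lv_config=lv_cfg,
        seed=annulus_cfg.seed,
    )
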