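"""LV volumes, beat detection, hemodynamic summaries and E_es."""

import dataclasses
import warnings

import numpy as np
import pytest

from annulokin.beats import BeatWindow
from annulokin.hemodynamics import (
    BodyMetrics,
    HemodynamicsError,
    bsa_kelley,
    correct_for_wall_thickness,
    detect_ed_es,
    estimate_ees,
    interpolate_wall_thickness,
    lv_volume_ellipsoid,
    pv_beats,
    select_ao_beat,
    select_icc_beat,
    summarize_state,
    volume_from_dimensions,
)
from annulokin.simulate import LVSimConfig, simulate_pv


class TestBsaKelley:
    def test_reference_weight(self):
        assert bsa_kelley(58.0) == pytest.approx(1.053, abs=0.001)

    def test_monotone_in_weight(self):
        w = np.linspace(20, 120, 25)
        b = np.array([bsa_kelley(x) for x in w])
        assert np.all(np.diff(b) > 0)

    def test_non_positive_weight_rejected(self):
        with pytest.raises(HemodynamicsError):
            bsa_kelley(0.0)


class TestEllipsoidVolume:
    def test_direct_formula(self):
        assert lv_volume_ellipsoid(60.0, 80.0) == pytest.approx(150.80, abs=0.01)

    def test_zero_diameter(self):
        assert lv_volume_ellipsoid(0.0, 80.0) == 0.0

    def test_scaling_structure(self):
        v = lv_volume_ellipsoid(60.0, 80.0)
        assert lv_volume_ellipsoid(120.0, 80.0) == pytest.approx(4 * v)
        assert lv_volume_ellipsoid(60.0, 160.0) == pytest.approx(2 * v)

    def test_negative_rejected(self):
        with pytest.raises(HemodynamicsError):
            lv_volume_ellipsoid(-1.0, 80.0)


class TestWallThickness:
    def test_equatorial_correction(self):
        d, ln = correct_for_wall_thickness(72.0, 90.0, 6.0, 10.0)
        assert d == 60.0
        assert ln == 80.0

    def test_zero_thickness_identity(self):
        d, ln = correct_for_wall_thickness(72.0, 90.0, 0.0, 0.0)
        assert (d, ln) == (72.0, 90.0)

    def test_overcorrection_rejected(self):
        with pytest.raises(HemodynamicsError):
            correct_for_wall_thickness(10.0, 90.0, 6.0, 10.0)

    def test_midway_interpolation(self):
        assert interpolate_wall_thickness(0.5, 8.0, 12.0) == pytest.approx(10.0)

    def test_volume_inversion_recovers_simulator_truth(self):
        cfg = LVSimConfig(n_beats=6)
        _, traces, truth = simulate_pv(cfg)
        v = volume_from_dimensions(
            traces["d_epi"], traces["l_epi"], cfg.wt_ed_mm, cfg.wt_es_mm, cfg.wt_apical_mm,
            windows=truth.windows,
        )
        w0, w1 = truth.windows[0], truth.windows[-1]
        err = np.abs(v - traces["volume"])[w0.start : w1.end]
        assert err.max() < 0.5  # mL


class TestDetectEdEs:
    def test_events_within_one_sample_of_truth(self):
        times, traces, truth = simulate_pv(LVSimConfig(n_beats=8))
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        det = np.array([w.start for w in windows])
        for tw in truth.windows[1:-1]:
            j = int(np.argmin(np.abs(det - tw.start)))
            assert abs(det[j] - tw.start) <= 1
            assert abs(windows[j].es - tw.es) <= 1

    def test_heart_rate_recovered(self):
        cfg = LVSimConfig(n_beats=10)
        times, traces, _ = simulate_pv(cfg)
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        hr = 60.0 / (np.mean([w.n_samples for w in windows]) * cfg.dt_s)
        assert hr == pytest.approx(135.0, abs=1.0)

    def test_five_second_record_yields_eleven_beats(self):
        # floor(5 s / (60/135) s) = 11 complete ED-to-ED cycles
        from annulokin.kinematics import segment_beats

        cfg = LVSimConfig(n_beats=13)
        times, traces, truth = simulate_pv(cfg)
        n = int(round(5.0 / cfg.dt_s))
        inside = [w for w in truth.windows if w.end <= n]
        beats = segment_beats(times[:n], traces["volume"][:n], inside)
        assert len(beats) == 11

    def test_constant_pressure_rejected(self):
        t = np.arange(200) * 0.00853
        with pytest.raises(HemodynamicsError, match="constant"):
            detect_ed_es(t, np.full(200, 50.0), np.full(200, 100.0))


class TestSummaries:
    @pytest.fixture
    def record(self):
        cfg = LVSimConfig(n_beats=8)
        times, traces, _ = simulate_pv(cfg)
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        return times, traces, windows

    def test_sv_ef_identities(self, record):
        times, traces, windows = record
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows)
        for b in beats:
            assert b.sv == pytest.approx(b.edv - b.esv)
            assert b.ef == pytest.approx(100.0 * b.sv / b.edv)

    def test_ci_identity_and_bsa_indexing(self, record):
        times, traces, windows = record
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows)
        body = BodyMetrics.from_weight(58.0)
        s = summarize_state(beats, body)
        assert s.ci == pytest.approx(s.hr_bpm * s.sv_i / 1000.0, rel=1e-12)
        body2 = BodyMetrics(bw_kg=58.0, bsa_m2=2.0 * body.bsa_m2)
        s2 = summarize_state(beats, body2)
        assert s2.edv_i == pytest.approx(s.edv_i / 2.0, rel=1e-12)

    def test_non_ejecting_beat_flagged(self):
        t = np.arange(40) * 0.00853
        p = np.full(40, 50.0)
        v = np.full(40, 100.0)
        v[20] = 99.9  # "minimum" but EDV == 100 at start? craft EDV < ESV
        v[0] = 99.0
        w = [BeatWindow(start=0, end=40, es=20, sp_max=10)]
        with pytest.warns(UserWarning, match="non-ejecting"):
            beats = pv_beats(t, p, v, w)
        assert beats[0].flag_non_ejecting
        assert beats[0].ef <= 0.0

    def test_insufficient_beats_rejected(self, record):
        times, traces, windows = record
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows[:2])
        with pytest.raises(HemodynamicsError):
            summarize_state(beats, BodyMetrics.from_weight(58.0), n_average=3)


class TestStateSelection:
    def test_icc_beat_at_twenty_percent_edp_drop(self):
        cfg = LVSimConfig(n_beats=12)
        pven = 0.93 ** np.arange(12)
        times, traces, _ = simulate_pv(cfg, pven_scale=pven)
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows)
        baseline_edp = beats[0].edp
        i = select_icc_beat(beats, baseline_edp)
        assert beats[i].edp <= 0.8 * baseline_edp
        assert all(b.edp > 0.8 * baseline_edp for b in beats[:i])

    def test_icc_criterion_failure_named(self):
        cfg = LVSimConfig(n_beats=5)
        times, traces, _ = simulate_pv(cfg)
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows)
        with pytest.raises(HemodynamicsError, match="EDP drop"):
            select_icc_beat(beats, beats[0].edp)

    def test_ao_plateau_selection(self):
        cfg = LVSimConfig(n_beats=20)
        rp = 1.0 + 5.0 * (1.0 - 0.65 ** np.arange(20))
        times, traces, _ = simulate_pv(cfg, rp_scale=rp)
        windows = detect_ed_es(times, traces["pressure"], traces["volume"])
        beats = pv_beats(times, traces["pressure"], traces["volume"], windows)
        i = select_ao_beat(beats)
        assert i <= 20
        assert abs(beats[i].sp_max - beats[i - 1].sp_max) < 0.02 * beats[i - 1].sp_max

    def test_ao_criterion_failure_named(self):
        # strictly ramping SP_max with >2% steps never plateaus
        fake = []
        for k in range(6):
            w = BeatWindow(start=50 * k, end=50 * (k + 1), es=50 * k + 25, sp_max=50 * k + 12)
            fake.append(
                type("B", (), {"sp_max": 80.0 * 1.1**k, "window": w})()
            )
        with pytest.raises(HemodynamicsError, match="plateau"):
            select_ao_beat(fake)


class TestEstimateEes:
    def test_exact_on_noiseless_linear_espvr(self):
        esv = np.linspace(30.0, 43.0, 10)
        esp = 2.66 * (esv - 15.0)
        est = estimate_ees(esv, esp)
        assert est.slope == pytest.approx(2.66, abs=1e-9)
        assert est.v0 == pytest.approx(15.0, abs=1e-6)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_uses_at_most_ten_beats(self):
        esv = np.r_[np.linspace(30, 43, 10), 500.0]
        esp = np.r_[2.66 * (np.linspace(30, 43, 10) - 15.0), 0.0]
        est = estimate_ees(esv, esp)
        assert est.n_beats == 10
        assert est.slope == pytest.approx(2.66, abs=1e-9)

    def test_two_beats_rejected(self):
        with pytest.raises(HemodynamicsError, match="at least 3"):
            estimate_ees(np.array([30.0, 40.0]), np.array([40.0, 66.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(HemodynamicsError, match="variance"):
            estimate_ees(np.full(5, 40.0), np.arange(5.0))

    def test_unbiased_under_esp_noise(self, rng):
        esv = np.linspace(30.0, 43.0, 10)
        esp = 2.66 * (esv - 15.0)
        slopes = [
            estimate_ees(esv, esp + rng.normal(0, 2.0, 10)).slope for _ in range(300)
        ]
        assert np.mean(slopes) == pytest.approx(2.66, rel=0.02)
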