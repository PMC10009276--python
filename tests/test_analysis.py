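"""Flux-rate, beat-metric, alternans and border-zone analyses on synthetic
fixtures with closed-form answers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiak import analysis, fixtures


class TestKFluxRate:
    def test_zero_current_gives_zero(self):
        t, i = fixtures.constant_current(0.0)
        assert analysis.k_flux_rate(t, i, 0.0, 1000.0, 134.9) == 0.0

    def test_constant_current_closed_form(self):
        t, i = fixtures.constant_current(0.5)
        rate = analysis.k_flux_rate(t, i, 0.0, 1000.0, alpha_um_s=134.9)
        assert rate == pytest.approx(134.9 * 0.5, rel=1e-12)

    def test_pump_stoichiometry(self):
        t, i = fixtures.constant_current(0.5)
        rate = analysis.k_flux_rate(t, i, 0.0, 1000.0, 134.9, pump=True)
        assert rate == pytest.approx(-2.0 * 134.9 * 0.5, rel=1e-12)

    def test_incomplete_window_raises(self):
        t, i = fixtures.constant_current(0.5, duration_ms=2000.0)
        with pytest.raises(ValueError):
            analysis.k_flux_rate(t, i, 0.0, 1000.0, 134.9)


class TestFluxReports:
    def test_additivity_and_balance(self, run0d_control):
        reports = analysis.decompose_fluxes(run0d_control)
        for rep in reports:
            assert rep.check_additivity()
            assert rep.net == pytest.approx(rep.efflux + rep.influx, abs=1e-12)

    def test_net_flux_matches_ko_change(self, run0d_control):
        """0D consistency: the net flux rate over a window equals the [K+]o
        change divided by the window length (no wash-out after occlusion)."""
        run = run0d_control
        t0 = run.t_occ_ms + 3.0 * 60000.0
        rep = analysis.flux_report(run, t0)
        i0, i1 = int(t0), int(t0 + rep.window_ms)
        dko_rate = (run.ko[i1] - run.ko[i0]) / rep.window_ms * 1.0e6
        assert rep.net == pytest.approx(dko_rate, rel=1e-4, abs=1e-3)

    def test_missing_window_raises(self, run0d_control):
        with pytest.raises(ValueError):
            analysis.flux_report(run0d_control, 1e9)


class TestApd90:
    def test_square_ap_has_exact_duration(self):
        t, vm, stim = fixtures.square_ap(apd_ms=200.0)
        apd, peak, dvdt, cap = analysis.apd90(t, vm, stim[0], 1000.0)
        assert cap
        assert apd == pytest.approx(200.0, abs=1.5)

    def test_non_captured_beat_flagged_not_zero(self):
        t, vm, stim = fixtures.square_ap(v_peak=-60.0)   # subthreshold blip
        apd, peak, dvdt, cap = analysis.apd90(t, vm, stim[0], 1000.0)
        assert not cap
        assert np.isnan(apd)

    @given(apd_true=st.floats(80.0, 400.0))
    @settings(max_examples=20, deadline=None)
    def test_recovers_constructed_duration(self, apd_true):
        t, vm, stim = fixtures.square_ap(apd_ms=apd_true)
        apd, _, _, cap = analysis.apd90(t, vm, stim[1], 1000.0)
        assert cap
        assert apd == pytest.approx(apd_true, abs=1.5)


class TestAlternansDetection:
    def test_constant_series_has_no_episode(self):
        assert analysis.detect_alternans(np.full(40, 210.0)) == []

    def test_alternating_series_single_22_episode(self):
        s = fixtures.alternating_apd_series(n_beats=30, delta_ms=10.0)
        eps = analysis.detect_alternans(s)
        assert len(eps) == 1
        assert eps[0].pattern == "2:2"
        assert eps[0].onset_beat == 0
        assert eps[0].offset_beat == 29

    def test_complex_pattern_labelled(self):
        # alternation with two same-direction jumps inside (not pure 2:2)
        s = np.array([200.0, 180, 220, 180, 160, 200, 160, 200, 160])
        eps = analysis.detect_alternans(s, min_beats=6)
        assert len(eps) == 1
        assert eps[0].pattern == "complex"

    def test_small_fluctuations_below_threshold_ignored(self):
        rng = np.random.default_rng(11)
        s = 210.0 + rng.uniform(-2.0, 2.0, size=40)
        assert analysis.detect_alternans(s, threshold_ms=5.0) == []

    def test_non_captured_beats_break_episodes(self):
        s = fixtures.alternating_apd_series(n_beats=24, delta_ms=10.0)
        s[12] = np.nan
        eps = analysis.detect_alternans(s, min_beats=8)
        assert all(not (e.onset_beat <= 12 <= e.offset_beat) for e in eps)


class TestDmkl:
    def test_constant_ko_returns_constant(self):
        t = np.arange(4001, dtype=float)
        ko = np.full_like(t, 5.4)
        stim = np.array([10.0, 1010.0, 2010.0])
        d = analysis.dmkl(ko, t, stim, 1000.0)
        assert np.allclose(d, 5.4)

    def test_normoxic_run_dmkl_stable(self, run0d_control):
        run = run0d_control
        bm = analysis.beat_metrics(run)
        pre = bm.dmkl[60:240]      # normoxic segment, settled
        assert np.nanmax(pre) - np.nanmin(pre) < 0.02

    def test_early_ischemia_dmkl_increases(self, run0d_control):
        run = run0d_control
        bm = analysis.beat_metrics(run)
        b0 = int(run.t_occ_ms // 1000) + 60     # ~1 min post-occlusion
        seq = bm.dmkl[b0:b0 + 90]
        assert np.all(np.diff(seq) > 0.0)


class TestBZMetrics:
    def test_flat_profile_zero_width(self):
        x = np.linspace(0.0, 4.0, 161)
        rep = analysis.bz_metrics(x, np.full(161, 5.4))
        assert rep.width_cm == 0.0
        assert np.isnan(rep.peak_x_cm)

    def test_constructed_profile_geometry(self):
        """Sigmoid rise beyond the border with a bump peaking at 3.2 cm:
        border-to-peak width must recover 1.2 cm."""
        x = np.linspace(0.0, 4.0, 401)
        base = 5.4 + 6.0 / (1.0 + np.exp(-(x - 2.4) / 0.15))
        bump = 1.5 * np.exp(-((x - 3.2) / 0.5) ** 2)
        rep = analysis.bz_metrics(x, base + bump)
        assert rep.width_cm == pytest.approx(1.2, abs=0.05)
        assert rep.peak_ko > rep.ciz_ko

    def test_invasion_depth(self):
        x = np.linspace(0.0, 4.0, 401)
        ko = 5.4 + 6.0 / (1.0 + np.exp(-(x - 2.0) / 0.1))
        rep = analysis.bz_metrics(x, ko)
        assert rep.invasion_cm > 0.0
        assert rep.invasion_cm < 1.0
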