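"""Cable solver and K+ transport operator properties."""

import math

import numpy as np
import pytest

from cardiak import cable, fixtures, params as par, transport
from cardiak import _kernel as K


class TestExtracellularPotential:
    LAM = 3.647

    def test_uniform_vm_gives_uniform_vo(self):
        vo = cable.extracellular_potential(np.full(41, -80.0), self.LAM, 0.1)
        assert np.allclose(vo, vo[0], atol=1e-12)

    def test_closed_form_on_zero_flux_profile(self):
        x, vm = fixtures.zero_flux_vm_profile(n_nodes=161)
        vo = cable.extracellular_potential(vm, self.LAM, 0.025)
        comb = vo + vm / (1.0 + self.LAM)
        rng = vm.max() - vm.min()
        assert comb.max() - comb.min() < 1e-8 * rng

    def test_peak_to_peak_ratio(self):
        x, vm = fixtures.zero_flux_vm_profile(amp_mv=50.0)
        vo = cable.extracellular_potential(vm, self.LAM, 0.025)
        ratio = (vo.max() - vo.min()) / (vm.max() - vm.min())
        assert ratio == pytest.approx(1.0 / (1.0 + self.LAM), rel=1e-6)

    def test_gauges(self):
        x, vm = fixtures.zero_flux_vm_profile()
        vo_mean = cable.extracellular_potential(vm, self.LAM, 0.025)
        vo_left = cable.extracellular_potential(vm, self.LAM, 0.025,
                                                gauge="zero-left")
        assert vo_mean.mean() == pytest.approx(0.0, abs=1e-9)
        assert vo_left[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(np.diff(vo_mean), np.diff(vo_left), atol=1e-9)

    def test_unknown_gauge_raises(self):
        with pytest.raises(ValueError):
            cable.extracellular_potential(np.zeros(5), self.LAM, 0.1, gauge="x")


class TestInjuryCurrent:
    def test_zero_on_uniform_profile(self):
        inj = cable.injury_current(np.full(101, -84.0), 0.0026, 0.025)
        assert np.allclose(inj, 0.0, atol=1e-12)

    def test_constant_on_quadratic_profile(self):
        x, vm = fixtures.quadratic_vm_profile(a=10.0)
        inj = cable.injury_current(vm, 0.0026, 0.025)
        assert np.allclose(inj[1:-1], 2.0 * 10.0 * 0.0026, rtol=1e-9)

    def test_volume_units_conversion(self):
        x, vm = fixtures.quadratic_vm_profile(a=10.0)
        inj = cable.injury_current(vm, 0.0026, 0.025, per_volume=True)
        assert inj[5] == pytest.approx(2.0 * 10.0 * 0.0026 * 363.6 / 100.0)


class TestDiffusionOperator:
    def test_zero_flux_stencil_conserves_mass(self):
        rng = np.random.default_rng(7)
        vm = rng.normal(-70.0, 20.0, size=83)
        assert cable.second_difference(vm).sum() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_cable_stays_uniform(self, cp, y_ss):
        """No stimulus, uniform initial state: the diffusion term is exactly
        zero and the profile remains spatially uniform."""
        sc = cable.Scenario1D(tissue=par.TissueParams(dx_cm=0.1),
                              normoxia_min=0.005, ischemia_min=0.0,
                              regional=False, stim_amp=0.0, bpm=0.0,
                              probes_cm=(1.0, 3.0))
        run = cable.run_cable(sc, cp, y0=y_ss)
        assert np.ptp(run.snap_v[-1]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(run.snap_ko[-1]) == pytest.approx(0.0, abs=1e-9)

    def test_stability_guard_at_construction(self):
        with pytest.raises(ValueError, match="stability"):
            par.TissueParams(dx_cm=0.005, dt_ms=0.02)


class TestTransportOperator:
    TP = transport.TransportParams(dx_cm=0.05)

    def test_uniform_state_is_stationary(self):
        ko = np.full(81, 7.0)
        vo = np.zeros(81)
        out = transport.step_k_transport(ko, vo, np.zeros(81), 0.1, self.TP,
                                         alpha_internal=0.0)
        assert np.allclose(out, ko)

    def test_washout_closed_form(self):
        tp = transport.TransportParams(dk_cm2_ms=0.0, dx_cm=0.05)
        tau = tp.tau_profile(np.zeros(5, bool))
        ko = np.full(5, 9.0)
        vo = np.zeros(5)
        dt = 1.0
        for _ in range(15000):
            ko = transport.step_k_transport(ko, vo, np.zeros(5), dt, tp, 0.0,
                                            tau_wo_ms=tau)
        expected = 5.4 + (9.0 - 5.4) * math.exp(-1.0)
        assert np.allclose(ko, expected, rtol=1e-3)

    def test_mass_conservation_with_zero_flux_ends(self):
        rng = np.random.default_rng(3)
        ko = 5.4 + rng.random(61)
        vo = rng.normal(0.0, 5.0, size=61)
        tp = transport.TransportParams(dk_cm2_ms=1.5e-6, dx_cm=0.05)
        total0 = ko.sum()
        for _ in range(200):
            ko = transport.step_k_transport(ko, vo, np.zeros(61), 0.5, tp, 0.0)
        assert ko.sum() == pytest.approx(total0, rel=1e-12)

    def test_electromigration_vanishes_for_uniform_vo(self):
        rng = np.random.default_rng(4)
        ko = 5.4 + rng.random(41)
        rate_flat = transport.transport_rate(ko, np.zeros(41), 1.5e-6, 0.05)
        rate_const = transport.transport_rate(ko, np.full(41, -12.0), 1.5e-6, 0.05)
        assert np.allclose(rate_flat, rate_const)

    def test_electromigration_zero_for_uniform_ko_linear_vo(self):
        ko = np.full(41, 8.0)
        vo = np.linspace(-5.0, 5.0, 41)
        rate = transport.transport_rate(ko, vo, 1.5e-6, 0.05)
        assert np.allclose(rate[1:-1], 0.0, atol=1e-12)

    def test_rate_sign_matches_curvature(self):
        x = np.linspace(-1.0, 1.0, 81)
        ko = 7.0 + 0.5 * np.sin(np.pi * x)      # antisymmetric about center
        rate = transport.transport_rate(ko, np.zeros(81), 1.5e-6, 0.025)
        curv = cable.second_difference(ko)
        inner = slice(2, -2)
        assert np.all(np.sign(rate[inner]) == np.sign(curv[inner]))

    def test_negative_concentration_aborts(self):
        tp = transport.TransportParams(dk_cm2_ms=0.0, dx_cm=0.05)
        ko = np.full(5, 0.01)
        sink = np.full(5, -10.0)     # strong artificial K+ sink
        with pytest.raises(RuntimeError, match="negative"):
            transport.step_k_transport(ko, np.zeros(5), sink, 10.0, tp,
                                       alpha_internal=1e-4)


class TestConductionVelocity:
    def test_normoxic_cv_near_seventy(self, cv_normoxic):
        cv = cv_normoxic.conduction_velocity(1.0, 1.5)
        assert cv == pytest.approx(70.0, rel=0.10)

    def test_cv_increases_with_refinement(self, cv_normoxic, cv_refined):
        """Halving dx and dt raises the measured CV by a small amount
        (discretization recovery, about 2%)."""
        cv_c = cv_normoxic.conduction_velocity(1.0, 1.5)
        cv_f = cv_refined.conduction_velocity(1.0, 1.5)
        gain = (cv_f - cv_c) / cv_c
        assert 0.002 < gain < 0.06

    def test_reduced_conductivity_slows_conduction(self, cable_ctrl, cable_dv04):
        cv_ctrl = cable_ctrl.conduction_velocity(1.0, 1.5, beat=0)
        cv_dv = cable_dv04.conduction_velocity(1.0, 1.5, beat=0)
        assert cv_dv < cv_ctrl
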