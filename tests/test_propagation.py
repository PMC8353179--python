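"""Liouvillian propagation: unitarity, conservation laws, rotor-step quadrature."""

import numpy as np
import pytest
from scipy.linalg import expm

from qcest import (
    CrystalliteOrientation,
    ExchangeNetwork,
    ExperimentParams,
    QuadrupolarTensor,
    Site,
    build_liouvillian,
    evolve_saturation,
    rotor_propagator,
    thermal_state,
    total_sz,
    two_site_flip,
)
from qcest.propagation import SZ, saturate


class TestLiouvillianStructure:
    def test_coherent_block_antisymmetric(self, single_site_network, orientation):
        p = ExperimentParams(rf_hz=1300.0, offset_hz=7e3, mas_hz=25e3)
        lo = build_liouvillian(single_site_network, p, orientation, t=1e-6)
        block = lo[:8, :8]
        assert np.abs(block + block.T).max() < 1e-9

    def test_exchange_block_column_sums(self, dms_network, orientation):
        p = ExperimentParams(rf_hz=0.0, offset_hz=0.0, mas_hz=25e3)
        lo = build_liouvillian(dms_network, p, orientation)
        # for each coherence label a, sum over sites of L[8i+a, 8j+a] vanishes
        for a in range(8):
            sub = lo[a::8, a::8][:2, :2]
            assert np.abs(sub.sum(axis=0)).max() < 1e-6

    def test_dimension_mismatch_raises(self, dms_network, orientation):
        p = ExperimentParams(rf_hz=0.0, offset_hz=0.0, mas_hz=25e3)
        lo = build_liouvillian(dms_network, p, orientation)
        v = thermal_state(dms_network)
        assert lo.shape == (len(v), len(v))


class TestT1Term:
    @pytest.mark.parametrize("t1_mode", ["all", "sz"])
    def test_monoexponential_return_to_equilibrium(self, t1_mode):
        """With wRF = 0, Sz(t) = eq + (Sz0 - eq) exp(-t/T1) exactly."""
        net = two_site_flip(55.3e3, 0.0, np.deg2rad(106), 0.0, populations=(0.7, 0.3))
        t1 = 30e-3
        p = ExperimentParams(
            rf_hz=0.0, offset_hz=5e3, mas_hz=25e3, t1=t1, t1_mode=t1_mode
        )
        o = CrystalliteOrientation(0.5, 1.0)
        rho0 = thermal_state(net)
        rho0[SZ] = 0.1  # perturb site 1 Zeeman order away from equilibrium
        for t_sat in (1e-3, 7.77e-3, 25e-3):
            out = saturate(net, p.replace(sat_time=t_sat),
                           np.array([o.alpha]), np.array([o.beta]), [t_sat], rho0=rho0)[0, 0]
            expect = 0.7 + (0.1 - 0.7) * np.exp(-t_sat / t1)
            assert out[SZ] == pytest.approx(expect, abs=1e-10)


class TestRotorPropagator:
    def test_on_axis_crystallite_equals_constant_exponential(self, single_site_network):
        """beta = 0 with an aligned tensor has wQ(t) = 0: one rotor period is a
        single exponential of the (constant) Liouvillian."""
        p = ExperimentParams(rf_hz=1300.0, offset_hz=4e3, mas_hz=25e3)
        o = CrystalliteOrientation(0.9, 0.0)
        u = rotor_propagator(single_site_network, p, o)
        lo = build_liouvillian(single_site_network, p, o, t=0.0)
        assert np.abs(u - expm(lo / 25e3)).max() < 1e-10

    def test_20_vs_100_steps(self, dms_network, orientation):
        """The saturation observable computed with 20 rotor steps matches the
        100-step computation within 1e-3 at DMS-like parameters."""
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3, sat_time=3e-3)
        v0 = thermal_state(dms_network)
        s20 = evolve_saturation(v0, dms_network, p, orientation)
        s100 = evolve_saturation(v0, dms_network, p.replace(n_rotor_steps=100), orientation)
        assert abs(total_sz(s20, dms_network) - total_sz(s100, dms_network)) < 1e-3

    def test_20_step_vs_fine_step_saturation_observable(self, dms_network, orientation):
        """Per-crystallite saturation observables agree with a 2000-step oracle
        at the standard 25 kHz MAS rate (the 1 kHz case is checked on the
        powder-averaged observable in the acceptance suite)."""
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3, sat_time=3e-3)
        v0 = thermal_state(dms_network)
        s20 = evolve_saturation(v0, dms_network, p, orientation)
        s_fine = evolve_saturation(
            v0, dms_network, p.replace(n_rotor_steps=2000), orientation
        )
        assert abs(total_sz(s20, dms_network) - total_sz(s_fine, dms_network)) < 1e-3


class TestSaturationEvolution:
    def test_zero_time_is_identity(self, dms_network, dms_params, orientation):
        v0 = thermal_state(dms_network)
        out = evolve_saturation(v0, dms_network, dms_params.replace(sat_time=0.0), orientation)
        assert np.abs(out - v0).max() == 0.0

    def test_integer_rotor_periods_are_pure_powers(self, dms_network, orientation):
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3)
        u = rotor_propagator(dms_network, p, orientation)
        v0 = thermal_state(dms_network)
        out = evolve_saturation(v0, dms_network, p.replace(sat_time=3 / 25e3), orientation)
        assert np.abs(u @ u @ u @ v0 - out).max() < 1e-12

    def test_propagator_power_identity(self, dms_network, orientation):
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3)
        u = rotor_propagator(dms_network, p, orientation)
        v0 = thermal_state(dms_network)
        out = evolve_saturation(v0, dms_network, p.replace(sat_time=2 / 25e3), orientation)
        assert np.abs(u @ (u @ v0) - out).max() < 1e-12

    def test_arbitrary_time_equals_stepwise_integration(self, dms_network, orientation):
        """Powers + fractional factor equal direct sequential sub-step integration."""
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3)
        t_sat = 2.37 / 25e3  # 2 periods + fraction spanning sub-steps
        v0 = thermal_state(dms_network)
        out = evolve_saturation(v0, dms_network, p.replace(sat_time=t_sat), orientation)
        # oracle: march sub-step by sub-step over the whole interval
        from qcest.propagation import _liouvillians

        dt = (1 / 25e3) / 20
        n_full = int(t_sat / dt)
        rem = t_sat - n_full * dt
        v = v0.copy()
        al = np.array([orientation.alpha])
        be = np.array([orientation.beta])
        for k in range(n_full):
            tk = (k % 20) * dt + dt / 2
            lo = _liouvillians(dms_network, p, al, be, np.array([tk]))[0, 0]
            v = expm(lo * dt) @ v
        if rem > 0:
            tk = (n_full % 20) * dt + rem / 2
            lo = _liouvillians(dms_network, p, al, be, np.array([tk]))[0, 0]
            v = expm(lo * rem) @ v
        assert np.abs(out - v).max() < 1e-8


class TestConservationLaws:
    def test_coherent_norm_preserved_over_long_evolution(self, single_site_network, orientation):
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3, sat_time=128e-3)
        v0 = thermal_state(single_site_network)
        out = evolve_saturation(v0, single_site_network, p, orientation)
        assert abs(np.linalg.norm(out[:8]) - np.linalg.norm(v0[:8])) < 1e-10

    def test_total_sz_conserved_without_rf(self, dms_network, orientation):
        p = ExperimentParams(rf_hz=0.0, offset_hz=10e3, mas_hz=25e3, sat_time=20e-3)
        out = evolve_saturation(thermal_state(dms_network), dms_network, p, orientation)
        assert total_sz(out, dms_network) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_batch_matches_single(self, dms_network):
        """Pure per-orientation computation: batching does not change results."""
        p = ExperimentParams(rf_hz=1300.0, offset_hz=10e3, mas_hz=25e3)
        orients = [CrystalliteOrientation(0.3, 0.9), CrystalliteOrientation(2.0, 2.1)]
        al = np.array([o.alpha for o in orients])
        be = np.array([o.beta for o in orients])
        batch = saturate(dms_network, p, al, be, [3e-3])
        for i, o in enumerate(orients):
            single = evolve_saturation(
                thermal_state(dms_network), dms_network, p.replace(sat_time=3e-3), o
            )
            assert np.abs(batch[0, i] - single).max() < 1e-12
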