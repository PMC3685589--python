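"""Spatial discretization and implicit integration of the cable."""

import numpy as np
import pytest

from hhcable import (AxonGeometry, CableModel, InvalidInputError,
                     NumericalError, PassiveParams, SimControl,
                     StimulusTrain, build_compartments, detect_spikes)
from hhcable.cable_model import resting_leak_potential
from hhcable.recording_analysis import _interpolated_peak_time

from reference_ode import reference_voltage


class TestBuildCompartments:
    def test_total_area_is_cylinder_area(self):
        geom = AxonGeometry(L=10000, diam=500, nseg=100)
        cable = build_compartments(geom, PassiveParams())
        total_um2 = cable.area_cm2.sum() * 1e8
        assert total_um2 == pytest.approx(np.pi * 500 * 10000, rel=1e-12)
        # uniform split: each compartment is pi*500*100 um2
        assert cable.area_cm2[0] * 1e8 == pytest.approx(np.pi * 500 * 100,
                                                        rel=1e-12)

    def test_single_compartment_degenerate(self):
        cable = build_compartments(AxonGeometry(nseg=1), PassiveParams())
        assert cable.area_cm2.size == 1
        assert cable.g_axial_S.size == 0

    def test_axial_conductance_formula_and_Ra_scaling(self):
        geom = AxonGeometry(L=10000, diam=500, nseg=100)
        c1 = build_compartments(geom, PassiveParams(Ra=35.4))
        c2 = build_compartments(geom, PassiveParams(Ra=70.8))
        dx_cm, d_cm = 100 * 1e-4, 500 * 1e-4
        expected = (np.pi * d_cm ** 2 / 4) / (35.4 * dx_cm)
        assert c1.g_axial_S[0] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(c2.g_axial_S, c1.g_axial_S / 2)

    def test_invalid_nseg(self):
        with pytest.raises(InvalidInputError):
            AxonGeometry(nseg=0)


class TestInitialization:
    def test_gating_at_steady_state(self, default_model):
        state = default_model.initialize()
        assert np.allclose(state.V, -65.0)
        assert np.allclose(state.gating.m, 0.052932, atol=1e-5)
        assert np.allclose(state.gating.h, 0.596121, atol=1e-5)
        assert np.allclose(state.gating.n, 0.317677, atol=1e-5)
        assert state.t == 0.0

    def test_auto_leak_balances_rest(self, default_model):
        # with EL chosen by resting_leak_potential, dV/dt = 0 at Vinit
        EL = resting_leak_potential(default_model.ap, default_model.pp.GL,
                                    -65.0, default_model.ENa,
                                    default_model.EK)
        assert default_model.EL == pytest.approx(EL)
        state = default_model.initialize()
        default_model.step(state, np.zeros(101), 0.025)
        assert np.abs(state.V + 65.0).max() < 1e-6

    def test_explicit_leak_reversal_is_honored(self):
        model = CableModel(pp=PassiveParams(EL=-54.3))
        assert model.EL == -54.3


class TestStep:
    def test_uniform_state_stays_uniform(self, default_model):
        state = default_model.initialize()
        state.V[:] = -50.0  # uniform but off-rest
        for _ in range(40):
            default_model.step(state, np.zeros(101), 0.025)
        assert np.ptp(state.V) < 1e-9

    def test_nonfinite_state_reported_with_compartment(self, default_model):
        state = default_model.initialize()
        state.V[7] = np.nan
        with pytest.raises(NumericalError, match="compartment 7"):
            default_model.step(state, np.zeros(101), 0.025)

    def test_invalid_dt(self, default_model):
        state = default_model.initialize()
        with pytest.raises(InvalidInputError):
            default_model.step(state, np.zeros(101), 0.0)


class TestSimulate:
    def test_trace_length(self):
        model = CableModel(ctl=SimControl(dt=0.025, ts=1.0))
        res = model.simulate(StimulusTrain(NoStim=0))
        assert len(res.time) == 41
        assert len(res.vm) == 41

    def test_resting_stability_without_stimulus(self):
        model = CableModel(ctl=SimControl(ts=50.0))
        res = model.simulate(StimulusTrain(NoStim=0))
        assert np.abs(res.vm + 65.0).max() < 1.0

    def test_gating_bounded_on_full_trajectory(self, suprathreshold_result):
        for x in (suprathreshold_result.m, suprathreshold_result.h,
                  suprathreshold_result.n):
            assert np.all((x >= 0.0) & (x <= 1.0))

    def test_current_balance_at_measuring_point(self, suprathreshold_result):
        r = suprathreshold_result
        np.testing.assert_allclose(r.im, r.ina + r.ik + r.ileak + r.icap,
                                   atol=1e-9)

    def test_single_suprathreshold_pulse_gives_one_spike(
            self, suprathreshold_result):
        spikes = detect_spikes(suprathreshold_result.time,
                               suprathreshold_result.vm)
        assert spikes.size == 1

    def test_implicit_fallback_close_to_cn(self):
        stim = StimulusTrain(NoStim=1, Amp=12000, Dur=0.2, Delay=1)
        ctl = SimControl(ts=15.0)
        r_cn = CableModel(ctl=ctl, method="cn").simulate(stim)
        r_be = CableModel(ctl=ctl, method="implicit").simulate(stim)
        t_cn = _interpolated_peak_time(r_cn.time, r_cn.vm, 0.0, 1.0)
        t_be = _interpolated_peak_time(r_be.time, r_be.vm, 0.0, 1.0)
        assert abs(t_cn - t_be) < 0.5


class TestAccuracy:
    def test_single_compartment_matches_reference_ode(
            self, single_compartment_run):
        model, stim, res = single_compartment_run
        Vref = reference_voltage(model, stim, res.time)
        assert abs(res.vm.max() - Vref.max()) < 0.5
        t_sim = res.time[np.argmax(res.vm)]
        t_ref = res.time[np.argmax(Vref)]
        assert abs(t_sim - t_ref) <= 0.1

    def test_peak_time_converges_under_refinement(self):
        stim = StimulusTrain(NoStim=1, Amp=12000, Dur=0.2, Delay=1)

        def peak_time(dt, nseg):
            model = CableModel(AxonGeometry(nseg=nseg),
                               ctl=SimControl(dt=dt, ts=15.0))
            res = model.simulate(stim)
            return _interpolated_peak_time(res.time, res.vm, 0.0, 1.0)

        base = peak_time(0.025, 101)
        assert abs(peak_time(0.0125, 101) - base) < 0.1
        assert abs(peak_time(0.025, 203) - base) < 0.1
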