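"""Simulator physics: effort waveform, tube drop, integration, calibration,
steady state, and asynchrony detection."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sbtsim.config import AirwayApparatus, EffortProfile, bench_condition
from sbtsim.errors import CalibrationError, InvalidInputError, SimulationDivergedError
from sbtsim.mechanics import (
    SimState,
    apparatus_pressure_drop,
    calibrate_constant_vt,
    detect_asynchrony,
    equilibrium_state,
    pmus_waveform,
    simulate_condition,
    step,
)
from tests.conftest import run_calibrated


class TestPmusWaveform:
    def test_zero_amplitude_is_identically_zero(self):
        eff = EffortProfile(rate=24.0, amplitude=0.0)
        assert all(pmus_waveform(t, eff) == 0.0 for t in np.linspace(0, 2.49, 40))

    def test_minimum_reached_at_end_of_rise(self):
        eff = EffortProfile(rate=24.0, amplitude=8.0)
        t_rise = eff.rise_fraction * eff.cycle_time
        assert pmus_waveform(t_rise - 1e-9, eff) == pytest.approx(-8.0, abs=1e-6)
        grid = [pmus_waveform(t, eff) for t in np.arange(0, eff.cycle_time, 1e-3)]
        assert min(grid) == pytest.approx(-8.0, abs=1e-6)

    def test_zero_outside_effort_window(self):
        eff = EffortProfile(rate=24.0, amplitude=8.0)
        t_end = (eff.rise_fraction + eff.hold_fraction + eff.release_fraction) * eff.cycle_time
        assert pmus_waveform(t_end + 1e-6, eff) == 0.0
        assert pmus_waveform(eff.cycle_time - 1e-6, eff) == 0.0

    def test_cycle_integral_negative_whenever_effort_present(self):
        eff = EffortProfile(rate=30.0, amplitude=3.0)
        t = np.linspace(0, eff.cycle_time - 1e-9, 5000)
        integral = np.trapezoid([pmus_waveform(x, eff) for x in t], t)
        assert integral < 0

    def test_outside_cycle_rejected(self):
        eff = EffortProfile(rate=24.0)
        with pytest.raises(InvalidInputError):
            pmus_waveform(eff.cycle_time, eff)


class TestApparatusDrop:
    def test_zero_flow_and_bare_mode_give_zero(self):
        tube = AirwayApparatus(mode="t_piece", tube_label="ETT-3.0")
        bare = AirwayApparatus(mode="bare", tube_label=None)
        assert apparatus_pressure_drop(0.0, tube) == 0.0
        assert apparatus_pressure_drop(0.12, bare) == 0.0

    @given(q=st.floats(-0.5, 0.5))
    def test_sign_symmetry(self, q):
        tube = AirwayApparatus(mode="intubated", tube_label="ETT-3.5")
        assert apparatus_pressure_drop(-q, tube) == pytest.approx(
            -apparatus_pressure_drop(q, tube), rel=1e-12, abs=1e-15
        )

    @given(q=st.floats(1e-4, 0.3))
    def test_quadratic_term_makes_drop_superlinear(self, q):
        tube = AirwayApparatus(mode="intubated", tube_label="ETT-3.0")
        assert apparatus_pressure_drop(2 * q, tube) > 2 * apparatus_pressure_drop(q, tube)


class TestIntegration:
    def test_equilibrium_stays_at_rest(self):
        """PS 0, PEEP 4, no effort, started at the PEEP equilibrium: no flow
        develops at any step."""
        cfg = bench_condition("psv", rate=24.0, ps=0.0)
        cfg.effort.amplitude = 0.0
        state = equilibrium_state(cfg.lung, cfg.ventilator)
        for _ in range(400):
            step(state, cfg.lung, cfg.apparatus, cfg.ventilator, cfg.effort, 5e-4)
        assert state.flow == pytest.approx(0.0, abs=1e-12)
        assert state.volume == pytest.approx(cfg.lung.compliance * 1e-3 * 4.0, abs=1e-12)

    def test_step_rejects_coarse_dt(self):
        cfg = bench_condition("bare")
        with pytest.raises(InvalidInputError):
            step(SimState(), cfg.lung, cfg.apparatus, cfg.ventilator, cfg.effort, 2e-3)

    def test_quasi_static_volume_equals_compliance_times_amplitude(self):
        """With no resistive losses and slow breathing the lung tracks Pmus:
        delivered VT -> C * amplitude."""
        cfg = bench_condition("bare", rate=5.0)
        cfg.lung.resistance = 0.0
        cfg.effort.amplitude = 20.0
        trace = simulate_condition(cfg, n_breaths=2, discard=2)
        assert trace.delivered_vt(1) == pytest.approx(1.5 * 20.0, rel=0.02)

    def test_divergence_error_names_parameters(self):
        cfg = bench_condition("bare", rate=36.0)
        cfg.effort.amplitude = 500.0
        with pytest.raises(SimulationDivergedError, match="amplitude=500"):
            simulate_condition(cfg, n_breaths=2, discard=2)

    def test_volume_tracks_integral_of_flow(self):
        cfg = bench_condition("t_piece", rate=36.0)
        cfg.effort.amplitude = 20.0
        tr = simulate_condition(cfg, n_breaths=3, discard=3)
        recon = tr.volume[0] + np.concatenate(
            [[0.0], np.cumsum((tr.flow[1:] + tr.flow[:-1]) / 2) * tr.dt * 1e3]
        )
        assert np.max(np.abs(recon - tr.volume)) < 0.02  # mL, one quadrature step

    def test_invalid_breath_counts_rejected(self):
        cfg = bench_condition("bare")
        with pytest.raises(InvalidInputError):
            simulate_condition(cfg, n_breaths=0)
        with pytest.raises(InvalidInputError):
            simulate_condition(cfg, discard=1)


class TestSteadyState:
    def test_requested_breath_count_delivered(self):
        trace, _ = run_calibrated("bare", 24.0)
        assert trace.n_breaths == 10
        assert len(trace.breath_boundaries) == 11

    def test_periodic_steady_state_vt_spread_below_one_percent(self):
        trace, _ = run_calibrated("bare", 24.0)
        vts = np.array([trace.delivered_vt(i) for i in range(trace.n_breaths)])
        assert vts.std() / vts.mean() < 0.01

    def test_volume_conservation_per_cycle(self):
        """Inspired volume equals expired volume over a steady-state cycle
        to < 1% of VT."""
        trace, _ = run_calibrated("t_piece", 36.0)
        for i in range(trace.n_breaths):
            s = trace.breath_slice(i)
            drift = abs(trace.volume[s.stop - 1] - trace.volume[s.start])
            assert drift < 0.01 * 30.0


class TestCalibration:
    def test_zero_target_gives_zero_amplitude(self):
        cfg = bench_condition("bare")
        cfg.effort.tidal_volume_target = 0.0
        assert calibrate_constant_vt(cfg) == 0.0

    def test_quasi_static_amplitude_near_elastic_prediction(self):
        """Bare, slow breathing: the elastic part alone needs VT/C = 20
        cmH2O; the calibrated amplitude adds only a small resistive margin."""
        cfg = bench_condition("bare", rate=5.0)
        amp = calibrate_constant_vt(cfg)
        assert 20.0 <= amp < 22.0

    def test_pressure_support_unloads_the_muscle(self):
        cfg14 = bench_condition("psv", rate=24.0, ps=14.0)
        cfg0 = bench_condition("psv", rate=24.0, ps=0.0)
        assert calibrate_constant_vt(cfg14) < calibrate_constant_vt(cfg0)

    def test_unreachable_target_reports_achieved_vt(self):
        cfg = bench_condition("bare", rate=24.0)
        cfg.effort.tidal_volume_target = 30.0
        with pytest.raises(CalibrationError) as exc:
            calibrate_constant_vt(cfg, bracket=(0.0, 5.0))
        assert exc.value.achieved_vt_ml is not None
        assert exc.value.achieved_vt_ml < 30.0

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(InvalidInputError):
            calibrate_constant_vt(bench_condition("bare"), vt_tolerance=0.0)


class TestAsynchrony:
    def test_unassisted_breathing_is_trivially_synchronous(self):
        trace, cfg = run_calibrated("bare", 24.0)
        report = detect_asynchrony(trace, cfg.effort)
        assert report.synchronous and report.n_pressurizations == 0

    def test_calibrated_psv_triggers_once_per_effort(self):
        trace, cfg = run_calibrated("psv", 24.0, ps=10.0)
        report = detect_asynchrony(trace, cfg.effort)
        assert report.classification == "synchronous"
        assert report.n_pressurizations == report.n_efforts
        for i in range(trace.n_breaths):
            assert len(trace.pressurization_onsets(i)) == 1

    def test_feeble_effort_fails_to_trigger(self):
        """An effort too weak to deviate circuit flow past the trigger
        threshold produces mis-triggering."""
        cfg = bench_condition("psv", rate=36.0, ps=5.0)
        cfg.effort.amplitude = 0.15
        trace = simulate_condition(cfg)
        report = detect_asynchrony(trace, cfg.effort)
        assert report.classification == "mis_triggering"
        assert report.mis_triggered_breaths > 0

    def test_short_traces_rejected(self):
        cfg = bench_condition("bare")
        cfg.effort.amplitude = 15.0
        trace = simulate_condition(cfg, n_breaths=3, discard=2)
        with pytest.raises(InvalidInputError):
            detect_asynchrony(trace, cfg.effort)


def test_auto_peep_develops_under_psv_at_high_rate():
    """Intubated 3.0-mm at 36/min: end-expiratory alveolar pressure stays
    above set PEEP (dynamic hyperinflation)."""
    from sbtsim.metrics import auto_peep

    trace, _ = run_calibrated("psv", 36.0, ps=10.0, tube="ETT-3.0", n_breaths=5)
    assert all(auto_peep(trace, i) > 0.1 for i in range(5))
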