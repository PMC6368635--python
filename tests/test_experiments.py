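"""Closed-form WOB surface, regression machinery, and sweep invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sbtsim.config import bench_condition
from sbtsim.errors import InsufficientDataError, NoIntersectionError
from sbtsim.experiments import (
    RegressionFit,
    SweepResult,
    WOBSurface,
    eq4_wob_surface,
    eq5_compensating_ps,
    fit_shape_models,
    fit_wob_line,
    intersect_with_reference,
    run_condition,
    run_ps_sweep,
    run_rate_sweep,
)


class TestWOBSurface:
    def test_zero_at_maximum_pressure_support(self):
        s = WOBSurface()
        for f in (20.0, 24.0, 30.0, 36.0, 40.0):
            assert s.wob(14.0, f) == 0.0

    def test_anchor_value_at_ps1_rate24(self):
        # (1.24*24 + 0.89) * 13 / 13 = 30.65 mJ/breath
        assert WOBSurface().wob(1.0, 24.0) == pytest.approx(30.65, abs=1e-9)

    @given(ps1=st.floats(0, 14), ps2=st.floats(0, 14), f=st.floats(10, 60))
    def test_affine_in_pressure_support(self, ps1, ps2, f):
        s = WOBSurface()
        lhs = s.wob(ps1, f) + s.wob(ps2, f)
        rhs = 2.0 * s.wob((ps1 + ps2) / 2.0, f)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_compensating_ps_values(self):
        s = WOBSurface()
        assert round(s.compensating_ps(24.0)) == 1       # 0.979 cmH2O
        assert s.compensating_ps(36.0) == pytest.approx(5.234, abs=5e-3)
        assert s.compensating_ps_integer(36.0) == 6
        assert s.compensating_ps_integer(24.0) == 1

    def test_compensating_ps_increases_with_rate(self):
        s = WOBSurface()
        rates = np.linspace(15, 60, 20)
        ps = [s.compensating_ps(r) for r in rates]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("f", [20.0, 24.0, 30.0, 36.0, 40.0])
    def test_round_trip_recovers_reference_work(self, f):
        """Substituting the compensating PS back into the surface returns
        the reference WOB (399.1/13 = 30.7) identically."""
        s = WOBSurface()
        assert eq4_wob_surface(eq5_compensating_ps(f), f) == pytest.approx(
            399.1 / 13.0, abs=1e-12
        )

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            WOBSurface().wob(5.0, 0.0)


def _sweep_from_line(slope, intercept, levels, sync=True):
    rows = [
        {"pressure_support": float(p), "wob_mean": slope * p + intercept,
         "synchronous": sync}
        for p in levels
    ]
    return SweepResult(axis="pressure_support", table=pd.DataFrame(rows))


class TestWobLineFit:
    def test_noiseless_line_recovered_to_machine_precision(self):
        sweep = _sweep_from_line(-2.1, 40.0, range(14, 0, -1))
        fit = fit_wob_line(sweep)
        assert fit.coefficients[0] == pytest.approx(-2.1, rel=1e-12)
        assert fit.coefficients[1] == pytest.approx(40.0, rel=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_fit_of_surface_evaluations_at_24(self):
        """A line through the closed-form surface at 24/min has slope
        -30.65/13 and PS-0 intercept 33.0 mJ/breath."""
        s = WOBSurface()
        rows = [{"pressure_support": float(p), "wob_mean": s.wob(float(p), 24.0),
                 "synchronous": True} for p in range(14, 0, -1)]
        fit = fit_wob_line(SweepResult(axis="pressure_support", table=pd.DataFrame(rows)))
        assert fit.coefficients[0] == pytest.approx(-30.65 / 13.0, rel=1e-9)
        assert fit.coefficients[1] == pytest.approx(30.65 * 14.0 / 13.0, rel=1e-9)

    def test_ps_zero_always_excluded(self):
        sweep = _sweep_from_line(-2.0, 40.0, range(14, -1, -1))
        fit = fit_wob_line(sweep, ps_range=(0.0, 14.0))
        assert fit.fit_range[0] >= 1.0

    def test_too_few_levels_rejected(self):
        sweep = _sweep_from_line(-2.0, 40.0, [14, 13])
        with pytest.raises(InsufficientDataError):
            fit_wob_line(sweep)

    def test_wrong_axis_rejected(self):
        sweep = SweepResult(axis="rate", table=pd.DataFrame())
        with pytest.raises(InsufficientDataError):
            fit_wob_line(sweep)


class TestIntersection:
    def test_self_consistency_at_ps7(self):
        fit = RegressionFit("linear", (-2.0, 40.0), (1.0, 14.0), 0.0)
        inter = intersect_with_reference(fit, reference_wob=-2.0 * 7 + 40.0)
        assert inter.ps == pytest.approx(7.0)
        assert not inter.extrapolated

    def test_surface_fit_meets_bench_reference_near_ps1(self):
        """The 24/min surface line meets the 30.7 mJ unassisted reference at
        PS ~ 0.98 cmH2O, flagged as below the fitted range."""
        fit = RegressionFit("linear", (-30.65 / 13.0, 30.65 * 14.0 / 13.0), (1.0, 14.0), 0.0)
        inter = intersect_with_reference(fit, 30.7)
        assert inter.ps == pytest.approx(14.0 - 399.1 / 30.65, abs=1e-9)
        assert inter.ps == pytest.approx(1.0, abs=0.05)
        assert inter.extrapolated

    def test_zero_slope_has_no_intersection(self):
        fit = RegressionFit("linear", (0.0, 40.0), (1.0, 14.0), 0.0)
        with pytest.raises(NoIntersectionError):
            intersect_with_reference(fit, 30.0)


class TestShapeModels:
    def test_noiseless_logistic_recovered(self):
        x = np.array([24.0, 26, 28, 30, 32, 34, 36])
        true = (20.0, 50.0, 30.0, 2.0)
        y = true[0] + (true[1] - true[0]) / (1 + np.exp(-(x - true[2]) / true[3]))
        fit = fit_shape_models(x, y, "sigmoid")
        assert np.allclose(fit.coefficients, true, rtol=1e-6)
        assert fit.residual_sd < 1e-8

    def test_noiseless_exponential_recovered(self):
        x = np.arange(4.0, 10.0)
        true = (200.0, 0.8, 0.5)
        y = true[0] * np.exp(-true[1] * x) + true[2]
        fit = fit_shape_models(x, y, "exponential")
        assert np.allclose(fit.coefficients, true, rtol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_shape_models(np.arange(3.0), np.arange(3.0), "sigmoid")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_shape_models(np.arange(5.0), np.arange(5.0), "spline")


class TestSweepDrivers:
    def test_single_level_sweep_yields_one_row_and_no_fit(self):
        sweep = run_ps_sweep(rate=24.0, ps_levels=[10.0])
        assert len(sweep.table) == 1
        with pytest.raises(InsufficientDataError):
            fit_wob_line(sweep)

    def test_single_rate_single_arm(self):
        arms = {"bare": bench_condition("bare")}
        res = run_rate_sweep(rates=[24.0], arms=arms)
        assert len(res["bare"].table) == 1
        assert res["bare"].table.loc[0, "rate"] == 24.0

    def test_sweep_stops_at_first_asynchronous_level(self):
        """With a fixed feeble effort (no constant-VT calibration) every
        level mis-triggers, so the protocol stops immediately."""
        sweep = run_ps_sweep(rate=36.0, ps_levels=[14.0, 13.0], amplitude=0.15)
        assert sweep.stop_level == 14.0
        assert len(sweep.table) == 1
        assert sweep.table.loc[0, "asynchrony"] == "mis_triggering"

    def test_noise_layer_is_seed_reproducible(self):
        cfg = bench_condition("t_piece", rate=36.0)
        cfg.numerics.noise_rel_sd = 0.01
        cfg.numerics.seed = 11
        a = run_condition(cfg, amplitude=22.0)
        b = run_condition(cfg, amplitude=22.0)
        cfg.numerics.seed = 12
        c = run_condition(cfg, amplitude=22.0)
        assert a["wob_mean"] == b["wob_mean"]
        assert a["wob_mean"] != c["wob_mean"]
        assert a["wob_sd"] > 0


class TestSweepInvariants:
    def test_trigger_work_never_exceeds_wob(self, ps_sweeps):
        for sweep in ps_sweeps.values():
            t = sweep.table
            assert (t["trigger_work_mean"] <= t["wob_mean"] + 1e-9).all()

    def test_auto_peep_non_decreasing_in_rate_under_psv(self, rate_sweep):
        for arm in ("psv_ps10", "psv_ps10_30"):
            ap = rate_sweep[arm].mean("auto_peep")
            assert all(b >= a - 0.02 for a, b in zip(ap, ap[1:]))

    def test_distending_pressure_tracks_tpiece_at_24(self, ps_sweeps, rate_sweep):
        """At 24/min the dynamic distending pressure under PSV is nearly
        PS-independent and lies within +/-20% of the T-piece value."""
        tp = rate_sweep["t_piece"].table
        tp_ddp = float(tp.loc[tp["rate"] == 24.0, "ddp_mean"].iloc[0])
        psv = ps_sweeps[(24.0, "ETT-3.5")].table
        sel = psv[psv["pressure_support"] >= 1.0]["ddp_mean"]
        assert sel.max() / sel.min() < 1.10  # flat across PS
        assert abs(sel.mean() / tp_ddp - 1.0) < 0.20

    def test_intubation_never_lowers_work_unassisted(self, rate_sweep):
        """Removing the tube (bare vs T-piece at the same delivered VT)
        never increases WOB."""
        bare = rate_sweep["bare"].mean("wob")
        tp = rate_sweep["t_piece"].mean("wob")
        assert (tp >= bare).all()
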