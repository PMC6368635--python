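"""Idealized breath-trace fixtures with closed-form expected metrics.

Each fixture constructs a :class:`~sbtsim.mechanics.BreathTrace` directly
from analytic signal shapes -- never from the simulator -- together with
the metric values those shapes imply in closed form, so the metric
implementations can be asserted against an independent oracle.
"""

from __future__ import annotations

import math

import numpy as np

from .mechanics import BreathTrace, STATE_EXHALE
from .units import CMH2O_L_TO_MJ

FIXTURE_NAMES = (
    "rectangle-pmus",
    "half-sine-flow",
    "no-effort",
    "exponential-emptying",
)


def _trace(dt, p_aw, p_alv, p_mus, flow, volume, boundaries, meta) -> BreathTrace:
    n = len(volume)
    base = dict(vent_mode="none", peep=0.0, tube_label=None, apparatus_mode="bare")
    base.update(meta)
    return BreathTrace(
        dt=dt,
        t=np.arange(n) * dt,
        p_aw=np.asarray(p_aw, float),
        p_alv=np.asarray(p_alv, float),
        p_mus=np.asarray(p_mus, float),
        flow=np.asarray(flow, float),
        volume=np.asarray(volume, float),
        vent_state=np.full(n, STATE_EXHALE, dtype=np.int8),
        breath_boundaries=np.asarray(boundaries, dtype=np.int64),
        meta=base,
    )


def make_fixture(name: str) -> tuple[BreathTrace, dict]:
    """Return (trace, expected) for a named idealized breath.

    ``expected`` maps metric names to closed-form values.
    """
    if name == "rectangle-pmus":
        return _rectangle_pmus()
    if name == "half-sine-flow":
        return _half_sine_flow()
    if name == "no-effort":
        return _no_effort()
    if name == "exponential-emptying":
        return _exponential_emptying()
    raise KeyError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")


def _rectangle_pmus() -> tuple[BreathTrace, dict]:
    """Rectangular Pmus = -10 cmH2O while 31 mL is inhaled then exhaled.

    The 0.5-mL window rule makes the WOB integral span exactly 30.5 mL of
    inhalation (0.5 -> 31 mL) minus the 0.5-mL exhaled tail, i.e. a net
    30 mL at 10 cmH2O: WOB = 0.300 cmH2O*L = 29.42 mJ.
    """
    dt = 1.0e-3
    vt, pm = 31.0, -10.0
    n_half = 621  # grid step 0.05 mL puts the 0.5-mL window edges on-grid
    v = np.concatenate([np.linspace(0.0, vt, n_half),
                        np.linspace(vt, 0.0, n_half)[1:]])
    n = len(v)
    p_mus = np.full(n, pm)
    flow = np.gradient(v, dt) * 1e-3  # L/s, for completeness
    boundaries = [0, n - 1]
    expected_wob = (vt - 0.5) * 10.0 * 1e-3 * CMH2O_L_TO_MJ - 0.5 * 10.0 * 1e-3 * CMH2O_L_TO_MJ
    trace = _trace(dt, np.zeros(n), v / 1.5, p_mus, flow, v, boundaries, {})
    return trace, {"wob": expected_wob}


def _half_sine_flow() -> tuple[BreathTrace, dict]:
    """Half-sine inspiratory flow with peak 0.06 L/s over 0.5 s.

    Mean of a half-sine is (2/pi) of its peak; inspired volume is
    (2/pi)*peak*Ti.
    """
    dt = 1.0e-3
    q_peak, ti, te = 0.06, 0.5, 1.0
    n_i, n_e = int(ti / dt), int(te / dt)
    t_i = np.arange(n_i) * dt
    q = np.concatenate([q_peak * np.sin(math.pi * t_i / ti),
                        np.full(n_e, -0.01)])
    n = len(q)
    v = np.concatenate([[0.0], np.cumsum((q[1:] + q[:-1]) / 2) * dt]) * 1e3
    v = np.maximum(v, 0.0)
    boundaries = [0, n - 1]
    trace = _trace(dt, np.zeros(n), v / 1.5, np.zeros(n), q, v, boundaries, {})
    return trace, {"mean_flow": (2 / math.pi) * q_peak * 60.0,
                   "peak_flow": q_peak * 60.0}


def _no_effort() -> tuple[BreathTrace, dict]:
    """Equilibrium: all signals flat; every work metric is zero."""
    dt = 1.0e-3
    n = 2001
    z = np.zeros(n)
    trace = _trace(dt, z, z, z, z, z, [0, 1000, 2000], {})
    return trace, {"wob": 0.0, "trigger_work": 0.0, "auto_peep": 0.0}


def _exponential_emptying() -> tuple[BreathTrace, dict]:
    """Periodic instant-fill / exponential-emptying breaths.

    With tidal volume VT inhaled instantaneously and passive emptying with
    time constant tau = R*C over expiratory time Te, the periodic
    end-expiratory volume is the geometric-series limit
    V_ee = VT * e^(-Te/tau) / (1 - e^(-Te/tau)), giving
    auto-PEEP = V_ee / C above the (zero) baseline.
    """
    dt = 1.0e-3
    C, R = 1.5, 200.0          # mL/cmH2O, cmH2O/(L/s)
    tau = R * C * 1e-3         # s
    vt = 30.0
    n_e = 900                  # samples per cycle; fill happens between
    te = (n_e - 1) * dt        # onset sample and the next one
    x = math.exp(-te / tau)
    v_ee = vt * x / (1.0 - x)
    cycle = np.empty(n_e)
    cycle[0] = v_ee            # end-expiration = effort onset, pre-fill
    cycle[1:] = (v_ee + vt) * np.exp(-np.arange(n_e - 1) * dt / tau)
    v = np.concatenate([cycle, cycle, [v_ee]])
    n = len(v)
    boundaries = [0, n_e, 2 * n_e]
    p_alv = v / C
    flow = np.gradient(v, dt) * 1e-3
    trace = _trace(dt, p_alv, p_alv, np.zeros(n), flow, v, boundaries,
                   {"peep": 0.0})
    return trace, {"auto_peep": v_ee / C, "tau": tau, "te": te, "vt": vt,
                   "compliance": C}
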