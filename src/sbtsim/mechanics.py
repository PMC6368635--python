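"""Single-compartment lung + active effort + tube + PSV ventilator simulator.

This module replaces the physical bench (active lung simulator driven in
constant-tidal-volume mode, breathing bare / through a T-piece tube / under
pressure-support ventilation) with a deterministic fixed-step integration of
the single-compartment equation of motion

    p_aw(t) = R_lung * q(t) + V(t)/C + Pmus(t)

where the airway-opening pressure is the ventilator source pressure minus
the apparatus (tube) Rohrer drop, dP = k1*q + k2*q*|q|.  In PSV mode the
source pressure relaxes first-order toward PEEP+PS while pressurizing and
toward PEEP while exhaling; triggering is flow-based with an actuation
delay; cycling is flow-based with an inspiratory-time cap.  Expiratory flow
in PSV additionally traverses the expiratory limb / exhalation valve,
modelled as a linear resistance.

All internal quantities use the clinical-consistent system cmH2O / L / s;
volumes cross the interface in mL.

Integration is an explicit midpoint (RK2) scheme at dt = 0.5 ms; the flow
is obtained at each stage by solving the quadratic Rohrer balance exactly,
and the ventilator source pressure is advanced with the exact exponential
relaxation, so halving dt changes per-breath work integrals by far less
than the 0.5% contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import AirwayApparatus, EffortProfile, LungModel, RunConfig, VentilatorSettings
from .errors import CalibrationError, InvalidInputError, SimulationDivergedError
from .units import LPM_TO_LPS, ML_TO_L

# vent_state codes stored per sample
STATE_EXHALE = 0
STATE_TRIGGERED = 1
STATE_PRESSURIZING = 2

#: Minimum pressurization time before flow-cycling is evaluated, s.  Lets
#: inspiratory flow build past the cycling threshold at pressurization onset.
MIN_PRESSURIZATION_TIME = 0.05

#: Shape constant of the exponential Pmus release: the release phase decays
#: with time constant (release window)/RELEASE_DECAY and is re-anchored to
#: end exactly at zero.
RELEASE_DECAY = 1.5


@dataclass
class BreathTrace:
    """Uniformly sampled signals for a run of simulated breaths.

    ``volume`` is in mL above the condition's resting end-expiratory
    equilibrium; ``flow`` is in L/s, inspiratory positive.
    ``breath_boundaries`` are sample indices of effort onsets and include
    the onset closing the final breath, so the trace holds
    ``len(breath_boundaries) - 1`` complete breaths.
    """

    dt: float
    t: np.ndarray
    p_aw: np.ndarray
    p_alv: np.ndarray
    p_mus: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    vent_state: np.ndarray
    breath_boundaries: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_breaths(self) -> int:
        return len(self.breath_boundaries) - 1

    def breath_slice(self, i: int) -> slice:
        """Half-open sample range of breath ``i`` (onset to next onset)."""
        if not 0 <= i < self.n_breaths:
            raise IndexError(f"breath index {i} out of range (have {self.n_breaths})")
        return slice(int(self.breath_boundaries[i]), int(self.breath_boundaries[i + 1]) + 1)

    def delivered_vt(self, i: int) -> float:
        """Delivered tidal volume of breath ``i`` in mL (peak - onset)."""
        s = self.breath_slice(i)
        v = self.volume[s]
        return float(v.max() - v[0])

    def pressurization_onsets(self, i: int) -> np.ndarray:
        """Sample indices (trace-relative) where pressurization starts
        within breath ``i``."""
        s = self.breath_slice(i)
        st = self.vent_state[s.start:s.stop - 1]
        starts = np.flatnonzero((st[1:] == STATE_PRESSURIZING) & (st[:-1] != STATE_PRESSURIZING)) + 1
        if st.size and st[0] == STATE_PRESSURIZING and (i == 0 or self.vent_state[s.start - 1] != STATE_PRESSURIZING):
            starts = np.concatenate(([0], starts))
        return starts + s.start


def pmus_waveform(t_in_cycle: float, effort: EffortProfile) -> float:
    """Muscle pressure (cmH2O, <= 0) at time ``t_in_cycle`` into the cycle.

    Half-sine descent to -amplitude over the rise window, optional hold,
    exponential release back to exactly zero, zero elsewhere.
    """
    T = effort.cycle_time
    if not 0 <= t_in_cycle < T:
        raise InvalidInputError(f"t_in_cycle must be in [0, {T}), got {t_in_cycle}")
    a = effort.amplitude
    if a == 0.0:
        return 0.0
    t_rise = effort.rise_fraction * T
    t_hold = effort.hold_fraction * T
    t_rel = effort.release_fraction * T
    if t_in_cycle < t_rise:
        return -a * math.sin(0.5 * math.pi * t_in_cycle / t_rise)
    if t_in_cycle < t_rise + t_hold:
        return -a
    if t_in_cycle < t_rise + t_hold + t_rel:
        u = (t_in_cycle - t_rise - t_hold) / t_rel
        e0 = math.exp(-RELEASE_DECAY)
        return -a * (math.exp(-RELEASE_DECAY * u) - e0) / (1.0 - e0)
    return 0.0


def apparatus_pressure_drop(flow: float, apparatus: AirwayApparatus) -> float:
    """Rohrer pressure drop across the apparatus, cmH2O (signed with flow)."""
    if apparatus.mode == "bare":
        return 0.0
    return apparatus.rohrer_k1 * flow + apparatus.rohrer_k2 * flow * abs(flow)


def _solve_flow(drive: float, a_lin: float, k2: float) -> float:
    """Solve drive = a_lin*q + k2*q*|q| for q (exact, sign-consistent)."""
    if k2 == 0.0:
        return drive / a_lin
    if drive >= 0.0:
        return (-a_lin + math.sqrt(a_lin * a_lin + 4.0 * k2 * drive)) / (2.0 * k2)
    return -(-a_lin + math.sqrt(a_lin * a_lin - 4.0 * k2 * drive)) / (2.0 * k2)


@dataclass
class SimState:
    """Mutable integration state for :func:`step` / the inner loop."""

    t: float = 0.0
    volume: float = 0.0          # L, absolute above relaxed volume at p=0
    flow: float = 0.0            # L/s at the airway opening
    p_src: float = 0.0           # ventilator source pressure, cmH2O
    vent_state: int = STATE_EXHALE
    trigger_timer: float = 0.0
    t_insp: float = 0.0
    peak_insp_flow: float = 0.0
    armed: bool = True           # re-trigger guard: needs expiratory flow first


def _run(
    lung: LungModel,
    apparatus: AirwayApparatus,
    vent: VentilatorSettings,
    effort: EffortProfile,
    dt: float,
    n_steps: int,
    state: SimState,
    record: bool,
):
    """Advance ``state`` by ``n_steps`` samples of ``dt``.

    Returns (t, p_aw, p_alv, p_mus, flow, volume, vent_state) arrays when
    ``record`` is true, else ``None``.  The stored flow sample is the
    instantaneous flow consistent with the stored volume/pressures at that
    sample time; the volume update uses the midpoint flow (RK2).
    """
    C = lung.compliance * ML_TO_L          # L/cmH2O
    R = lung.resistance                    # cmH2O/(L/s)
    k1 = float(apparatus.rohrer_k1 or 0.0)
    k2 = float(apparatus.rohrer_k2 or 0.0)
    psv = vent.mode == "psv"
    peep = vent.peep if psv else 0.0
    ps = vent.pressure_support if psv else 0.0
    # Zero total resistance makes the flow balance algebraic; a small
    # numerical floor (time constant ~ dt) yields the quasi-static limit.
    a_in = max(R + k1, 0.5)
    a_ex = max(R + k1 + (vent.exp_resistance if psv else 0.0), 0.5)
    trig_q = vent.trigger_deviation * LPM_TO_LPS
    delay = vent.actuation_delay
    tau = vent.rise_time_constant
    relax = 1.0 - math.exp(-dt / tau) if psv else 0.0
    T = effort.cycle_time
    insp_cap = vent.insp_fraction * T
    cyc_frac = vent.cycle_off_fraction
    vt_limit = max(10.0 * effort.tidal_volume_target * ML_TO_L, 0.15) + C * (peep + ps)

    if record:
        arr_t = np.empty(n_steps)
        arr_paw = np.empty(n_steps)
        arr_palv = np.empty(n_steps)
        arr_pmus = np.empty(n_steps)
        arr_q = np.empty(n_steps)
        arr_v = np.empty(n_steps)
        arr_state = np.empty(n_steps, dtype=np.int8)

    t = state.t
    V = state.volume
    p_src = state.p_src
    vstate = state.vent_state
    timer = state.trigger_timer
    t_insp = state.t_insp
    peak_q = state.peak_insp_flow
    armed = state.armed

    half_relax = 1.0 - math.exp(-0.5 * dt / tau) if psv else 0.0

    for k in range(n_steps):
        tc = t % T
        pmus = pmus_waveform(tc, effort)
        # instantaneous flow consistent with current state
        p_alv = V / C + pmus
        drive = p_src - p_alv
        q = _solve_flow(drive, a_in if drive >= 0 else a_ex, k2)

        if record:
            arr_t[k] = t
            arr_pmus[k] = pmus
            arr_palv[k] = p_alv
            arr_q[k] = q
            arr_v[k] = V
            arr_paw[k] = p_alv + R * q
            arr_state[k] = vstate

        # ventilator state machine (decisions on the instantaneous flow)
        if psv:
            if vstate == STATE_EXHALE:
                if q <= 0.0:
                    armed = True
                if armed and q > trig_q:
                    if delay > 0.0:
                        vstate = STATE_TRIGGERED
                        timer = delay
                    else:
                        vstate = STATE_PRESSURIZING
                        t_insp = 0.0
                        peak_q = 0.0
            elif vstate == STATE_TRIGGERED:
                timer -= dt
                if timer <= 0.0:
                    vstate = STATE_PRESSURIZING
                    t_insp = 0.0
                    peak_q = 0.0
            elif vstate == STATE_PRESSURIZING:
                t_insp += dt
                if q > peak_q:
                    peak_q = q
                if (t_insp >= MIN_PRESSURIZATION_TIME and q <= cyc_frac * peak_q) or t_insp >= insp_cap:
                    vstate = STATE_EXHALE
                    armed = False
            target = peep + ps if vstate == STATE_PRESSURIZING else peep
        else:
            target = 0.0

        # midpoint (RK2) volume update; source pressure relaxed exactly
        p_src_half = p_src + (target - p_src) * half_relax if psv else 0.0
        tc_half = (t + 0.5 * dt) % T
        pmus_half = pmus_waveform(tc_half, effort)
        V_half = V + 0.5 * dt * q
        drive_h = p_src_half - (V_half / C + pmus_half)
        q_half = _solve_flow(drive_h, a_in if drive_h >= 0 else a_ex, k2)
        V += dt * q_half
        p_src = p_src + (target - p_src) * relax if psv else 0.0
        t += dt

        if abs(V) > vt_limit:
            raise SimulationDivergedError(
                f"volume |{V * 1e3:.1f} mL| exceeded {vt_limit * 1e3:.1f} mL at "
                f"t={t:.3f} s (dt={dt}, rate={effort.rate}, amplitude={effort.amplitude}, "
                f"PS={ps}, apparatus={apparatus.mode})",
                dt=dt,
            )

    state.t = t
    state.volume = V
    state.flow = q
    state.p_src = p_src
    state.vent_state = vstate
    state.trigger_timer = timer
    state.t_insp = t_insp
    state.peak_insp_flow = peak_q
    state.armed = armed

    if record:
        return arr_t, arr_paw, arr_palv, arr_pmus, arr_q, arr_v, arr_state
    return None


def step(
    state: SimState,
    lung: LungModel,
    apparatus: AirwayApparatus,
    vent: VentilatorSettings,
    effort: EffortProfile,
    dt: float,
) -> SimState:
    """Advance the simulation by one sample of ``dt`` (<= 1 ms) in place."""
    if dt > 1.0e-3:
        raise InvalidInputError(f"dt must be <= 1 ms, got {dt}")
    _run(lung, apparatus, vent, effort, dt, 1, state, record=False)
    return state


def equilibrium_state(lung: LungModel, vent: VentilatorSettings) -> SimState:
    """Resting state: lung inflated to the source-pressure equilibrium."""
    peep = vent.peep if vent.mode == "psv" else 0.0
    return SimState(volume=lung.compliance * ML_TO_L * peep, p_src=peep)


def simulate_condition(
    config: RunConfig,
    n_breaths: Optional[int] = None,
    dt: Optional[float] = None,
    discard: Optional[int] = None,
) -> BreathTrace:
    """Simulate one bench condition and return its steady-state breaths.

    ``discard`` transient breaths are run first and dropped; the returned
    trace holds ``n_breaths`` complete breaths plus the sample at the onset
    closing the last one, with ``breath_boundaries`` marking effort onsets.
    """
    num = config.numerics
    n_breaths = num.n_breaths if n_breaths is None else n_breaths
    discard = num.discard_breaths if discard is None else discard
    dt = num.dt if dt is None else dt
    if n_breaths < 1:
        raise InvalidInputError("n_breaths must be >= 1")
    if discard < 2:
        raise InvalidInputError("discard must be >= 2 transient breaths")

    effort = config.effort
    T = effort.cycle_time
    steps_per_breath = int(round(T / dt))
    total_breaths = discard + n_breaths
    n_steps = steps_per_breath * total_breaths + 1

    state = equilibrium_state(config.lung, config.ventilator)
    arrays = _run(config.lung, config.apparatus, config.ventilator, effort,
                  dt, n_steps, state, record=True)
    t, p_aw, p_alv, p_mus, flow, volume, vent_state = arrays

    k0 = steps_per_breath * discard
    boundaries = np.array(
        [steps_per_breath * m - k0 for m in range(discard, total_breaths + 1)],
        dtype=np.int64,
    )
    sl = slice(k0, n_steps)
    v_ref = volume[k0]  # end-expiratory volume at steady-state onset
    trace = BreathTrace(
        dt=dt,
        t=t[sl] - t[k0],
        p_aw=p_aw[sl].copy(),
        p_alv=p_alv[sl].copy(),
        p_mus=p_mus[sl].copy(),
        flow=flow[sl].copy(),
        volume=(volume[sl] - v_ref) / ML_TO_L,
        vent_state=vent_state[sl].copy(),
        breath_boundaries=boundaries,
        meta={
            "apparatus_mode": config.apparatus.mode,
            "tube_label": config.apparatus.tube_label,
            "vent_mode": config.ventilator.mode,
            "pressure_support": config.ventilator.pressure_support,
            "peep": config.ventilator.peep if config.ventilator.mode == "psv" else 0.0,
            "rate": effort.rate,
            "amplitude": effort.amplitude,
            "compliance": config.lung.compliance,
            "resistance": config.lung.resistance,
            "dt": dt,
            # absolute alveolar-pressure offset removed from `volume`:
            "end_expiratory_volume_ml": v_ref / ML_TO_L,
        },
    )
    return trace


def measure_delivered_vt(trace: BreathTrace, last: int = 3) -> float:
    """Mean delivered VT (mL) over the last ``last`` breaths of a trace."""
    n = trace.n_breaths
    take = range(max(0, n - last), n)
    return float(np.mean([trace.delivered_vt(i) for i in take]))


def calibrate_constant_vt(
    config: RunConfig,
    vt_tolerance: Optional[float] = None,
    bracket: tuple[float, float] = (0.0, 60.0),
    max_iter: int = 60,
) -> float:
    """Find the effort amplitude delivering the target tidal volume.

    Emulates the bench's constant-VT controller: monotone bisection on the
    Pmus amplitude until the steady-state delivered VT is within
    ``vt_tolerance`` (default from numerics, 0.1 mL) of the target.
    Deterministic for fixed inputs.  Returns the calibrated amplitude in
    cmH2O; the caller is responsible for storing it in the effort profile.
    """
    target = config.effort.tidal_volume_target
    tol = config.numerics.vt_tolerance if vt_tolerance is None else vt_tolerance
    if tol <= 0:
        raise InvalidInputError("vt_tolerance must be > 0")
    if target == 0.0:
        return 0.0

    def vt_at(amplitude: float) -> float:
        cfg = config.model_copy(deep=True)
        cfg.effort.amplitude = amplitude
        trace = simulate_condition(cfg, n_breaths=3, discard=4)
        return measure_delivered_vt(trace, last=2)

    lo, hi = bracket
    vt_hi = vt_at(hi)
    if vt_hi < target - tol:
        raise CalibrationError(
            f"amplitude bracket [{lo}, {hi}] cmH2O cannot reach VT "
            f"{target} mL (achieved {vt_hi:.2f} mL at {hi} cmH2O)",
            achieved_vt_ml=vt_hi,
        )
    if abs(vt_hi - target) <= tol:
        return hi
    vt_mid = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        vt_mid = vt_at(mid)
        if abs(vt_mid - target) <= tol:
            return mid
        if vt_mid < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(last VT {vt_mid:.3f} mL vs target {target} mL)",
        achieved_vt_ml=vt_mid,
    )


@dataclass(frozen=True)
class AsynchronyReport:
    """Classification of patient-ventilator interaction over a trace."""

    classification: str  # synchronous | double_triggering | mis_triggering
    n_efforts: int
    n_pressurizations: int
    double_triggered_breaths: int
    mis_triggered_breaths: int

    @property
    def synchronous(self) -> bool:
        return self.classification == "synchronous"


def detect_asynchrony(trace: BreathTrace, effort: EffortProfile) -> AsynchronyReport:
    """Flag double-triggering (>1 pressurization per effort) and
    mis-triggering (an effort with no pressurization, PSV only).

    Requires a trace spanning at least 5 breaths.  For unassisted modes the
    report is trivially synchronous.
    """
    n = trace.n_breaths
    if n < 5:
        raise InvalidInputError(f"asynchrony detection needs >= 5 breaths, got {n}")
    if trace.meta.get("vent_mode") != "psv":
        return AsynchronyReport("synchronous", n, 0, 0, 0)
    per_breath = [len(trace.pressurization_onsets(i)) for i in range(n)]
    double = sum(1 for c in per_breath if c > 1)
    missed = sum(1 for c in per_breath if c == 0)
    if double:
        cls = "double_triggering"
    elif missed:
        cls = "mis_triggering"
    else:
        cls = "synchronous"
    return AsynchronyReport(cls, n, int(sum(per_breath)), double, missed)
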