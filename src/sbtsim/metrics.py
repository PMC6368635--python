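"""Per-breath scalar metrics from a :class:`~sbtsim.mechanics.BreathTrace`.

Work of breathing is the effort integral WOB = int (-Pmus) dV over the
measurement window that starts once 0.5 mL has been inhaled and ends once
0.5 mL has been exhaled from peak inspiratory volume; the result is
converted from cmH2O*L to mJ (1 cmH2O*L = 98.0665 mJ, applied in exactly
one place, :mod:`sbtsim.units`).  Trigger work is the same integral
truncated where airway pressure first returns to the set PEEP after its
trigger-induced downward deflection.  Dynamic distending pressure is
PIP - Pmus with Pmus the breath's most negative (peak-effort) value; for
unassisted breathing no ventilator pressure is delivered and the distending
pressure reduces to |Pmus|.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import WindowUndefinedError
from .gas import DRY_GAS_FIO2_04, CONDUITS, GasProperties, reynolds_number_lpm
from .mechanics import BreathTrace
from .units import CMH2O_L_TO_MJ, ML_TO_L

#: Volume threshold of the work-of-breathing window, mL.
WOB_WINDOW_ML = 0.5


@dataclass(frozen=True)
class BreathMetrics:
    """Scalar summary of one breath."""

    wob: float               # mJ
    trigger_work: float      # mJ
    pip: float               # cmH2O (0 for unassisted breathing)
    pmus_min: float          # cmH2O, most negative Pmus
    max_trigger_drop: float  # cmH2O, min(p_aw - PEEP) before pressurization
    auto_peep: float         # cmH2O, clipped at 0
    auto_peep_raw: float     # cmH2O, unclipped (audit)
    ddp: float               # cmH2O, dynamic distending pressure
    mean_flow: float         # L/min, inspiratory
    peak_flow: float         # L/min, inspiratory
    re_mean: float           # Reynolds number at mean flow
    re_peak: float           # Reynolds number at peak flow
    vt: float                # mL, delivered tidal volume


def _wob_window(trace: BreathTrace, i: int) -> tuple[int, int, np.ndarray]:
    """Sample window [k_start, k_end] of the WOB integral for breath i.

    Returns trace-relative indices plus the breath's onset-referenced
    volume (mL).  Raises :class:`WindowUndefinedError` when the breath
    never inhales past the 0.5-mL threshold.
    """
    s = trace.breath_slice(i)
    v = trace.volume[s] - trace.volume[s.start]
    above = np.flatnonzero(v >= WOB_WINDOW_ML)
    if above.size == 0:
        raise WindowUndefinedError(
            f"breath {i} never inhales {WOB_WINDOW_ML} mL (peak {v.max():.3f} mL)"
        )
    k_start = int(above[0])
    k_peak = int(np.argmax(v))
    v_peak = v[k_peak]
    below = np.flatnonzero(v[k_peak:] <= v_peak - WOB_WINDOW_ML)
    if below.size == 0:
        raise WindowUndefinedError(
            f"breath {i} never exhales {WOB_WINDOW_ML} mL from its peak"
        )
    k_end = k_peak + int(below[0])
    return s.start + k_start, s.start + k_end, v


def _effort_integral(trace: BreathTrace, k_start: int, k_end: int) -> float:
    """Trapezoidal int of (-Pmus) dV over [k_start, k_end], in mJ."""
    if k_end <= k_start:
        return 0.0
    pm = trace.p_mus[k_start:k_end + 1]
    v_l = trace.volume[k_start:k_end + 1] * ML_TO_L
    work_cmh2o_l = float(np.trapezoid(-pm, v_l))
    return work_cmh2o_l * CMH2O_L_TO_MJ


def work_of_breathing(trace: BreathTrace, i: int) -> float:
    """Work of breathing of breath ``i`` in mJ (0.5-mL window rule)."""
    k_start, k_end, _ = _wob_window(trace, i)
    return _effort_integral(trace, k_start, k_end)


def trigger_work(trace: BreathTrace, i: int, set_peep: Optional[float] = None) -> float:
    """Trigger work of breath ``i`` in mJ.

    Same integrand and start as the WOB window; the upper limit is the
    first sample, after airway pressure has deflected below the set PEEP,
    at which it recovers to >= PEEP.  Returns 0 when no downward deflection
    occurs in the window, and 0 for unassisted (non-PSV) breathing.

    TW is a sub-portion of WOB, so it is capped at the breath's WOB: when
    pressure recovery happens only near peak volume, the truncated integral
    can exceed the full-window WOB by up to the small negative 0.5-mL
    exhaled tail that only the full window includes.
    """
    if trace.meta.get("vent_mode") != "psv":
        return 0.0
    peep = trace.meta["peep"] if set_peep is None else set_peep
    k_start, k_end, _ = _wob_window(trace, i)
    paw = trace.p_aw[k_start:k_end + 1]
    dipped = np.flatnonzero(paw < peep - 1e-9)
    if dipped.size == 0:
        return 0.0
    rec = np.flatnonzero(paw[dipped[0]:] >= peep)
    k_stop = k_end if rec.size == 0 else k_start + int(dipped[0]) + int(rec[0])
    tw = _effort_integral(trace, k_start, min(k_stop, k_end))
    return min(tw, _effort_integral(trace, k_start, k_end))


def dynamic_distending_pressure(pip: float, pmus_min: float) -> float:
    """PIP - Pmus (Pmus entered signed, so the result is >= PIP)."""
    return pip - pmus_min


def auto_peep(trace: BreathTrace, i: int, set_peep: Optional[float] = None) -> float:
    """End-expiratory alveolar pressure above set PEEP, clipped at 0."""
    return max(0.0, auto_peep_raw(trace, i, set_peep))


def auto_peep_raw(trace: BreathTrace, i: int, set_peep: Optional[float] = None) -> float:
    """Unclipped p_alv(next effort onset) - set PEEP (audit value)."""
    peep = trace.meta.get("peep", 0.0) if set_peep is None else set_peep
    if i >= trace.n_breaths:
        raise WindowUndefinedError(
            f"breath {i} has no following effort onset in the trace"
        )
    k_next = int(trace.breath_boundaries[i + 1])
    return float(trace.p_alv[k_next] - peep)


def max_trigger_pressure_drop(
    trace: BreathTrace, i: int, set_peep: Optional[float] = None
) -> float:
    """Most negative p_aw - PEEP between effort onset and pressurization.

    0 when no pressurization occurs in the breath or pressure never drops.
    """
    if trace.meta.get("vent_mode") != "psv":
        return 0.0
    peep = trace.meta["peep"] if set_peep is None else set_peep
    onsets = trace.pressurization_onsets(i)
    s = trace.breath_slice(i)
    k_stop = int(onsets[0]) if onsets.size else s.stop - 1
    seg = trace.p_aw[s.start:k_stop + 1] - peep
    if seg.size == 0:
        return 0.0
    return min(0.0, float(seg.min()))


def flow_stats(trace: BreathTrace, i: int) -> tuple[float, float]:
    """(mean_flow, peak_flow) in L/min over the inspiratory phase.

    The inspiratory window is the set of positive-flow samples within the
    breath; mean flow is inspired volume divided by that window's duration
    (equivalently the mean of the positive flow samples).
    """
    s = trace.breath_slice(i)
    q = trace.flow[s.start:s.stop - 1]  # exclude the closing onset sample
    pos = q[q > 0]
    if pos.size == 0:
        raise WindowUndefinedError(f"breath {i} has no inspiratory (flow > 0) samples")
    mean_lps = float(pos.mean())
    peak_lps = float(pos.max())
    return mean_lps * 60.0, peak_lps * 60.0


def breath_metrics(
    trace: BreathTrace,
    i: int,
    gas: GasProperties = DRY_GAS_FIO2_04,
) -> BreathMetrics:
    """Compute the full scalar summary for breath ``i``."""
    s = trace.breath_slice(i)
    pmus_min = float(trace.p_mus[s].min())
    assisted = trace.meta.get("vent_mode") == "psv"
    # PIP is the ventilator-delivered peak: airway pressure over the
    # inspiratory phase (onset to peak volume), excluding the expiratory
    # pressure transient across the exhalation pathway.
    k_peak = s.start + int(np.argmax(trace.volume[s]))
    pip = float(trace.p_aw[s.start:k_peak + 1].max()) if assisted else 0.0
    mean_f, peak_f = flow_stats(trace, i)
    label = trace.meta.get("tube_label") or "adapter-port-22mm"
    conduit = CONDUITS[label]
    ap_raw = auto_peep_raw(trace, i)
    return BreathMetrics(
        wob=work_of_breathing(trace, i),
        trigger_work=trigger_work(trace, i),
        pip=pip,
        pmus_min=pmus_min,
        max_trigger_drop=max_trigger_pressure_drop(trace, i),
        auto_peep=max(0.0, ap_raw),
        auto_peep_raw=ap_raw,
        ddp=dynamic_distending_pressure(pip, pmus_min),
        mean_flow=mean_f,
        peak_flow=peak_f,
        re_mean=reynolds_number_lpm(mean_f, conduit, gas),
        re_peak=reynolds_number_lpm(peak_f, conduit, gas),
        vt=trace.delivered_vt(i),
    )


def metrics_table(trace: BreathTrace, gas: GasProperties = DRY_GAS_FIO2_04) -> pd.DataFrame:
    """One row of :class:`BreathMetrics` per breath, plus condition columns."""
    rows = [asdict(breath_metrics(trace, i, gas)) for i in range(trace.n_breaths)]
    df = pd.DataFrame(rows)
    df.insert(0, "breath", np.arange(trace.n_breaths))
    for key in ("apparatus_mode", "tube_label", "vent_mode", "pressure_support", "rate"):
        df[key] = trace.meta.get(key)
    return df
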