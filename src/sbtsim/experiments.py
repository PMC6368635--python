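"""Sweep drivers, regression fits, and the closed-form WOB surface.

The bench protocol has two control settings: a respiratory-rate sweep
(24 -> 36 /min) over the three breathing settings (lung simulator alone,
T-piece, PSV at fixed PS), and a pressure-support sweep (PS 14 -> 0 cmH2O)
at fixed rate.  Each condition is re-calibrated to constant tidal volume,
simulated to periodic steady state, and summarised as per-breath metric
means and SDs over 10 breaths.

The closed-form work-of-breathing surface for the 3.5-mm tube,

    WOB(PS, f_B) = -(a*f_B + b) * (PS - PS_max) / s

with a = 1.24 mJ/breath per breath/min, b = 0.89 mJ/breath,
PS_max = 14 cmH2O and s = 13 cmH2O, is zero at PS_max and linear in both
arguments.  Setting it equal to a reference unassisted WOB W_ref and
solving for PS gives the compensating pressure support

    PS(f_B) = PS_max - s*W_ref / (a*f_B + b)

which with the bench's W_ref = 30.7 mJ/breath (lung simulator alone at
24/min) is PS = 14 - 399.1 / (1.24*f_B + 0.89).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import RunConfig, bench_condition
from .errors import (
    FitFailureError,
    InsufficientDataError,
    NoIntersectionError,
    WindowUndefinedError,
)
from .mechanics import calibrate_constant_vt, detect_asynchrony, simulate_condition
from .metrics import metrics_table

log = logging.getLogger(__name__)

#: Metric columns aggregated into sweep tables.
_METRIC_COLS = [
    "wob", "trigger_work", "pip", "pmus_min", "max_trigger_drop",
    "auto_peep", "auto_peep_raw", "ddp", "mean_flow", "peak_flow",
    "re_mean", "re_peak", "vt",
]


@dataclass(frozen=True)
class WOBSurface:
    """Coefficients of the closed-form WOB(PS, f_B) plane (3.5-mm tube)."""

    slope_in_rate: float = 1.24   # a, mJ/breath per (breath/min)
    offset: float = 0.89          # b, mJ/breath
    ps_max: float = 14.0          # cmH2O at which WOB vanishes
    scale: float = 13.0           # cmH2O
    tube_label: str = "ETT-3.5"

    def wob(self, ps: float, rate: float) -> float:
        """Evaluate the surface; warns outside the studied PS range."""
        if rate <= 0:
            raise ValueError(f"respiratory rate must be > 0, got {rate}")
        if not 0.0 <= ps <= self.ps_max:
            log.warning("PS %.2f cmH2O outside the studied range [0, %.0f]",
                        ps, self.ps_max)
        return -(self.slope_in_rate * rate + self.offset) * (ps - self.ps_max) / self.scale

    def compensating_ps(self, rate: float, reference_wob: float = 30.7) -> float:
        """PS at which the surface equals ``reference_wob`` (default: the
        bench's unassisted WOB anchor, 30.7 mJ/breath)."""
        if rate <= 0:
            raise ValueError(f"respiratory rate must be > 0, got {rate}")
        return self.ps_max - self.scale * reference_wob / (self.slope_in_rate * rate + self.offset)

    def compensating_ps_integer(self, rate: float, reference_wob: float = 30.7) -> int:
        """Smallest whole-cmH2O PS that at least offsets the tube load
        (ceiling of the raw value, floored at 0)."""
        return max(0, math.ceil(self.compensating_ps(rate, reference_wob)))


def eq4_wob_surface(ps: float, rate: float, surface: WOBSurface = WOBSurface()) -> float:
    """Closed-form WOB surface evaluation (module-level convenience)."""
    return surface.wob(ps, rate)


def eq5_compensating_ps(rate: float, surface: WOBSurface = WOBSurface()) -> float:
    """Compensating pressure support as a function of respiratory rate."""
    return surface.compensating_ps(rate)


@dataclass
class SweepResult:
    """Tabulated per-condition metric means/SDs across one sweep."""

    axis: str                      # "pressure_support" or "rate"
    table: pd.DataFrame
    stop_level: Optional[float] = None  # PS level at which the sweep stopped
    meta: dict = field(default_factory=dict)

    @property
    def conditions(self) -> np.ndarray:
        return self.table[self.axis].to_numpy()

    def mean(self, metric: str) -> np.ndarray:
        return self.table[f"{metric}_mean"].to_numpy()

    def sd(self, metric: str) -> np.ndarray:
        return self.table[f"{metric}_sd"].to_numpy()


@dataclass(frozen=True)
class RegressionFit:
    """A fitted line/curve over a sweep range."""

    kind: str                      # linear | sigmoid | exponential
    coefficients: tuple            # kind-specific, documented per fitter
    fit_range: tuple[float, float]
    residual_sd: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            slope, intercept = self.coefficients
            return slope * x + intercept
        if self.kind == "exponential":
            a, b, c = self.coefficients
            return a * np.exp(-b * x) + c
        if self.kind == "sigmoid":
            lo, hi, x50, steep = self.coefficients
            return lo + (hi - lo) / (1.0 + np.exp(-(x - x50) / steep))
        raise ValueError(f"unknown fit kind {self.kind!r}")


def _noise_rng(config: RunConfig):
    num = config.numerics
    if num.noise_rel_sd > 0:
        return np.random.default_rng(num.seed), num.noise_rel_sd
    return None, 0.0


def run_condition(config: RunConfig, amplitude: Optional[float] = None) -> dict:
    """Calibrate (unless ``amplitude`` is given), simulate, and summarise
    one condition.  Returns a flat dict of metric means/SDs plus flags."""
    cfg = config.model_copy(deep=True)
    if amplitude is None:
        amplitude = calibrate_constant_vt(cfg)
    cfg.effort.amplitude = amplitude
    trace = simulate_condition(cfg)
    try:
        table = metrics_table(trace)
    except WindowUndefinedError:
        # condition not measurable (e.g. effort too feeble to inhale past
        # the metric window); report NaNs with the asynchrony flag
        table = None
    if table is not None:
        rng, rel_sd = _noise_rng(cfg)
        if rng is not None:
            noisy = table[_METRIC_COLS].to_numpy(dtype=float)
            noisy *= rng.normal(1.0, rel_sd, size=noisy.shape)
            table = table.copy()
            table[_METRIC_COLS] = noisy
    sync = detect_asynchrony(trace, cfg.effort)
    row: dict = {
        "apparatus_mode": cfg.apparatus.mode,
        "tube_label": cfg.apparatus.tube_label,
        "vent_mode": cfg.ventilator.mode,
        "pressure_support": cfg.ventilator.pressure_support if cfg.ventilator.mode == "psv" else np.nan,
        "rate": cfg.effort.rate,
        "amplitude": amplitude,
        "n_breaths": trace.n_breaths,
        "synchronous": sync.synchronous,
        "asynchrony": sync.classification,
    }
    for m in _METRIC_COLS:
        row[f"{m}_mean"] = float(table[m].mean()) if table is not None else np.nan
        row[f"{m}_sd"] = float(table[m].std(ddof=1)) if table is not None else np.nan
    return row


def run_rate_sweep(
    rates: Sequence[float] = (24.0, 28.0, 32.0, 36.0),
    arms: Optional[dict[str, RunConfig]] = None,
    tube: str = "ETT-3.5",
) -> dict[str, SweepResult]:
    """Rate sweep over the bench arms.

    Default arms: lung simulator alone (``bare``), T-piece through ``tube``,
    and PSV at PS 10 and PS 8 through ``tube``.  Each arm is re-calibrated
    at every rate.  Custom arms may be passed as {label: RunConfig built at
    any rate}; the sweep overrides the rate.
    """
    if len(rates) == 0:
        raise InsufficientDataError("rate sweep needs at least one rate")
    if arms is None:
        arms = {
            "bare": bench_condition("bare"),
            "t_piece": bench_condition("t_piece", tube=tube),
            "psv_ps10": bench_condition("psv", ps=10.0, tube=tube),
            "psv_ps8": bench_condition("psv", ps=8.0, tube=tube),
        }
    results: dict[str, SweepResult] = {}
    for label, base in arms.items():
        rows = []
        for rate in sorted(rates):
            cfg = base.model_copy(deep=True)
            cfg.effort.rate = rate
            log.info("rate sweep: arm=%s rate=%g", label, rate)
            row = run_condition(cfg)
            row["arm"] = label
            rows.append(row)
        results[label] = SweepResult(axis="rate", table=pd.DataFrame(rows),
                                     meta={"arm": label})
    return results


def run_ps_sweep(
    rate: float,
    tube: str = "ETT-3.5",
    ps_levels: Sequence[float] = tuple(range(14, -1, -1)),
    stop_on_asynchrony: bool = True,
    amplitude: Optional[float] = None,
) -> SweepResult:
    """PS sweep (descending) at fixed rate through one tube.

    Mirrors the bench protocol: conditions are run from high to low PS and
    the sweep stops, flagging the level, at the first non-synchronous
    condition.  ``amplitude`` fixes the effort (skipping constant-VT
    calibration); by default every level is re-calibrated.
    """
    levels = sorted(ps_levels, reverse=True)
    rows = []
    stop_level = None
    for ps in levels:
        cfg = bench_condition("psv", rate=rate, ps=float(ps), tube=tube)
        log.info("PS sweep: rate=%g tube=%s PS=%g", rate, tube, ps)
        row = run_condition(cfg, amplitude=amplitude)
        rows.append(row)
        if stop_on_asynchrony and not row["synchronous"]:
            stop_level = float(ps)
            log.warning("PS sweep stopped at PS %g (%s)", ps, row["asynchrony"])
            break
    table = pd.DataFrame(rows)
    return SweepResult(axis="pressure_support", table=table, stop_level=stop_level,
                       meta={"rate": rate, "tube_label": tube})


def fit_wob_line(
    sweep: SweepResult,
    ps_range: tuple[float, float] = (1.0, 14.0),
    metric: str = "wob",
) -> RegressionFit:
    """Least-squares line of mean WOB on PS over the synchronous range.

    PS 0 is always excluded (a PS 0 breath is not pressure-supported; the
    bench excluded it for the same modelling reason).  Coefficients are
    (slope, intercept).
    """
    if sweep.axis != "pressure_support":
        raise InsufficientDataError("fit_wob_line expects a PS sweep")
    t = sweep.table
    lo, hi = min(ps_range), max(ps_range)
    lo = max(lo, 1.0)  # PS 0 never enters the fit
    mask = (t["pressure_support"] >= lo) & (t["pressure_support"] <= hi) & t["synchronous"]
    sub = t[mask]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 synchronous PS levels in [{lo}, {hi}], have {len(sub)}"
        )
    x = sub["pressure_support"].to_numpy(dtype=float)
    y = sub[f"{metric}_mean"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(1, len(sub) - 2)
    return RegressionFit(
        kind="linear",
        coefficients=(float(slope), float(intercept)),
        fit_range=(float(x.min()), float(x.max())),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


@dataclass(frozen=True)
class Intersection:
    ps: float
    extrapolated: bool


def intersect_with_reference(fit: RegressionFit, reference_wob: float) -> Intersection:
    """PS at which a linear WOB-vs-PS fit equals a reference WOB.

    The intersection may fall below the synchronous range; it is then
    flagged as extrapolated, as on the bench where the convergence point
    lay below the last measurable PS level.
    """
    if fit.kind != "linear":
        raise NoIntersectionError("intersection requires a linear fit")
    slope, intercept = fit.coefficients
    if slope == 0.0:
        raise NoIntersectionError("zero-slope fit never meets the reference")
    ps = (reference_wob - intercept) / slope
    lo, hi = fit.fit_range
    return Intersection(ps=float(ps), extrapolated=not (lo <= ps <= hi))


def _logistic(x, lo, hi, x50, steep):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - x50) / steep))


def _exponential(x, a, b, c):
    return a * np.exp(-b * x) + c


def fit_shape_models(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
) -> RegressionFit:
    """Fit a 4-parameter logistic (``sigmoid``) or 3-parameter decaying
    ``exponential`` (y = a*exp(-b*x)+c) by least squares.

    Model choice is the caller's; nothing is selected automatically.
    Needs >= 4 points.  Raises :class:`FitFailureError` on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError(f"{kind} fit needs >= 4 points, have {len(x)}")
    try:
        if kind == "sigmoid":
            p0 = (float(y.min()), float(y.max()), float(np.median(x)),
                  max(1e-3, (x.max() - x.min()) / 4))
            popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
            pred = _logistic(x, *popt)
        elif kind == "exponential":
            span = max(y.max() - y.min(), 1e-9)
            p0 = (span, 1.0 / max(x.max() - x.min(), 1e-9), float(y.min()))
            popt, _ = curve_fit(_exponential, x, y, p0=p0, maxfev=20000)
            pred = _exponential(x, *popt)
        else:
            raise ValueError(f"unknown shape model {kind!r}")
    except RuntimeError as exc:
        raise FitFailureError(f"{kind} fit failed to converge: {exc}") from exc
    n_par = 4 if kind == "sigmoid" else 3
    dof = max(1, len(x) - n_par)
    resid_sd = float(np.sqrt(np.sum((y - pred) ** 2) / dof))
    return RegressionFit(kind=kind, coefficients=tuple(float(p) for p in popt),
                         fit_range=(float(x.min()), float(x.max())),
                         residual_sd=resid_sd)
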