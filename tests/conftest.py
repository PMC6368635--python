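"""Shared fixtures: heavy sweep computations are session-scoped so the
qualitative-surface tests share one set of simulations."""

import hypothesis
import pytest

from sbtsim.config import bench_condition
from sbtsim.experiments import run_ps_sweep, run_rate_sweep
from sbtsim.mechanics import calibrate_constant_vt, simulate_condition

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("deterministic")

RATES = (24.0, 28.0, 32.0, 36.0)


def run_calibrated(setting, rate, ps=10.0, tube="ETT-3.5", n_breaths=None, **tweaks):
    """Calibrate constant-VT effort and simulate one bench condition."""
    cfg = bench_condition(setting, rate=rate, ps=ps, tube=tube)
    for dotted, value in tweaks.items():
        block, name = dotted.split("__")
        setattr(getattr(cfg, block), name, value)
    cfg.effort.amplitude = calibrate_constant_vt(cfg)
    return simulate_condition(cfg, n_breaths=n_breaths), cfg


@pytest.fixture(scope="session")
def ps_sweeps():
    """Full descending PS sweeps (14 -> 0) at 24 and 36/min, both tubes."""
    return {
        (rate, tube): run_ps_sweep(rate=rate, tube=tube)
        for rate in (24.0, 36.0)
        for tube in ("ETT-3.5", "ETT-3.0")
    }


@pytest.fixture(scope="session")
def rate_sweep():
    """Rate sweep over the bench arms (3.5-mm tube for the PSV/T-piece arms,
    plus a 3.0-mm PSV arm for the auto-PEEP comparisons)."""
    arms = {
        "bare": bench_condition("bare"),
        "t_piece": bench_condition("t_piece", tube="ETT-3.5"),
        "psv_ps10": bench_condition("psv", ps=10.0, tube="ETT-3.5"),
        "psv_ps10_30": bench_condition("psv", ps=10.0, tube="ETT-3.0"),
    }
    return run_rate_sweep(rates=RATES, arms=arms)
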