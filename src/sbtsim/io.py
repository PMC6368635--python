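"""Delimited-text readers/writers, trace export, and run manifests.

All tables are tab-separated text with a header row; floats are written with
``repr`` precision so a write/read round-trip is bit-identical.  Only the
dot decimal separator is accepted.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import TableSchemaError
from .mechanics import BreathTrace

TRACE_COLUMNS = ["t", "p_aw", "p_alv", "p_mus", "flow", "volume", "vent_state"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as tab-separated text at full float precision."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, expected_columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a tab-separated table, optionally enforcing a column schema.

    Raises :class:`TableSchemaError` naming missing/unexpected columns, and
    rejects numeric fields using a comma decimal separator.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if expected_columns is not None:
        got, want = list(df.columns), list(expected_columns)
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            raise TableSchemaError(
                f"column mismatch in {path}: missing={missing}, unexpected={extra}, "
                f"order got {got} vs expected {want}"
            )
    for col in df.columns:
        if df[col].dtype == object:
            vals = df[col].dropna().astype(str)
            localized = vals.str.fullmatch(r"-?\d+,\d+")
            if localized.any():
                raise TableSchemaError(
                    f"column {col!r} in {path} uses a localized decimal separator; "
                    "only '.' is accepted"
                )
    return df


def write_trace(trace: BreathTrace, path: str | Path) -> None:
    """Export a breath trace as delimited text (one row per sample)."""
    df = pd.DataFrame({
        "t": trace.t,
        "p_aw": trace.p_aw,
        "p_alv": trace.p_alv,
        "p_mus": trace.p_mus,
        "flow": trace.flow,
        "volume": trace.volume,
        "vent_state": trace.vent_state.astype(int),
    })
    path = Path(path)
    write_table(df, path)
    sidecar = {
        "dt": trace.dt,
        "breath_boundaries": [int(b) for b in trace.breath_boundaries],
        "meta": _jsonable(trace.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> BreathTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    df = read_table(path, expected_columns=TRACE_COLUMNS)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return BreathTrace(
        dt=float(sidecar["dt"]),
        t=df["t"].to_numpy(),
        p_aw=df["p_aw"].to_numpy(),
        p_alv=df["p_alv"].to_numpy(),
        p_mus=df["p_mus"].to_numpy(),
        flow=df["flow"].to_numpy(),
        volume=df["volume"].to_numpy(),
        vent_state=df["vent_state"].to_numpy().astype(np.int8),
        breath_boundaries=np.asarray(sidecar["breath_boundaries"], dtype=np.int64),
        meta=sidecar["meta"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunManifest:
    """Reproducibility record written alongside every output table."""

    config: dict
    numerics: dict
    seed: int | str = "deterministic"
    software_version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    @classmethod
    def for_run(cls, config: RunConfig) -> "RunManifest":
        seed = config.numerics.seed
        return cls(
            config=config.model_dump(),
            numerics=config.numerics.model_dump(),
            seed="deterministic" if seed is None or config.numerics.noise_rel_sd == 0 else seed,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(self.__dict__), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
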