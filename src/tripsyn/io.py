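"""Trace/summary writers, run manifests.

Traces are RFC-4180 CSV with a header row (one row per time sample, columns
keyed by name, so column order is irrelevant on read); manifests are JSON
documents carrying everything needed to bit-reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .synapse import TraceSet

__all__ = ["write_traces", "read_traces", "RunManifest"]


def write_traces(trace: TraceSet, path) -> None:
    """Write a :class:`TraceSet` as CSV with a ``t`` column plus channels."""
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_traces(path) -> TraceSet:
    """Read a trace CSV back into a :class:`TraceSet` (column order agnostic)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if "t" not in df.columns:
        raise ValueError(f"trace file {path} lacks a 't' column")
    t = df["t"].to_numpy(dtype=float)
    channels = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "t"
    }
    return TraceSet(t=t, channels=channels)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Resolved configuration + seeds + output inventory for one run."""

    config: dict
    protocol: dict
    seed: int | None = None
    software_version: str = ""
    python_version: str = field(default_factory=platform.python_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: dict = field(default_factory=dict)

    @classmethod
    def create(cls, config, protocol, seed=None) -> "RunManifest":
        from . import __version__

        return cls(
            config=_jsonable(config),
            protocol=_jsonable(protocol),
            seed=seed,
            software_version=__version__,
        )

    def register_output(self, path) -> None:
        self.outputs[str(path)] = file_checksum(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(_jsonable(asdict(self)), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
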