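"""Stimulus protocols: single pulse, paired pulse, random-interval trains.

A protocol is an ordered list of impulsive :class:`~tripsyn.cleft.ReleaseEvent`
objects plus metadata.  Random-interval trains (RITs) draw exponential
inter-event intervals at a stated mean rate from a seeded generator, with a
1 ms floor so release kernels never coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cleft import ReleaseEvent

__all__ = ["StimulusProtocol", "single_pulse", "paired_pulse", "generate_rit"]

#: Minimum inter-event interval (ms) for random trains.
MIN_INTERVAL_MS = 1.0


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered release-event sequence with protocol metadata."""

    kind: str
    events: tuple
    intervals: tuple = ()
    mean_rate: float | None = None
    duration: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("single_pulse", "paired_pulse", "rit", "empty"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        t0s = [ev.t0 for ev in self.events]
        if any(b < a for a, b in zip(t0s, t0s[1:])):
            raise ValueError("events must be sorted by t0")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_times(self) -> np.ndarray:
        return np.array([ev.t0 for ev in self.events])


def single_pulse(t0: float = 1.0, Q: float = 3000.0) -> StimulusProtocol:
    """A single vesicular release at ``t0`` ms."""
    return StimulusProtocol(kind="single_pulse", events=(ReleaseEvent(t0, Q),))


def paired_pulse(interval: float, t0: float = 1.0, Q: float = 3000.0) -> StimulusProtocol:
    """Two releases separated by ``interval`` ms."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    events = (ReleaseEvent(t0, Q), ReleaseEvent(t0 + interval, Q))
    return StimulusProtocol(kind="paired_pulse", events=events, intervals=(interval,))


def generate_rit(
    mean_rate: float,
    duration: float,
    seed: int,
    Q: float = 3000.0,
    t_start: float = 0.0,
) -> StimulusProtocol:
    """Random-interval train of releases at ``mean_rate`` Hz over ``duration`` ms.

    Inter-event intervals are exponential with mean 1000/mean_rate ms,
    floored at 1 ms; the first interval is measured from ``t_start``.
    Reproducible per seed.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    mean_ms = 1000.0 / mean_rate
    times = []
    t = t_start
    while True:
        t = t + max(MIN_INTERVAL_MS, rng.exponential(mean_ms))
        if t > t_start + duration:
            break
        times.append(t)
    events = tuple(ReleaseEvent(t0, Q) for t0 in times)
    return StimulusProtocol(
        kind="rit", events=events, mean_rate=mean_rate, duration=duration, seed=seed
    )
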