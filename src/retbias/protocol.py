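"""Agonist-application protocols for single-cell recordings.

A protocol lists when each agonist is superfused over the cell.  Events must
not overlap; between events the cell sees buffer only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import ProtocolError

__all__ = ["ApplicationEvent", "ApplicationProtocol"]


@dataclass(frozen=True)
class ApplicationEvent:
    """One agonist application: ``agonist_id`` at ``concentration`` (mol/L)
    from ``t_start`` to ``t_end`` (seconds)."""

    agonist_id: str
    concentration: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ProtocolError(
                f"concentration must be > 0 for {self.agonist_id!r}, "
                f"got {self.concentration}"
            )
        if not self.t_start < self.t_end:
            raise ProtocolError(
                f"event {self.agonist_id!r}: t_start ({self.t_start}) must be "
                f"< t_end ({self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ApplicationProtocol:
    """Ordered, non-overlapping agonist applications over one recording.

    Parameters
    ----------
    events:
        Applications in chronological order.
    total_duration:
        Recording length in seconds; every event must end at or before it.
    sampling_rate:
        Acquisition rate in Hz (default 2).
    """

    events: tuple[ApplicationEvent, ...]
    total_duration: float
    sampling_rate: float = 2.0

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, ApplicationEvent) else ApplicationEvent(*e)
            for e in self.events
        )
        object.__setattr__(self, "events", events)
        if self.total_duration <= 0:
            raise ProtocolError("total_duration must be > 0")
        if self.sampling_rate <= 0:
            raise ProtocolError("sampling_rate must be > 0")
        prev_end = -float("inf")
        for ev in events:
            if ev.t_start < prev_end:
                raise ProtocolError(
                    f"overlapping events: {ev.agonist_id!r} starts at "
                    f"{ev.t_start}s before previous event ends at {prev_end}s"
                )
            if ev.t_end > self.total_duration:
                raise ProtocolError(
                    f"event {ev.agonist_id!r} ends at {ev.t_end}s, after "
                    f"total_duration {self.total_duration}s"
                )
            prev_end = ev.t_end

    def __iter__(self) -> Iterator[ApplicationEvent]:
        return iter(self.events)

    @property
    def agonists(self) -> list[str]:
        """Unique agonist ids in order of first application."""
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.agonist_id, None)
        return list(seen)

    def time_vector(self):
        import numpy as np

        n = int(round(self.total_duration * self.sampling_rate)) + 1
        return np.arange(n) / self.sampling_rate

    def in_any_event(self, time):
        """Boolean mask of samples that fall inside any application window."""
        import numpy as np

        time = np.asarray(time, dtype=float)
        mask = np.zeros(time.shape, dtype=bool)
        for ev in self.events:
            mask |= (time >= ev.t_start) & (time < ev.t_end)
        return mask

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "agonist_id": e.agonist_id,
                    "concentration_M": e.concentration,
                    "t_start_s": e.t_start,
                    "t_end_s": e.t_end,
                }
                for e in self.events
            ],
            "total_duration_s": self.total_duration,
            "sampling_rate_hz": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApplicationProtocol":
        events = tuple(
            ApplicationEvent(
                agonist_id=e["agonist_id"],
                concentration=e["concentration_M"],
                t_start=e["t_start_s"],
                t_end=e["t_end_s"],
            )
            for e in d["events"]
        )
        return cls(
            events=events,
            total_duration=d["total_duration_s"],
            sampling_rate=d.get("sampling_rate_hz", 2.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ApplicationProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))
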