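"""Injectable clocks.

Decision timestamps drive the "most recent decision wins" working view and
the release dates stamped into glossary files.  The engine therefore takes
its notion of time from a pluggable clock object: the default reads the
system clock, while :class:`TickClock` produces a deterministic, strictly
increasing sequence so replays and golden-file exports are reproducible.
"""
from __future__ import annotations

from datetime import datetime, timedelta, timezone

EPOCH = datetime(2000, 1, 1, tzinfo=timezone.utc)


class SystemClock:
    """Wall-clock time in UTC."""

    kind = "system"

    def __call__(self) -> datetime:
        return datetime.now(timezone.utc)

    def to_dict(self) -> dict:
        return {"kind": "system"}


class TickClock:
    """Deterministic clock advancing by a fixed step on every call.

    Parameters
    ----------
    start:
        First instant returned (UTC).  Defaults to 2000-01-01T00:00:00Z.
    step_seconds:
        Seconds between consecutive calls.
    count:
        Number of ticks already consumed; lets a persisted workspace resume
        its clock so per-user timestamps stay non-decreasing across runs.
    """

    kind = "tick"

    def __init__(self, start: datetime = EPOCH, step_seconds: float = 1.0,
                 count: int = 0):
        if start.tzinfo is None:
            start = start.replace(tzinfo=timezone.utc)
        self.start = start
        self.step_seconds = step_seconds
        self.count = count

    def __call__(self) -> datetime:
        t = self.start + timedelta(seconds=self.step_seconds * self.count)
        self.count += 1
        return t

    def to_dict(self) -> dict:
        return {"kind": "tick", "start": self.start.isoformat(),
                "step_seconds": self.step_seconds, "count": self.count}


def clock_from_dict(d: dict | None):
    if not d or d.get("kind") == "system":
        return SystemClock()
    return TickClock(start=datetime.fromisoformat(d["start"]),
                     step_seconds=d.get("step_seconds", 1.0),
                     count=d.get("count", 0))
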