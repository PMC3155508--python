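"""Injectable clocks.

All write operations stamp UTC ISO-8601 timestamps.  A :class:`SimClock`
makes fixture generation byte-reproducible and lets federation tests move
time forward past a cache or token TTL without sleeping.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone


def isoformat(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).replace(microsecond=0).isoformat().replace("+00:00", "Z")


class Clock:
    """Wall-clock time (UTC)."""

    def now(self) -> datetime:
        return datetime.now(timezone.utc)


class SimClock(Clock):
    """Deterministic clock: each call to :meth:`now` advances by ``step`` seconds.

    ``advance`` jumps forward explicitly (e.g. to expire a 24 h cache entry).
    """

    def __init__(self, start: datetime | None = None, step: float = 1.0):
        if start is None:
            start = datetime(2011, 7, 14, tzinfo=timezone.utc)
        if start.tzinfo is None:
            start = start.replace(tzinfo=timezone.utc)
        self._t = start
        self.step = step

    def now(self) -> datetime:
        t = self._t
        self._t = t + timedelta(seconds=self.step)
        return t

    def peek(self) -> datetime:
        return self._t

    def advance(self, seconds: float) -> None:
        self._t += timedelta(seconds=seconds)
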