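"""Injectable clocks.

Timestamps on score records come from a clock object so that simulations
and tests are deterministic: :class:`FixedClock` hands out a fixed start
time advanced by a constant step per call, while :class:`SystemClock`
reads wall time.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

__all__ = ["SystemClock", "FixedClock"]


class SystemClock:
    def now(self) -> str:
        """Current UTC time, ISO-8601 with seconds precision."""
        return datetime.now(timezone.utc).isoformat(timespec="seconds")


class FixedClock:
    """Deterministic clock: starts at ``start`` and advances ``step_seconds``
    on every call."""

    def __init__(self, start: str = "2013-05-01T09:00:00+00:00",
                 step_seconds: int = 60) -> None:
        self._t = datetime.fromisoformat(start)
        self._step = timedelta(seconds=step_seconds)

    def now(self) -> str:
        t = self._t
        self._t = t + self._step
        return t.isoformat(timespec="seconds")
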