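"""Planted state schedules for the wild type and the Ser-67 mutants.

Each schedule lists contiguous (state, start, end) segments in ns and is the
ground truth the segmentation stage must recover from a generated
trajectory.  The packaged values:

* WT   — I 0–40, II 40–240, III 240–260, IV 260–280, released at 280 ns
  (steps 40 / 200 / 20 / 20 ns).
* S67Q — Step 2 stretched to 300 ns, the other steps unchanged: release at
  380 ns.  S67Y behaves like S67Q (π-cation trapping in Step 2 gives the
  same 300 ns dwell).
* S67V — State II skipped; I→III takes 100 ns, Step 3 somewhat longer than
  wild type, total 200 ns (split 100 / 75 / 25 is a package choice inside
  the fixed total).
* S67P — State II skipped; I→III 100 ns, Steps 3 and 4 also shortened,
  total 150 ns (split 100 / 30 / 20 inside the fixed total).

Every schedule ends with 20 ns of post-release frames so the released state
is observable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from ..errors import ScheduleError, UnknownVariantError
from ..states import STATE_NAMES

__all__ = ["StateSchedule", "variant_schedule", "VARIANTS"]

_ORDER = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class StateSchedule:
    """Ordered, contiguous (state, start_ns, end_ns) segments from t = 0."""

    variant: str
    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScheduleError("schedule has no segments")
        prev_end = 0.0
        prev_rank = -1
        for state, start, end in self.segments:
            if state not in _ORDER or state == "none":
                raise ScheduleError(f"unknown state {state!r}")
            if start != prev_end:
                raise ScheduleError(
                    f"segments must be contiguous from 0: segment {state!r} "
                    f"starts at {start}, expected {prev_end}")
            if end <= start:
                raise ScheduleError(f"segment {state!r} has non-positive span")
            rank = _ORDER[state]
            if rank <= prev_rank:
                raise ScheduleError("states must appear in increasing order")
            prev_rank, prev_end = rank, end
        if self.segments[-1][0] not in ("V", "released"):
            raise ScheduleError("final segment must be State V or released")

    @property
    def total_ns(self) -> float:
        return self.segments[-1][2]

    @property
    def release_time_ns(self) -> float | None:
        """Start of the first V or released segment (the planted release)."""
        for state, start, _ in self.segments:
            if state in ("V", "released"):
                return start
        return None

    def state_at(self, t: float) -> str:
        """Scheduled state for time t (segments are [start, end))."""
        for state, start, end in self.segments:
            if start <= t < end:
                return state
        if t == self.total_ns:
            return self.segments[-1][0]
        raise ScheduleError(f"time {t} ns outside schedule [0, {self.total_ns}]")

    def to_json(self, path=None) -> str:
        payload = json.dumps({"variant": self.variant,
                              "segments": [list(s) for s in self.segments]},
                             indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _schedule(variant, *segments) -> StateSchedule:
    return StateSchedule(variant=variant, segments=tuple(segments))


_SCHEDULES = {
    "WT": _schedule("WT",
                    ("I", 0.0, 40.0), ("II", 40.0, 240.0),
                    ("III", 240.0, 260.0), ("IV", 260.0, 280.0),
                    ("released", 280.0, 300.0)),
    "S67Q": _schedule("S67Q",
                      ("I", 0.0, 40.0), ("II", 40.0, 340.0),
                      ("III", 340.0, 360.0), ("IV", 360.0, 380.0),
                      ("released", 380.0, 400.0)),
    "S67V": _schedule("S67V",
                      ("I", 0.0, 100.0), ("III", 100.0, 175.0),
                      ("IV", 175.0, 200.0), ("released", 200.0, 220.0)),
    "S67P": _schedule("S67P",
                      ("I", 0.0, 100.0), ("III", 100.0, 130.0),
                      ("IV", 130.0, 150.0), ("released", 150.0, 170.0)),
}
_SCHEDULES["S67Y"] = _schedule("S67Y", *(
    (s, a, b) for s, a, b in _SCHEDULES["S67Q"].segments))

VARIANTS = tuple(_SCHEDULES)


def variant_schedule(name: str) -> StateSchedule:
    """The packaged schedule for one variant (WT, S67Q, S67Y, S67V, S67P)."""
    try:
        return _SCHEDULES[name]
    except KeyError:
        raise UnknownVariantError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANTS)}"
        ) from None
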