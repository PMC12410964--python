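"""Light schedules and Zeitgeber time.

A :class:`LightSchedule` is an ordered list of contiguous phases covering
the analysis window, each of kind ``"L"`` (lights on), ``"D"`` (lights
off), or — for free-running constant-darkness experiments — the subjective
equivalents ``"subjective_day"`` / ``"subjective_night"``.  Zeitgeber time
(ZT) is hours since the lights-on reference ``zt0``, modulo 24; ZT0 is
lights-on and ZT12 lights-off in a standard 12:12 LD entrainment cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigError, ScheduleRangeError

PhaseKind = Literal["L", "D", "subjective_day", "subjective_night"]

#: phases counted as "day" when splitting metrics into day/night totals
DAY_KINDS = frozenset({"L", "subjective_day"})
NIGHT_KINDS = frozenset({"D", "subjective_night"})


@dataclass(frozen=True)
class Phase:
    kind: PhaseKind
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ConfigError(f"phase {self.kind} has non-positive duration")


@dataclass(frozen=True)
class LightSchedule:
    """Contiguous light/dark phases plus the lights-on (ZT0) reference time."""

    phases: tuple[Phase, ...]
    zt0: float = 0.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ConfigError("schedule must contain at least one phase")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ConfigError("schedule phases must be contiguous and ordered")

    # -- constructors ------------------------------------------------------

    @classmethod
    def ld(cls, n_days: int, day_h: float = 12.0, night_h: float = 12.0,
           start_s: float = 0.0, zt0: float | None = None) -> "LightSchedule":
        """Standard LD entrainment: ``n_days`` cycles of L then D, starting at lights-on."""
        phases = []
        t = start_s
        for _ in range(n_days):
            phases.append(Phase("L", t, t + day_h * 3600.0))
            t += day_h * 3600.0
            phases.append(Phase("D", t, t + night_h * 3600.0))
            t += night_h * 3600.0
        return cls(tuple(phases), zt0=start_s if zt0 is None else zt0)

    @classmethod
    def dd(cls, n_days: int, day_h: float = 12.0, night_h: float = 12.0,
           start_s: float = 0.0, zt0: float | None = None) -> "LightSchedule":
        """Constant darkness: subjective day/night phases on the entrained cycle."""
        phases = []
        t = start_s
        for _ in range(n_days):
            phases.append(Phase("subjective_day", t, t + day_h * 3600.0))
            t += day_h * 3600.0
            phases.append(Phase("subjective_night", t, t + night_h * 3600.0))
            t += night_h * 3600.0
        return cls(tuple(phases), zt0=start_s if zt0 is None else zt0)

    # -- queries -----------------------------------------------------------

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    def phase_at(self, t: float) -> Phase:
        """Phase containing experiment time ``t`` (half-open intervals [start, end))."""
        if t < self.start_s or t >= self.end_s:
            raise ScheduleRangeError(
                f"t={t} s outside schedule coverage [{self.start_s}, {self.end_s})"
            )
        # phases are few; linear scan is fine and unambiguous at boundaries
        for ph in self.phases:
            if ph.start_s <= t < ph.end_s:
                return ph
        raise ScheduleRangeError(f"t={t} s not covered by any phase")  # pragma: no cover

    def zt_of(self, t: float) -> float:
        """Zeitgeber time in hours, in [0, 24)."""
        return ((t - self.zt0) / 3600.0) % 24.0

    def kind_at(self, t) -> np.ndarray:
        """Vectorised phase-kind lookup; returns an object array of kind strings."""
        t = np.asarray(t, dtype=float)
        edges = np.array([ph.start_s for ph in self.phases] + [self.end_s])
        if np.any(t < edges[0]) or np.any(t >= edges[-1]):
            raise ScheduleRangeError("some times lie outside schedule coverage")
        idx = np.searchsorted(edges, t, side="right") - 1
        kinds = np.array([ph.kind for ph in self.phases], dtype=object)
        return kinds[idx]

    def is_day(self, t) -> np.ndarray:
        """Boolean mask: True where ``t`` falls in an L or subjective-day phase."""
        kinds = self.kind_at(t)
        return np.isin(kinds, list(DAY_KINDS))

    def light_transitions(self) -> list[float]:
        """Times of actual L<->D light switches (subjective transitions excluded).

        These are the moments that trigger startle activity peaks.
        """
        out = []
        for a, b in zip(self.phases, self.phases[1:]):
            if {a.kind, b.kind} == {"L", "D"}:
                out.append(b.start_s)
        return out

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "zt0": self.zt0,
            "phases": [
                {"kind": ph.kind, "hours": (ph.end_s - ph.start_s) / 3600.0}
                for ph in self.phases
            ],
            "start_s": self.start_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        t = float(d.get("start_s", 0.0))
        phases = []
        for entry in d["phases"]:
            dur = float(entry["hours"]) * 3600.0
            phases.append(Phase(entry["kind"], t, t + dur))
            t += dur
        return cls(tuple(phases), zt0=float(d.get("zt0", phases[0].start_s)))


def split_day_night(schedule: LightSchedule) -> tuple[list[Phase], list[Phase]]:
    """Partition phases into (day-like, night-like) lists."""
    day = [p for p in schedule.phases if p.kind in DAY_KINDS]
    night = [p for p in schedule.phases if p.kind in NIGHT_KINDS]
    return day, night
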