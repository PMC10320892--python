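"""Treatment-schedule simulation and comparison.

Declarative future schedules use the clinical "qNd" nomenclature (q7d =
every seven days).  A schedule expands to session events, the individual's
severity trajectory is simulated from the severe baseline over the horizon
(typically 180 days of treatment followed by 180 days without), and summary
metrics support ranking candidate plans against a response threshold.

The default threshold 0.625 is the top of the sub-moderate band on the
two-item severity scale: item averages of 2 ("mild") and 3 ("moderate")
map to severities 0.5 and 0.75, so their midpoint separates mild-to-
moderate from moderate-to-severe symptom levels.  It is configurable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .model import (ServiceType, SessionEvent, StructuralParameters,
                    ValidationError, simulate_trajectory)

__all__ = [
    "ScheduleItem",
    "TreatmentSchedule",
    "PlanMetrics",
    "parse_schedule",
    "expand_schedule",
    "simulate_plan",
    "compare_plans",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.625


@dataclass(frozen=True)
class ScheduleItem:
    """One periodic block: ``service`` every ``interval`` days on [start, end)."""

    service: ServiceType
    interval: float
    start: float
    end: float

    def __post_init__(self):
        if not (math.isfinite(self.interval) and self.interval > 0):
            raise ValidationError(f"interval must be > 0, got {self.interval}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"need 0 <= start < end, got start={self.start}, end={self.end}")


@dataclass(frozen=True)
class TreatmentSchedule:
    """A declarative future session plan over a simulation horizon (days)."""

    items: tuple[ScheduleItem, ...]
    horizon: float

    def __init__(self, items, horizon: float):
        items = tuple(items)
        if not (math.isfinite(horizon) and horizon > 0):
            raise ValidationError(f"horizon must be > 0, got {horizon}")
        for it in items:
            if it.end > horizon:
                raise ValidationError(
                    f"schedule item ends at {it.end} beyond horizon {horizon}")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "horizon", float(horizon))


@dataclass(frozen=True)
class PlanMetrics:
    """Summary of one simulated plan against a response threshold."""

    min_severity: float
    time_below_threshold: float  # days spent strictly below the threshold
    relapse_time: float | None   # first grid time after the last session with
                                 # severity >= threshold; None if never
    final_severity: float
    n_sessions: int

    def to_dict(self) -> dict:
        return {"min_severity": self.min_severity,
                "time_below_threshold": self.time_below_threshold,
                "relapse_time": self.relapse_time,
                "final_severity": self.final_severity,
                "n_sessions": self.n_sessions}


_ITEM_RE = re.compile(
    r"^(?P<service>[a-z]+):q(?P<interval>\d+(?:\.\d+)?)d"
    r"(?::(?P<start>\d+(?:\.\d+)?)-(?P<end>\d+(?:\.\d+)?))?$")


def parse_schedule(text: str, horizon: float,
                   default_end: float | None = None) -> TreatmentSchedule:
    """Parse the schedule mini-language.

    Comma-separated items ``<service>:q<N>d[:<start>-<end>]``, e.g.
    ``"therapy:q14d:0-180,coaching:q30d:0-180"``.  An item without an
    explicit window runs from day 0 to ``default_end`` (the horizon unless
    given otherwise).
    """
    items = []
    for chunk in [c.strip() for c in text.split(",") if c.strip()]:
        m = _ITEM_RE.match(chunk.lower())
        if not m:
            raise ValidationError(
                f"cannot parse schedule item {chunk!r}; expected "
                f"'<service>:q<N>d[:<start>-<end>]'")
        service = ServiceType.from_string(m.group("service"))
        start = float(m.group("start")) if m.group("start") else 0.0
        end = (float(m.group("end")) if m.group("end")
               else float(default_end if default_end is not None else horizon))
        items.append(ScheduleItem(service=service,
                                  interval=float(m.group("interval")),
                                  start=start, end=end))
    return TreatmentSchedule(items, horizon)


def expand_schedule(schedule: TreatmentSchedule) -> list[SessionEvent]:
    """Expand every item to events at start, start+interval, ... < end."""
    events: list[SessionEvent] = []
    for it in schedule.items:
        n = int(math.ceil((it.end - it.start) / it.interval - 1e-12))
        for k in range(max(n, 0)):
            t = it.start + k * it.interval
            if t < it.end - 1e-12:
                events.append(SessionEvent(float(t), it.service))
    return sorted(events, key=lambda e: e.time)


def simulate_plan(indiv: StructuralParameters, schedule: TreatmentSchedule,
                  threshold: float = DEFAULT_THRESHOLD,
                  grid_step: float = 0.25,
                  inhibition_fn=None) -> tuple[np.ndarray, np.ndarray, PlanMetrics]:
    """Simulate a plan from the severe baseline and compute its metrics.

    Returns (grid, severities, metrics).  ``time_below_threshold`` counts
    grid intervals with severity strictly below the threshold;
    ``relapse_time`` is the first grid time strictly after the final planned
    session at which severity is at or above the threshold (time 0 for an
    untreated severe patient), or None if no such time exists within the
    horizon.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    if grid_step <= 0:
        raise ValidationError(f"grid_step must be > 0, got {grid_step}")
    events = expand_schedule(schedule)
    n_steps = int(round(schedule.horizon / grid_step))
    grid = np.linspace(0.0, n_steps * grid_step, n_steps + 1)
    dep = simulate_trajectory(events, indiv, grid, dep0=1.0,
                              inhibition_fn=inhibition_fn)
    below = dep < threshold
    t_last = max((e.time for e in events), default=0.0)
    after = grid > t_last if events else grid >= 0.0
    relapse_idx = np.flatnonzero(after & (dep >= threshold))
    metrics = PlanMetrics(
        min_severity=float(dep.min()),
        time_below_threshold=float(np.count_nonzero(below) * grid_step),
        relapse_time=float(grid[relapse_idx[0]]) if relapse_idx.size else None,
        final_severity=float(dep[-1]),
        n_sessions=len(events))
    return grid, dep, metrics


def _rank_key(name: str, m: PlanMetrics):
    # no relapse ranks best; then later relapse; then more time in response;
    # ties broken by fewer sessions, then name for full determinism
    return ((0,) if m.relapse_time is None else (1, -m.relapse_time),
            -m.time_below_threshold, m.n_sessions, name)


def compare_plans(indiv: StructuralParameters,
                  schedules: dict[str, TreatmentSchedule],
                  threshold: float = DEFAULT_THRESHOLD,
                  grid_step: float = 0.25) -> list[tuple[str, PlanMetrics]]:
    """Simulate named candidate plans and return them best-first."""
    if not schedules:
        raise ValidationError("need at least one schedule to compare")
    results = {name: simulate_plan(indiv, sched, threshold, grid_step)[2]
               for name, sched in schedules.items()}
    return sorted(results.items(), key=lambda kv: _rank_key(kv[0], kv[1]))
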