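"""Structural indirect-response model of depressive symptom severity.

Each mental-healthcare session (coaching, therapy or psychiatry) deposits a
unit bolus of latent "therapeutic mass" into a service-specific compartment
that decays with a first-order rate constant ``k_out``.  The combined mass
TRT(t) inhibits symptom production through a capacity-limited (Hill-type)
function with maximum effect fixed at 1, so severity ``Dep`` follows

    dDep/dt = r * (1 - TRT(t) / (TRT(t) + S50)) - r * Dep,   Dep(0) = 1,

where the shared turnover rate ``r`` caps severity at the severe level
(Dep = 1) in the absence of treatment.  Severity is the average of the two
DSM-5 Level 1 depression items normalised to [0, 1].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import dep_profile

__all__ = [
    "ValidationError",
    "SolverError",
    "ServiceType",
    "SessionEvent",
    "SeverityObservation",
    "PatientRecord",
    "StructuralParameters",
    "severity_from_items",
    "treatment_mass",
    "inhibition",
    "simulate_trajectory",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain contract."""


class SolverError(RuntimeError):
    """Raised when trajectory integration fails to converge."""


class ServiceType(enum.Enum):
    """The three mental-healthcare service types carrying a session bolus."""

    COACHING = "coaching"
    THERAPY = "therapy"
    PSYCHIATRY = "psychiatry"

    @classmethod
    def from_string(cls, name: str) -> "ServiceType":
        try:
            return cls(name.strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown service type {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    @property
    def index(self) -> int:
        """Stable compartment index: coaching=0, therapy=1, psychiatry=2."""
        return _SERVICE_INDEX[self]


_SERVICE_INDEX = {
    ServiceType.COACHING: 0,
    ServiceType.THERAPY: 1,
    ServiceType.PSYCHIATRY: 2,
}


@dataclass(frozen=True, order=True)
class SessionEvent:
    """One treatment session: a unit bolus at ``time`` days since baseline."""

    time: float
    service: ServiceType = field(compare=False)

    def __post_init__(self):
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"session time must be finite and >= 0, got {self.time}")
        if not isinstance(self.service, ServiceType):
            raise ValidationError(f"service must be a ServiceType, got {self.service!r}")


@dataclass(frozen=True, order=True)
class SeverityObservation:
    """A DSM-L1 two-item severity report in [0, 1] at ``time`` days."""

    time: float
    severity: float

    def __post_init__(self):
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"observation time must be finite and >= 0, got {self.time}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValidationError(f"severity must lie in [0, 1], got {self.severity}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's session events and severity observations.

    Times are real-valued days on a common per-patient clock with baseline
    at 0.  A record is *inclusion eligible* when it has at least two
    severity reports with at least one session (of any kind) strictly
    between a pair of them.
    """

    id: str
    events: tuple[SessionEvent, ...]
    observations: tuple[SeverityObservation, ...]

    def __init__(self, id: str, events: Iterable[SessionEvent],
                 observations: Iterable[SeverityObservation]):
        object.__setattr__(self, "id", str(id))
        ev = tuple(events)
        ob = tuple(observations)
        for name, coll in (("events", ev), ("observations", ob)):
            times = [x.time for x in coll]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValidationError(
                    f"patient {id!r}: {name} times must be non-decreasing"
                )
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "observations", ob)

    @property
    def is_inclusion_eligible(self) -> bool:
        if len(self.observations) < 2:
            return False
        t_first = self.observations[0].time
        t_last = self.observations[-1].time
        return any(t_first < e.time < t_last for e in self.events)

    @property
    def n_post_baseline(self) -> int:
        """Observations at time > 0 (baseline reports carry zero residual)."""
        return sum(1 for o in self.observations if o.time > 0)

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted event times and compartment indices as flat arrays."""
        t = np.array([e.time for e in self.events], dtype=np.float64)
        s = np.array([e.service.index for e in self.events], dtype=np.int64)
        return t, s


@dataclass(frozen=True)
class StructuralParameters:
    """The five per-individual constants of the structural model.

    k_out_* are first-order elimination rates (1/day) of the three latent
    service compartments; ``s50`` is the treatment mass giving half-maximal
    inhibition of symptom production (latent-mass units); ``r`` is the
    shared symptom production/elimination turnover rate (1/day).
    """

    k_out_coaching: float
    k_out_therapy: float
    k_out_psychiatry: float
    s50: float
    r: float

    PARAM_NAMES = ("k_out_coaching", "k_out_therapy", "k_out_psychiatry", "s50", "r")

    def __post_init__(self):
        for name in self.PARAM_NAMES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")

    def k_out(self, service: ServiceType) -> float:
        return self.as_array()[service.index]

    def as_array(self) -> np.ndarray:
        """Vector (k_out_coaching, k_out_therapy, k_out_psychiatry, s50, r)."""
        return np.array([self.k_out_coaching, self.k_out_therapy,
                         self.k_out_psychiatry, self.s50, self.r])

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "StructuralParameters":
        return cls(*(float(v) for v in vec))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in self.PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralParameters":
        return cls(**{n: float(d[n]) for n in cls.PARAM_NAMES})


def severity_from_items(anhedonia: int, depressed_mood: int) -> float:
    """Two-item DSM-L1 severity: mean of the items divided by the max score 4.

    Both items are 5-point Likert responses in {0..4}; the result lies on a
    0.125 grid in [0, 1].
    """
    for name, v in (("anhedonia", anhedonia), ("depressed_mood", depressed_mood)):
        if v not in (0, 1, 2, 3, 4):
            raise ValidationError(f"{name} must be an integer in 0..4, got {v!r}")
    return (anhedonia + depressed_mood) / 2.0 / 4.0


def treatment_mass(events: Sequence[SessionEvent], params: StructuralParameters,
                   t: float) -> float:
    """Combined latent treatment mass TRT(t).

    Superposition of unit boluses: each session at time t_e <= t contributes
    exp(-k_out,service * (t - t_e)).
    """
    t = float(t)
    if not math.isfinite(t) or t < 0:
        raise ValidationError(f"time must be finite and >= 0, got {t}")
    kv = params.as_array()[:3]
    total = 0.0
    for e in events:
        if e.time <= t:
            total += math.exp(-kv[e.service.index] * (t - e.time))
    return total


def inhibition(trt: float, s50: float) -> float:
    """Fractional inhibition of symptom production: trt / (trt + s50).

    A Hill function with maximum effect fixed at 1, so inhibition is bounded
    strictly below 1 for finite mass.
    """
    if not (math.isfinite(s50) and s50 > 0):
        raise ValidationError(f"s50 must be finite and > 0, got {s50}")
    if not (math.isfinite(trt) and trt >= 0):
        raise ValidationError(f"treatment mass must be finite and >= 0, got {trt}")
    return trt / (trt + s50)


def _validate_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=np.float64)
    if g.ndim != 1 or g.size == 0:
        raise ValidationError("grid must be a non-empty 1-D sequence of times")
    if np.any(~np.isfinite(g)) or np.any(g < 0):
        raise ValidationError("grid times must be finite and >= 0")
    if np.any(np.diff(g) < 0):
        raise ValidationError("grid must be sorted in non-decreasing order")
    return g


def simulate_trajectory(events: Sequence[SessionEvent],
                        params: StructuralParameters,
                        grid: Sequence[float],
                        dep0: float = 1.0,
                        method: str = "rk45",
                        inhibition_fn: Callable[[float], float] | None = None,
                        ) -> np.ndarray:
    """Severity trajectory Dep(t) on ``grid`` for a given session history.

    Parameters
    ----------
    events
        Session events; need not be sorted (they are sorted internally).
    params
        Structural constants of the individual.
    grid
        Sorted, non-negative evaluation times (days).
    dep0
        Severity at time 0 (default 1: cohort screened in severe).
    method
        ``"rk45"`` — adaptive explicit Runge–Kutta (rtol=atol=1e-8) with
        integration restarts at every event time, TRT evaluated analytically.
        ``"exact"`` — exponential integrating-factor update per inter-event
        segment with fixed Gauss–Legendre quadrature (the fast path used by
        estimation).  Both agree to well below 1e-6.
    inhibition_fn
        Test hook: a function of time replacing the Hill inhibition term
        entirely (TRT is then ignored).  Forces the RK path.

    Returns
    -------
    numpy.ndarray of severities on ``grid``, each in (0, 1] up to solver
    tolerance.
    """
    g = _validate_grid(grid)
    if not (0.0 < dep0 <= 1.0):
        raise ValidationError(f"dep0 must lie in (0, 1], got {dep0}")
    ev = sorted(events, key=lambda e: e.time)
    if inhibition_fn is not None:
        return _simulate_rk(ev, params, g, dep0, inhibition_fn)
    if method == "exact":
        ev_t = np.array([e.time for e in ev], dtype=np.float64)
        ev_s = np.array([e.service.index for e in ev], dtype=np.int64)
        return dep_profile(g, ev_t, ev_s, params.as_array()[:3],
                           params.s50, params.r, dep0)
    if method == "rk45":
        return _simulate_rk(ev, params, g, dep0, None)
    raise ValidationError(f"unknown method {method!r}; expected 'rk45' or 'exact'")


def _simulate_rk(events: list[SessionEvent], params: StructuralParameters,
                 grid: np.ndarray, dep0: float,
                 inhibition_fn: Callable[[float], float] | None) -> np.ndarray:
    """Adaptive RK45 integration with mandatory restarts at event times.

    TRT inside each inter-event segment is the analytic decay of the three
    compartment masses frozen at the segment start; boluses are applied at
    segment boundaries, so the right-hand side is smooth on every segment.
    """
    kv = params.as_array()[:3]
    s50, r = params.s50, params.r
    ev_t = np.array([e.time for e in events])
    ev_s = np.array([e.service.index for e in events], dtype=int)

    t_end = float(grid[-1])
    stops = np.unique(np.concatenate([[0.0], ev_t[ev_t <= t_end], [t_end]]))
    out = np.empty_like(grid, dtype=np.float64)
    out[grid == 0.0] = dep0

    masses = np.zeros(3)
    dep = dep0
    for a, b in zip(stops[:-1], stops[1:]):
        # boluses landing exactly at the segment start
        for s in ev_s[ev_t == a]:
            masses[s] += 1.0

        if inhibition_fn is None:
            m0 = masses.copy()

            def rhs(t, y, _a=a, _m=m0):
                trt = float(np.sum(_m * np.exp(-kv * (t - _a))))
                return [r * (1.0 - trt / (trt + s50)) - r * y[0]]
        else:
            def rhs(t, y):
                return [r * (1.0 - inhibition_fn(t)) - r * y[0]]

        inside = (grid > a) & (grid <= b)
        t_eval = np.unique(np.concatenate([grid[inside], [b]]))
        sol = solve_ivp(rhs, (a, b), [dep], method="RK45",
                        t_eval=t_eval, rtol=1e-8, atol=1e-8)
        if not sol.success:
            raise SolverError(
                f"trajectory integration failed on [{a}, {b}]: {sol.message}"
            )
        out[inside] = np.interp(grid[inside], sol.t, sol.y[0])
        dep = float(sol.y[0, -1])
        masses *= np.exp(-kv * (b - a))

    # grid points beyond handled above; points at 0 already set
    return out
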