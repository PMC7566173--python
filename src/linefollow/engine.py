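"""A minimal production-system interpreter with ACT-R-style timing.

Provides the pieces a cognitive agent is assembled from:

* productions with learned utilities, matched against a buffer snapshot;
* conflict resolution as noisy-max over utilities (logistic noise of scale
  ``s``; with ``s = 0``, strict argmax with uniform random tie-break) — the
  sampled-selection realization of the softmax choice rule
  ``P(i) = exp(U_i / (sqrt(2) s)) / sum_j exp(U_j / (sqrt(2) s))``;
* reward-triggered utility learning ``U <- U + alpha (R - U)`` applied once
  per reward to every production fired since the previous reward (the
  Q-learning delta rule);
* a motor module with preparation/execution latencies and a FIFO request
  queue (a request to a busy module waits, it is never dropped);
* a temporal module estimating subjective elapsed time, either exactly
  (default) or by ACT-R-style geometrically growing ticks.

Timing is kept on an integer grid of 1/1200 s: every canonical period of the
simulated task (1/48 s command sampling, 40 ms screen updates, 50 ms rule
firings, 50/100 ms motor phases) is an exact multiple, so event times never
accumulate floating-point error and schedules are exactly reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, MutableMapping, Sequence

import numpy as np

__all__ = [
    "UNITS_PER_SECOND",
    "PRIO_COMMAND",
    "PRIO_FRAME",
    "PRIO_MOTOR",
    "PRIO_EFFECT",
    "PRIO_AGENT",
    "EngineError",
    "seconds_to_units",
    "units_to_seconds",
    "Production",
    "ProductionSet",
    "ConflictParams",
    "LearningParams",
    "MotorParams",
    "TemporalParams",
    "FiringRecord",
    "RewardEvent",
    "match",
    "select",
    "apply_reward",
    "MotorModule",
    "TemporalModule",
    "estimate_duration",
]

#: integer clock resolution; all schedulable periods must sit on this grid
UNITS_PER_SECOND = 1200

# dispatch priorities for simultaneous events: environment commands first,
# then screen updates, then motor completions, then rule effects
PRIO_COMMAND = 0
PRIO_FRAME = 1
PRIO_MOTOR = 2
PRIO_EFFECT = 3
PRIO_AGENT = 4

#: one production firing takes 50 ms
FIRING_TIME = 0.050


class EngineError(ValueError):
    """Raised for invalid engine configuration or protocol misuse."""


def seconds_to_units(seconds: float, what: str = "duration") -> int:
    """Convert a time in seconds to integer clock units, requiring it to sit
    (to within 1e-9 s) on the 1/1200 s grid."""
    units = round(seconds * UNITS_PER_SECOND)
    if abs(units / UNITS_PER_SECOND - seconds) > 1e-9:
        raise EngineError(
            f"{what} = {seconds} s is not representable on the "
            f"1/{UNITS_PER_SECOND} s clock grid"
        )
    return int(units)


def units_to_seconds(units: int) -> float:
    return units / UNITS_PER_SECOND


# ---------------------------------------------------------------------------
# productions and conflict resolution
# ---------------------------------------------------------------------------

@dataclass
class Production:
    """A named condition-action rule carrying a learned utility.

    ``condition`` is a predicate over a buffer snapshot; ``effect`` is applied
    by the agent 50 ms after the rule wins conflict resolution.  ``phase``
    tags the point of the perception-action cycle the rule belongs to and is
    used only to index the rule set for matching.
    """

    name: str
    phase: str
    condition: Callable[[object], bool]
    effect: Callable | None = None
    utility: float = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Production({self.name}, U={self.utility:.3f})"


class _UtilityView(MutableMapping):
    """A live name -> utility mapping aliasing a ProductionSet's rules."""

    def __init__(self, pset: "ProductionSet"):
        self._pset = pset

    def __getitem__(self, name):
        return self._pset[name].utility

    def __setitem__(self, name, value):
        self._pset[name].utility = float(value)

    def __delitem__(self, name):  # pragma: no cover
        raise TypeError("utilities cannot be deleted")

    def __iter__(self):
        return iter(self._pset.names())

    def __len__(self):
        return len(self._pset)


class ProductionSet:
    """An ordered collection of uniquely named productions."""

    def __init__(self, productions: Iterable[Production]):
        self._rules: dict[str, Production] = {}
        self._by_phase: dict[str, list[Production]] = {}
        for p in productions:
            if p.name in self._rules:
                raise EngineError(f"duplicate production name {p.name!r}")
            self._rules[p.name] = p
            self._by_phase.setdefault(p.phase, []).append(p)

    def __getitem__(self, name: str) -> Production:
        return self._rules[name]

    def __contains__(self, name: str) -> bool:
        return name in self._rules

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules.values())

    def names(self) -> list[str]:
        return list(self._rules)

    def in_phase(self, phase: str) -> list[Production]:
        return self._by_phase.get(phase, [])

    @property
    def utilities(self) -> MutableMapping:
        """Live view of rule utilities (writes go to the rules themselves)."""
        return _UtilityView(self)

    def set_utilities(self, value: float) -> None:
        for p in self:
            p.utility = float(value)

    def match(self, snapshot) -> list[Production]:
        """The productions whose condition holds on the snapshot."""
        phase = getattr(snapshot, "phase", None)
        pool = self.in_phase(phase) if phase is not None else list(self)
        return [p for p in pool if p.condition(snapshot)]


def match(productions: ProductionSet, buffers) -> list[Production]:
    """Operation-style wrapper around :meth:`ProductionSet.match`."""
    return productions.match(buffers)


@dataclass
class ConflictParams:
    """Conflict-resolution parameters.

    s is the utility noise scale (ACT-R's ``egs``); with s = 0 selection is a
    strict argmax with uniform random tie-break.
    """

    s: float = 0.0

    def __post_init__(self):
        if self.s < 0:
            raise EngineError("noise scale s must be >= 0")


def select(eligible: Sequence[Production], params: ConflictParams, rng) -> Production:
    """Choose one production among the eligible set.

    Noisy-max: independent logistic noise of scale s is added to each utility
    and the argmax taken.  For s = 0 this degenerates to exact argmax with a
    uniform random tie-break among equal maxima.
    """
    if not eligible:
        raise EngineError("select() requires a nonempty eligible set")
    if len(eligible) == 1:
        return eligible[0]
    if params.s == 0.0:
        best = max(p.utility for p in eligible)
        ties = [p for p in eligible if p.utility == best]
        if len(ties) == 1:
            return ties[0]
        return ties[int(rng.integers(len(ties)))]
    noisy = [p.utility + rng.logistic(0.0, params.s) for p in eligible]
    return eligible[int(np.argmax(noisy))]


def softmax_probabilities(utilities: Sequence[float], s: float) -> np.ndarray:
    """Closed-form selection probabilities exp(U/(sqrt(2) s)) / sum(...).

    The standard closed-form description of noisy-max selection; used as an
    analytic cross-check of empirical selection frequencies.
    """
    u = np.asarray(utilities, dtype=float)
    if s == 0.0:
        out = (u == u.max()).astype(float)
        return out / out.sum()
    z = u / (math.sqrt(2.0) * s)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# utility learning
# ---------------------------------------------------------------------------

@dataclass
class LearningParams:
    """Utility-learning parameters: alpha is the learning rate, all rules
    start at ``initial_utility``.  When ``time_discount_in_propagation`` is
    on, the reward handed to each rule is reduced by the time elapsed since
    that rule fired (ACT-R's official variant); by default the plain delta
    rule is applied."""

    alpha: float = 0.2
    initial_utility: float = 5.0
    time_discount_in_propagation: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise EngineError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class FiringRecord:
    """One production firing: name and the time its effects applied (s)."""

    name: str
    time: float


@dataclass(frozen=True)
class RewardEvent:
    """A triggered reward: value R, trigger time, and the elapsed interval T
    since the previous reward.  gamma is carried for completeness; the
    reward schemes used here are undiscounted sums (gamma = 1)."""

    value: float
    time: float
    elapsed: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.elapsed < 0:
            raise EngineError("elapsed time since last reward must be >= 0")
        if not math.isfinite(self.value):
            raise EngineError("reward value must be finite")


def apply_reward(
    log: Sequence[FiringRecord],
    reward: RewardEvent,
    params: LearningParams,
    utilities: MutableMapping,
) -> MutableMapping:
    """Update the utility of every production fired since the last reward.

    Each production in the log receives ``U <- U + alpha (R - U)`` once per
    reward event (its most recent firing time is used when the optional
    time-discount is enabled).  Returns the same mapping; the caller clears
    the log.
    """
    latest: dict[str, float] = {}
    for rec in log:
        latest[rec.name] = rec.time
    for name, t_fire in latest.items():
        r = reward.value
        if params.time_discount_in_propagation:
            r = r - (reward.time - t_fire)
        u = utilities[name]
        utilities[name] = u + params.alpha * (r - u)
    return utilities


# ---------------------------------------------------------------------------
# motor module
# ---------------------------------------------------------------------------

@dataclass
class MotorParams:
    """Motor timing: feature preparation (skipped when a movement repeats the
    previous one) plus execution, per key press or release; and the 50 ms
    production firing time."""

    prep_time: float = 0.050
    exec_time: float = 0.100
    firing_time: float = FIRING_TIME

    def __post_init__(self):
        for name in ("prep_time", "exec_time", "firing_time"):
            if getattr(self, name) < 0:
                raise EngineError(f"{name} must be >= 0")

    @property
    def prep_units(self) -> int:
        return seconds_to_units(self.prep_time, "prep_time")

    @property
    def exec_units(self) -> int:
        return seconds_to_units(self.exec_time, "exec_time")

    @property
    def firing_units(self) -> int:
        return seconds_to_units(self.firing_time, "firing_time")


class MotorModule:
    """Serializes key press/release requests with ACT-R-style latencies.

    Requests queue FIFO; each takes prep (0 if the movement repeats the last
    one) + exec time.  The key-state change in the environment happens at
    completion.  ``target_keys`` is the key state after the queue drains —
    rule conditions consult it so that an in-flight press is not requested
    twice.
    """

    def __init__(self, params: MotorParams, schedule, on_complete):
        """schedule(t_units, prio, kind, data) enqueues a scheduler event;
        on_complete(t_units, kind, key) applies the completed movement."""
        self.params = params
        self._schedule = schedule
        self._on_complete = on_complete
        self._queue: deque[tuple[str, str]] = deque()
        self._busy = False
        self._last_movement: tuple[str, str] | None = None
        self.target_keys: set[str] = set()
        self._prep_u = params.prep_units
        self._exec_u = params.exec_units

    @property
    def idle(self) -> bool:
        return not self._busy and not self._queue

    def request(self, t_units: int, kind: str, key: str) -> None:
        """Queue a movement (kind: 'press' or 'release')."""
        if kind == "press" and key in ("left", "right"):
            self.target_keys.add(key)
        elif kind == "release":
            self.target_keys.discard(key)
        self._queue.append((kind, key))
        if not self._busy:
            self._start(t_units)

    def _start(self, t_units: int) -> None:
        kind, key = self._queue[0]
        prep = 0 if (kind, key) == self._last_movement else self._prep_u
        self._last_movement = (kind, key)
        self._busy = True
        self._schedule(
            t_units + prep + self._exec_u, PRIO_MOTOR, "motor", (self, (kind, key))
        )

    def complete(self, t_units: int, data) -> None:
        """Scheduler callback at a movement's completion time."""
        kind, key = self._queue.popleft()
        if self._queue:
            self._start(t_units)
        else:
            self._busy = False
        self._on_complete(t_units, kind, key)


# ---------------------------------------------------------------------------
# temporal module
# ---------------------------------------------------------------------------

@dataclass
class TemporalParams:
    """Subjective-duration estimation.  Noiseless mode (default) returns the
    true elapsed time, keeping time-summed rewards exactly reproducible.
    Tick mode emulates ACT-R's temporal module: tick lengths grow
    geometrically (start_tick, multiplier) with optional logistic noise of
    scale noise_b * multiplier * tick."""

    noiseless: bool = True
    start_tick: float = 0.011
    multiplier: float = 1.1
    noise_b: float = 0.015

    def __post_init__(self):
        if self.start_tick <= 0:
            raise EngineError("start_tick must be > 0")
        if self.multiplier < 1.0:
            raise EngineError("multiplier must be >= 1")


class TemporalModule:
    """A restartable subjective timer."""

    def __init__(self, params: TemporalParams):
        self.params = params
        self._started_at: float | None = None

    def start(self, t: float) -> None:
        self._started_at = t

    @property
    def running(self) -> bool:
        return self._started_at is not None

    def estimate(self, now: float, rng=None) -> float:
        """Estimated duration since the timer was started, in seconds."""
        if self._started_at is None:
            raise EngineError("temporal module queried before the timer started")
        elapsed = now - self._started_at
        if elapsed < 0:
            raise EngineError("clock ran backwards past the timer start")
        p = self.params
        if p.noiseless:
            return elapsed
        total = 0.0
        tick = p.start_tick
        if rng is not None and p.noise_b > 0:
            tick += rng.logistic(0.0, p.noise_b * tick)
        while total + tick <= elapsed:
            total += tick
            tick *= p.multiplier
            if rng is not None and p.noise_b > 0:
                tick += rng.logistic(0.0, p.noise_b * tick)
            if tick <= 0:  # noise drew an unusable tick; clamp to keep moving
                tick = 1e-6
        return total


def estimate_duration(temporal: TemporalModule, now: float, rng=None) -> float:
    """Operation-style wrapper around :meth:`TemporalModule.estimate`."""
    return temporal.estimate(now, rng)
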