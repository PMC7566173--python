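"""The discrete-time line-following task environment.

A vehicle sits at a fixed screen row while the course scrolls past at
24 px/s.  Commands ("left"/"straight"/"right") are sampled at 48 Hz; each
left/right command succeeds with probability Ca (auto mode) or Cm (manual
mode) and moves the vehicle 1 px, so at full capability the vehicle covers
2 px per scrolled line pixel.  The screen — and the on-line check feeding
both the score and the model's warning bit — updates every 40 ms.  The auto
controller steers toward the optimal (goal-to-goal) line; manual commands
come from held arrow keys; the space bar toggles the mode.

Trials run on a unified discrete-event schedule (command ticks, frame
updates, motor completions, rule effects) over an exact integer clock; see
:mod:`linefollow.engine` for the time grid.  Two interchangeable drivers are
provided: a heap-based event-driven scheduler (the default) and a brute-force
fixed-step driver used as an independent oracle in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Callable, NamedTuple

import numpy as np

from .course import Course, CourseError, generate_course, SEGMENT_HEIGHT
from .engine import (
    PRIO_AGENT,
    PRIO_COMMAND,
    PRIO_FRAME,
    PRIO_MOTOR,
    UNITS_PER_SECOND,
    EngineError,
    seconds_to_units,
    units_to_seconds,
)

__all__ = [
    "VehicleGeometry",
    "EnvConfig",
    "EnvState",
    "Command",
    "TrialResult",
    "TrialError",
    "HeapScheduler",
    "FixedStepScheduler",
    "Simulation",
    "init_trial",
    "command_tick",
    "auto_command",
    "toggle_mode",
    "frame_update",
    "run_trial",
    "course_for_trial",
    "write_trace",
]

AUTO = "auto"
MANUAL = "manual"


class TrialError(RuntimeError):
    """A trial aborted; carries the partial event trace for diagnosis."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class VehicleGeometry:
    """Screen-geometry constants (px).  The original environment's exact
    values are not published; these defaults are config parameters chosen to
    match its look: a 300-px-wide window, a 10-px-radius vehicle on a 5-px
    line."""

    vehicle_radius: float = 10.0
    line_width: float = 5.0
    vehicle_row: float = 250.0
    screen_width: float = 300.0

    def __post_init__(self):
        if min(self.vehicle_radius, self.line_width, self.screen_width) <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def overlap_reach(self) -> float:
        return self.vehicle_radius + self.line_width / 2.0


@dataclass(frozen=True)
class EnvConfig:
    """Trial configuration.  Defaults are the task's printed constants:
    24 px/s scroll, 40 ms screen updates, 48 Hz command sampling, 40 s
    trials."""

    ca: float = 0.5
    cm: float = 0.5
    scroll_speed: float = 24.0
    frame_dt: float = 0.040
    command_rate: float = 48.0
    trial_duration: float = 40.0
    geometry: VehicleGeometry = field(default_factory=VehicleGeometry)
    initial_mode: str = MANUAL

    def __post_init__(self):
        for name in ("ca", "cm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("scroll_speed", "frame_dt", "command_rate", "trial_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.initial_mode not in (AUTO, MANUAL):
            raise ValueError(f"initial_mode must be 'auto' or 'manual'")
        # validate representability on the integer clock grid
        self.command_period_units
        self.frame_units
        self.duration_units

    @property
    def command_period_units(self) -> int:
        if UNITS_PER_SECOND % round(self.command_rate) or (
            self.command_rate != round(self.command_rate)
        ):
            raise EngineError(
                f"command_rate {self.command_rate} does not divide the "
                f"{UNITS_PER_SECOND}/s clock"
            )
        return UNITS_PER_SECOND // int(self.command_rate)

    @property
    def frame_units(self) -> int:
        return seconds_to_units(self.frame_dt, "frame_dt")

    @property
    def duration_units(self) -> int:
        return seconds_to_units(self.trial_duration, "trial_duration")

    @property
    def scroll_per_command(self) -> float:
        """Pixels the line scrolls per command tick (0.5 at defaults)."""
        return self.scroll_speed / self.command_rate


class Command(NamedTuple):
    direction: str  # 'left' | 'straight' | 'right'
    source: str     # 'auto' | 'manual'


@dataclass
class EnvState:
    """Mutable world state for one trial."""

    t: float = 0.0
    vehicle_x: float = 0.0
    scroll_offset: float = 0.0
    mode: str = MANUAL
    held_keys: set = field(default_factory=set)
    on_line: bool = True
    switch_count: int = 0
    frames_on_line: int = 0
    frames_total: int = 0


@dataclass
class TrialResult:
    """The three behavioral indices plus the event trace."""

    performance: float
    auto_use_ratio: float
    n_switches: int
    trace: list = field(default_factory=list)
    utilities: dict = field(default_factory=dict)
    seed: object = None


# ---------------------------------------------------------------------------
# operations on the raw environment (used directly by unit tests; the
# Simulation event loop applies the same updates)
# ---------------------------------------------------------------------------

def init_trial(config: EnvConfig, course: Course) -> EnvState:
    """Fresh state: clock zero, vehicle centered on the line at its row."""
    needed = config.scroll_speed * config.trial_duration
    if course.length < needed:
        raise CourseError(
            f"course length {course.length} px cannot cover a "
            f"{config.trial_duration} s trial ({needed} px of scroll)"
        )
    x0 = course.line_x_at(0.0)
    return EnvState(
        t=0.0,
        vehicle_x=min(max(x0, 0.0), config.geometry.screen_width),
        scroll_offset=0.0,
        mode=config.initial_mode,
        on_line=True,
    )


def auto_command(state: EnvState, course: Course) -> Command:
    """The auto controller's correction toward the optimal line (0.5-px
    deadband)."""
    target = course.optimal_x_at(state.scroll_offset)
    if state.vehicle_x < target - 0.5:
        return Command("right", AUTO)
    if state.vehicle_x > target + 0.5:
        return Command("left", AUTO)
    return Command("straight", AUTO)


def _manual_direction(held_keys) -> str:
    if "left" in held_keys and "right" not in held_keys:
        return "left"
    if "right" in held_keys and "left" not in held_keys:
        return "right"
    return "straight"


def command_tick(state: EnvState, config: EnvConfig, course: Course, rng) -> EnvState:
    """One 48 Hz command sample: advance the clock and scroll, determine the
    intended command, and apply it with probability Ca/Cm (1 px, clamped to
    the screen)."""
    state.t += 1.0 / config.command_rate
    state.scroll_offset += config.scroll_per_command
    if state.mode == AUTO:
        cmd = auto_command(state, course)
        p = config.ca
    else:
        cmd = Command(_manual_direction(state.held_keys), MANUAL)
        p = config.cm
    if cmd.direction != "straight":
        if rng.random() < p:
            step = -1.0 if cmd.direction == "left" else 1.0
            state.vehicle_x = min(
                max(state.vehicle_x + step, 0.0), config.geometry.screen_width
            )
    return state


def toggle_mode(state: EnvState) -> EnvState:
    """Flip the control mode (space-bar press); key releases precede the
    press, so held keys are emptied."""
    state.mode = MANUAL if state.mode == AUTO else AUTO
    state.switch_count += 1
    state.held_keys.clear()
    return state


def frame_update(state: EnvState, config: EnvConfig, course: Course) -> EnvState:
    """40 ms screen update: evaluate the on-line predicate (the warning bit
    available to perception) and advance the frame counters."""
    line_x = course.line_x_at(state.scroll_offset)
    on = abs(state.vehicle_x - line_x) <= config.geometry.overlap_reach
    state.on_line = on
    state.frames_total += 1
    if on:
        state.frames_on_line += 1
    return state


# ---------------------------------------------------------------------------
# event scheduling
# ---------------------------------------------------------------------------

class HeapScheduler:
    """Event-driven driver: a binary heap ordered by (time, priority, seq)."""

    def __init__(self):
        self._heap = []
        self._seq = 0

    def push(self, t_units: int, prio: int, kind: str, data=None) -> None:
        heappush(self._heap, (t_units, prio, self._seq, kind, data))
        self._seq += 1

    def run(self, dispatch, end_units: int) -> None:
        heap = self._heap
        while heap:
            t, prio, seq, kind, data = heappop(heap)
            if t > end_units:
                break
            dispatch(t, kind, data)


class FixedStepScheduler:
    """Brute-force driver: advances a 1 ms fixed-step clock and, at each
    step, linearly scans the pending-event list for everything due.  An
    independent oracle for the heap driver — same handlers, same event
    times, a deliberately naive data structure."""

    def __init__(self, step_ms: int = 1):
        self._pending = []
        self._seq = 0
        self.step_ms = step_ms

    def push(self, t_units: int, prio: int, kind: str, data=None) -> None:
        self._pending.append((t_units, prio, self._seq, kind, data))
        self._seq += 1

    def run(self, dispatch, end_units: int) -> None:
        pending = self._pending
        step = 0
        # t_units/1200 <= step_ms*step/1000  <=>  5*t_units <= 6*step_ms*step
        while pending and min(ev[0] for ev in pending) <= end_units:
            step += 1
            bound = 6 * self.step_ms * step
            while True:
                due = [ev for ev in pending if 5 * ev[0] <= bound]
                if not due:
                    break
                ev = min(due)
                if ev[0] > end_units:
                    return
                pending.remove(ev)
                dispatch(ev[0], ev[3], ev[4])


class Simulation:
    """One trial: environment state, schedule, RNG and (optionally) an agent.

    The agent contract: ``start(sim, t_units)`` is called once before the
    clock runs; scheduler events of unknown kind are forwarded to
    ``agent.handle(sim, t_units, kind, data)``; ``agent.on_motor_event`` and
    ``agent.on_toggle`` fire at motor completions and mode toggles.  Scripted
    agents may implement any subset.
    """

    def __init__(
        self,
        config: EnvConfig,
        course: Course,
        agent=None,
        rng=None,
        trace: bool = False,
        scheduler=None,
    ):
        self.config = config
        self.course = course
        self.agent = agent
        self.rng = rng if rng is not None else np.random.default_rng()
        self.scheduler = scheduler if scheduler is not None else HeapScheduler()
        self.state = init_trial(config, course)
        self.trace: list | None = [] if trace else None

        self._cmd_units = config.command_period_units
        self._frame_units = config.frame_units
        self._end_units = config.duration_units
        self._scroll_per_cmd = config.scroll_per_command
        self._screen_w = config.geometry.screen_width
        self._reach = config.geometry.overlap_reach
        self._n_commands = self._end_units // self._cmd_units
        # pre-drawn per-command uniforms indexed by tick, so command-success
        # draws are independent of how many other consumers touch the stream
        self._u = self.rng.random(self._n_commands)

        # flat per-segment arrays for the hot path
        segs = course.segments
        self._seg_x0 = [s.start_x for s in segs]
        self._seg_cot = [s.cot for s in segs]
        self._n_seg = len(segs)
        gx = [g.x for g in course.goals]
        gy = [g.y for g in course.goals]
        self._opt_x0 = []
        self._opt_slope = []
        j = 0
        for i in range(self._n_seg):
            y0 = i * SEGMENT_HEIGHT
            while j + 1 < len(gy) and gy[j + 1] <= y0:
                j += 1
            dy = gy[j + 1] - gy[j]
            slope = (gx[j + 1] - gx[j]) / dy
            self._opt_x0.append(gx[j] + (y0 - gy[j]) * slope)
            self._opt_slope.append(slope)

        # mode-time bookkeeping
        self._mode_since_units = 0
        self._auto_units = 0
        self._aborted = None

    # -- geometry helpers (exact views of the course arrays) ---------------

    def line_x(self, y: float) -> float:
        i = min(int(y // SEGMENT_HEIGHT), self._n_seg - 1)
        return self._seg_x0[i] + (y - i * SEGMENT_HEIGHT) * self._seg_cot[i]

    def optimal_x(self, y: float) -> float:
        i = min(int(y // SEGMENT_HEIGHT), self._n_seg - 1)
        return self._opt_x0[i] + (y - i * SEGMENT_HEIGHT) * self._opt_slope[i]

    # -- scheduling --------------------------------------------------------

    def schedule(self, t_units: int, prio: int, kind: str, data=None) -> None:
        self.scheduler.push(t_units, prio, kind, data)

    def record(self, t_units: int, kind: str, payload: dict) -> None:
        if self.trace is not None:
            entry = {"t": units_to_seconds(t_units), "type": kind}
            entry.update(payload)
            self.trace.append(entry)

    # -- event handlers ----------------------------------------------------

    def _on_command(self, t_units: int) -> None:
        st = self.state
        k = t_units // self._cmd_units
        st.t = units_to_seconds(t_units)
        st.scroll_offset = self._scroll_per_cmd * k
        if st.mode == AUTO:
            target = self.optimal_x(st.scroll_offset)
            if st.vehicle_x < target - 0.5:
                direction = "right"
            elif st.vehicle_x > target + 0.5:
                direction = "left"
            else:
                direction = "straight"
            p = self.config.ca
        else:
            direction = _manual_direction(st.held_keys)
            p = self.config.cm
        moved = False
        if direction != "straight" and self._u[k - 1] < p:
            step = -1.0 if direction == "left" else 1.0
            st.vehicle_x = min(max(st.vehicle_x + step, 0.0), self._screen_w)
            moved = True
        if self.trace is not None:
            self.record(
                t_units,
                "command",
                {"direction": direction, "source": st.mode, "applied": moved,
                 "vehicle_x": st.vehicle_x},
            )

    def _on_frame(self, t_units: int) -> None:
        st = self.state
        line_x = self.line_x(st.scroll_offset)
        on = abs(st.vehicle_x - line_x) <= self._reach
        st.on_line = on
        st.frames_total += 1
        if on:
            st.frames_on_line += 1
        if self.trace is not None:
            self.record(t_units, "frame", {"on_line": on, "vehicle_x": st.vehicle_x,
                                           "line_x": line_x})

    def _on_motor_complete(self, t_units: int, kind: str, key: str) -> None:
        st = self.state
        if self.trace is not None:
            self.record(t_units, "motor", {"kind": kind, "key": key})
        if key in ("left", "right"):
            if kind == "press":
                st.held_keys.add(key)
            else:
                st.held_keys.discard(key)
        elif key == "space" and kind == "press":
            self._do_toggle(t_units)
        if self.agent is not None and hasattr(self.agent, "on_motor_event"):
            self.agent.on_motor_event(self, t_units)

    def _do_toggle(self, t_units: int) -> None:
        st = self.state
        if st.mode == AUTO:
            self._auto_units += t_units - self._mode_since_units
        self._mode_since_units = t_units
        toggle_mode(st)
        if self.trace is not None:
            self.record(t_units, "toggle", {"mode": st.mode})
        if self.agent is not None and hasattr(self.agent, "on_toggle"):
            self.agent.on_toggle(self, t_units)

    def dispatch(self, t_units: int, kind: str, data) -> None:
        if kind == "command":
            self._on_command(t_units)
        elif kind == "frame":
            self._on_frame(t_units)
        elif kind == "motor":
            data[0].complete(t_units, data[1])
        else:
            self.agent.handle(self, t_units, kind, data)

    # -- trial loop --------------------------------------------------------

    def run(self) -> TrialResult:
        end = self._end_units
        for k in range(1, self._n_commands + 1):
            self.schedule(k * self._cmd_units, PRIO_COMMAND, "command")
        for k in range(1, end // self._frame_units + 1):
            self.schedule(k * self._frame_units, PRIO_FRAME, "frame")
        if self.agent is not None:
            self.agent.start(self, 0)
        try:
            self.scheduler.run(self.dispatch, end)
        except Exception as exc:
            raise TrialError(
                f"trial aborted at t={self.state.t:.3f}s: {exc}",
                trace=self.trace,
            ) from exc
        st = self.state
        if st.mode == AUTO:
            self._auto_units += end - self._mode_since_units
        performance = st.frames_on_line / st.frames_total if st.frames_total else 0.0
        auto_use = self._auto_units / end
        utilities = {}
        if self.agent is not None and hasattr(self.agent, "utilities"):
            utilities = dict(self.agent.utilities)
        return TrialResult(
            performance=performance,
            auto_use_ratio=auto_use,
            n_switches=st.switch_count,
            trace=self.trace if self.trace is not None else [],
            utilities=utilities,
        )


def course_for_trial(config: EnvConfig, rng) -> Course:
    """Generate a course long enough for one trial (plus slack so a goal is
    always ahead of the vehicle at the final frame)."""
    n = math.ceil(config.scroll_speed * config.trial_duration / SEGMENT_HEIGHT) + 2
    seed = int(rng.integers(2**31 - 1))
    return generate_course(seed, n)


def run_trial(
    agent,
    config: EnvConfig,
    seed=None,
    course: Course | None = None,
    trace: bool = False,
    scheduler=None,
) -> TrialResult:
    """Run one complete trial.

    The seed drives a single per-trial RNG stream covering course
    generation (when no course is passed), command-success draws and the
    agent's conflict-resolution draws, so one seed pins down the whole
    trial.
    """
    rng = np.random.default_rng(seed)
    if course is None:
        course = course_for_trial(config, rng)
    sim = Simulation(config, course, agent=agent, rng=rng, trace=trace,
                     scheduler=scheduler)
    result = sim.run()
    result.seed = seed
    return result


def write_trace(trace: list, path) -> None:
    """Write an event trace as JSON-lines (one event per line)."""
    with open(path, "w") as fh:
        for entry in trace:
            fh.write(json.dumps(entry) + "\n")
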