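"""Procedural course geometry for the line-following task.

The course is a vertical chain of 48-px-high straight segments whose angles are
drawn uniformly from {30, 45, 90, 135, 150} degrees (measured from the
horizontal axis: 90 deg is vertical, angles below 90 slope rightward, above 90
leftward, so {30, 150} and {45, 135} are mirror pairs).  "Goals" sit on every
corner where the angle changes, plus the course start and end; the optimal
path is the polyline through the goals in y-order, which — with a goal on
every corner — coincides with the drawn centerline.

Coordinates are real-valued: x rightward, y downward along the course, with
y = 0 at the vehicle row when the trial starts.  Rounding to integer pixels is
a rendering concern only; keeping geometry exact avoids accumulation error at
30/150 degrees, whose horizontal run per segment (48 * sqrt(3)) is irrational.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ALLOWED_ANGLES",
    "SEGMENT_HEIGHT",
    "CourseError",
    "CourseSegment",
    "GoalPoint",
    "Course",
    "generate_course",
    "line_x_at",
    "goals_of",
    "optimal_x_at",
    "is_on_line",
]

ALLOWED_ANGLES: tuple[int, ...] = (30, 45, 90, 135, 150)
SEGMENT_HEIGHT: float = 48.0

#: default admissible horizontal range and start, matching a 300-px-wide screen
DEFAULT_X_BOUNDS: tuple[float, float] = (30.0, 270.0)
DEFAULT_START_X: float = 150.0


class CourseError(ValueError):
    """Raised for invalid course construction or out-of-extent queries."""


def segment_dx(angle_deg: float) -> float:
    """Horizontal run of one 48-px segment: 48 / tan(angle).

    Exactly 0 for the vertical 90-degree case; positive (rightward) below 90,
    negative above.
    """
    if angle_deg == 90:
        return 0.0
    return SEGMENT_HEIGHT / math.tan(math.radians(angle_deg))


@dataclass(frozen=True)
class CourseSegment:
    """One 48-px-high straight piece of the course."""

    index: int
    angle_deg: int
    start_x: float

    height: float = SEGMENT_HEIGHT

    def __post_init__(self) -> None:
        if self.angle_deg not in ALLOWED_ANGLES:
            raise CourseError(f"angle {self.angle_deg} not in {ALLOWED_ANGLES}")

    @property
    def end_x(self) -> float:
        return self.start_x + segment_dx(self.angle_deg)

    @property
    def y_start(self) -> float:
        return self.index * self.height

    @property
    def y_end(self) -> float:
        return (self.index + 1) * self.height

    @property
    def cot(self) -> float:
        """dx per unit dy along this segment."""
        return segment_dx(self.angle_deg) / self.height


@dataclass(frozen=True)
class GoalPoint:
    """A corner goal; y is always a multiple of the segment height."""

    x: float
    y: float


@dataclass
class Course:
    """A generated course: segments, corner goals and the optimal polyline."""

    segments: list[CourseSegment]
    x_bounds: tuple[float, float]
    seed: int | None = None
    goals: list[GoalPoint] = field(init=False)
    optimal: list[tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if not math.isclose(prev.end_x, nxt.start_x, abs_tol=1e-9):
                raise CourseError(
                    f"segments {prev.index} and {nxt.index} are not continuous"
                )
        self.goals = goals_of(self) if self.segments else []
        self.optimal = [(g.x, g.y) for g in self.goals]
        self._goal_ys = [g.y for g in self.goals]
        self._goal_xs = [g.x for g in self.goals]

    # -- basic extent ------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def length(self) -> float:
        """Vertical extent in px."""
        return self.n_segments * SEGMENT_HEIGHT

    @property
    def start_x(self) -> float:
        return self.segments[0].start_x

    # -- interpolation -----------------------------------------------------

    def line_x_at(self, y: float) -> float:
        """x of the drawn centerline at course ordinate y."""
        if not 0.0 <= y <= self.length:
            raise CourseError(f"y={y} outside course extent [0, {self.length}]")
        i = min(int(y // SEGMENT_HEIGHT), self.n_segments - 1)
        seg = self.segments[i]
        return seg.start_x + (y - seg.y_start) * seg.cot

    def optimal_x_at(self, y: float) -> float:
        """x of the optimal (goal-to-goal) polyline at course ordinate y."""
        if not 0.0 <= y <= self.length:
            raise CourseError(f"y={y} outside course extent [0, {self.length}]")
        ys, xs = self._goal_ys, self._goal_xs
        j = bisect.bisect_right(ys, y)
        if j == 0:
            return xs[0]
        if j == len(ys):
            return xs[-1]
        y0, y1 = ys[j - 1], ys[j]
        frac = (y - y0) / (y1 - y0)
        return xs[j - 1] + frac * (xs[j] - xs[j - 1])

    def next_goal_after(self, y: float) -> GoalPoint:
        """The nearest upcoming goal: smallest goal y strictly greater than y."""
        j = bisect.bisect_right(self._goal_ys, y)
        if j == len(self._goal_ys):
            raise CourseError(f"no goal ahead of y={y}; course exhausted")
        return self.goals[j]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "x_bounds": list(self.x_bounds),
            "start_x": self.start_x,
            "angles": [s.angle_deg for s in self.segments],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Course":
        return cls.from_angles(
            d["angles"],
            start_x=d["start_x"],
            x_bounds=tuple(d["x_bounds"]),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, s: str) -> "Course":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_angles(
        cls,
        angles: Sequence[int],
        start_x: float = DEFAULT_START_X,
        x_bounds: tuple[float, float] | None = None,
        seed: int | None = None,
    ) -> "Course":
        """Build a course from an explicit angle sequence (no bound checks
        unless x_bounds is given)."""
        segments = []
        x = float(start_x)
        for i, a in enumerate(angles):
            seg = CourseSegment(index=i, angle_deg=int(a), start_x=x)
            if x_bounds is not None:
                lo, hi = x_bounds
                if not (lo <= seg.start_x <= hi and lo <= seg.end_x <= hi):
                    raise CourseError(
                        f"segment {i} (angle {a}) leaves x_bounds {x_bounds}"
                    )
            segments.append(seg)
            x = seg.end_x
        if x_bounds is None:
            xs = [s.start_x for s in segments] + [segments[-1].end_x] if segments else [x]
            x_bounds = (min(xs), max(xs))
        return cls(segments=segments, x_bounds=x_bounds, seed=seed)


def generate_course(
    seed,
    n_segments: int,
    x_bounds: tuple[float, float] = DEFAULT_X_BOUNDS,
    start_x: float = DEFAULT_START_X,
) -> Course:
    """Randomly chain 48-px segments, resampling any angle that would exit
    x_bounds.  A pure function of its arguments: the same seed yields the
    same course.
    """
    lo, hi = x_bounds
    if not lo < hi:
        raise CourseError(f"invalid x_bounds {x_bounds}")
    if not lo <= start_x <= hi:
        raise CourseError(f"start_x {start_x} outside x_bounds {x_bounds}")
    if n_segments < 0:
        raise CourseError("n_segments must be >= 0")
    rng = np.random.default_rng(seed)
    angles: list[int] = []
    x = float(start_x)
    for _ in range(n_segments):
        feasible = [a for a in ALLOWED_ANGLES if lo <= x + segment_dx(a) <= hi]
        if not feasible:
            # cannot happen while x is in bounds (90 deg always fits), but the
            # contract demands an explicit error rather than an endless loop
            raise CourseError(
                f"no admissible angle from x={x} within bounds {x_bounds}"
            )
        while True:
            a = ALLOWED_ANGLES[int(rng.integers(len(ALLOWED_ANGLES)))]
            nx = x + segment_dx(a)
            if lo <= nx <= hi:
                break
        angles.append(a)
        x = nx
    course = Course.from_angles(angles, start_x=start_x, x_bounds=x_bounds)
    course.seed = seed
    return course


# -- functional wrappers (operation-style API) -----------------------------

def line_x_at(course: Course, y: float) -> float:
    return course.line_x_at(y)


def optimal_x_at(course: Course, y: float) -> float:
    return course.optimal_x_at(y)


def goals_of(course: Course) -> list[GoalPoint]:
    """Goals at every angle-change junction, plus course start and end."""
    segs = course.segments
    if not segs:
        raise CourseError("course has no segments")
    goals = [GoalPoint(segs[0].start_x, 0.0)]
    for prev, nxt in zip(segs, segs[1:]):
        if prev.angle_deg != nxt.angle_deg:
            goals.append(GoalPoint(nxt.start_x, nxt.y_start))
    goals.append(GoalPoint(segs[-1].end_x, segs[-1].y_end))
    return goals


def is_on_line(vehicle_x: float, course: Course, scroll_offset: float, geometry) -> bool:
    """True iff the vehicle overlaps the line at its row (inclusive boundary).

    The vehicle row's course ordinate is the scroll offset; overlap means
    |vehicle_x - line_x| <= vehicle_radius + line_width / 2.
    """
    line_x = course.line_x_at(scroll_offset)
    reach = geometry.vehicle_radius + geometry.line_width / 2.0
    return abs(vehicle_x - line_x) <= reach
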