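"""The task model: an 11-rule perception/action cycle, two rewarding schemes
and a gating mechanism, composable into four model variants.

The cycle (per mode):

* perception — ``FindVehicle`` reads the vehicle's horizontal position into
  the goal buffer and triggers a reward (this is where learning happens);
  ``FindGoal`` reads the x of the nearest upcoming corner goal;
* motor, auto mode — ``KeepA`` just clears the buffer; ``ToManual`` begins a
  mode switch;
* motor, manual mode — ``ToLeft``/``ToRight`` start holding an arrow key,
  ``LtoS``/``RtoS`` release it when the goal is no longer off to that side,
  ``KeepM`` otherwise just clears the buffer; their conditions partition the
  (goal position, held key) space so exactly one applies at a time (see
  :func:`manual_action`), and each competes with ``ToAuto`` for the right to
  fire;
* a mode switch first releases any held keys, then ``PressSpace`` punches the
  space bar; the mode flips when the press completes.

Rewarding schemes (both triggered by ``FindVehicle``):

* default — a fixed reward, 10 when the vehicle is on the line and 0 off it;
* SMDP — the reward sums over the (irregular) interval since the last
  reward: on line, max vehicle speed (48 px/s) times the subjectively
  estimated interval; off line, the absolute distance the vehicle actually
  moved since the last reward.  This balances reward mass across rules that
  fire at different rates, the semi-Markov correction to plain per-firing
  rewards.

Gating: self-confidence SC and trust T are read off the utilities of KeepM
and KeepA (aliases, not copies).  In gating variants a mode switch is only
eligible when the order relation permits it: ToAuto requires SC <= T,
ToManual requires SC >= T (both inclusive: at equality either switch is
possible and ordinary conflict resolution decides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .engine import (
    PRIO_EFFECT,
    ConflictParams,
    EngineError,
    FiringRecord,
    LearningParams,
    MotorModule,
    MotorParams,
    Production,
    ProductionSet,
    RewardEvent,
    TemporalModule,
    TemporalParams,
    apply_reward,
    select,
    units_to_seconds,
)

__all__ = [
    "ALIGN_TOL",
    "RULE_NAMES",
    "ModelVariant",
    "RewardParams",
    "GateState",
    "PerceptBuffer",
    "BufferSnapshot",
    "build_model",
    "manual_action",
    "default_reward",
    "smdp_reward",
    "gate_open",
    "CognitiveAgent",
]

#: |goal_x - vehicle_x| <= ALIGN_TOL counts as aligned — 2 px, the vehicle's
#: maximal displacement per scrolled pixel
ALIGN_TOL = 2.0

RULE_NAMES = (
    "FindVehicle",
    "FindGoal",
    "KeepA",
    "ToManual",
    "PressSpace",
    "KeepM",
    "ToAuto",
    "ToLeft",
    "ToRight",
    "LtoS",
    "RtoS",
)

REWARDING_SCHEMES = ("default", "smdp")
CONFLICT_SCHEMES = ("default", "gating")


@dataclass(frozen=True)
class ModelVariant:
    """One of the four model variants: rewarding in {default, smdp} crossed
    with conflict resolution in {default, gating}."""

    rewarding: str = "default"
    conflict: str = "default"

    def __post_init__(self):
        if self.rewarding not in REWARDING_SCHEMES:
            raise EngineError(f"unknown rewarding scheme {self.rewarding!r}")
        if self.conflict not in CONFLICT_SCHEMES:
            raise EngineError(f"unknown conflict scheme {self.conflict!r}")

    @property
    def label(self) -> str:
        """Conventional name, e.g. 'Gating-SMDP' or 'Default-Default'."""
        c = "Gating" if self.conflict == "gating" else "Default"
        r = "SMDP" if self.rewarding == "smdp" else "Default"
        return f"{c}-{r}"

    @classmethod
    def from_label(cls, label: str) -> "ModelVariant":
        c, _, r = label.partition("-")
        return cls(
            rewarding="smdp" if r.lower() == "smdp" else "default",
            conflict="gating" if c.lower() == "gating" else "default",
        )

    @classmethod
    def all_variants(cls) -> list["ModelVariant"]:
        return [
            cls(rewarding=r, conflict=c)
            for c in CONFLICT_SCHEMES
            for r in REWARDING_SCHEMES
        ]


@dataclass
class RewardParams:
    """Reward constants: the default scheme's on/off-line rewards and the
    SMDP scheme's maximum vehicle speed (48 commands/s x 1 px).  gamma is
    the SMDP time-discount rate, fixed at 1 — the time-summed rewards are
    undiscounted sums."""

    reward_online: float = 10.0
    reward_offline: float = 0.0
    max_vehicle_speed: float = 48.0
    gamma: float = 1.0


@dataclass
class PerceptBuffer:
    """The goal buffer's task-relevant content during one cycle; cleared at
    the end of each motor phase.  vposi_prev persists across cycles: the
    vehicle position at the last reward, used by the SMDP off-line reward."""

    vehicle_x: float | None = None
    goal_x: float | None = None
    on_line: bool = True
    vposi_prev: float = 0.0

    def clear(self) -> None:
        self.vehicle_x = None
        self.goal_x = None


class BufferSnapshot(NamedTuple):
    """What rule conditions can see at a decision point."""

    phase: str          # 'perceive-vehicle' | 'perceive-goal' | 'motor' | 'switch'
    mode: str           # 'auto' | 'manual'
    vehicle_x: float | None
    goal_x: float | None
    on_line: bool
    left_held: bool     # target key state (queued motor requests included)
    right_held: bool
    sc: float           # utility of KeepM (self-confidence)
    trust: float        # utility of KeepA (trust)
    motor_idle: bool


class GateState:
    """Live view of (SC, T) as aliases of the KeepM/KeepA utilities."""

    def __init__(self, productions: ProductionSet):
        self._keep_m = productions["KeepM"] if "KeepM" in productions else None
        self._keep_a = productions["KeepA"] if "KeepA" in productions else None

    @property
    def sc(self) -> float:
        return self._keep_m.utility if self._keep_m is not None else 0.0

    @property
    def trust(self) -> float:
        return self._keep_a.utility if self._keep_a is not None else 0.0


def gate_open(direction: str, gate) -> bool:
    """Whether the gate permits a mode switch: to_auto needs SC <= T,
    to_manual needs SC >= T (inclusive)."""
    if direction == "to_auto":
        return gate.sc <= gate.trust
    if direction == "to_manual":
        return gate.sc >= gate.trust
    raise EngineError(f"unknown gate direction {direction!r}")


def default_reward(on_line: bool, params: RewardParams) -> float:
    """Fixed reward: 10 on line, 0 off line (at defaults)."""
    return params.reward_online if on_line else params.reward_offline


def smdp_reward(
    on_line: bool,
    duration_est: float,
    vposi_now: float,
    vposi_prev: float,
    params: RewardParams,
) -> float:
    """Time-summed reward: on line, max speed x estimated interval; off
    line, the vehicle's absolute displacement since the last reward."""
    if duration_est < 0:
        raise EngineError("duration estimate must be >= 0")
    if on_line:
        return params.max_vehicle_speed * duration_est
    return abs(vposi_now - vposi_prev)


def manual_action(percept, held_keys) -> str:
    """The one applicable manual-mode action for a percept and key state.

    The five manual rules' conditions partition the (goal position, held
    key) space, so exactly one of them applies at any decision point (and
    competes only with ToAuto for the right to fire):

    ========  ==============  =======================================
    held key  goal position   applicable rule
    ========  ==============  =======================================
    none      left of band    ToLeft   (start holding the left arrow)
    none      right of band   ToRight
    none      within band     KeepM    (nothing to change)
    left      still left      KeepM    (keep holding)
    left      no longer left  LtoS     (release)
    right     still right     KeepM
    right     no longer right RtoS
    ========  ==============  =======================================

    "band" is vehicle_x +/- ALIGN_TOL.
    """
    goal_x, vehicle_x = percept.goal_x, percept.vehicle_x
    if "left" in held_keys:
        return "KeepM" if goal_x < vehicle_x - ALIGN_TOL else "LtoS"
    if "right" in held_keys:
        return "KeepM" if goal_x > vehicle_x + ALIGN_TOL else "RtoS"
    if goal_x < vehicle_x - ALIGN_TOL:
        return "ToLeft"
    if goal_x > vehicle_x + ALIGN_TOL:
        return "ToRight"
    return "KeepM"


# ---------------------------------------------------------------------------
# rule effects (applied 50 ms after selection; they receive the owning agent)
# ---------------------------------------------------------------------------

def _fx_find_vehicle(agent, sim, t_units):
    st = sim.state
    agent.percept.vehicle_x = st.vehicle_x
    agent.percept.on_line = st.on_line
    agent._trigger_reward(sim, t_units)


def _fx_find_goal(agent, sim, t_units):
    goal = sim.course.next_goal_after(sim.state.scroll_offset)
    agent.percept.goal_x = goal.x


def _fx_keep(agent, sim, t_units):
    agent.percept.clear()


def _fx_to_left(agent, sim, t_units):
    if "right" in agent.motor.target_keys:
        agent.motor.request(t_units, "release", "right")
    agent.motor.request(t_units, "press", "left")
    agent.percept.clear()


def _fx_to_right(agent, sim, t_units):
    if "left" in agent.motor.target_keys:
        agent.motor.request(t_units, "release", "left")
    agent.motor.request(t_units, "press", "right")
    agent.percept.clear()


def _fx_l_to_s(agent, sim, t_units):
    agent.motor.request(t_units, "release", "left")
    agent.percept.clear()


def _fx_r_to_s(agent, sim, t_units):
    agent.motor.request(t_units, "release", "right")
    agent.percept.clear()


def _fx_begin_switch(agent, sim, t_units):
    for key in sorted(agent.motor.target_keys):
        agent.motor.request(t_units, "release", key)
    agent.switch_pending = True
    agent.percept.clear()


def _fx_press_space(agent, sim, t_units):
    agent.motor.request(t_units, "press", "space")


class _ManualPercept(NamedTuple):
    goal_x: float
    vehicle_x: float


def _cond_for(rule_name: str):
    """Condition predicate of one manual-mode action rule, derived from the
    :func:`manual_action` partition so the table lives in one place."""

    def cond(s) -> bool:
        if s.mode != "manual" or s.goal_x is None:
            return False
        held = {k for k, h in (("left", s.left_held), ("right", s.right_held)) if h}
        return manual_action(_ManualPercept(s.goal_x, s.vehicle_x), held) == rule_name

    return cond


def build_model(
    variant: ModelVariant,
    learning: LearningParams | None = None,
    exclude: tuple = (),
) -> ProductionSet:
    """Assemble the canonical 11-rule set for a model variant.

    FindVehicle's on-line/off-line reward branches share one name and one
    utility (the canonical count stays 11); gating variants add the SC/T
    order test to the ToAuto / ToManual conditions.  ``exclude`` drops rules
    by name — the manual-only baseline removes ToAuto.
    """
    if not isinstance(variant, ModelVariant):
        raise EngineError(f"unknown variant {variant!r}")
    u0 = (learning or LearningParams()).initial_utility
    gating = variant.conflict == "gating"

    def manual(s):
        return s.mode == "manual"

    def auto(s):
        return s.mode == "auto"

    if gating:
        to_auto_cond = lambda s: s.mode == "manual" and s.sc <= s.trust
        to_manual_cond = lambda s: s.mode == "auto" and s.sc >= s.trust
    else:
        to_auto_cond = manual
        to_manual_cond = auto

    rules = [
        Production("FindVehicle", "perceive-vehicle", lambda s: True,
                   _fx_find_vehicle, u0),
        Production("FindGoal", "perceive-goal", lambda s: True,
                   _fx_find_goal, u0),
        Production("KeepA", "motor", auto, _fx_keep, u0),
        Production("ToManual", "motor", to_manual_cond, _fx_begin_switch, u0),
        Production("PressSpace", "switch", lambda s: s.motor_idle,
                   _fx_press_space, u0),
        Production("KeepM", "motor", _cond_for("KeepM"), _fx_keep, u0),
        Production("ToAuto", "motor", to_auto_cond, _fx_begin_switch, u0),
        Production("ToLeft", "motor", _cond_for("ToLeft"), _fx_to_left, u0),
        Production("ToRight", "motor", _cond_for("ToRight"), _fx_to_right, u0),
        Production("LtoS", "motor", _cond_for("LtoS"), _fx_l_to_s, u0),
        Production("RtoS", "motor", _cond_for("RtoS"), _fx_r_to_s, u0),
    ]
    rules = [r for r in rules if r.name not in exclude]
    return ProductionSet(rules)


# ---------------------------------------------------------------------------
# the cognitive agent
# ---------------------------------------------------------------------------

class CognitiveAgent:
    """A production-system agent performing the line-following task.

    Wires the rule set to the engine primitives: a 50 ms firing clock,
    utility-based conflict resolution, reward-triggered learning, a motor
    module for key presses, and a temporal module for the SMDP scheme's
    subjective interval estimates.
    """

    def __init__(
        self,
        variant: ModelVariant | None = None,
        productions: ProductionSet | None = None,
        learning: LearningParams | None = None,
        conflict: ConflictParams | None = None,
        reward_params: RewardParams | None = None,
        motor_params: MotorParams | None = None,
        temporal_params: TemporalParams | None = None,
        manual_only: bool = False,
    ):
        self.variant = variant or ModelVariant()
        self.learning = learning or LearningParams()
        self.conflict = conflict or ConflictParams()
        self.reward_params = reward_params or RewardParams()
        self.motor_params = motor_params or MotorParams()
        self.temporal = TemporalModule(temporal_params or TemporalParams())
        if productions is None:
            exclude = ("ToAuto",) if manual_only else ()
            productions = build_model(self.variant, self.learning, exclude=exclude)
        self.productions = productions
        self.gate = GateState(productions)
        self.percept = PerceptBuffer()
        self.firing_log: list[FiringRecord] = []
        self.switch_pending = False
        self._busy = False
        self._firing_units = self.motor_params.firing_units
        self.last_reward_t = 0.0
        self.motor: MotorModule | None = None

    # -- agent contract ----------------------------------------------------

    def start(self, sim, t_units: int) -> None:
        self.motor = MotorModule(
            self.motor_params, sim.schedule, sim._on_motor_complete
        )
        self.percept.vposi_prev = sim.state.vehicle_x
        self.temporal.start(0.0)
        self.last_reward_t = 0.0
        self.decide(sim, t_units)

    def handle(self, sim, t_units: int, kind: str, data) -> None:
        if kind != "fire":
            raise EngineError(f"unexpected event kind {kind!r}")
        rule = data
        self._busy = False
        t = units_to_seconds(t_units)
        self.firing_log.append(FiringRecord(rule.name, t))
        rule.effect(self, sim, t_units)
        sim.record(t_units, "fire", {"rule": rule.name})
        self.decide(sim, t_units)

    def on_motor_event(self, sim, t_units: int) -> None:
        self.decide(sim, t_units)

    def on_toggle(self, sim, t_units: int) -> None:
        self.switch_pending = False

    # -- internals ---------------------------------------------------------

    @property
    def utilities(self) -> dict:
        return {p.name: p.utility for p in self.productions}

    def phase(self) -> str:
        if self.switch_pending:
            return "switch"
        if self.percept.vehicle_x is None:
            return "perceive-vehicle"
        if self.percept.goal_x is None:
            return "perceive-goal"
        return "motor"

    def snapshot(self, sim) -> BufferSnapshot:
        target = self.motor.target_keys if self.motor is not None else ()
        return BufferSnapshot(
            phase=self.phase(),
            mode=sim.state.mode,
            vehicle_x=self.percept.vehicle_x,
            goal_x=self.percept.goal_x,
            on_line=sim.state.on_line,
            left_held="left" in target,
            right_held="right" in target,
            sc=self.gate.sc,
            trust=self.gate.trust,
            motor_idle=self.motor.idle if self.motor is not None else True,
        )

    def decide(self, sim, t_units: int) -> None:
        """Match, resolve the conflict, and schedule the winner's effects
        50 ms out.  With nothing eligible the engine idles until the next
        buffer or motor change."""
        if self._busy:
            return
        eligible = self.productions.match(self.snapshot(sim))
        if not eligible:
            return
        rule = select(eligible, self.conflict, sim.rng)
        self._busy = True
        sim.schedule(t_units + self._firing_units, PRIO_EFFECT, "fire", rule)

    def _trigger_reward(self, sim, t_units: int) -> None:
        t = units_to_seconds(t_units)
        st = sim.state
        if self.variant.rewarding == "smdp":
            dur = self.temporal.estimate(t, sim.rng)
            value = smdp_reward(
                st.on_line, dur, st.vehicle_x, self.percept.vposi_prev,
                self.reward_params,
            )
        else:
            value = default_reward(st.on_line, self.reward_params)
        event = RewardEvent(value=value, time=t, elapsed=t - self.last_reward_t)
        apply_reward(self.firing_log, event, self.learning,
                     self.productions.utilities)
        self.firing_log.clear()
        self.last_reward_t = t
        self.percept.vposi_prev = st.vehicle_x
        self.temporal.start(t)
        if sim.trace is not None:
            sim.record(t_units, "reward",
                       {"value": value, "on_line": st.on_line,
                        "utilities": self.utilities})
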