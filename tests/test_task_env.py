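"""Environment dynamics: command channel, kinematics, scrolling, auto
controller, mode toggling, trial loop."""

import numpy as np
import pytest

import linefollow as lf
from linefollow.task_env import _manual_direction


def wide_config(**kw):
    """Config with an effectively unbounded screen so clamping never hides
    kinematics."""
    geom = lf.VehicleGeometry(screen_width=1e9)
    defaults = dict(ca=0.5, cm=0.5, geometry=geom)
    defaults.update(kw)
    return lf.EnvConfig(**defaults)


class TestInitTrial:
    def test_fresh_counters_and_centered_vehicle(self, straight_course):
        st = lf.init_trial(lf.EnvConfig(trial_duration=40.0), straight_course)
        assert st.frames_total == 0 and st.switch_count == 0
        assert st.vehicle_x == straight_course.line_x_at(0.0)
        assert st.on_line

    def test_determinism(self, straight_course):
        cfg = lf.EnvConfig()
        assert lf.init_trial(cfg, straight_course) == lf.init_trial(cfg, straight_course)

    def test_short_course_rejected(self):
        short = lf.Course.from_angles([90] * 3)
        with pytest.raises(lf.CourseError):
            lf.init_trial(lf.EnvConfig(trial_duration=40.0), short)


class TestCommandTick:
    def test_certain_manual_command_moves_one_pixel(self, straight_course, rng):
        cfg = wide_config(cm=1.0)
        st = lf.init_trial(cfg, straight_course)
        st.held_keys.add("left")
        x0 = st.vehicle_x
        for k in range(10):
            lf.command_tick(st, cfg, straight_course, rng)
            assert st.vehicle_x == x0 - (k + 1)

    def test_zero_capability_never_moves(self, straight_course, rng):
        cfg = wide_config(cm=0.0)
        st = lf.init_trial(cfg, straight_course)
        st.held_keys.add("right")
        x0 = st.vehicle_x
        for _ in range(200):
            lf.command_tick(st, cfg, straight_course, rng)
        assert st.vehicle_x == x0

    def test_two_pixels_per_scrolled_pixel(self, straight_course, rng):
        # 48 commands/s against 24 px/s of scroll: 2 px per scrolled pixel
        cfg = wide_config(cm=1.0)
        st = lf.init_trial(cfg, straight_course)
        st.held_keys.add("right")
        x0 = st.vehicle_x
        for _ in range(48):
            lf.command_tick(st, cfg, straight_course, rng)
        assert st.vehicle_x - x0 == 48.0
        assert st.scroll_offset == pytest.approx(24.0)
        assert (st.vehicle_x - x0) / st.scroll_offset == pytest.approx(2.0)

    def test_opposed_keys_cancel(self):
        assert _manual_direction({"left", "right"}) == "straight"
        assert _manual_direction(set()) == "straight"

    def test_vehicle_clamped_at_screen_edges(self, rng):
        course = lf.Course.from_angles([90] * 25, start_x=2.0,
                                       x_bounds=(0.0, 300.0))
        cfg = lf.EnvConfig(cm=1.0)
        st = lf.init_trial(cfg, course)
        st.held_keys.add("left")
        for _ in range(20):
            lf.command_tick(st, cfg, course, rng)
        assert st.vehicle_x == 0.0


class TestAutoCommand:
    def test_on_target_is_straight(self, straight_course):
        st = lf.init_trial(lf.EnvConfig(), straight_course)
        assert lf.auto_command(st, straight_course).direction == "straight"

    def test_left_of_target_commands_right(self, straight_course):
        st = lf.init_trial(lf.EnvConfig(), straight_course)
        st.vehicle_x -= 10.0
        assert lf.auto_command(st, straight_course).direction == "right"

    def test_converges_within_deadband_and_stays(self, straight_course, rng):
        # 5 px off at full capability: 5 ticks to converge, then straight
        cfg = wide_config(ca=1.0, initial_mode="auto")
        st = lf.init_trial(cfg, straight_course)
        st.vehicle_x += 5.0
        for _ in range(5):
            lf.command_tick(st, cfg, straight_course, rng)
        assert abs(st.vehicle_x - 150.0) <= 0.5
        x = st.vehicle_x
        for _ in range(50):
            lf.command_tick(st, cfg, straight_course, rng)
        assert st.vehicle_x == x


class TestToggleMode:
    def test_flip_and_count(self):
        st = lf.EnvState(mode="auto")
        lf.toggle_mode(st)
        assert st.mode == "manual" and st.switch_count == 1

    def test_double_toggle_is_involution(self):
        st = lf.EnvState(mode="manual")
        lf.toggle_mode(st)
        lf.toggle_mode(st)
        assert st.mode == "manual" and st.switch_count == 2

    def test_toggle_empties_held_keys(self):
        st = lf.EnvState(mode="manual", held_keys={"left"})
        lf.toggle_mode(st)
        assert st.held_keys == set()


class TestFrameUpdate:
    def test_forty_second_trial_has_1000_frames(self, rng):
        # 40 s of 40 ms screen updates
        course = lf.generate_course(1, 23)
        cfg = lf.EnvConfig(ca=1.0, initial_mode="auto")
        sim = lf.Simulation(cfg, course, agent=None, rng=rng)
        sim.run()
        assert sim.state.frames_total == 1000

    def test_on_line_counters(self, straight_course):
        cfg = lf.EnvConfig()
        st = lf.init_trial(cfg, straight_course)
        lf.frame_update(st, cfg, straight_course)
        assert st.frames_total == 1 and st.frames_on_line == 1
        st.vehicle_x += 100.0
        lf.frame_update(st, cfg, straight_course)
        assert st.frames_total == 2 and st.frames_on_line == 1
        assert not st.on_line


class _ScriptedToggler:
    """Scripted agent: toggles the mode directly at given times (seconds)."""

    def __init__(self, times):
        self.times = times

    def start(self, sim, t_units):
        for t in self.times:
            sim.schedule(round(t * 1200), 4, "toggle-now", None)

    def handle(self, sim, t_units, kind, data):
        sim._do_toggle(t_units)


class TestRunTrial:
    def test_perfect_auto_has_perfect_performance(self):
        cfg = lf.EnvConfig(ca=1.0, initial_mode="auto")
        res = lf.run_trial(None, cfg, seed=3)
        assert res.performance == 1.0
        assert res.auto_use_ratio == 1.0
        assert res.n_switches == 0

    def test_do_nothing_manual_on_vertical_course(self, straight_course):
        cfg = lf.EnvConfig(initial_mode="manual")
        res = lf.run_trial(None, cfg, seed=0, course=straight_course)
        assert res.performance == 1.0
        assert res.auto_use_ratio == 0.0

    def test_do_nothing_manual_on_drifting_course(self):
        drifting = lf.Course.from_angles([45] * 25, start_x=20.0,
                                         x_bounds=(0.0, 1300.0))
        cfg = lf.EnvConfig(initial_mode="manual")
        res = lf.run_trial(None, cfg, seed=0, course=drifting)
        assert res.performance < 1.0

    def test_same_seed_identical_traces(self):
        cfg = lf.EnvConfig(ca=0.6, cm=0.4)
        agent_a = lf.CognitiveAgent(variant=lf.ModelVariant("smdp", "gating"))
        agent_b = lf.CognitiveAgent(variant=lf.ModelVariant("smdp", "gating"))
        ra = lf.run_trial(agent_a, cfg, seed=99, trace=True)
        rb = lf.run_trial(agent_b, cfg, seed=99, trace=True)
        assert ra.trace == rb.trace
        assert ra.performance == rb.performance

    def test_mode_time_conservation(self, straight_course):
        # auto time + manual time = trial duration, exactly
        cfg = lf.EnvConfig(initial_mode="manual", trial_duration=10.0)
        agent = _ScriptedToggler([1.37, 2.0, 5.555, 9.1])
        sim = lf.Simulation(cfg, straight_course, agent=agent,
                            rng=np.random.default_rng(0))
        res = sim.run()
        assert res.n_switches == 4
        auto_time = res.auto_use_ratio * 10.0
        assert auto_time == pytest.approx((2.0 - 1.37) + (9.1 - 5.555), abs=1e-9)

    def test_switch_count_equals_trace_toggles(self):
        cfg = lf.EnvConfig(ca=0.4, cm=0.4)
        agent = lf.CognitiveAgent(variant=lf.ModelVariant("default", "default"))
        res = lf.run_trial(agent, cfg, seed=5, trace=True)
        toggles = [e for e in res.trace if e["type"] == "toggle"]
        assert res.n_switches == len(toggles)
        assert 0.0 <= res.performance <= 1.0
        assert 0.0 <= res.auto_use_ratio <= 1.0

    def test_agent_failure_aborts_with_diagnostic(self, straight_course):
        class Exploding:
            def start(self, sim, t):
                sim.schedule(600, 4, "boom", None)

            def handle(self, sim, t, kind, data):
                raise RuntimeError("agent bug")

        cfg = lf.EnvConfig(trial_duration=2.0)
        with pytest.raises(lf.TrialError):
            lf.run_trial(Exploding(), cfg, seed=0, course=straight_course)


class TestAutoMonotonicity:
    def test_mean_performance_nondecreasing_in_ca(self):
        # always-auto agent: more capable automation tracks better
        means = []
        ses = []
        for ca in (0.3, 0.5, 0.7):
            s = lf.run_condition("auto-only", ca, 0.5, 60, master_seed=4)
            means.append(s.performance_mean)
            ses.append(s.performance_sd / np.sqrt(s.n_runs))
        assert means[0] < means[1] < means[2]
        assert means[2] - means[0] > 4 * (ses[0] + ses[2])
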