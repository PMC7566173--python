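"""Engine primitives: conflict resolution, utility learning, motor timing,
subjective duration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import linefollow as lf
from linefollow.engine import (
    FiringRecord,
    MotorModule,
    RewardEvent,
    TemporalModule,
    seconds_to_units,
    softmax_probabilities,
)


def _prods(*utilities):
    return [
        lf.Production(f"p{i}", "x", lambda s: True, None, u)
        for i, u in enumerate(utilities)
    ]


class TestSelect:
    def test_single_rule_always_chosen(self, rng):
        (p,) = _prods(5.0)
        assert lf.select([p], lf.ConflictParams(s=0.0), rng) is p

    def test_zero_noise_is_strict_argmax(self, rng):
        prods = _prods(6.0, 5.0)
        assert all(
            lf.select(prods, lf.ConflictParams(s=0.0), rng) is prods[0]
            for _ in range(1000)
        )

    def test_zero_noise_tie_break_uniform(self, rng):
        prods = _prods(5.0, 5.0)
        picks = np.array(
            [lf.select(prods, lf.ConflictParams(s=0.0), rng) is prods[0]
             for _ in range(10_000)]
        )
        assert abs(picks.mean() - 0.5) < 0.05

    @pytest.mark.parametrize("utilities", [(5.0, 5.0), (5.5, 5.0), (5.0, 5.3, 5.5)])
    def test_noisy_selection_matches_closed_form(self, utilities, rng):
        # empirical frequencies vs the softmax form exp(U/(sqrt(2) s)),
        # within 3 sigma binomial error at 10,000 draws
        n = 10_000
        params = lf.ConflictParams(s=1.0)
        prods = _prods(*utilities)
        counts = np.zeros(len(prods))
        for _ in range(n):
            chosen = lf.select(prods, params, rng)
            counts[prods.index(chosen)] += 1
        expected = softmax_probabilities(utilities, 1.0)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(counts / n - expected) < 3 * sigma)

    def test_empty_eligible_errors(self, rng):
        with pytest.raises(lf.EngineError):
            lf.select([], lf.ConflictParams(), rng)


class TestApplyReward:
    PARAMS = lf.LearningParams(alpha=0.2, initial_utility=5.0)

    def test_one_step_update(self):
        # U=5, R=10, alpha=0.2 -> 6.0
        u = {"a": 5.0}
        lf.apply_reward([FiringRecord("a", 0.0)], RewardEvent(10.0, 1.0),
                        self.PARAMS, u)
        assert u["a"] == pytest.approx(6.0, abs=1e-12)

    def test_reward_at_utility_is_fixed_point(self):
        u = {"a": 7.25}
        lf.apply_reward([FiringRecord("a", 0.0)], RewardEvent(7.25, 1.0),
                        self.PARAMS, u)
        assert u["a"] == 7.25

    def test_iterated_updates_match_closed_form(self):
        # oracle: U_n = R + (1 - alpha)^n (U_0 - R)
        u = {"a": 5.0}
        for k in range(10):
            lf.apply_reward([FiringRecord("a", float(k))],
                            RewardEvent(10.0, float(k) + 0.5), self.PARAMS, u)
        assert u["a"] == pytest.approx(10.0 + 0.8**10 * (5.0 - 10.0), abs=1e-12)

    def test_each_rule_updated_once_per_reward(self):
        u = {"a": 5.0, "b": 5.0}
        log = [FiringRecord("a", 0.0), FiringRecord("b", 0.1),
               FiringRecord("a", 0.2)]
        lf.apply_reward(log, RewardEvent(10.0, 1.0), self.PARAMS, u)
        assert u["a"] == pytest.approx(6.0) and u["b"] == pytest.approx(6.0)

    def test_time_discount_subtracts_elapsed(self):
        params = lf.LearningParams(alpha=0.5, time_discount_in_propagation=True)
        u = {"a": 0.0}
        lf.apply_reward([FiringRecord("a", 1.0)], RewardEvent(10.0, 3.0), params, u)
        assert u["a"] == pytest.approx(0.5 * (10.0 - 2.0))

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=40),
           st.floats(0.0, 10.0))
    def test_utilities_stay_in_reward_range(self, rewards, u0):
        # invariant: rewards in [0, R_max] and U_0 in range keep U in range
        u = {"a": u0}
        for k, r in enumerate(rewards):
            lf.apply_reward([FiringRecord("a", float(k))],
                            RewardEvent(r, float(k)),
                            lf.LearningParams(alpha=0.2), u)
            assert 0.0 <= u["a"] <= 10.0


class _Recorder:
    """Fake scheduler + environment for exercising the motor module."""

    def __init__(self):
        self.events = []     # (t_units, prio, kind, data)
        self.completed = []  # (t_units, kind, key)

    def schedule(self, t, prio, kind, data):
        self.events.append((t, prio, kind, data))

    def on_complete(self, t, kind, key):
        self.completed.append((t, kind, key))

    def deliver_all(self):
        while self.events:
            t, prio, kind, (module, data) = self.events.pop(0)
            module.complete(t, data)


class TestMotorModule:
    def _module(self):
        rec = _Recorder()
        mod = MotorModule(lf.MotorParams(), rec.schedule, rec.on_complete)
        return mod, rec

    def test_first_movement_takes_prep_plus_exec(self):
        mod, rec = self._module()
        mod.request(0, "press", "left")
        (t, prio, kind, data), = rec.events
        assert t == seconds_to_units(0.050 + 0.100)

    def test_repeated_movement_skips_preparation(self):
        mod, rec = self._module()
        mod.request(0, "press", "left")
        rec.deliver_all()
        mod.request(1200, "press", "left")
        t = rec.events[-1][0]
        assert t == 1200 + seconds_to_units(0.100)

    def test_requests_queue_never_drop(self):
        mod, rec = self._module()
        mod.request(0, "press", "left")      # busy until 180 units
        mod.request(60, "release", "left")   # queued behind the press
        rec.deliver_all()
        assert [(k, key) for _, k, key in rec.completed] == [
            ("press", "left"), ("release", "left")
        ]
        # second movement starts only at the first one's completion
        assert rec.completed[1][0] == 180 + seconds_to_units(0.050 + 0.100)

    def test_target_keys_reflect_queued_requests(self):
        mod, rec = self._module()
        mod.request(0, "press", "left")
        assert "left" in mod.target_keys  # in flight but already intended
        mod.request(0, "release", "left")
        assert "left" not in mod.target_keys

    def test_idle_flag(self):
        mod, rec = self._module()
        assert mod.idle
        mod.request(0, "press", "space")
        assert not mod.idle
        rec.deliver_all()
        assert mod.idle


class TestTemporalModule:
    def test_noiseless_returns_true_elapsed(self):
        tm = TemporalModule(lf.TemporalParams())
        tm.start(1.0)
        assert tm.estimate(1.5) == pytest.approx(0.5)
        assert tm.estimate(1.0) == 0.0

    def test_unstarted_timer_errors(self):
        tm = TemporalModule(lf.TemporalParams())
        with pytest.raises(lf.EngineError):
            tm.estimate(1.0)

    def test_tick_mode_sums_whole_geometric_ticks(self):
        # oracle: sum 0.011 * 1.1^k of whole ticks fitting in the interval
        tm = TemporalModule(
            lf.TemporalParams(noiseless=False, start_tick=0.011,
                              multiplier=1.1, noise_b=0.0)
        )
        tm.start(0.0)
        elapsed = 0.1
        total, tick = 0.0, 0.011
        while total + tick <= elapsed:
            total += tick
            tick *= 1.1
        assert tm.estimate(elapsed) == pytest.approx(total, abs=1e-12)

    def test_tick_estimate_close_to_elapsed(self, rng):
        tm = TemporalModule(lf.TemporalParams(noiseless=False))
        tm.start(0.0)
        est = tm.estimate(2.0, rng)
        assert 1.5 < est <= 2.0


class TestProductionSet:
    def test_duplicate_names_rejected(self):
        with pytest.raises(lf.EngineError):
            lf.ProductionSet(_prods(5.0) + _prods(5.0))

    def test_utility_view_aliases_rules(self):
        pset = lf.ProductionSet(
            [lf.Production("a", "x", lambda s: True, None, 5.0)]
        )
        pset.utilities["a"] = 7.0
        assert pset["a"].utility == 7.0
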