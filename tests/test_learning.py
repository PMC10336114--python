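"""Input/output schedule, window judgement, reward/punishment and the engine."""

import numpy as np
import pytest

from cocosim import Config, Engine, IOSchedule, apply_outcome, evaluate_io, inject_input
from cocosim.experiments import _build
from cocosim.learning import Outcome
from cocosim.selection import ActiveState

from conftest import make_toy_population


def state(members, t=0, scores=None):
    s = ActiveState(time=t, members=list(members))
    if scores:
        s.seat_scores = dict(scores)
    return s


class TestIOSchedule:
    def test_default_task_shape(self):
        sched = IOSchedule()
        assert len(sched.input_cycle) == len(sched.output_cycle) == 5
        assert sched.cycle_length == 15

    def test_mismatched_cycles_rejected(self):
        with pytest.raises(ValueError):
            IOSchedule(input_cycle=(1, 2), output_cycle=(1000,))

    def test_window_is_three_states(self):
        with pytest.raises(ValueError):
            IOSchedule(window=2)

    @pytest.mark.parametrize("t,is_input,pos", [(1, True, 0), (2, False, 0), (4, True, 1), (16, True, 0)])
    def test_input_step_and_cycle_position(self, t, is_input, pos):
        sched = IOSchedule()
        assert sched.is_input_step(t) is is_input
        if is_input:
            assert sched.cycle_pos(t) == pos


class TestInjectInput:
    def test_input_replaces_lowest_scoring_member(self):
        st = state([4, 5, 6], scores={4: 3.0, 5: 1.0, 6: 2.0})
        inject_input(st, 1, valid_inputs=(1, 2, 3))
        assert 1 in st.members and 5 not in st.members
        assert 1 in st.forced

    def test_injecting_present_member_is_idempotent(self):
        st = state([1, 5, 6], scores={1: 3.0, 5: 1.0, 6: 2.0})
        inject_input(st, 1, valid_inputs=(1, 2, 3))
        assert st.members == [1, 5, 6] and 1 in st.forced

    def test_non_input_address_rejected(self):
        with pytest.raises(ValueError):
            inject_input(state([4, 5, 6]), 500, valid_inputs=(1, 2, 3))


class TestEvaluateIO:
    def _win(self, *memberships):
        return [state(m, t=i) for i, m in enumerate(memberships)]

    def test_expected_output_anywhere_in_window_rewards(self, rng):
        win = self._win([1, 5, 6], [7, 8, 9], [1000, 11, 12])
        out = evaluate_io(win, 0, IOSchedule(), rng)
        assert out.kind == "reward" and out.forced_output is None

    def test_wrong_output_present_punishes_without_forcing(self, rng):
        win = self._win([1, 5, 6], [999, 8, 9], [10, 11, 12])
        out = evaluate_io(win, 0, IOSchedule(), rng)  # expected 1000
        assert out.kind == "punish" and out.forced_output is None

    def test_no_output_forces_one_into_last_state(self, rng):
        win = self._win([1, 5, 6], [7, 8, 9], [10, 11, 12])
        out = evaluate_io(win, 0, IOSchedule(), rng)
        assert out.forced_output in (998, 999, 1000)
        assert out.forced_output in win[-1].members

    def test_forced_output_matching_expectation_rewards(self):
        # drive the rng until each possible forced output occurs; judging must
        # match the forced address against the expectation
        kinds = set()
        for s in range(30):
            win = self._win([1, 5, 6], [7, 8, 9], [10, 11, 12])
            out = evaluate_io(win, 0, IOSchedule(), np.random.default_rng(s))
            kinds.add((out.forced_output == 1000, out.kind))
        assert (True, "reward") in kinds and (False, "punish") in kinds

    def test_malformed_window_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_io(self._win([1], [2]), 0, IOSchedule(), rng)


class TestApplyOutcome:
    def test_rewarded_pair_gains_one_occurrence(self):
        pop = make_toy_population({}, n=6)
        win = [state([1, 2], t=0), state([3, 4], t=1), state([5, 6], t=2)]
        apply_outcome(Outcome("reward", win), pop)
        assert pop[1].now_field.count(2) == 1
        assert pop[1].next_field.count(3) == 1  # cross-step pair
        assert pop[3].next_field.count(5) == 1

    def test_punishing_absent_pair_is_noop(self):
        pop = make_toy_population({}, n=6)
        win = [state([1, 2], t=0), state([3, 4], t=1), state([5, 6], t=2)]
        apply_outcome(Outcome("punish", win), pop)
        assert pop[1].now_field.total == 0

    def test_reward_then_punish_restores_occurrence_counts(self):
        pop = make_toy_population({1: ({2: 3}, {3: 2})}, n=6)
        win = [state([1, 2], t=0), state([3, 4], t=1), state([5, 6], t=2)]
        before = {a: (dict(pop[a].now_field.occurrences), dict(pop[a].next_field.occurrences)) for a in pop}
        apply_outcome(Outcome("reward", win), pop)
        apply_outcome(Outcome("punish", win), pop)
        after = {a: (dict(pop[a].now_field.occurrences), dict(pop[a].next_field.occurrences)) for a in pop}
        assert before == after

    def test_fixed_ppdp_fields_untouched(self):
        pop = make_toy_population({}, n=6)
        pop[1].now_field.fixed = True
        pop[1].now_field.occurrences = {5: 2}
        pop[1].now_field.capacity = 1
        win = [state([1, 2], t=0), state([1, 3], t=1), state([2, 4], t=2)]
        pop[1].downtime_exempt = True
        apply_outcome(Outcome("reward", win), pop)
        assert pop[1].now_field.occurrences == {5: 2}
        assert pop[1].now_field.capacity == 1

    def test_capacity_growth_capped_at_eight(self):
        pop = make_toy_population({}, n=6)
        win = [state([1, 2], t=0), state([3, 4], t=1), state([5, 6], t=2)]
        for _ in range(12):
            apply_outcome(Outcome("reward", win), pop)
        assert all(pop[a].now_field.capacity <= 8 for a in pop)

    def test_capacity_shrink_floors_at_one(self):
        pop = make_toy_population({}, n=6)
        win = [state([1, 2], t=0), state([3, 4], t=1), state([5, 6], t=2)]
        for _ in range(5):
            apply_outcome(Outcome("punish", win), pop)
        assert all(pop[a].now_field.capacity >= 1 for a in pop)

    def test_entering_transition_learned_with_window(self):
        pop = make_toy_population({}, n=6)
        entering = state([5, 6], t=0)
        win = [state([1, 2], t=1), state([3, 4], t=2), state([5, 6], t=3)]
        apply_outcome(Outcome("reward", win, entering_state=entering), pop)
        assert pop[5].next_field.count(1) == 1


class TestEngine:
    def test_free_run_conserves_connectivity_exactly(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=0)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        fp = pop.connectivity_fingerprint()
        eng.run(60, mode="free_run")
        assert pop.connectivity_fingerprint() == fp

    def test_learning_mode_seats_scheduled_input(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=0)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        st, _ = eng.step("learning")  # t=1 is an input step (input 1)
        assert 1 in st.members and 1 in st.forced

    def test_no_outcome_between_windows(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=0)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        _, out1 = eng.step("learning")  # t=1
        _, out2 = eng.step("learning")  # t=2
        _, out3 = eng.step("learning")  # t=3 closes the window
        assert out1 is None and out2 is None and out3 is not None

    def test_capacity_bounds_maintained_through_learning(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=1)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        eng.run(150, mode="learning")
        for a in pop:
            for fld in (pop[a].now_field, pop[a].next_field):
                if not fld.fixed:
                    assert 1 <= fld.capacity <= 8
                    assert fld.distinct <= fld.capacity

    def test_no_consecutive_membership_without_exemption(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=2)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        eng.run(100, mode="learning")
        for s1, s2 in zip(eng.trace.states, eng.trace.states[1:]):
            for a in set(s1.members) & set(s2.members):
                assert pop[a].downtime_exempt or a in s2.forced

    def test_guaranteed_element_in_every_state(self, config):
        pop, rng = _build(config, with_ppdp=True, seed=3)
        eng = Engine(pop, config, rng)
        eng.seed_state()
        eng.run(80, mode="learning")
        for s in eng.trace.states[1:]:
            assert 10 in s.members


def test_learning_signal_improves_in_the_long_run():
    """Across seeds, the clean-window (rewarded, unforced) rate late in the
    run should not fall below the early exploratory rate for a majority."""
    improved = 0
    seeds = range(1, 6)
    for seed in seeds:
        cfg = Config(max_steps=2400)
        pop, rng = _build(cfg, with_ppdp=True, seed=seed)
        eng = Engine(pop, cfg, rng)
        eng.seed_state()
        clean = []
        while eng.t < cfg.max_steps and not eng.converged:
            _, out = eng.step("learning")
            if out is not None:
                clean.append(out.kind == "reward" and out.forced_output is None)
        early = np.mean(clean[:150])
        late = np.mean(clean[-150:])
        improved += late >= early
    assert improved > len(seeds) / 2
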