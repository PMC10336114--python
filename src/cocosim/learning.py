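"""Input/output schedule, reward/punishment learning, and the step engine.

The task is a repeating cycle of scheduled environmental inputs, each of
which must be answered by its paired output address within a three-state
window (the input state and the following two).  When the window closes it
is judged:

* if no output address appeared anywhere in the window, a uniformly random
  output address is first forced into the last state — so that the window
  can be judged (and its elements rewarded or punished) like any other;
* the window is **rewarded** when the expected output address is present
  (naturally or by forcing) and **punished** otherwise.

Reward adds one occurrence of every co-active partner to each member's
*Now* field, one occurrence of every member of the following state to each
member's *Next* field, and grows every participating learnable field's
capacity by one (max 8).  Punishment is the mirror image: occurrences are
removed (floored at zero) and capacities shrink (min 1), evicting excess
distinct addresses lowest-multiplicity-first.  Fixed (PPDP) fields are
exempt from all of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .config import Config
from .core_state import Address, Population
from .selection import GUARANTEED, ActiveState, select_next_state
from .trace import Trace


@dataclass(frozen=True)
class IOSchedule:
    input_cycle: tuple[Address, ...] = (1, 2, 3, 2, 3)
    output_cycle: tuple[Address, ...] = (1000, 999, 999, 1000, 998)
    period: int = 3
    window: int = 3

    def __post_init__(self) -> None:
        if len(self.input_cycle) != len(self.output_cycle):
            raise ValueError("input_cycle and output_cycle lengths differ")
        if self.window != 3:
            raise ValueError("the response window is three states")
        if self.period < self.window:
            raise ValueError("period must be >= window (windows must not overlap)")

    @classmethod
    def from_config(cls, config: Config) -> "IOSchedule":
        return cls(config.input_cycle, config.output_cycle, config.input_period, config.io_window)

    @property
    def cycle_length(self) -> int:
        return self.period * len(self.input_cycle)

    def is_input_step(self, t: int, start: int = 1) -> bool:
        return t >= start and (t - start) % self.period == 0

    def cycle_pos(self, t: int, start: int = 1) -> int:
        return ((t - start) // self.period) % len(self.input_cycle)


@dataclass
class Outcome:
    kind: Literal["reward", "punish"]
    window_states: list[ActiveState]
    forced_output: Address | None = None
    cycle_pos: int = 0
    entering_state: ActiveState | None = None  # state preceding the window
    expected_output: Address | None = None
    wrong_outputs: frozenset[Address] = frozenset()


def _force_member(state: ActiveState, address: Address) -> None:
    """Seat ``address`` in ``state``, evicting the lowest-scoring member that
    is neither forced nor seat-guaranteed; no-op (bar flagging) if present."""
    if address in state.members:
        state.forced.add(address)
        return
    evictable = [
        m
        for m in state.members
        if m not in state.forced and state.seat_scores.get(m, 0.0) != GUARANTEED
    ]
    if not evictable:
        raise ValueError(f"no evictable member in state at t={state.time}")
    victim = min(evictable, key=lambda m: (state.seat_scores.get(m, 0.0), -m))
    idx = state.members.index(victim)
    state.members[idx] = address
    state.seat_scores.pop(victim, None)
    state.seat_scores[address] = 0.0
    state.forced.add(address)


def inject_input(state: ActiveState, input_addr: Address, valid_inputs) -> ActiveState:
    """Insert a scheduled environmental input into a state (mutating it).

    The input replaces the lowest-scoring non-forced member; if it is
    already a member only the forced flag is set.
    """
    if input_addr not in valid_inputs:
        raise ValueError(f"{input_addr} is not an input address {tuple(valid_inputs)}")
    _force_member(state, input_addr)
    return state


def evaluate_io(
    window_states: list[ActiveState],
    cycle_pos: int,
    schedule: IOSchedule,
    rng,
    output_addresses: tuple[Address, ...] = (998, 999, 1000),
) -> Outcome:
    """Judge a closed three-state window, forcing an output if none appeared.

    Mutates the final window state when forcing occurs; the caller must then
    re-commit activity bookkeeping for the forced address.
    """
    if len(window_states) != schedule.window:
        raise ValueError(f"window must hold {schedule.window} states, got {len(window_states)}")
    expected = schedule.output_cycle[cycle_pos]
    present: set[Address] = set()
    for s in window_states:
        present |= s.member_set()
    forced_output: Address | None = None
    if not (present & set(output_addresses)):
        forced_output = int(output_addresses[int(rng.integers(len(output_addresses)))])
        _force_member(window_states[-1], forced_output)
        present.add(forced_output)
    kind: Literal["reward", "punish"] = "reward" if expected in present else "punish"
    return Outcome(
        kind=kind,
        window_states=list(window_states),
        forced_output=forced_output,
        cycle_pos=cycle_pos,
        expected_output=expected,
        wrong_outputs=frozenset((present & set(output_addresses)) - {expected}),
    )


def apply_outcome(
    outcome: Outcome,
    pop: Population,
    increment: int = 1,
    capacity_step: int = 1,
    cap_min: int = 1,
    cap_max: int = 8,
) -> Population:
    """Apply the reward/punishment connectivity update for one window.

    Reward: +``increment`` occurrences for every ordered co-active pair
    (Now) and every cross-step pair (Next), capacities +``capacity_step``
    (max ``cap_max``).  Punish: the mirror removals, capacities
    -``capacity_step`` (min ``cap_min``) with lowest-multiplicity eviction.
    Fixed fields untouched.  Mutates and returns ``pop``.
    """
    states = outcome.window_states
    participants = set()
    for s in states:
        participants |= s.member_set()
    reward = outcome.kind == "reward"

    if reward:
        # grow capacities first so fresh connections have room
        for a in participants:
            for fld in (pop[a].now_field, pop[a].next_field):
                if not fld.fixed:
                    fld.capacity = min(fld.capacity + capacity_step, cap_max)

    def _update(fld, y: Address) -> None:
        fld.add(y, increment) if reward else fld.remove(y, increment)

    for s in states:
        for x in s.members:
            fld = pop[x].now_field
            for y in s.members:
                if x != y:
                    _update(fld, y)
    # state-to-state pairs: the transition entering the window is included,
    # so that consecutive windows tile every transition of the sequence
    # exactly once and no Next link escapes the learning signal
    transitions = list(zip(states, states[1:]))
    if outcome.entering_state is not None:
        transitions.insert(0, (outcome.entering_state, states[0]))
    for s1, s2 in transitions:
        for x in s1.members:
            fld = pop[x].next_field
            for y in s2.members:
                if x != y:
                    _update(fld, y)

    if not reward:
        # capacity shrink clamps future growth but never evicts surviving
        # content: punishment already removed the co-active occurrences, and
        # evicting unrelated links as well makes the reward signal unlearnable
        # (every freshly rewarded output link would be the lowest-multiplicity
        # entry and die in the next punished window).
        for a in participants:
            for fld in (pop[a].now_field, pop[a].next_field):
                if not fld.fixed:
                    fld.capacity = max(fld.capacity - capacity_step, fld.distinct, cap_min)
    return pop


class Engine:
    """Drives the simulation one state at a time.

    ``mode='learning'`` runs the full loop: selection, scheduled input
    injection, window judgement and the connectivity update.  In
    ``mode='free_run'`` only selection happens — no inputs, no outputs, no
    learning — so the connectivity is conserved exactly.
    """

    def __init__(
        self,
        pop: Population,
        config: Config,
        rng: np.random.Generator,
        schedule: IOSchedule | None = None,
        input_start: int = 1,
    ):
        self.pop = pop
        self.cfg = config
        self.rng = rng
        self.schedule = schedule or IOSchedule.from_config(config)
        self.input_start = input_start
        self.active_size = config.active_size
        self.trace = Trace(config_snapshot=config.to_dict())
        self.t = -1
        self._window_results: list[bool] = []  # rewarded-without-forcing flags
        self.converged = False
        self.convergence_step: int | None = None

    # -- initial state ---------------------------------------------------
    def seed_state(self, members: list[Address] | None = None) -> ActiveState:
        """Install the state at t=0.

        By default the members are drawn at random from the initially
        *connected* elements (the structured groups): a phenotype state is a
        set of interacting factors, so the run starts inside the connected
        fabric rather than among unengaged elements.
        """
        if members is None:
            pool = sorted(
                a
                for a, e in self.pop.elements.items()
                if e.now_field.occurrences or e.next_field.occurrences
            ) or sorted(self.pop.elements)
            idx = self.rng.choice(len(pool), size=self.active_size, replace=False)
            members = [pool[int(i)] for i in sorted(idx)]
        state = ActiveState(time=0, members=list(members))
        self.trace.append(state)
        self.pop.mark_active(state.members, 0)
        self.t = 0
        return state

    @property
    def current(self) -> ActiveState:
        return self.trace.states[-1]

    def overwrite_state(self, members: list[Address], note: str = "") -> ActiveState:
        """Replace the current state's membership wholesale (perturbations)."""
        state = self.current
        state.members = list(members)
        state.forced = set(members)
        state.seat_scores = {m: 0.0 for m in members}
        self.pop.mark_active(members, state.time)
        self.trace.log(state.time, "overwrite", tuple(members), note)
        return state

    # -- stepping --------------------------------------------------------
    def step(self, mode: Literal["learning", "free_run"] = "learning"):
        """Advance one time step; returns ``(state, outcome_or_None)``."""
        t = self.t + 1
        preseat: list[Address] | None = None
        if mode == "learning" and self.schedule.is_input_step(t, self.input_start):
            pos = self.schedule.cycle_pos(t, self.input_start)
            addr = self.schedule.input_cycle[pos]
            if addr not in self.pop.input_addresses:
                raise ValueError(f"scheduled input {addr} is not an input address")
            preseat = [addr]
        state = select_next_state(
            self.current, self.pop, t, self.rng, size=self.active_size, preseat=preseat
        )
        outcome = None
        if preseat:
            self.trace.log(t, "input", tuple(preseat), f"pos={self.schedule.cycle_pos(t, self.input_start)}")
        self.trace.append(state)
        self.pop.mark_active(state.members, t)
        self.t = t

        if mode == "learning":
            outcome = self._maybe_close_window(t)
        return state, outcome

    def _maybe_close_window(self, t: int):
        w = self.schedule.window
        t_in = t - (w - 1)
        if len(self.trace.states) < w:
            return None
        if not self.schedule.is_input_step(t_in, self.input_start) or t_in < self.input_start:
            return None
        pos = self.schedule.cycle_pos(t_in, self.input_start)
        window = self.trace.states[-w:]
        entering = self.trace.states[-(w + 1)] if len(self.trace.states) > w else None
        expected = self.schedule.output_cycle[pos]
        naturally_seen = {m for s in window for m in s.members} & set(self.pop.output_addresses)
        outcome = evaluate_io(window, pos, self.schedule, self.rng, self.pop.output_addresses)
        outcome.entering_state = entering
        if outcome.forced_output is not None:
            self.pop.mark_active([outcome.forced_output], t)
            self.trace.log(t, "forced_output", (outcome.forced_output,))
        elif naturally_seen:
            self.trace.log(t, "output_seen", tuple(sorted(naturally_seen)))
        apply_outcome(
            outcome,
            self.pop,
            self.cfg.reward_increment,
            self.cfg.capacity_step,
            self.cfg.field_cap_min,
            self.cfg.field_cap_max,
        )
        self.trace.log(t, outcome.kind, (expected,), f"pos={pos}")
        self._track_convergence(outcome, t)
        return outcome

    def _track_convergence(self, outcome: Outcome, t: int) -> None:
        clean = outcome.kind == "reward" and outcome.forced_output is None
        self._window_results.append(clean)
        need = self.cfg.convergence_cycles * len(self.schedule.input_cycle)
        if not self.converged and len(self._window_results) >= need and all(
            self._window_results[-need:]
        ):
            self.converged = True
            self.convergence_step = t
            self.trace.log(t, "converged")

    def run(self, until: int, mode: Literal["learning", "free_run"] = "learning") -> None:
        """Step until ``self.t == until`` (inclusive)."""
        while self.t < until:
            self.step(mode)


def run_step(
    t: int,
    pop: Population,
    prev_state: ActiveState,
    schedule: IOSchedule,
    mode: Literal["learning", "free_run"],
    rng,
    config: Config | None = None,
):
    """One-shot functional wrapper around :class:`Engine` for a single step.

    Builds a throwaway engine positioned after ``prev_state`` and advances
    it once; window judgement only fires when the step closes a window of
    states the caller has supplied through ``prev_state``'s trace context,
    so for multi-step runs prefer driving an :class:`Engine` directly.
    """
    cfg = config or Config()
    eng = Engine(pop, cfg, rng, schedule)
    eng.trace.states.append(prev_state)
    eng.t = prev_state.time
    eng.active_size = len(prev_state.members)
    if t != prev_state.time + 1:
        raise ValueError(f"run_step expects t == prev_state.time + 1, got {t}")
    return eng.step(mode)
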