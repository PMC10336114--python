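"""End-to-end experiment protocols and their summary metrics.

Four protocols, all reproducible bit-exactly per seed:

``run_learning``
    Learn the input/output task, with or without the PPDP hub, and measure
    how strongly the post-learning states are *restricted* to the PPDP's
    partner range.

``run_perturbation``
    Learn, freeze the connectivity (free run), then at a fixed step double
    the Active-subset size and overwrite one state with addresses from
    outside the learnt sequence.  The overlap between the learnt membership
    and a late post-perturbation window measures how well the phenotype
    trajectory survived.

``run_second_ppdp``
    Learn with the first PPDP, graft a mimicking second PPDP network onto
    never-active elements and introduce it (the learnt sequence is lost);
    optionally silence the second PPDP and force one scheduled input, and
    test whether the learnt membership recovers.

Metrics: ``restriction_fraction`` (fraction of non-excluded seats inside an
allowed address set) and ``state_overlap`` (Jaccard index between the
learnt membership and the union of a trailing window of states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config
from .core_state import Address, Population, init_population
from .learning import Engine, inject_input
from .ppdp import graft_pattern, make_ppdp, record_pattern, silence_ppdp
from .selection import naive_pool
from .trace import Trace

__all__ = [
    "ExperimentReport",
    "run_learning",
    "run_perturbation",
    "run_second_ppdp",
    "restriction_fraction",
    "state_overlap",
]


@dataclass
class ExperimentReport:
    """Summary of one experiment run."""

    seed: int
    converged: bool = False
    convergence_step: int | None = None
    restriction: float | None = None
    overlap_pre_post: float | None = None
    overlap_final: float | None = None
    recovered: bool | None = None
    second_ppdp_address: Address | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def restriction_fraction(
    trace: Trace, allowed: set[Address], exclude: set[Address], window: int
) -> float:
    """Fraction of seated addresses (excluding ``exclude``) inside ``allowed``
    over the last ``window`` states."""
    states = trace.last_states(window)  # raises if window > len(trace)
    seats = [m for s in states for m in s.members if m not in exclude]
    if not seats:
        raise ValueError("all seats excluded; restriction undefined")
    return sum(1 for m in seats if m in allowed) / len(seats)


def state_overlap(
    reference: set[Address],
    trace: Trace,
    window: int,
    start: int | None = None,
) -> float:
    """Fraction of the reference membership re-observed in a window of states
    (containment overlap).

    The window is the ``window`` states starting at time ``start`` (or the
    trailing ``window`` states when ``start`` is None).  Containment rather
    than a symmetric set index is used because a perturbation that doubles
    the Active-subset size necessarily adds members a symmetric index would
    punish even under perfect preservation of the learnt membership.
    """
    if not reference:
        raise ValueError("reference membership is empty")
    if start is None:
        observed = trace.members_union(window)
    else:
        states = trace.states_between(start, start + window)
        if not states:
            raise ValueError(f"no states in window [{start}, {start + window})")
        observed = set()
        for s in states:
            observed |= s.member_set()
    return len(reference & observed) / len(reference)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _rngs(seed: int) -> tuple[int, np.random.Generator]:
    """Derive the population seed and the dynamics generator from one seed."""
    ss = np.random.SeedSequence([int(seed), 0xC0C0])
    pop_seed = int(ss.generate_state(1)[0] % (2**31))
    return pop_seed, np.random.default_rng(ss.spawn(1)[0])


def _build(config: Config, with_ppdp: bool, seed: int) -> tuple[Population, np.random.Generator]:
    pop_seed, rng = _rngs(seed)
    pop = init_population(config, pop_seed)
    if with_ppdp:
        for spec in config.ppdp:
            make_ppdp(spec, pop)
    return pop, rng


def _learn_until(eng: Engine, cutoff: int) -> None:
    """Learning mode until convergence or ``cutoff`` steps."""
    while eng.t < cutoff and not eng.converged:
        eng.step("learning")


def _learnt_reference(eng: Engine, config: Config) -> set[Address]:
    """Membership of the learnt trajectory: the union of members over the
    final full task cycle."""
    return eng.trace.members_union(config.cycle_length)


def _never_input_one_step(eng: Engine, after: int) -> int:
    """First step > ``after`` where the schedule would present input 1."""
    t = after + 1
    sched = eng.schedule
    while not (sched.is_input_step(t, eng.input_start) and sched.cycle_pos(t, eng.input_start) == 0):
        t += 1
    return t


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def run_learning(
    config: Config, with_ppdp: bool, seed: int
) -> tuple[Trace, ExperimentReport]:
    """Learn the task; measure restriction to the PPDP partner range."""
    report = ExperimentReport(seed=seed)
    pop, rng = _build(config, with_ppdp, seed)
    eng = Engine(pop, config, rng)
    if config.max_steps <= 0:
        return eng.trace, report
    eng.seed_state()
    _learn_until(eng, config.max_steps)
    report.converged = eng.converged
    report.convergence_step = eng.convergence_step

    window = min(config.post_window, len(eng.trace))
    allowed = config.ppdp_field_union()
    exclude = set(config.inputs) | set(config.outputs) | config.ppdp_addresses()
    report.restriction = restriction_fraction(eng.trace, allowed, exclude, window)
    return eng.trace, report


def run_perturbation(config: Config, with_ppdp: bool, seed: int) -> ExperimentReport:
    """Subset-size doubling plus state overwrite; measure trajectory survival."""
    report = ExperimentReport(seed=seed)
    pop, rng = _build(config, with_ppdp, seed)
    eng = Engine(pop, config, rng)
    eng.seed_state()
    _learn_until(eng, config.learning_cutoff_step)
    report.converged = eng.converged
    report.convergence_step = eng.convergence_step

    # the learnt phenotype keeps cycling without selection pressure
    eng.run(config.perturbation_step - 1, mode="free_run")
    reference = _learnt_reference(eng, config)

    # perturbation 1: the Active subset doubles from this step on
    eng.active_size = 2 * config.active_size
    eng.step("free_run")

    # perturbation 2: overwrite the next would-be input-1 state with
    # addresses from outside the learnt sequence
    t_overwrite = _never_input_one_step(eng, eng.t)
    eng.run(t_overwrite, mode="free_run")
    # inactive elements: naive (never-active, unconnected) ones where
    # possible, otherwise anything outside the learnt membership
    outside = naive_pool(pop) or [a for a in sorted(pop.elements) if a not in reference]
    outside = [a for a in outside if a not in reference]
    idx = rng.choice(len(outside), size=eng.active_size, replace=False)
    eng.overwrite_state([outside[int(i)] for i in idx], note="perturbation")

    eng.run(min(config.perturb_end_step, t_overwrite + config.post_window), mode="free_run")
    report.overlap_pre_post = state_overlap(
        reference, eng.trace, config.post_window, start=t_overwrite + 1
    )
    return report


def run_second_ppdp(
    config: Config, seed: int, then_remove: bool
) -> ExperimentReport:
    """Graft and introduce a mimicking second PPDP; optionally remove it.

    Disruption is measured as the overlap between the learnt membership and
    the window just before the removal step; recovery (when ``then_remove``)
    as the overlap over the final window of the run.
    """
    report = ExperimentReport(seed=seed)
    pop, rng = _build(config, True, seed)
    eng = Engine(pop, config, rng)
    eng.seed_state()
    _learn_until(eng, config.learning_cutoff_step)
    report.converged = eng.converged
    report.convergence_step = eng.convergence_step

    eng.run(config.graft_step, mode="free_run")
    reference = _learnt_reference(eng, config)

    pattern = record_pattern(eng.trace, pop, k=24)
    _, second = graft_pattern(pattern, pop, rng)
    report.second_ppdp_address = second

    # introduce the second PPDP along with its strongest partners
    eng.run(config.intro_step, mode="free_run")
    partners = _top_partners(pop, second, eng.active_size - 1)
    eng.overwrite_state([second] + partners, note="second-ppdp introduction")

    pre_removal_end = config.silence_step
    eng.run(pre_removal_end - 1, mode="free_run")
    report.overlap_pre_post = state_overlap(reference, eng.trace, config.post_window)

    if then_remove:
        silence_ppdp(second, pop)
        eng.step("free_run")
        # one forced environmental input, once only
        inject_input(eng.current, config.input_cycle[0], pop.input_addresses)
        pop.mark_active([config.input_cycle[0]], eng.t)
        eng.trace.log(eng.t, "input", (config.input_cycle[0],), "forced recovery input")

    eng.run(config.second_end_step, mode="free_run")
    report.overlap_final = state_overlap(reference, eng.trace, config.post_window)
    if then_remove:
        report.recovered = report.overlap_final > 0.8
    return report


def _top_partners(pop: Population, ppdp_addr: Address, k: int) -> list[Address]:
    """The ``k`` addresses with the highest total multiplicity across the
    PPDP's Now and Next fields (ties to the lower address)."""
    el = pop[ppdp_addr]
    totals: dict[Address, int] = {}
    for fld in (el.now_field, el.next_field):
        for a, m in fld.occurrences.items():
            if a != ppdp_addr:
                totals[a] = totals.get(a, 0) + m
    ranked = sorted(totals, key=lambda a: (-totals[a], a))
    return ranked[:k]
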