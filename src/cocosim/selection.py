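"""Coherence-competition selection of successive Active-subset states.

Two integer connectivity scores drive the competition:

* the **Next** score of a candidate is the number of times its address
  occurs in the *Next* fields of the members of the *previous* state
  (state-to-state coherence);
* the **Now** score is the number of times its address occurs in the *Now*
  fields of the members already seated in the *developing* new state
  (within-state coherence).

The first seat goes to the top of the Next ranking; every further seat is
decided by comparing the best remaining Next candidate against the best Now
candidate — the higher score wins, a Next-vs-Now tie goes to the Next
candidate, and score ties within a ranking go to the lower address.  When
every candidate scores zero the seat is filled uniformly at random from the
eligible non-members (exploratory noise).

A ``guaranteed_next`` element (a PPDP) outranks every scored Next candidate;
a ``next_silenced`` element scores zero in the Next ranking no matter what
the fields say.  Downtime makes recently active elements ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .core_state import Address, Population, SimulationError

GUARANTEED = float("inf")


@dataclass
class ActiveState:
    """One state of the Active subset: an ordered set of distinct addresses."""

    time: int
    members: list[Address]
    forced: set[Address] = dc_field(default_factory=set)
    seat_scores: dict[Address, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("ActiveState members must be distinct")

    def __contains__(self, address: Address) -> bool:
        return address in self.members

    def member_set(self) -> set[Address]:
        return set(self.members)


@dataclass
class ScoreTable:
    """Scores plus the ranking they induce.

    ``guaranteed`` members outrank every scored candidate.  Ranking order:
    guaranteed (ascending address), then descending score, ties by
    ascending address.
    """

    scores: dict[Address, int]
    guaranteed: frozenset[Address] = frozenset()

    @property
    def ranking(self) -> list[Address]:
        ranked = sorted(self.scores, key=lambda a: (-self.scores[a], a))
        return sorted(self.guaranteed) + [a for a in ranked if a not in self.guaranteed]

    def effective_score(self, address: Address) -> float:
        if address in self.guaranteed:
            return GUARANTEED
        return self.scores.get(address, 0)

    def top(self, exclude: set[Address] = frozenset()) -> Address | None:
        for a in self.ranking:
            if a not in exclude:
                return a
        return None


def eligible(address: Address, pop: Population, t: int) -> bool:
    """Downtime rule: an element that was active at step s is excluded from
    states s+1 .. s+downtime and becomes eligible again at s+downtime+1."""
    e = pop[address]
    if e.downtime_exempt:
        return True
    last = pop.last_active.get(address)
    if last is None:
        return True
    return t - last > e.downtime


def next_scores(prev: ActiveState, pop: Population, t: int) -> ScoreTable:
    """Next-connectivity scores of all eligible candidates, summed over the
    *Next* fields of the previous state's members."""
    if not prev.members:
        raise SimulationError(f"cannot score step {t}: previous state is empty")
    raw: dict[Address, int] = {}
    for m in prev.members:
        for cand, mult in pop[m].next_field.occurrences.items():
            raw[cand] = raw.get(cand, 0) + mult
    scores: dict[Address, int] = {}
    guaranteed: set[Address] = set()
    for cand, s in raw.items():
        if not eligible(cand, pop, t):
            continue
        scores[cand] = 0 if pop[cand].next_silenced else s
    # guaranteed elements top the ranking whether or not any field names them
    for a, e in pop.elements.items():
        if e.guaranteed_next and eligible(a, pop, t):
            scores.setdefault(a, 0)
            guaranteed.add(a)
    return ScoreTable(scores, frozenset(guaranteed))


def now_scores(developing: list[Address], pop: Population, t: int) -> ScoreTable:
    """Now-connectivity scores over the *Now* fields of the members already
    seated in the developing state (those members are excluded)."""
    if not developing:
        raise SimulationError(f"cannot score step {t}: developing state is empty")
    seated = set(developing)
    scores: dict[Address, int] = {}
    for m in developing:
        for cand, mult in pop[m].now_field.occurrences.items():
            if cand in seated or not eligible(cand, pop, t):
                continue
            scores[cand] = scores.get(cand, 0) + mult
    return ScoreTable(scores)


def naive_pool(pop: Population, exclude: set[Address] = frozenset()) -> list[Address]:
    """Elements that were never active and carry no connections — the
    unengaged regulatory material exploratory noise recruits from."""
    return sorted(
        a
        for a, e in pop.elements.items()
        if a not in exclude
        and a not in pop.last_active
        and not e.now_field.occurrences
        and not e.next_field.occurrences
    )


def _random_eligible(pop: Population, t: int, exclude: set[Address], rng) -> Address:
    """Exploratory noise for all-zero-score seats: drawn uniformly from the
    naive (never-active, unconnected) elements while any remain, otherwise
    from all eligible elements."""
    pool = naive_pool(pop, exclude) or sorted(
        a for a in pop.elements if a not in exclude and eligible(a, pop, t)
    )
    if not pool:
        raise SimulationError(f"step {t}: no eligible elements left to seat")
    return pool[int(rng.integers(len(pool)))]


def select_next_state(
    prev: ActiveState,
    pop: Population,
    t: int,
    rng,
    size: int | None = None,
    preseat: list[Address] | None = None,
) -> ActiveState:
    """Run the ranking competition and return the state at step ``t``.

    ``size`` is the Active-subset size in force at ``t`` (defaults to the
    previous state's size).  ``preseat`` members (forced environmental
    inputs) are seated before the competition starts, so the rest of the
    state develops around them.  Deterministic given the population,
    previous state and RNG state.  Does **not** update ``pop.last_active``;
    the caller commits activity once forced insertions are resolved.
    """
    s = size if size is not None else len(prev.members)
    nxt = next_scores(prev, pop, t)
    members: list[Address] = []
    seat_scores: dict[Address, float] = {}
    forced: set[Address] = set()
    for a in preseat or ():
        if a not in members:
            members.append(a)
            seat_scores[a] = 0.0
            forced.add(a)

    while len(members) < s:
        seated_set = set(members)
        ncand = nxt.top(exclude=seated_set)
        nscore = nxt.effective_score(ncand) if ncand is not None else -1.0
        wcand: Address | None = None
        wscore = -1.0
        if members:
            now_tab = now_scores(members, pop, t)
            wcand = now_tab.top(exclude=seated_set)
            if wcand is not None:
                wscore = now_tab.effective_score(wcand)
        best = max(nscore, wscore)
        if best <= 0:
            pick = _random_eligible(pop, t, seated_set, rng)
            members.append(pick)
            seat_scores[pick] = 0.0
        elif nscore >= wscore:  # Next wins ties
            members.append(ncand)  # type: ignore[arg-type]
            seat_scores[ncand] = nscore  # type: ignore[index]
        else:
            members.append(wcand)  # type: ignore[arg-type]
            seat_scores[wcand] = wscore  # type: ignore[index]

    return ActiveState(time=t, members=members, forced=forced, seat_scores=seat_scores)
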