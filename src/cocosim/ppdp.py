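"""Phenotype-preserving disordered protein (PPDP) elements.

A PPDP models a stable, highly connected intrinsically disordered protein:
zero Downtime (stable, so it can sit in consecutive states), a guaranteed
top rank in the Next competition, and large *fixed* Now/Next fields (its
many binding partners) that reward and punishment cannot touch.

A *second* PPDP is built by recording the connectivity pattern among the
recently active elements and mimicking it — through an address bijection —
onto elements that were never active, then designating the image of the
first PPDP as the new hub.  Silencing a PPDP zeroes its Next score without
touching its fields, so its network can still pull it in via Now
connections.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .config import ConfigurationError, PpdpSpec
from .core_state import Address, ConnectionField, FieldKind, Population
from .trace import Trace

__all__ = [
    "PpdpSpec",
    "ConnectivityPattern",
    "make_ppdp",
    "record_pattern",
    "graft_pattern",
    "silence_ppdp",
]


@dataclass
class ConnectivityPattern:
    """Field-occurrence pairs among a roster of recently active elements."""

    pairs: Counter  # (source, target, field_kind) -> multiplicity
    element_roster: tuple[Address, ...]

    def __post_init__(self) -> None:
        roster = set(self.element_roster)
        for (src, tgt, _kind), mult in self.pairs.items():
            if src not in roster or tgt not in roster:
                raise ValueError(f"pair ({src},{tgt}) outside roster")
            if mult < 1:
                raise ValueError("pair multiplicities must be >= 1")


def make_ppdp(spec: PpdpSpec, pop: Population) -> Population:
    """Turn ``pop[spec.address]`` into a PPDP (mutates and returns pop)."""
    if spec.address not in pop.elements:
        raise ConfigurationError(f"PPDP address {spec.address} not in population")
    n = pop.n
    for lo, hi in (spec.now_range, spec.next_range):
        if lo < 1 or hi > n:
            raise ConfigurationError(f"PPDP field range {lo}..{hi} outside 1..{n}")
    e = pop[spec.address]
    now = {a: spec.multiplicity for a in spec.now_addresses()}
    nxt = {a: spec.multiplicity for a in spec.next_addresses()}
    e.now_field = ConnectionField(now, capacity=len(now), fixed=True)
    e.next_field = ConnectionField(nxt, capacity=len(nxt), fixed=True)
    e.downtime_exempt = True
    e.guaranteed_next = True
    e.next_silenced = False
    return pop


def record_pattern(trace: Trace, pop: Population, k: int = 24) -> ConnectivityPattern:
    """Record the connectivity among elements active in the last ``k`` states.

    The roster is the union of members over those states; pairs are the
    current field occurrences restricted to source and target both in the
    roster.
    """
    if len(trace) < k:
        raise ValueError(f"trace has {len(trace)} states, need at least {k}")
    roster = sorted(trace.members_union(k))
    roster_set = set(roster)
    pairs: Counter = Counter()
    for src in roster:
        el = pop[src]
        for kind in ("now", "next"):
            for tgt, mult in el.field(kind).occurrences.items():  # type: ignore[arg-type]
                if tgt in roster_set:
                    pairs[(src, tgt, kind)] = mult
    return ConnectivityPattern(pairs=pairs, element_roster=tuple(roster))


def graft_pattern(
    pattern: ConnectivityPattern, pop: Population, rng
) -> tuple[Population, Address]:
    """Mimic ``pattern`` onto never-active elements; returns the second PPDP.

    A random bijection maps each roster address to a distinct never-active
    host; every pattern pair is copied through it.  Hosts become
    downtime-exempt (they were never consumed by the learnt trajectory and
    model factors of a competing phenotype that are not yet turned over);
    the host mapped from the first PPDP inherits its guaranteed Next rank
    and fixed fields.
    """
    if not pattern.pairs:
        raise ValueError("cannot graft an empty connectivity pattern")
    primaries = [a for a in pattern.element_roster if pop[a].guaranteed_next]
    if not primaries:
        raise ValueError("pattern roster contains no PPDP to mirror")
    primary = primaries[0]

    io = set(pop.input_addresses) | set(pop.output_addresses)
    pool = [a for a in pop.never_active() if a not in io]
    roster = list(pattern.element_roster)
    if len(pool) < len(roster):
        raise ValueError(
            f"only {len(pool)} never-active elements for a roster of {len(roster)}"
        )
    idx = rng.choice(len(pool), size=len(roster), replace=False)
    hosts = [pool[int(i)] for i in idx]
    mapping = dict(zip(roster, hosts))

    # rebuild host fields from scratch through the bijection
    host_fields: dict[Address, dict[FieldKind, Counter]] = {
        h: {"now": Counter(), "next": Counter()} for h in hosts
    }
    for (src, tgt, kind), mult in pattern.pairs.items():
        host_fields[mapping[src]][kind][mapping[tgt]] += mult

    second = mapping[primary]
    for h in hosts:
        el = pop[h]
        is_second = h == second
        for kind in ("now", "next"):
            occ = dict(host_fields[h][kind])
            cap = max(len(occ), 1)
            fld = ConnectionField(occ, capacity=cap, fixed=is_second)
            if kind == "now":
                el.now_field = fld
            else:
                el.next_field = fld
        el.downtime_exempt = True
    pop[second].guaranteed_next = True
    pop[second].next_silenced = False
    return pop, second


def silence_ppdp(address: Address, pop: Population) -> Population:
    """Zero a PPDP's Next connectivity score; its fields stay intact, so its
    partners' Now fields can still pull it into a state."""
    e = pop[address]
    if not e.guaranteed_next:
        raise ValueError(f"element {address} is not a PPDP (guaranteed_next unset)")
    e.guaranteed_next = False
    e.next_silenced = True
    return pop
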