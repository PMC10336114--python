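"""Element/population data model and the occurrence-counting primitive.

Every element owns two connection fields, *Now* and *Next*.  A field is a
multiset of element addresses: the same address may occur many times, and
the multiplicity is the connection strength.  A field additionally has a
*capacity* — the maximum number of **distinct** addresses it may hold —
which itself grows and shrinks with reward and punishment (between 1 and 8
for learnable fields; fixed PPDP fields are exempt).

The population is the fixed set of N addressable elements plus the
bookkeeping needed for Downtime eligibility (``last_active``), which lives
here rather than on the elements so that eligibility is a pure function of
``(population, t)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .config import Config, ConfigurationError

Address = int
FieldKind = Literal["now", "next"]

NEVER_ACTIVE = -(10**9)  # sentinel for "never been in an Active state"


class SimulationError(RuntimeError):
    """Raised when the simulation cannot proceed (e.g. no eligible elements)."""


@dataclass
class ConnectionField:
    """A multiset of addresses with a distinct-address capacity."""

    occurrences: dict[Address, int] = dc_field(default_factory=dict)
    capacity: int = 1
    fixed: bool = False

    def __post_init__(self) -> None:
        for addr, mult in self.occurrences.items():
            if mult < 1:
                raise ValueError(f"multiplicity of {addr} must be >= 1, got {mult}")
        if len(self.occurrences) > self.capacity:
            raise ValueError(
                f"{len(self.occurrences)} distinct addresses exceed capacity {self.capacity}"
            )

    @property
    def distinct(self) -> int:
        return len(self.occurrences)

    @property
    def total(self) -> int:
        return sum(self.occurrences.values())

    def count(self, target: Address) -> int:
        return self.occurrences.get(target, 0)

    def add(self, target: Address, copies: int = 1) -> bool:
        """Add ``copies`` of ``target``; a new distinct address is rejected
        (returns False) when the field is at capacity."""
        if self.fixed:
            return False
        if target in self.occurrences:
            self.occurrences[target] += copies
            return True
        if self.distinct >= self.capacity:
            return False
        self.occurrences[target] = copies
        return True

    def remove(self, target: Address, copies: int = 1) -> bool:
        """Remove up to ``copies`` of ``target``; absent targets are a no-op."""
        if self.fixed or target not in self.occurrences:
            return False
        left = self.occurrences[target] - copies
        if left > 0:
            self.occurrences[target] = left
        else:
            del self.occurrences[target]
        return True

    def shrink_to_capacity(self) -> None:
        """Evict excess distinct addresses, lowest multiplicity first
        (ties: highest address evicted first)."""
        while self.distinct > self.capacity:
            victim = min(self.occurrences, key=lambda a: (self.occurrences[a], -a))
            del self.occurrences[victim]

    def copy(self) -> "ConnectionField":
        return ConnectionField(dict(self.occurrences), self.capacity, self.fixed)


@dataclass
class Element:
    address: Address
    now_field: ConnectionField
    next_field: ConnectionField
    downtime: int = 12
    downtime_exempt: bool = False
    guaranteed_next: bool = False
    next_silenced: bool = False

    def __post_init__(self) -> None:
        if self.guaranteed_next and self.next_silenced:
            raise ValueError("guaranteed_next and next_silenced are mutually exclusive")

    def field(self, kind: FieldKind) -> ConnectionField:
        if kind == "now":
            return self.now_field
        if kind == "next":
            return self.next_field
        raise ValueError(f"unknown field kind {kind!r}")

    def copy(self) -> "Element":
        return Element(
            self.address,
            self.now_field.copy(),
            self.next_field.copy(),
            self.downtime,
            self.downtime_exempt,
            self.guaranteed_next,
            self.next_silenced,
        )


@dataclass
class Population:
    """The fixed set of N elements plus activity bookkeeping."""

    elements: dict[Address, Element]
    input_addresses: tuple[Address, ...]
    output_addresses: tuple[Address, ...]
    last_active: dict[Address, int] = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.elements)

    def __getitem__(self, address: Address) -> Element:
        return self.elements[address]

    def __iter__(self) -> Iterator[Address]:
        return iter(self.elements)

    def mark_active(self, addresses, t: int) -> None:
        for a in addresses:
            self.last_active[a] = t

    def never_active(self) -> list[Address]:
        """Addresses that have never appeared in an Active state."""
        return sorted(a for a in self.elements if a not in self.last_active)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "inputs": list(self.input_addresses),
            "outputs": list(self.output_addresses),
            "last_active": {str(a): t for a, t in sorted(self.last_active.items())},
            "elements": {
                str(a): {
                    "now": {str(k): v for k, v in sorted(e.now_field.occurrences.items())},
                    "next": {str(k): v for k, v in sorted(e.next_field.occurrences.items())},
                    "capacity_now": e.now_field.capacity,
                    "capacity_next": e.next_field.capacity,
                    "flags": {
                        "fixed_now": e.now_field.fixed,
                        "fixed_next": e.next_field.fixed,
                        "downtime": e.downtime,
                        "downtime_exempt": e.downtime_exempt,
                        "guaranteed_next": e.guaranteed_next,
                        "next_silenced": e.next_silenced,
                    },
                }
                for a, e in sorted(self.elements.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Population":
        elements: dict[Address, Element] = {}
        for a_str, ed in d["elements"].items():
            a = int(a_str)
            fl = ed["flags"]
            elements[a] = Element(
                address=a,
                now_field=ConnectionField(
                    {int(k): v for k, v in ed["now"].items()},
                    ed["capacity_now"],
                    fl["fixed_now"],
                ),
                next_field=ConnectionField(
                    {int(k): v for k, v in ed["next"].items()},
                    ed["capacity_next"],
                    fl["fixed_next"],
                ),
                downtime=fl["downtime"],
                downtime_exempt=fl["downtime_exempt"],
                guaranteed_next=fl["guaranteed_next"],
                next_silenced=fl["next_silenced"],
            )
        return cls(
            elements=elements,
            input_addresses=tuple(d["inputs"]),
            output_addresses=tuple(d["outputs"]),
            last_active={int(a): t for a, t in d.get("last_active", {}).items()},
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Population":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))

    def connectivity_fingerprint(self) -> str:
        """SHA-256 over fields, capacities and flags (activity bookkeeping
        excluded) — used to assert conservation under free running."""
        d = self.to_dict()
        d.pop("last_active")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def count_occurrences(element: Element, field_kind: FieldKind, target: Address) -> int:
    """Multiplicity of ``target`` in the element's named field (0 if absent)."""
    return element.field(field_kind).count(target)


def init_population(config: Config, seed: int) -> Population:
    """Build the initial population with group-structured random connectivity.

    Within each configured address group, every member's *Now* and *Next*
    fields are filled with ``init_capacity`` distinct addresses drawn
    uniformly from the other members of the same group (multiplicity
    ``init_multiplicity`` each).  Elements outside all groups start with
    empty fields at capacity ``field_cap_min``.
    """
    if not isinstance(config, Config):
        raise ConfigurationError("config must be a Config instance")
    rng = np.random.default_rng(seed)
    io_set = set(config.inputs) | set(config.outputs)
    io_downtime = config.downtime if config.io_downtime is None else config.io_downtime

    elements: dict[Address, Element] = {}
    for a in range(1, config.n_elements + 1):
        elements[a] = Element(
            address=a,
            now_field=ConnectionField({}, config.field_cap_min),
            next_field=ConnectionField({}, config.field_cap_min),
            downtime=io_downtime if a in io_set else config.downtime,
        )

    for start, size in config.groups:
        members = list(range(start, start + size))
        for a in members:
            peers = np.array([m for m in members if m != a])
            k = min(config.init_capacity, len(peers))
            for kind in ("now", "next"):
                chosen = rng.choice(peers, size=k, replace=False)
                fld = ConnectionField(
                    {int(c): config.init_multiplicity for c in chosen},
                    capacity=max(k, config.field_cap_min),
                )
                if kind == "now":
                    elements[a].now_field = fld
                else:
                    elements[a].next_field = fld

    return Population(
        elements=elements,
        input_addresses=tuple(config.inputs),
        output_addresses=tuple(config.outputs),
    )
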