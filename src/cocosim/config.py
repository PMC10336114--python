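"""Run configuration for the coherence-competition simulator.

A :class:`Config` collects every knob of the simulator: population size,
Active-subset size, field-capacity bounds, Downtime, the structured initial
connectivity (address groups), the input/output schedule, the learning rule
magnitudes, PPDP definitions and the timeline of the perturbation
experiments.  Configurations are plain frozen dataclasses and round-trip
through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigurationError(ValueError):
    """Raised for inconsistent or out-of-bounds configuration."""


@dataclass(frozen=True)
class PpdpSpec:
    """Definition of a phenotype-preserving disordered protein element.

    The element identified by ``address`` gets zero Downtime, a guaranteed
    top rank in the state-to-state (*Next*) competition, and large fixed
    *Now*/*Next* fields: every address in ``now_range`` / ``next_range``
    (inclusive bounds) occurs ``multiplicity`` times.  With the defaults the
    two fields each hold 30 distinct addresses, 60 occurrences in total.
    """

    address: int = 10
    now_range: tuple[int, int] = (111, 140)
    next_range: tuple[int, int] = (141, 170)
    multiplicity: int = 2

    def now_addresses(self) -> range:
        return range(self.now_range[0], self.now_range[1] + 1)

    def next_addresses(self) -> range:
        return range(self.next_range[0], self.next_range[1] + 1)

    def field_addresses(self) -> set[int]:
        """Union of both field ranges (the PPDP's partner pool)."""
        return set(self.now_addresses()) | set(self.next_addresses())


def _default_groups() -> tuple[tuple[int, int], ...]:
    # nine groups of 36 consecutive addresses anchored at 150, 250, ..., 950
    return tuple((anchor, 36) for anchor in range(150, 1000, 100))


@dataclass(frozen=True)
class Config:
    """All parameters of a simulation run.

    Attributes
    ----------
    n_elements : total number of addressable elements.
    active_size : number of distinct addresses in one Active-subset state.
    field_cap_min, field_cap_max : bounds on the number of *distinct*
        addresses a learnable connection field may hold.
    downtime : states an element must sit out after being active.
    groups : ``(start, size)`` pairs; members of a group receive initial
        random connections to other members of the same group.
    inputs, outputs : the environment-coupled element addresses.
    init_capacity : distinct addresses initially placed in each field of a
        group member (multiplicity ``init_multiplicity`` each).
    input_cycle, output_cycle : the task — each scheduled input must be
        answered by the paired output within a three-state window.
    input_period : states between consecutive scheduled inputs.
    io_downtime : Downtime of the environment-coupled input/output elements
        (None = same as everything else).  The default of 4 is forced by the
        task: an output repeated in adjacent three-state windows (999 at
        positions 1 and 2) must be re-selectable within five steps, so its
        Downtime can be at most 4; anything below 3 lets an output recur
        inside its own window and drift into every state.
    reward_increment, capacity_step : learning-rule magnitudes.
    convergence_cycles : full task cycles that must be rewarded without
        forcing for the run to count as converged.
    max_steps : learning budget for :func:`cocosim.experiments.run_learning`.
    ppdp : PPDP definitions applied when a run is started "with PPDP".
    learning_cutoff_step, perturbation_step, perturb_end_step,
    graft_step, intro_step, silence_step, second_end_step :
        timeline of the perturbation / second-PPDP experiments.
    post_window : states over which restriction/overlap metrics are taken
        (two task-cycle lengths by default).
    """

    n_elements: int = 1000
    active_size: int = 6
    field_cap_min: int = 1
    field_cap_max: int = 8
    downtime: int = 12
    groups: tuple[tuple[int, int], ...] = field(default_factory=_default_groups)
    inputs: tuple[int, ...] = (1, 2, 3)
    outputs: tuple[int, ...] = (998, 999, 1000)
    init_capacity: int = 4
    init_multiplicity: int = 1
    input_cycle: tuple[int, ...] = (1, 2, 3, 2, 3)
    output_cycle: tuple[int, ...] = (1000, 999, 999, 1000, 998)
    input_period: int = 3
    io_window: int = 3
    io_downtime: int | None = 4
    reward_increment: int = 1
    capacity_step: int = 1
    convergence_cycles: int = 10
    max_steps: int = 3000
    ppdp: tuple[PpdpSpec, ...] = (PpdpSpec(),)
    learning_cutoff_step: int = 900
    perturbation_step: int = 999
    perturb_end_step: int = 1200
    graft_step: int = 999
    intro_step: int = 1000
    silence_step: int = 1500
    second_end_step: int = 1800
    post_window: int = 30
    seed: int = 0

    # -- validation ------------------------------------------------------
    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ConfigurationError("n_elements must be positive")
        if not (1 <= self.field_cap_min <= self.field_cap_max <= 8):
            raise ConfigurationError(
                "field capacity bounds must satisfy 1 <= min <= max <= 8"
            )
        if self.active_size < 1:
            raise ConfigurationError("active_size must be >= 1")
        if len(self.input_cycle) != len(self.output_cycle):
            raise ConfigurationError("input_cycle and output_cycle lengths differ")
        if set(self.inputs) & set(self.outputs):
            raise ConfigurationError("input and output address sets must be disjoint")
        seen: set[int] = set()
        for start, size in self.groups:
            addrs = set(range(start, start + size))
            if start < 1 or start + size - 1 > self.n_elements:
                raise ConfigurationError(
                    f"group {start}..{start + size - 1} outside 1..{self.n_elements}"
                )
            if addrs & seen:
                raise ConfigurationError(f"group starting at {start} overlaps another")
            seen |= addrs
        for spec in self.ppdp:
            for lo, hi in (spec.now_range, spec.next_range):
                if lo < 1 or hi > self.n_elements or lo > hi:
                    raise ConfigurationError(
                        f"PPDP field range {lo}..{hi} outside 1..{self.n_elements}"
                    )
            if spec.field_addresses() & (set(self.inputs) | set(self.outputs)):
                raise ConfigurationError("PPDP field ranges overlap input/output addresses")

    # -- derived quantities ---------------------------------------------
    @property
    def cycle_length(self) -> int:
        """States per full task cycle."""
        return self.input_period * len(self.input_cycle)

    def ppdp_addresses(self) -> set[int]:
        return {spec.address for spec in self.ppdp}

    def ppdp_field_union(self) -> set[int]:
        """All addresses reachable through any configured PPDP field."""
        out: set[int] = set()
        for spec in self.ppdp:
            out |= spec.field_addresses()
        return out

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        d["ppdp"] = [dataclasses.asdict(s) for s in self.ppdp]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(tuple(g) for g in d["groups"])
        if "ppdp" in d:
            specs = []
            for s in d["ppdp"]:
                s = dict(s)
                for key in ("now_range", "next_range"):
                    if key in s:
                        s[key] = tuple(s[key])
                specs.append(PpdpSpec(**s))
            d["ppdp"] = tuple(specs)
        for key in ("inputs", "outputs", "input_cycle", "output_cycle"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Config":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))
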