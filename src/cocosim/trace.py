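"""Time-ordered record of a run: states plus event annotations."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .selection import ActiveState


@dataclass
class Event:
    time: int
    kind: str  # input | output_seen | forced_output | reward | punish | ...
    addresses: tuple[int, ...] = ()
    note: str = ""


@dataclass
class Trace:
    states: list[ActiveState] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    config_snapshot: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.states)

    def append(self, state: ActiveState) -> None:
        if self.states and state.time != self.states[-1].time + 1:
            raise ValueError(
                f"state times must increase by 1 (got {state.time} after {self.states[-1].time})"
            )
        self.states.append(state)

    def log(self, time: int, kind: str, addresses: tuple[int, ...] = (), note: str = "") -> None:
        self.events.append(Event(time, kind, addresses, note))

    def last_states(self, k: int) -> list[ActiveState]:
        if k > len(self.states):
            raise ValueError(f"window {k} exceeds trace length {len(self.states)}")
        return self.states[-k:]

    def members_union(self, window: int | None = None) -> set[int]:
        states = self.states if window is None else self.last_states(window)
        out: set[int] = set()
        for s in states:
            out |= s.member_set()
        return out

    def states_between(self, t0: int, t1: int) -> list[ActiveState]:
        """States with t0 <= time < t1."""
        return [s for s in self.states if t0 <= s.time < t1]

    # -- TSV writers -----------------------------------------------------
    def write_states_tsv(self, path: str | Path) -> None:
        events_at: dict[int, list[str]] = {}
        for ev in self.events:
            events_at.setdefault(ev.time, []).append(ev.kind)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["time", "slot", "address", "forced_flag", "event"])
            for s in self.states:
                evs = ";".join(events_at.get(s.time, []))
                for slot, addr in enumerate(s.members):
                    w.writerow([s.time, slot, addr, int(addr in s.forced), evs])

    def write_events_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["time", "event", "addresses", "note"])
            for ev in self.events:
                w.writerow([ev.time, ev.kind, ",".join(map(str, ev.addresses)), ev.note])
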