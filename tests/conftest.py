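import numpy as np
import pytest

from cocosim import Config, PpdpSpec, init_population
from cocosim.core_state import ConnectionField, Element, Population


@pytest.fixture
def config():
    """Default full-size configuration."""
    return Config()


@pytest.fixture
def population(config):
    return init_population(config, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_toy_population(
    fields: dict[int, tuple[dict[int, int], dict[int, int]]],
    n: int = 6,
    downtime: int = 0,
    inputs: tuple[int, ...] = (),
    outputs: tuple[int, ...] = (),
) -> Population:
    """Hand-built population: ``fields[addr] = (now_occurrences, next_occurrences)``."""
    elements = {}
    for a in range(1, n + 1):
        now, nxt = fields.get(a, ({}, {}))
        elements[a] = Element(
            address=a,
            now_field=ConnectionField(dict(now), capacity=max(len(now), 8)),
            next_field=ConnectionField(dict(nxt), capacity=max(len(nxt), 8)),
            downtime=downtime,
        )
    return Population(elements=elements, input_addresses=inputs, output_addresses=outputs)


@pytest.fixture
def toy_population():
    """Six elements with hand-set fields and zero downtime."""
    return make_toy_population(
        {
            1: ({}, {3: 2, 4: 1}),
            2: ({}, {3: 1, 5: 1}),
            3: ({5: 3}, {}),
        }
    )
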