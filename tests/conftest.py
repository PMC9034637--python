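"""Shared fixtures and state builders for the test suite."""

from __future__ import annotations

import pytest

from cortexmc.model_state import (EAST, NORTH, SOUTH, WEST, DIR_OF,
                                  GlobalParams, GridState, SpeciesParams)

ORI = {"north": NORTH, "south": SOUTH, "east": EAST, "west": WEST}


def make_params(**kw) -> GlobalParams:
    """Small-system parameters with innocuous defaults; override freely."""
    defaults = dict(
        actin=SpeciesParams(mu0=0.0, N0=100, gamma=0.0, E_link=1.0),
        ac=SpeciesParams(mu0=0.0, N0=0, gamma=0.0, E_link=0.0),
        myosin=SpeciesParams(mu0=0.0, N0=0, gamma=0.0, E_link=0.0),
        E0=12.0, W3=0.0, width=8, height=8, seed=0, kappa=1.0,
    )
    defaults.update(kw)
    return GlobalParams(**defaults)


def grow_filament(state: GridState, x: int, y: int, ori, length: int):
    """Place a bonded chain of ``length`` monomers whose *pointed* end is at
    (x, y), growing along the orientation vector; returns the chain."""
    code = ORI[ori] if isinstance(ori, str) else ori
    dx, dy = DIR_OF[code]
    chain = None
    for i in range(length):
        chain = state.place_monomer(
            state.node((x + i * dx) % state.width,
                       (y + i * dy) % state.height), code)
    return chain


class FakeRng:
    """Scripted uniform stream for deterministic rule tests."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self) -> float:
        return self.values.pop(0)


@pytest.fixture
def params():
    return make_params()


@pytest.fixture
def state(params):
    return GridState(params)
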