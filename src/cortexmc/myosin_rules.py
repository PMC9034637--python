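"""Myosin rules: motors, load accumulation and tension-induced detachment.

A myosin bridges two *anti-parallel* filaments across a lattice edge with a
link energy E3 on each arm (insertion P+ = exp(mu3), removal
P- = exp(-2*E3)). Because cortical filaments are anchored to the membrane
and cannot slide, an attached motor converts its activity into elastic
load: each filament accumulates

    E_load = sum_i W3 * t_i       (over its currently attached motors)

with W3 the motor power in RT per calibrated second and t_i the attachment
time of motor i. Loads only accumulate; when a motor detaches, or one of
its filaments stops being a filament, its contribution is frozen into the
filament's load.

A filament whose load exceeds its membrane-anchoring capacity
E_threshold = E1 * L (strictly greater) detaches wholly: its monomers and
links return to the reservoirs and its load is redistributed homogeneously
to the filaments remaining in the same network (connected component through
AC/myosin links); without recipients the load is discarded. Detachments in
one pass are simultaneous; cascades are iterated until quiescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import mc_kernel
from .crosslinker_rules import candidate_pairs
from .model_state import (MYOSIN, Chain, GlobalParams, GridState, SlotError)


def myosin_eligible(state: GridState, edge: int) -> bool:
    """True iff the edge's myosin slot is free and it lies between monomers
    of two distinct anti-parallel filaments."""
    if edge in state.myo_edges:
        return False
    return bool(candidate_pairs(state, edge, require_filaments=True,
                                antiparallel=True))


def attempt_myosin_insert(state: GridState, edge: int, params: GlobalParams,
                          rng) -> str:
    if edge in state.myo_edges or state.reservoir(MYOSIN) <= 0:
        return "blocked"
    pairs = candidate_pairs(state, edge, require_filaments=True,
                            antiparallel=True)
    if not pairs:
        return "blocked"
    mu = mc_kernel.chemical_potential(params.myosin, state.n_grid[MYOSIN],
                                      params.log_base)
    if not mc_kernel.metropolis_accept(mc_kernel.insertion_probability(mu), rng):
        return "rejected"
    pair = pairs[0] if len(pairs) == 1 else pairs[int(rng.uniform() * len(pairs))]
    state.add_myosin(edge, *pair)
    return "accepted"


def attempt_myosin_remove(state: GridState, edge: int, params: GlobalParams,
                          rng) -> str:
    """P- = exp(-2*E3) for an active motor; a motor whose bridge broke
    (one partner no longer a filament) is returned to the reservoir
    unconditionally at its next evaluation."""
    link = state.myo_edges.get(edge)
    if link is None:
        raise SlotError("edge holds no myosin")
    if not link.active:
        state.remove_myosin(edge)
        return "accepted"
    p = mc_kernel.removal_probability(2.0 * params.myosin.E_link)
    if mc_kernel.metropolis_accept(p, rng):
        state.remove_myosin(edge)
        return "accepted"
    return "rejected"


def evaluate_myosin(state: GridState, edge: int, params: GlobalParams,
                    rng) -> str:
    if edge in state.myo_edges:
        return attempt_myosin_remove(state, edge, params, rng)
    return attempt_myosin_insert(state, edge, params, rng)


# ---------------------------------------------------------------------------
# Loads and detachment
# ---------------------------------------------------------------------------


def filament_threshold(L: int, E1: float) -> float:
    """Membrane-anchoring capacity E_threshold = E1 * L (current length)."""
    if L < 0:
        raise ValueError("length must be >= 0")
    return E1 * L


def accumulate_loads(state: GridState, dt_seconds: float, W3: float) -> None:
    """Explicit-clock load update: add W3*dt per active motor to each of its
    two bridged filaments.

    The sampling kernel accumulates the identical quantity in closed form
    from attachment timestamps (see ``Chain.load``); this incremental
    variant serves manually stepped states and tests."""
    if dt_seconds <= 0:
        raise ValueError("dt must be > 0")
    for link in state.myo_edges.values():
        if not link.active:
            continue
        for s in (link.slot_a, link.slot_b):
            ch = state.chain_by_slot[s]
            ch.load_offset += W3 * dt_seconds
            state.loaded.add(ch)


@dataclass
class DetachmentReport:
    """Outcome of one detachment-processing call."""

    detached: list = field(default_factory=list)       # chain ids, all passes
    redistributed: float = 0.0                          # RT handed to survivors
    discarded: float = 0.0                              # RT with no recipients
    passes: int = 0


def _filament_components(state: GridState) -> dict[int, set[Chain]]:
    """Connected components of filaments joined by AC/myosin links."""
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    fils = state.filaments()
    for c in fils:
        parent[c.cid] = c.cid
    for c in fils:
        for link in list(c.acs) + list(c.myosins):
            for s in (link.slot_a, link.slot_b):
                other = state.chain_by_slot[s]
                if other is not None and other.cid in parent:
                    ra, rb = find(c.cid), find(other.cid)
                    if ra != rb:
                        parent[ra] = rb
    comps: dict[int, set[Chain]] = {}
    for c in fils:
        comps.setdefault(find(c.cid), set()).add(c)
    return comps


def process_detachments(state: GridState, params: GlobalParams,
                        report: DetachmentReport = None) -> DetachmentReport:
    """Detach every filament whose load strictly exceeds E1 * L, with
    homogeneous load redistribution inside each network; iterate cascades."""
    rep = report or DetachmentReport()
    E1 = params.actin.E_link
    it, w3dt = state.iteration, state.w3_dt
    while True:
        over = [c for c in state.loaded
                if len(c.cells) >= 3 and c.load(it, w3dt) > E1 * len(c.cells)]
        if not over:
            break
        rep.passes += 1
        comps = _filament_components(state)
        comp_of: dict[int, set[Chain]] = {}
        for comp in comps.values():
            for c in comp:
                comp_of[c.cid] = comp
        detaching = set(c.cid for c in over)
        for c in over:
            load = c.load(it, w3dt)
            recipients = [o for o in comp_of[c.cid]
                          if o.cid not in detaching]
            rep.detached.append(c.cid)
            if recipients:
                share = load / len(recipients)
                for o in recipients:
                    o.load_offset += share
                    state.loaded.add(o)
                rep.redistributed += load
            else:
                rep.discarded += load
        for c in over:
            state.detach_chain(c)
    return rep
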