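"""Actin crosslinker (AC) rules.

An AC occupies a lattice edge and bridges two monomers on the edge's two
nodes, provided the monomers belong to two *distinct* filaments — parallel,
anti-parallel or perpendicular all qualify. Insertion is a reservoir
exchange with P+ = exp(mu2); each arm registers a link energy E2 on its
monomer, so ACs both glue filaments into networks and stabilize the actin
they touch. Removal releases both arms at once, hence P- = exp(-2*E2).

By default both endpoint monomers must sit in filaments (runs >= 3);
``ac_require_filaments=False`` relaxes eligibility to any two monomers of
distinct chains (used by the miniature-system oracle).
"""

from __future__ import annotations

from . import mc_kernel
from .model_state import AC, GlobalParams, GridState, OPPOSITE, SlotError


def candidate_pairs(state: GridState, edge: int, require_filaments: bool,
                    antiparallel: bool) -> list[tuple[int, int]]:
    """Eligible (slot_a, slot_b) monomer pairs across an edge.

    Shared eligibility engine for ACs (any relative orientation) and myosin
    (``antiparallel=True``: opposite orientations on the same axis)."""
    u, v = state.edge_nodes(edge)
    if v < 0:
        return []
    pairs = []
    for sa in (u * 2, u * 2 + 1):
        ca = state.chain_by_slot[sa]
        if ca is None or (require_filaments and len(ca.cells) < 3):
            continue
        for sb in (v * 2, v * 2 + 1):
            cb = state.chain_by_slot[sb]
            if cb is None or cb is ca or (require_filaments and len(cb.cells) < 3):
                continue
            if antiparallel and cb.ori != OPPOSITE[ca.ori]:
                continue
            pairs.append((sa, sb))
    return pairs


def ac_eligible(state: GridState, edge: int,
                params: GlobalParams = None) -> bool:
    """True iff the edge's AC slot is free and the edge lies between two
    monomers of two distinct filaments."""
    if edge in state.ac_edges:
        return False
    require = True if params is None else params.ac_require_filaments
    return bool(candidate_pairs(state, edge, require, antiparallel=False))


def attempt_ac_insert(state: GridState, edge: int, params: GlobalParams,
                      rng) -> str:
    """Metropolis insertion of an AC on ``edge`` with P+ = exp(mu2)."""
    if edge in state.ac_edges or state.reservoir(AC) <= 0:
        return "blocked"
    pairs = candidate_pairs(state, edge, params.ac_require_filaments,
                            antiparallel=False)
    if not pairs:
        return "blocked"
    mu = mc_kernel.chemical_potential(params.ac, state.n_grid[AC],
                                      params.log_base)
    if not mc_kernel.metropolis_accept(mc_kernel.insertion_probability(mu), rng):
        return "rejected"
    pair = pairs[0] if len(pairs) == 1 else pairs[int(rng.uniform() * len(pairs))]
    state.add_ac(edge, *pair)
    return "accepted"


def attempt_ac_remove(state: GridState, edge: int, params: GlobalParams,
                      rng) -> str:
    """Metropolis removal of the AC on ``edge`` with P- = exp(-2*E2)."""
    if edge not in state.ac_edges:
        raise SlotError("edge holds no AC")
    p = mc_kernel.removal_probability(2.0 * params.ac.E_link)
    if mc_kernel.metropolis_accept(p, rng):
        state.remove_ac(edge)
        return "accepted"
    return "rejected"


def evaluate_ac(state: GridState, edge: int, params: GlobalParams, rng) -> str:
    """Kernel entry point: removal if the edge holds an AC, else insertion."""
    if edge in state.ac_edges:
        return attempt_ac_remove(state, edge, params, rng)
    return attempt_ac_insert(state, edge, params, rng)
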