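"""Exact stationary distributions of miniature systems.

This module re-encodes the sampling rules (uniform position draw, uniform
orientation draw, Metropolis with P+ = exp(mu) and P- = exp(-E)) as an
explicit Markov transition matrix over an enumerable state space, entirely
independently of the simulation kernel's data structures, and solves for
the stationary vector. It is test support: long-run occupancy frequencies
of the kernel must match these exact answers.

States carry both slot contents and the bond partition (which adjacent
same-orientation monomers are polymer-bonded), because bonds depend on
insertion history. Covered systems are actin-only (optionally with ACs in
the relaxed any-monomer-pair eligibility) on grids with at most 12 slots;
closed boundaries avoid the degenerate self/double edges of 1-wide
periodic axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_state import (AXIS_OF, DIR_OF, NORTH, SOUTH, EAST, WEST,
                          GlobalParams)

MAX_SLOTS = 12
MAX_STATES = 200_000


class OracleSizeError(ValueError):
    pass


# A state is a frozenset of monomer entries plus a frozenset of bonds plus
# the AC occupancy:
#   monomers: ((x, y, axis) -> ori) as a sorted tuple of items
#   bonds:    sorted tuple of ((x,y,axis), (x,y,axis)) pairs (pointed->barbed)
#   acs:      sorted tuple of (edge_key, slot_key_a, slot_key_b)


def _axis(ori):
    return AXIS_OF[ori]


@dataclass(frozen=True)
class MiniState:
    monomers: tuple      # ((x, y, axis, ori), ...) sorted
    bonds: tuple         # (((xa,ya,axis), (xb,yb,axis)), ...) sorted
    acs: tuple           # ((x, y, d, slot_a, slot_b), ...) sorted

    def monomer_map(self):
        return {(x, y, a): o for (x, y, a, o) in self.monomers}

    @property
    def n_actin(self):
        return len(self.monomers)

    @property
    def n_ac(self):
        return len(self.acs)


def _chains(state: MiniState):
    """Partition monomers into bonded chains; each chain is a list of slot
    keys ordered pointed -> barbed."""
    nxt = {a: b for a, b in state.bonds}
    prv = {b: a for a, b in state.bonds}
    chains = []
    for (x, y, a, o) in state.monomers:
        key = (x, y, a)
        if key in prv:
            continue
        chain = [key]
        while chain[-1] in nxt:
            chain.append(nxt[chain[-1]])
        chains.append(chain)
    return chains


def _energy(state: MiniState, key, params: GlobalParams) -> float:
    """Total link energy of the monomer at slot ``key``: membrane E1 (only
    for filament members unless ``anchor_free_monomers``), an E0 bond
    unless pointed-terminal or sub-nucleus, E2 per AC arm."""
    e = 0.0
    for chain in _chains(state):
        if key in chain:
            if len(chain) >= 3:
                e += params.actin.E_link
                if chain[0] != key:
                    e += params.E0
            elif params.anchor_free_monomers:
                e += params.actin.E_link
            break
    for (_, _, _, sa, sb) in state.acs:
        if key in (sa, sb):
            e += params.ac.E_link
    return e


def _interior(state: MiniState, key) -> bool:
    for chain in _chains(state):
        if key in chain:
            return len(chain) >= 3 and chain[0] != key and chain[-1] != key
    return False


def _insert(state: MiniState, x, y, ori) -> MiniState:
    axis = _axis(ori)
    key = (x, y, axis)
    dx, dy = DIR_OF[ori]
    behind = (x - dx, y - dy, axis)
    mono = state.monomer_map()
    bonds = list(state.bonds)
    if mono.get((behind[0], behind[1], axis)) == ori:
        # bond only if the behind monomer is a chain's barbed end
        if not any(a == behind for a, b in state.bonds):
            bonds.append((behind, key))
    monomers = tuple(sorted(state.monomers + ((x, y, axis, ori),)))
    return MiniState(monomers, tuple(sorted(bonds)), state.acs)


def _remove(state: MiniState, key) -> MiniState:
    monomers = tuple(m for m in state.monomers if (m[0], m[1], m[2]) != key)
    bonds = tuple(b for b in state.bonds if key not in b)
    acs = tuple(a for a in state.acs if key not in (a[3], a[4]))
    return MiniState(monomers, bonds, acs)


def _edges(width, height):
    """Closed-boundary edges as (x, y, d) with d=0 toward (x+1,y), d=1
    toward (x, y+1)."""
    out = []
    for y in range(height):
        for x in range(width):
            if x + 1 < width:
                out.append((x, y, 0))
            if y + 1 < height:
                out.append((x, y, 1))
    return out


def _accept(mu: float) -> float:
    return 1.0 if mu >= 0 else min(1.0, math.exp(mu))


def _mu(n_on_grid: int, mu0: float, gamma: float, n0: int) -> float:
    if gamma == 0.0:
        return mu0
    if n_on_grid == 0:
        return math.inf
    return mu0 - gamma * math.log(n_on_grid / n0)


def _actin_branches(state: MiniState, x: int, y: int, params: GlobalParams):
    """(probability, state) outcomes of the actin sub-step at one node;
    probabilities sum to 1 (unchanged-state branches included)."""
    out = []
    mono = state.monomer_map()
    for ori in (NORTH, SOUTH, EAST, WEST):
        p_branch = 0.25
        axis = _axis(ori)
        key = (x, y, axis)
        if key in mono:
            if _interior(state, key) and params.forbid_interior_removal:
                out.append((p_branch, state))
                continue
            p_acc = min(1.0, math.exp(-_energy(state, key, params)))
            if p_acc:
                out.append((p_branch * p_acc, _remove(state, key)))
            if p_acc < 1.0:
                out.append((p_branch * (1.0 - p_acc), state))
        elif state.n_actin >= params.actin.N0:
            out.append((p_branch, state))
        else:
            p_acc = _accept(_mu(state.n_actin, params.actin.mu0,
                                params.actin.gamma, params.actin.N0))
            if p_acc:
                out.append((p_branch * p_acc, _insert(state, x, y, ori)))
            if p_acc < 1.0:
                out.append((p_branch * (1.0 - p_acc), state))
    return out


def _ac_branches(state: MiniState, x: int, y: int, d: int,
                 params: GlobalParams):
    """(probability, state) outcomes of the AC sub-step at one edge;
    probabilities sum to 1."""
    W, H = params.width, params.height
    nx, ny = (x + 1, y) if d == 0 else (x, y + 1)
    if nx >= W or ny >= H:
        return [(1.0, state)]
    occ = [a for a in state.acs if (a[0], a[1], a[2]) == (x, y, d)]
    if occ:
        p_acc = min(1.0, math.exp(-2.0 * params.ac.E_link))
        nxt = MiniState(state.monomers, state.bonds,
                        tuple(a for a in state.acs if a != occ[0]))
        return [(p_acc, nxt), (1.0 - p_acc, state)]
    if state.n_ac >= params.ac.N0:
        return [(1.0, state)]
    mono = state.monomer_map()
    chains = _chains(state)
    chain_of = {}
    for ci, ch in enumerate(chains):
        for k in ch:
            chain_of[k] = ci
    pairs = []
    for aa in (0, 1):
        ka = (x, y, aa)
        if ka not in mono:
            continue
        for ab in (0, 1):
            kb = (nx, ny, ab)
            if kb not in mono or chain_of[ka] == chain_of[kb]:
                continue
            if params.ac_require_filaments:
                if (len(chains[chain_of[ka]]) < 3
                        or len(chains[chain_of[kb]]) < 3):
                    continue
            pairs.append((ka, kb))
    if not pairs:
        return [(1.0, state)]
    p_acc = _accept(_mu(state.n_ac, params.ac.mu0, params.ac.gamma,
                        params.ac.N0))
    out = []
    for ka, kb in pairs:
        nxt = MiniState(state.monomers, state.bonds,
                        tuple(sorted(state.acs + ((x, y, d, ka, kb),))))
        out.append((p_acc / len(pairs), nxt))
    if p_acc < 1.0:
        out.append((1.0 - p_acc, state))
    return out


def _transitions(state: MiniState, params: GlobalParams):
    """Yield (probability, next_state, tag) for one full MC step.

    One step composes the species sub-steps at a single sampled node: the
    actin insertion/removal is evaluated first, then the AC sub-step acts
    on the *intermediate* state at one of the node's outgoing edges —
    matching the kernel's in-step evaluation order. Probabilities sum to 1
    (self-transitions included)."""
    W, H = params.width, params.height
    p_node = 1.0 / (W * H)
    ac_active = params.ac.N0 > 0
    out = []
    for y in range(H):
        for x in range(W):
            for p1, mid in _actin_branches(state, x, y, params):
                if not ac_active:
                    out.append((p_node * p1, mid, "step"))
                    continue
                for d in (0, 1):
                    for p2, fin in _ac_branches(mid, x, y, d, params):
                        out.append((p_node * p1 * 0.5 * p2, fin, "step"))
    return out


def enumerate_states(params: GlobalParams) -> list[MiniState]:
    """All states reachable from the empty grid under the step rules.

    Restricted to tiny systems: at most ``MAX_SLOTS`` monomer slots and
    closed boundaries (the kernel's periodic wrap is degenerate on 1-wide
    axes)."""
    if 2 * params.width * params.height > MAX_SLOTS:
        raise OracleSizeError("grid too large for exact enumeration")
    if params.boundary != "closed":
        raise OracleSizeError("oracle systems use closed boundaries")
    if params.myosin.N0:
        raise OracleSizeError("myosin's time-dependent load is out of oracle scope")
    empty = MiniState((), (), ())
    seen = {empty}
    frontier = [empty]
    while frontier:
        s = frontier.pop()
        for _, nxt, _ in _transitions(s, params):
            if nxt not in seen:
                seen.add(nxt)
                if len(seen) > MAX_STATES:
                    raise OracleSizeError("state space exceeds MAX_STATES")
                frontier.append(nxt)
    return sorted(seen, key=lambda s: (s.n_actin, s.n_ac, s.monomers,
                                       s.bonds, s.acs))


def stationary_distribution(states: list[MiniState],
                            params: GlobalParams) -> np.ndarray:
    """Exact stationary probability vector of the one-step chain."""
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))
    for s in states:
        i = index[s]
        total = 0.0
        for p, nxt, _ in _transitions(s, params):
            P[i, index[nxt]] += p
            total += p
        P[i, i] += 1.0 - total
    if np.any(P < -1e-12):
        raise RuntimeError("negative transition probability")
    # solve pi (P - I) = 0 with sum(pi) = 1
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_counts(states, pi) -> dict:
    """Stationary expectations of grid counts (actin monomers, ACs)."""
    n1 = float(sum(p * s.n_actin for s, p in zip(states, pi)))
    n2 = float(sum(p * s.n_ac for s, p in zip(states, pi)))
    return {"actin": n1, "ac": n2}


def occupancy_marginal(states, pi, slot_key) -> float:
    """Stationary probability that the slot (x, y, axis) is occupied."""
    return float(sum(p for s, p in zip(states, pi)
                     if slot_key in s.monomer_map()))


def two_state_occupancy(mu: float, E_total: float) -> float:
    """Closed-form stationary occupancy of a single slot: with per-attempt
    acceptance a = min(1, e^mu) and b = min(1, e^-E), pi_occ = a/(a+b)."""
    a = min(1.0, math.exp(min(mu, 0.0)) if mu < 0 else 1.0)
    b = min(1.0, math.exp(-E_total))
    return a / (a + b)
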