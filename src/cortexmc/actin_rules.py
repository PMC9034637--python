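"""G-actin insertion/removal rules, filament bookkeeping and census.

Polymerization is directional: a monomer entering the grid immediately in
front of the barbed end of a same-orientation chain bonds to it with energy
E0, and monomers incorporated in an F-actin carry a membrane anchor of
energy E1. Depolymerization is destabilized at the pointed end: the
trailing monomer of a filament keeps only its membrane link (its E0 bond
is released), which is what produces rear shrinkage and hence
treadmilling. Chains shorter than the three-monomer nucleus have all
their bonds destabilized and no anchor yet, so dimers dissolve as easily
as free monomers — nucleation is the rate-limiting step.

Removing an interior monomer would break a filament in two; because that
carries the full E0 (about five orders of magnitude suppression at the
default E0 = 12 RT), the probability of breaking is set to exactly zero by
default (``forbid_interior_removal``); switching the flag off replaces the
hard zero by the Metropolis factor exp(-E0 - ...).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import mc_kernel
from .model_state import (ACTIN, AXIS_OF, HORIZONTAL, ORIENTATION_NAMES,
                          VERTICAL, Chain, Filament, GlobalParams,
                          GridState, SlotError)


@dataclass(frozen=True)
class MonomerLinkEnergy:
    """Itemized link energy holding one cortical G-actin monomer."""

    E_membrane: float
    E_bond: float
    E_ac: float
    E_myosin: float

    @property
    def total(self) -> float:
        return self.E_membrane + self.E_bond + self.E_ac + self.E_myosin


def _bond_energy(chain: Chain, node: int, E0: float) -> float:
    """E0 if the monomer holds an intact polymer bond, else 0.

    The pointed-end terminal of a filament has its bond destabilized; in
    sub-nucleus chains (length < 3) every bond is destabilized."""
    if len(chain.cells) < 3:
        return 0.0
    if chain.cells[0] == node:   # pointed terminal
        return 0.0
    return E0


def monomer_link_energy(state: GridState, pos: tuple[int, int], axis,
                        params: GlobalParams) -> MonomerLinkEnergy:
    """Itemized energy of the monomer at ``pos`` on the given axis.

    The membrane anchor E1 is established when a monomer is incorporated
    into an F-actin, so monomers outside filaments contribute no membrane
    term (unless ``anchor_free_monomers`` is set) and, unlinked, leave the
    cortex with probability one when sampled."""
    if isinstance(axis, str):
        axis = {"vertical": VERTICAL, "horizontal": HORIZONTAL}[axis]
    node = state.node(*pos)
    slot = node * 2 + axis
    chain = state.chain_by_slot[slot]
    if chain is None:
        raise SlotError(f"no monomer at {pos} axis {axis}")
    anchored = len(chain.cells) >= 3 or params.anchor_free_monomers
    return MonomerLinkEnergy(
        E_membrane=params.actin.E_link if anchored else 0.0,
        E_bond=_bond_energy(chain, node, params.E0),
        E_ac=params.ac.E_link * state.ac_count(slot),
        E_myosin=params.myosin.E_link * state.myo_count(slot),
    )


def attempt_actin_insert(state: GridState, x: int, y: int,
                         params: GlobalParams, rng) -> str:
    """Try to insert a G-actin at (x, y): draw an orientation, then apply
    Metropolis with P+ = exp(mu1). Returns 'accepted', 'rejected' or
    'blocked' (slot of the drawn orientation occupied, or reservoir empty).
    """
    node = state.node(x, y)
    return _insert_at(state, node, params, rng)


def _insert_at(state: GridState, node: int, params: GlobalParams, rng) -> str:
    ori = 1 + int(rng.uniform() * 4.0)
    arr = state.horz if AXIS_OF[ori] else state.vert
    if arr[node] or state.reservoir(ACTIN) <= 0:
        return "blocked"
    mu = mc_kernel.chemical_potential(params.actin, state.n_grid[ACTIN],
                                      params.log_base)
    if mc_kernel.metropolis_accept(mc_kernel.insertion_probability(mu), rng):
        state.place_monomer(node, ori)
        return "accepted"
    return "rejected"


def attempt_actin_remove(state: GridState, pos: tuple[int, int], axis,
                         params: GlobalParams, rng) -> str:
    """Metropolis removal of the monomer at ``pos``: P- = exp(-E_total)."""
    if isinstance(axis, str):
        axis = {"vertical": VERTICAL, "horizontal": HORIZONTAL}[axis]
    node = state.node(*pos)
    return _remove_at(state, node * 2 + axis, params, rng)


def _remove_at(state: GridState, slot: int, params: GlobalParams, rng) -> str:
    chain = state.chain_by_slot[slot]
    if chain is None:
        raise SlotError("slot is empty")
    node = slot >> 1
    interior = len(chain.cells) >= 3 and chain.cells[0] != node and chain.cells[-1] != node
    if interior and params.forbid_interior_removal:
        return "rejected"   # breaking a filament has probability zero
    e = monomer_link_energy(state, state.xy(node), slot & 1, params)
    if mc_kernel.metropolis_accept(mc_kernel.removal_probability(e.total), rng):
        state.remove_monomer(slot)
        return "accepted"
    return "rejected"


def evaluate_actin(state: GridState, node: int, params: GlobalParams, rng) -> str:
    """Kernel entry point: insertion if the drawn orientation's slot is
    empty, otherwise removal of the monomer occupying that slot. Drawing
    the orientation uniformly makes the removal axis tie-break uniform when
    both of a node's slots are occupied."""
    if state.n0[ACTIN] == 0:
        return "blocked"
    ori = 1 + int(rng.uniform() * 4.0)
    axis = AXIS_OF[ori]
    arr = state.horz if axis else state.vert
    if arr[node]:
        return _remove_at(state, node * 2 + axis, params, rng)
    if state.reservoir(ACTIN) <= 0:
        return "blocked"
    mu = mc_kernel.chemical_potential(params.actin, state.n_grid[ACTIN],
                                      params.log_base)
    if mc_kernel.metropolis_accept(mc_kernel.insertion_probability(mu), rng):
        state.place_monomer(node, ori)
        return "accepted"
    return "rejected"


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def _chain_view(state: GridState, chain: Chain) -> Filament:
    cells = [state.xy(c) for c in chain.cells]
    return Filament(
        cid=chain.cid,
        orientation=ORIENTATION_NAMES[chain.ori],
        length=len(cells),
        monomers=cells,
        pointed=cells[0],
        barbed=cells[-1],
        E_load=chain.load(state.iteration, state.w3_dt),
    )


def find_filaments(state: GridState) -> list[Filament]:
    """All maximal bonded runs of >= 3 identically oriented monomers."""
    return [_chain_view(state, c) for c in sorted(state.chains.values(),
                                                  key=lambda c: c.cid)
            if len(c.cells) >= 3]


def find_oligomers(state: GridState) -> list[Filament]:
    """Runs of length 1-2 (not filaments), same census record format."""
    return [_chain_view(state, c) for c in sorted(state.chains.values(),
                                                  key=lambda c: c.cid)
            if 0 < len(c.cells) < 3]


def filament_census_tsv(state: GridState) -> str:
    """Filament census as TSV (one row per filament)."""
    lines = ["filament_id\torientation\tlength\tx_pointed\ty_pointed"
             "\tx_barbed\ty_barbed\tE_load"]
    for f in find_filaments(state):
        lines.append(f"{f.cid}\t{f.orientation}\t{f.length}"
                     f"\t{f.pointed[0]}\t{f.pointed[1]}"
                     f"\t{f.barbed[0]}\t{f.barbed[1]}\t{f.E_load:.6g}")
    return "\n".join(lines) + "\n"
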