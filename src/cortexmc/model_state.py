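"""Lattice, reservoir and bookkeeping for the cortex simulator.

The cortex is a 2D grid of nodes. Each node carries two independent monomer
slots: a *vertical* slot (north/south orientations) and a *horizontal* slot
(east/west), so perpendicular filaments may cross at a node but same-axis
overlap is forbidden. Crosslinkers (ACs) and myosin motors occupy lattice
*edges* between adjacent nodes, each edge holding at most one AC and at most
one myosin. Molecules not on the grid live in a zero-dimensional, instantly
mixed reservoir (the cytoplasm); per-species totals grid + reservoir are
conserved exactly.

All state mutation goes through the ``GridState`` methods defined here so
that chain (filament) membership, link registries, myosin load accounting
and conservation are updated atomically; the rule modules only decide
*whether* a move happens.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional

import math

# ---------------------------------------------------------------------------
# Orientations
# ---------------------------------------------------------------------------

#: orientation codes; 0 means "empty slot"
NORTH, SOUTH, EAST, WEST = 1, 2, 3, 4

ORIENTATION_NAMES = {NORTH: "north", SOUTH: "south", EAST: "east", WEST: "west"}
ORIENTATION_CODES = {v: k for k, v in ORIENTATION_NAMES.items()}

#: axis index per orientation: 0 = vertical slot, 1 = horizontal slot
VERTICAL, HORIZONTAL = 0, 1
AXIS_OF = {NORTH: VERTICAL, SOUTH: VERTICAL, EAST: HORIZONTAL, WEST: HORIZONTAL}
AXIS_NAMES = {VERTICAL: "vertical", HORIZONTAL: "horizontal"}

#: unit step of the growth (barbed) direction for each orientation
DIR_OF = {NORTH: (0, 1), SOUTH: (0, -1), EAST: (1, 0), WEST: (-1, 0)}
OPPOSITE = {NORTH: SOUTH, SOUTH: NORTH, EAST: WEST, WEST: EAST}

ACTIN, AC, MYOSIN = 0, 1, 2
SPECIES_NAMES = ("actin", "ac", "myosin")


class CoordinateError(IndexError):
    """Raised for out-of-range lattice coordinates."""


class SlotError(ValueError):
    """Raised when querying/mutating an empty slot or occupied slot wrongly."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """Reservoir-exchange parameters of one molecular species.

    mu0
        Reference chemical potential, in RT units. The working potential is
        mu = mu0 - gamma * log(N_grid / N0), so mu == mu0 exactly when the
        whole pool sits on the grid.
    N0
        Total molecule count (grid + reservoir), conserved.
    gamma
        Form factor of the potential; gamma == 0 gives a constant potential.
    E_link
        Link energy in RT (E1 membrane anchor for actin, E2 per AC arm,
        E3 per myosin arm).
    """

    mu0: float
    N0: int
    gamma: float
    E_link: float

    def __post_init__(self) -> None:
        if self.N0 < 0:
            raise ValueError("N0 must be >= 0")
        if self.E_link < 0:
            raise ValueError("E_link must be >= 0")


@dataclass(frozen=True)
class GlobalParams:
    """Complete configuration of a simulation run."""

    actin: SpeciesParams
    ac: SpeciesParams = SpeciesParams(0.0, 0, 0.0, 0.0)
    myosin: SpeciesParams = SpeciesParams(0.0, 0, 0.0, 0.0)
    E0: float = 12.0          # G-actin/G-actin bond energy, RT
    W3: float = 0.0           # single myosin motor power, RT per calibrated second
    width: int = 50
    height: int = 50
    boundary: str = "periodic"  # or "closed"
    seed: int = 0
    n_iterations: int = 0
    kappa: float = 1.0        # calibrated minutes per sweep-unit (2*area iterations)
    log_base: float = math.e
    #: if True, every cortical monomer carries the E1 membrane anchor; the
    #: default restricts the anchor to monomers incorporated in an F-actin
    #: (free monomers and dimers are then held only by AC/myosin links)
    anchor_free_monomers: bool = False
    forbid_interior_removal: bool = True
    ac_require_filaments: bool = True
    detach_check_stride: int = 100

    def __post_init__(self) -> None:
        if self.E0 < 0 or self.W3 < 0:
            raise ValueError("E0 and W3 must be >= 0")
        if self.boundary not in ("periodic", "closed"):
            raise ValueError("boundary must be 'periodic' or 'closed'")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def species(self) -> tuple[SpeciesParams, SpeciesParams, SpeciesParams]:
        return (self.actin, self.ac, self.myosin)

    @property
    def area(self) -> int:
        return self.width * self.height

    def with_(self, **kw) -> "GlobalParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Chains (filaments / oligomers) and links
# ---------------------------------------------------------------------------


class Chain:
    """A bonded run of identically oriented G-actin monomers.

    ``cells`` is ordered pointed end -> barbed end. A chain of length >= 3
    is a filament; shorter runs are oligomers. ``load_offset`` holds the
    frozen part of the myosin-imposed elastic load; the live part is
    accumulated lazily from the attachment bookkeeping of the active
    myosins (``n_myo``, ``sum_attach``) so the per-iteration cost stays
    constant:  E_load(it) = offset + W3*dt*(n_myo*it - sum_attach).
    """

    __slots__ = ("cid", "ori", "axis", "cells", "load_offset", "n_myo",
                 "sum_attach", "myosins", "acs")

    def __init__(self, cid: int, ori: int):
        self.cid = cid
        self.ori = ori
        self.axis = AXIS_OF[ori]
        self.cells: deque[int] = deque()
        self.load_offset = 0.0
        self.n_myo = 0              # active myosins pulling on this chain
        self.sum_attach = 0.0       # sum of their attachment iterations
        self.myosins: set = set()   # MyosinLink objects touching this chain
        self.acs: set = set()       # ACLink objects touching this chain

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def is_filament(self) -> bool:
        return len(self.cells) >= 3

    def load(self, iteration: int, w3_dt: float) -> float:
        """Current elastic load E_load in RT at the given iteration."""
        return self.load_offset + w3_dt * (self.n_myo * iteration - self.sum_attach)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chain {self.cid} {ORIENTATION_NAMES[self.ori]} L={len(self.cells)}>"


class ACLink:
    """An actin crosslinker occupying one edge, arms on two monomer slots."""

    __slots__ = ("edge", "slot_a", "slot_b")

    def __init__(self, edge: int, slot_a: int, slot_b: int):
        self.edge = edge
        self.slot_a = slot_a
        self.slot_b = slot_b


class MyosinLink:
    """A myosin motor bridging two anti-parallel filaments across an edge."""

    __slots__ = ("edge", "slot_a", "slot_b", "attach_iter", "active")

    def __init__(self, edge: int, slot_a: int, slot_b: int, attach_iter: int):
        self.edge = edge
        self.slot_a = slot_a
        self.slot_b = slot_b
        self.attach_iter = attach_iter
        self.active = True


@dataclass
class Filament:
    """Read-only census view of one filament (chain of length >= 3)."""

    cid: int
    orientation: str
    length: int
    monomers: list      # [(x, y), ...] pointed -> barbed
    pointed: tuple
    barbed: tuple
    E_load: float


# ---------------------------------------------------------------------------
# Grid state
# ---------------------------------------------------------------------------


class GridState:
    """Mutable lattice + reservoir state.

    Nodes are indexed ``node = y * width + x``; monomer slots as
    ``slot = node * 2 + axis``; edges as ``edge = node * 2 + d`` where
    ``d = 0`` points to (x+1, y) and ``d = 1`` to (x, y+1).
    """

    __slots__ = ("width", "height", "n_nodes", "periodic", "vert", "horz",
                 "ts", "chain_by_slot", "acs_by_slot", "myos_by_slot",
                 "ac_edges", "myo_edges", "chains", "n_grid", "n0",
                 "iteration", "w3_dt", "_next_cid", "loaded")

    def __init__(self, params: GlobalParams):
        self.width = params.width
        self.height = params.height
        self.n_nodes = params.width * params.height
        self.periodic = params.boundary == "periodic"
        n = self.n_nodes
        self.vert = [0] * n
        self.horz = [0] * n
        self.ts = [0] * (2 * n)                 # insertion iteration per slot
        self.chain_by_slot: list = [None] * (2 * n)
        self.acs_by_slot: dict[int, list] = {}
        self.myos_by_slot: dict[int, list] = {}
        self.ac_edges: dict[int, ACLink] = {}
        self.myo_edges: dict[int, MyosinLink] = {}
        self.chains: dict[int, Chain] = {}
        self.n_grid = [0, 0, 0]
        self.n0 = [params.actin.N0, params.ac.N0, params.myosin.N0]
        self.iteration = 0
        # RT gained per myosin per iteration: W3 [RT/s] * seconds/iteration
        self.w3_dt = params.W3 * params.kappa * 60.0 / (2.0 * n)
        self._next_cid = 0
        self.loaded: set[Chain] = set()         # chains that carry any load

    # -- geometry -----------------------------------------------------------

    def node(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise CoordinateError(f"({x}, {y}) outside {self.width}x{self.height} grid")
        return y * self.width + x

    def xy(self, node: int) -> tuple[int, int]:
        return node % self.width, node // self.width

    def neighbor(self, node: int, dx: int, dy: int) -> int:
        """Neighbor node index, or -1 if it falls off a closed boundary."""
        x, y = node % self.width, node // self.width
        x += dx
        y += dy
        if self.periodic:
            return (y % self.height) * self.width + (x % self.width)
        if 0 <= x < self.width and 0 <= y < self.height:
            return y * self.width + x
        return -1

    def edge_nodes(self, edge: int) -> tuple[int, int]:
        """The two nodes joined by an edge (second may be -1 on closed border)."""
        node, d = edge >> 1, edge & 1
        other = self.neighbor(node, 1 - d, d)
        if other == node:       # degenerate wrap on a 1-wide periodic axis
            other = -1
        return node, other

    # -- queries ------------------------------------------------------------

    def slot_orientation(self, slot: int) -> int:
        node, axis = slot >> 1, slot & 1
        return self.horz[node] if axis else self.vert[node]

    def reservoir(self, species: int) -> int:
        return self.n0[species] - self.n_grid[species]

    def ac_count(self, slot: int) -> int:
        lst = self.acs_by_slot.get(slot)
        return len(lst) if lst else 0

    def myo_count(self, slot: int) -> int:
        lst = self.myos_by_slot.get(slot)
        return len(lst) if lst else 0

    def filaments(self) -> list[Chain]:
        return [c for c in self.chains.values() if len(c.cells) >= 3]

    # -- monomer mutation ---------------------------------------------------

    def place_monomer(self, node: int, ori: int) -> Chain:
        """Place a G-actin monomer; bond to the chain whose barbed end it
        extends (same orientation, directly behind), otherwise start a new
        chain. Returns the chain the monomer ends up in."""
        axis = AXIS_OF[ori]
        arr = self.horz if axis else self.vert
        if arr[node]:
            raise SlotError("slot already occupied")
        arr[node] = ori
        slot = node * 2 + axis
        self.ts[slot] = self.iteration
        dx, dy = DIR_OF[ori]
        behind = self.neighbor(node, -dx, -dy)
        chain: Optional[Chain] = None
        if behind >= 0:
            prev = self.chain_by_slot[behind * 2 + axis]
            if prev is not None and prev.ori == ori and prev.cells[-1] == behind:
                chain = prev
        if chain is None:
            chain = Chain(self._next_cid, ori)
            self._next_cid += 1
            self.chains[chain.cid] = chain
        chain.cells.append(node)
        self.chain_by_slot[slot] = chain
        self.n_grid[ACTIN] += 1
        return chain

    def remove_monomer(self, slot: int) -> None:
        """Return one monomer to the reservoir, dissolving any AC/myosin
        links it carried (their molecules go back to their reservoirs)."""
        chain = self.chain_by_slot[slot]
        if chain is None:
            raise SlotError("slot is empty")
        node, axis = slot >> 1, slot & 1
        # dissolve links attached to this monomer
        for ac in list(self.acs_by_slot.get(slot, ())):
            self.remove_ac(ac.edge)
        for myo in list(self.myos_by_slot.get(slot, ())):
            self.remove_myosin(myo.edge)
        cells = chain.cells
        if len(cells) == 1:
            cells.clear()
            del self.chains[chain.cid]
            self.loaded.discard(chain)
        elif cells[0] == node:
            cells.popleft()
        elif cells[-1] == node:
            cells.pop()
        else:
            self._split_chain(chain, node)
        if chain.cid in self.chains and len(cells) == 2:
            self._chain_left_filament(chain)
        arr = self.horz if axis else self.vert
        arr[node] = 0
        self.chain_by_slot[slot] = None
        self.n_grid[ACTIN] -= 1

    def _split_chain(self, chain: Chain, node: int) -> None:
        # interior removal (only reachable when forbid_interior_removal=False);
        # freeze first, while the per-chain myosin bookkeeping is still valid
        for myo in list(chain.myosins):
            self._freeze_myosin(myo)
        cells = list(chain.cells)
        i = cells.index(node)
        left, right = cells[:i], cells[i + 1:]
        chain.cells = deque(left)
        new = Chain(self._next_cid, chain.ori)
        self._next_cid += 1
        self.chains[new.cid] = new
        new.cells = deque(right)
        for c in right:
            self.chain_by_slot[c * 2 + chain.axis] = new
        # split the frozen load pro rata and re-home link registries
        total = len(left) + len(right)
        if chain.load_offset:
            share = chain.load_offset
            chain.load_offset = share * len(left) / total
            new.load_offset = share * len(right) / total
            self.loaded.add(new)
        for links, attr in ((chain.myosins, "myosins"), (chain.acs, "acs")):
            for link in list(links):
                if new in (self.chain_by_slot[link.slot_a],
                           self.chain_by_slot[link.slot_b]):
                    links.discard(link)
                    getattr(new, attr).add(link)

    def _chain_left_filament(self, chain: Chain) -> None:
        """A chain just shrank below filament size: its myosins stop pulling
        (timers freeze); they are cleared at their next removal evaluation."""
        for myo in list(chain.myosins):
            self._freeze_myosin(myo)

    # -- AC mutation --------------------------------------------------------

    def add_ac(self, edge: int, slot_a: int, slot_b: int) -> ACLink:
        if edge in self.ac_edges:
            raise SlotError("edge already holds an AC")
        link = ACLink(edge, slot_a, slot_b)
        self.ac_edges[edge] = link
        for s in (slot_a, slot_b):
            self.acs_by_slot.setdefault(s, []).append(link)
            ch = self.chain_by_slot[s]
            ch.acs.add(link)
        self.n_grid[AC] += 1
        return link

    def remove_ac(self, edge: int) -> None:
        link = self.ac_edges.pop(edge, None)
        if link is None:
            raise SlotError("edge holds no AC")
        for s in (link.slot_a, link.slot_b):
            lst = self.acs_by_slot.get(s)
            if lst and link in lst:
                lst.remove(link)
            ch = self.chain_by_slot[s]
            if ch is not None:
                ch.acs.discard(link)
        self.n_grid[AC] -= 1

    # -- myosin mutation ----------------------------------------------------

    def add_myosin(self, edge: int, slot_a: int, slot_b: int) -> MyosinLink:
        if edge in self.myo_edges:
            raise SlotError("edge already holds a myosin")
        link = MyosinLink(edge, slot_a, slot_b, self.iteration)
        self.myo_edges[edge] = link
        for s in (slot_a, slot_b):
            self.myos_by_slot.setdefault(s, []).append(link)
            ch = self.chain_by_slot[s]
            ch.myosins.add(link)
            ch.n_myo += 1
            ch.sum_attach += link.attach_iter
            self.loaded.add(ch)
        self.n_grid[MYOSIN] += 1
        return link

    def _freeze_myosin(self, link: MyosinLink) -> None:
        """Stop a myosin's force generation, folding the load it has built
        so far into both bridged chains (accumulate-only semantics)."""
        if not link.active:
            return
        link.active = False
        dt_load = self.w3_dt * (self.iteration - link.attach_iter)
        for s in (link.slot_a, link.slot_b):
            ch = self.chain_by_slot[s]
            if ch is not None and link in ch.myosins:
                ch.load_offset += dt_load
                ch.n_myo -= 1
                ch.sum_attach -= link.attach_iter

    def remove_myosin(self, edge: int) -> None:
        link = self.myo_edges.pop(edge, None)
        if link is None:
            raise SlotError("edge holds no myosin")
        self._freeze_myosin(link)
        for s in (link.slot_a, link.slot_b):
            lst = self.myos_by_slot.get(s)
            if lst and link in lst:
                lst.remove(link)
            ch = self.chain_by_slot[s]
            if ch is not None:
                ch.myosins.discard(link)
        self.n_grid[MYOSIN] -= 1

    # -- whole-filament detachment -----------------------------------------

    def detach_chain(self, chain: Chain) -> None:
        """Tear down a whole filament: monomers to the actin reservoir,
        its ACs/myosins to theirs. Load redistribution is the caller's
        responsibility (myosin_rules.process_detachments)."""
        for myo in list(chain.myosins):
            self._freeze_myosin(myo)          # credits the partner chain too
        for c in list(chain.cells):
            for axis_slot in (c * 2 + chain.axis,):
                if self.chain_by_slot[axis_slot] is chain:
                    self.remove_monomer(axis_slot)
        self.loaded.discard(chain)


# ---------------------------------------------------------------------------
# Spec'd queries
# ---------------------------------------------------------------------------


def site_state(grid: GridState, x: int, y: int, axis) -> str:
    """Report the content of one monomer slot: 'empty' or 'occupied'."""
    if isinstance(axis, str):
        axis = {"vertical": VERTICAL, "horizontal": HORIZONTAL}[axis]
    node = grid.node(x, y)
    ori = grid.horz[node] if axis else grid.vert[node]
    return "occupied" if ori else "empty"


def check_conservation(grid: GridState, params: GlobalParams) -> bool:
    """True iff grid + reservoir counts equal N0 for all three species.

    Counts on the grid are re-tallied from scratch rather than trusting the
    running totals, so this doubles as an integrity check."""
    n_actin = sum(1 for v in grid.vert if v) + sum(1 for h in grid.horz if h)
    ok = (
        n_actin == grid.n_grid[ACTIN]
        and len(grid.ac_edges) == grid.n_grid[AC]
        and len(grid.myo_edges) == grid.n_grid[MYOSIN]
    )
    for sp, p in zip((ACTIN, AC, MYOSIN), params.species):
        ok = ok and (grid.n_grid[sp] + grid.reservoir(sp) == p.N0 == grid.n0[sp])
        ok = ok and grid.reservoir(sp) >= 0
    return ok


# ---------------------------------------------------------------------------
# Snapshot serialization (JSON lines, bit-exact round trip)
# ---------------------------------------------------------------------------


def snapshot_records(grid: GridState) -> list[dict]:
    """One JSON-ready record per occupied slot/edge plus a header record."""
    recs: list[dict] = [{
        "type": "header", "width": grid.width, "height": grid.height,
        "boundary": "periodic" if grid.periodic else "closed",
        "iteration": grid.iteration, "n0": list(grid.n0),
        "next_cid": grid._next_cid,
    }]
    for chain in sorted(grid.chains.values(), key=lambda c: c.cid):
        recs.append({
            "type": "chain", "cid": chain.cid,
            "orientation": ORIENTATION_NAMES[chain.ori],
            "cells": [list(grid.xy(c)) for c in chain.cells],
            "load_offset": chain.load_offset,
            "t_insert": [grid.ts[c * 2 + chain.axis] for c in chain.cells],
        })
    for edge in sorted(grid.ac_edges):
        link = grid.ac_edges[edge]
        x, y = grid.xy(edge >> 1)
        recs.append({"type": "ac", "x": x, "y": y, "dir": edge & 1,
                     "slots": [link.slot_a, link.slot_b]})
    for edge in sorted(grid.myo_edges):
        link = grid.myo_edges[edge]
        x, y = grid.xy(edge >> 1)
        recs.append({"type": "myosin", "x": x, "y": y, "dir": edge & 1,
                     "slots": [link.slot_a, link.slot_b],
                     "attach_iter": link.attach_iter, "active": link.active})
    return recs


def dump_snapshot(grid: GridState, fh: IO[str]) -> None:
    for rec in snapshot_records(grid):
        fh.write(json.dumps(rec, separators=(",", ":")) + "\n")


def load_snapshot(records: Iterable[dict], params: GlobalParams) -> GridState:
    """Rebuild a GridState from snapshot records (inverse of
    ``snapshot_records``)."""
    records = list(records)
    header = records[0]
    assert header["type"] == "header"
    params = params.with_(width=header["width"], height=header["height"],
                          boundary=header["boundary"])
    grid = GridState(params)
    grid.iteration = header["iteration"]
    grid.n0 = list(header["n0"])
    for rec in records:
        if rec["type"] != "chain":
            continue
        ori = ORIENTATION_CODES[rec["orientation"]]
        chain = Chain(rec["cid"], ori)
        chain.load_offset = rec["load_offset"]
        grid.chains[chain.cid] = chain
        if chain.load_offset:
            grid.loaded.add(chain)
        for (x, y), t in zip(rec["cells"], rec["t_insert"]):
            node = grid.node(x, y)
            arr = grid.horz if chain.axis else grid.vert
            if arr[node]:
                raise SlotError("snapshot places two same-axis monomers at one node")
            arr[node] = ori
            slot = node * 2 + chain.axis
            grid.ts[slot] = t
            grid.chain_by_slot[slot] = chain
            chain.cells.append(node)
            grid.n_grid[ACTIN] += 1
    for rec in records:
        if rec["type"] == "ac":
            edge = grid.node(rec["x"], rec["y"]) * 2 + rec["dir"]
            grid.add_ac(edge, *rec["slots"])
        elif rec["type"] == "myosin":
            edge = grid.node(rec["x"], rec["y"]) * 2 + rec["dir"]
            link = grid.add_myosin(edge, *rec["slots"])
            link.attach_iter = rec["attach_iter"]
            if not rec["active"]:
                # re-freeze with the recorded attachment time
                for s in (link.slot_a, link.slot_b):
                    ch = grid.chain_by_slot[s]
                    ch.n_myo -= 1
                    ch.sum_attach -= link.attach_iter
                link.active = False
            else:
                # correct the bookkeeping added with the wrong attach time
                for s in (link.slot_a, link.slot_b):
                    ch = grid.chain_by_slot[s]
                    ch.sum_attach += link.attach_iter - grid.iteration
    grid._next_cid = header["next_cid"]
    return grid


def load_snapshot_text(text: str, params: GlobalParams) -> GridState:
    return load_snapshot((json.loads(l) for l in text.splitlines() if l.strip()),
                         params)
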