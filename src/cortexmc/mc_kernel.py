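"""Semi-grand-canonical Metropolis kernel.

The ensemble: each species i exchanges with a finite reservoir under the
working chemical potential

    mu_i = mu_{i,0} - gamma_i * log(N_i / N_{i,0})

where N_i is the count of species i currently on the grid. Insertions are
accepted with P+ = exp(mu_i), removals with P- = exp(-E) where E sums the
link energies holding the molecule, both via the Metropolis comparison
u < P with u ~ Uniform(0, 1). P values above one simply mean certain
acceptance.

One iteration (``mc_step``) draws a single random lattice position and
evaluates, in the fixed order actin -> AC -> myosin, an insertion or a
removal for each species at that position. Myosin elastic loads advance
implicitly with the iteration counter (see ``model_state.Chain.load``) and
filament detachment is processed every ``detach_check_stride`` iterations.

RNG draw order within one step (draws are consumed only when the
corresponding decision point is reached):

1. position: one uniform, mapped to a node index
2. actin orientation: one uniform, mapped to {north, south, east, west}
3. actin Metropolis acceptance (insertion or removal)
4. edge direction for AC/myosin: one uniform, mapped to {east edge, south
   edge}; shared by both link species (drawn only if either species is
   present in the system)
5. AC acceptance; AC endpoint-pair tie-break (only if several pairs)
6. myosin acceptance; myosin endpoint-pair tie-break
"""

from __future__ import annotations

import math
import random
from typing import Optional

from . import actin_rules, crosslinker_rules, myosin_rules, observables
from .model_state import AC, MYOSIN, GlobalParams, GridState, SpeciesParams

_EXP_MAX = 700.0  # exp() overflow guard; anything above is certain acceptance


class RngStream:
    """Seedable uniform stream with a documented draw order (module docstring).

    Identical seed + configuration gives a bitwise identical trajectory.
    """

    __slots__ = ("seed", "_rng")

    def __init__(self, seed: int):
        self.seed = seed
        self._rng = random.Random(seed)

    def uniform(self) -> float:
        """Next uniform(0, 1) variate."""
        return self._rng.random()

    def spawn(self, index: int) -> "RngStream":
        """Child stream for replicate ``index`` (documented counter scheme)."""
        return RngStream((self.seed * 1_000_003 + index) % (2 ** 31))


def chemical_potential(p: SpeciesParams, N_on_grid: int,
                       log_base: float = math.e) -> float:
    """Working potential mu = mu0 - gamma*log(N/N0) in RT units.

    Returns +inf (certain-acceptance sentinel) when the grid count is zero
    and gamma > 0; raises if the grid count exceeds the species total.
    """
    if N_on_grid < 0 or N_on_grid > p.N0:
        raise ValueError(f"N_on_grid={N_on_grid} outside [0, N0={p.N0}]")
    if p.gamma == 0.0:
        return p.mu0
    if N_on_grid == 0:
        return math.inf
    log = math.log(N_on_grid / p.N0)
    if log_base != math.e:
        log /= math.log(log_base)
    return p.mu0 - p.gamma * log


def insertion_probability(mu: float) -> float:
    """P+ = exp(mu); may exceed 1 (then acceptance is certain)."""
    if mu > _EXP_MAX:
        return math.inf
    return math.exp(mu)


def removal_probability(E_total: float) -> float:
    """P- = exp(-E_total) for a molecule held by total link energy E_total."""
    if E_total < 0:
        raise ValueError("link energies are non-negative")
    return math.exp(-min(E_total, _EXP_MAX))


def metropolis_accept(P: float, rng: RngStream) -> bool:
    """Accept iff u < P for one uniform draw u (consumes exactly one draw)."""
    return rng.uniform() < P


def mc_step(state: GridState, params: GlobalParams, rng: RngStream) -> GridState:
    """One iteration: one random position, all three species evaluated."""
    node = int(rng.uniform() * state.n_nodes)
    actin_rules.evaluate_actin(state, node, params, rng)
    if state.n0[AC] or state.n0[MYOSIN]:
        d = 0 if rng.uniform() < 0.5 else 1
        edge = node * 2 + d
        if state.n0[AC]:
            crosslinker_rules.evaluate_ac(state, edge, params, rng)
        if state.n0[MYOSIN]:
            myosin_rules.evaluate_myosin(state, edge, params, rng)
    state.iteration += 1
    if params.W3 and state.iteration % params.detach_check_stride == 0:
        myosin_rules.process_detachments(state, params)
    return state


def run(params: GlobalParams,
        n_iterations: Optional[int] = None,
        seed: Optional[int] = None,
        record_stride: Optional[int] = None,
        snapshot_stride: Optional[int] = None,
        state: Optional[GridState] = None,
        progress: bool = False) -> "observables.Trajectory":
    """Execute the sampling loop and record a :class:`~cortexmc.observables.Trajectory`.

    Parameters default to the values stored in ``params``; ``record_stride``
    defaults to one sweep-unit (2 * area iterations, the unit the time
    calibration is expressed in). Passing ``state`` continues a run.
    """
    n_it = params.n_iterations if n_iterations is None else n_iterations
    rng = RngStream(params.seed if seed is None else seed)
    if state is None:
        state = GridState(params)
    if record_stride is None:
        record_stride = 2 * state.n_nodes
    traj = observables.Trajectory.empty(params, record_stride, snapshot_stride)
    traj.record(state)
    it_range = range(n_it)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            it_range = tqdm(it_range, unit="it")
        except ImportError:
            pass
    for i in it_range:
        mc_step(state, params, rng)
        if state.iteration % record_stride == 0:
            traj.record(state)
            if snapshot_stride and (state.iteration // record_stride) % snapshot_stride == 0:
                traj.snapshot(state)
    traj.finalize()
    traj.final_state = state
    return traj


def state_hash(state: GridState) -> int:
    """Order-independent structural hash of a grid state (determinism tests)."""
    h = hash((tuple(state.vert), tuple(state.horz),
              tuple(sorted(state.ac_edges)), tuple(sorted(state.myo_edges)),
              tuple(state.n_grid)))
    return h
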