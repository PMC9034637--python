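# Methods

## Model and sampling

The cortex is a `width x height` lattice (default 50x50, periodic; closed
boundaries available). A node carries one vertical and one horizontal
monomer slot, so filaments of perpendicular orientation may cross while
same-axis overlap is impossible. Orientation (north/south/east/west) is
drawn uniformly at insertion and never changes. Each species exchanges
with a finite, zero-dimensional reservoir under

    mu_i = mu_{i,0} - gamma_i * log(N_i / N_{i,0})        (natural log)

evaluated with the *current* grid count `N_i`; `mu_i = +inf` when the
grid is empty of species i (certain acceptance), and the per-species sum
grid + reservoir is conserved exactly.

One iteration samples a single lattice position and evaluates, in the
fixed order actin → AC → myosin: insertion with `P+ = exp(mu_i)` if the
relevant slot/edge is free (and eligible), otherwise removal with
`P- = exp(-E)`, both via the Metropolis comparison `u < P`. The edge used
for the two link species is one of the node's two outgoing edges, drawn
once per step. The RNG is a single seeded uniform stream with a
documented draw order (see `mc_kernel`); identical seed and configuration
reproduce a run bitwise.

### Actin

A monomer entering directly in front of the barbed end of a
same-orientation chain bonds to it with energy `E0`; chains never fuse
and never break in the interior (interior removal has probability zero
by default; disabling `forbid_interior_removal` replaces the hard zero
by the factor `exp(-E0)`, a ~`6e-6` suppression at the default
`E0 = 12` RT, from the 30 kJ/mol bond estimate at RT = 2.47 kJ/mol).
A chain of three or more monomers is an F-actin filament. The bond of the
pointed-end terminal monomer is destabilized (no `E0` term), as are all
bonds in sub-nucleus chains (length < 3) — this makes the trimer the
critical nucleus and produces barbed-end growth with pointed-end loss,
i.e. treadmilling.

The membrane anchor `E1` is carried by monomers incorporated in a
filament. Monomers outside filaments hold no anchor and leave with
probability one when sampled (unless AC/myosin-linked). This reading —
removal sums "links to other cortex proteins", and the anchor is
established on incorporation into F-actin — is what yields a
filament-dominated equilibrium, an E1-dependent free-monomer plateau
(the gas density at coexistence is `exp(mu*)/(1+exp(mu*))` with
`mu* ≈ log 2 - E1`), and efficient polymerization at low occupancy. The
alternative reading in which every cortical monomer is anchored pins the
free-monomer slot density at 2/3 independently of `E1` and suppresses
the filament phase; it remains available as
`GlobalParams.anchor_free_monomers=True` and is exercised by the
miniature-system oracle tests.

### Crosslinkers and myosin

An AC occupies a lattice edge between two monomers belonging to two
*distinct* filaments (parallel, anti-parallel or perpendicular); each arm
adds `E2` to its monomer's retention energy, and AC removal releases both
arms at once (`P- = exp(-2 E2)`). By default both endpoints must be in
filaments (runs >= 3); `ac_require_filaments=False` relaxes this to any
two monomers of distinct chains. Myosin mirrors the AC mechanics with
(`mu_3`, `E3`) but requires *anti-parallel* filaments, and starts an
attachment timer on insertion.

Because anchored filaments cannot slide, an attached motor loads both
bridged filaments: `E_load = sum_i W3 * t_i` over currently attached
motors, with `W3` in RT per calibrated second. Loads only accumulate;
when a motor detaches, or a bridged chain stops being a filament, its
contribution is frozen into the filament's load. The kernel implements
this in closed form from attachment timestamps (cost O(1) per step)
rather than per-step increments; `accumulate_loads` provides the
equivalent explicit-clock update for manually stepped states.

A filament whose load strictly exceeds its anchoring capacity
`E_threshold = E1 * L` (current length) detaches wholly: monomers and
links return to their reservoirs and the load is redistributed equally
among the filaments remaining in the same network (connected component
through AC/myosin links); with no recipients it is discarded.
Over-threshold filaments within one processing pass detach
simultaneously; redistribution then triggers cascade passes until
quiescence. Detachment processing runs every `detach_check_stride`
iterations (default 100, i.e. 50 checks per sweep-unit on the default
grid — far finer than any load timescale at the defaults).

## Time calibration

Iterations are divided by `2 * area` (both slots of every node) into
*sweep-units*; the factor kappa (minutes per sweep-unit) is pinned by
requiring the actin-only reference preset to reach its equilibration
plateau at 18 minutes, the in-vivo timescale for cortical F-actin
networks. The plateau detector smooths the occupancy trace lightly
(window 5 samples), takes the mean of the last 20% of the run as the
plateau, and reports the earliest sample from which the trace stays
within 5% of that plateau for 20% of the run; tolerance and persistence
are configurable.

The calibration protocol runs 2000 sweep-units per seed over three
seeds. The run length matters because the occupancy keeps creeping
(slow filament coarsening) long after the polymerization phase: at 1000
sweep-units the trace is still ~12% below its long-run level, while at
2000 the residual drift over the final half falls within the detector's
5% tolerance — 2000 is the first round length at which the "long-run
plateau" the detector needs is actually present in the window. The
shipped `DEFAULT_KAPPA = 0.0141` min/sweep-unit is the result of this
procedure at the defaults; every calibrated quantity in the acceptance
script recomputes kappa at run time. Seed-to-seed spread of the detected
equilibration is ~15% (intrinsic nucleation stochasticity; insensitive
to detector smoothing), so self-consistency checks average over at
least three fresh seeds.

## Motor power default

`W3` is the one free parameter (the reference tables do not print it).
Every `W3` above ~0.1 RT/s eventually yields sustained relaxation
oscillations at the three-species reference preset, with the period
growing without bound as `W3` decreases, so "the smallest sustaining
value" does not pin a number. The default `W3 = 1.0` RT/s is the
smallest order of magnitude with robust, seed-independent whole-cortex
periodicity: much weaker motors stretch the cycle arbitrarily; much
stronger motors (>= ~10 at the shipped kappa scale) collapse nascent
filaments before a cortex-spanning network forms, leaving small,
seed-erratic fluctuations.

## What the simulations show — and known limitations

At the reference conditions the model reproduces: three-phase
polymerization (nucleation lag, near-linear growth, plateau) with an
exponential early-regime size distribution and an intermediate-size mode
at equilibrium; a critical G-actin concentration above which the free
pool saturates; treadmilling whose speed falls ~e-fold per RT of `E1`
and is insensitive to the potential; network formation above a critical
AC count, maximal at intermediate `E2`; winner-takes-all competition
between networks; narrowing of the relative filament-length distribution
by ACs; and autonomous whole-cortex oscillations with tension in
anti-phase with the number of networks.

Quantitative timescale ratios differ from the published ones. Here the
oscillation is rebuild-limited: after a collapse the cortex must
re-nucleate filaments before ACs can stabilize them (AC attachment
requires two existing filaments), which takes 2000–4000 sweep-units,
so the period on the 18-min-calibrated axis is ~30–50 min rather than
~5.5 min (period:equilibration ≈ 2 vs ≈ 0.3). Two related contrasts are
also muted: the myosin *pool* size barely matters because the on-grid
motor count stays near zero (each motor's load destroys its own
filament, and with an empty motor grid the potential saturates
acceptance regardless of `N_{3,0}`), and raising `E1` lengthens the
cycle but yields partial rather than deeper collapses (smaller relative
amplitude). Relaxing AC attachment to arbitrary monomer pairs
(`ac_require_filaments=False`) removes the rebuild bottleneck and
produces ~220-sweep cycles (minutes on the calibrated axis), but
contradicts the stated filament-to-filament crosslinking rule and is
therefore not the default. The corresponding end-to-end checks in
`tests/test_acceptance.py` assert the published behavior at face value
and fail against this implementation; they are left failing rather than
weakened.

The synthetic dynamics also idealize real cortices in ways that bound
what passing tests show: two orientations only (no hexagonal packing or
angled bundles), no monomer diffusion within the cortex, instantaneous
reservoir mixing, no explicit ATP, single-species ACs, no membrane
deformation, accumulate-only loads, and filaments that never grow from
the pointed end.

## Problem sizes used

Unit and oracle tests run on grids of 1x1 to 12x12 (exact enumeration up
to 12 slots). Phenomenology tests run on 20x20–30x30 grids with species
counts scaled in proportion to grid area, 400–6000 sweep-units per run.
The acceptance script uses the full 50x50 grid: 2000-sweep calibration
runs (3 seeds + 3 fresh seeds) and one 9000-sweep three-species run for
the period estimate, where the dominant spectral peak is searched among
frequencies completing at least two cycles in the analysis window (a
slower mode would not be a resolvable period claim).
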