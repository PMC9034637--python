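# cortexmc

A coarse-grained Monte Carlo simulator of the actomyosin cell cortex: a
two-dimensional membrane lattice that exchanges G-actin, actin
crosslinkers (ACs) and myosin II motors with a finite, instantly mixed
cytoplasmic reservoir. The model is aimed at the mesoscale physics of the
cortex — filament polymerization and treadmilling, crosslinked network
assembly, and the autonomous tension-driven oscillations seen in systems
such as the basal cortex of *Drosophila* follicle cells — for readers who
want a minimal, fully inspectable model rather than molecular detail.

## Model

Each lattice node holds one vertical (north/south) and one horizontal
(east/west) monomer slot, so perpendicular filaments may cross. Species
*i* ∈ {actin, AC, myosin} exchanges with the reservoir under a
semi-grand-canonical potential

```
μᵢ = μᵢ,₀ − γᵢ · log(Nᵢ / Nᵢ,₀)
```

where `Nᵢ` is the count currently on the grid and `Nᵢ,₀` the conserved
total. A Metropolis step samples one lattice position and evaluates, for
each species, an insertion with `P⁺ = exp(μᵢ)` or a removal with
`P⁻ = exp(−E)`, `E` being the total link energy holding the molecule:

* a polymer bond `E₀` (default 12 RT, from a ~30 kJ/mol bond at
  RT = 2.47 kJ/mol) for every filament monomer except the destabilized
  pointed-end terminal — filaments therefore grow at the barbed end,
  shrink at the pointed end, and treadmill;
* a membrane anchor `E₁` per monomer incorporated in a filament
  (a filament of length L detaches bodily when its myosin-imposed elastic
  load exceeds `E₁·L`);
* `E₂` per AC arm and `E₃` per myosin arm (removal of a link releases
  both arms: `P⁻ = exp(−2E)`).

ACs bridge monomers of two distinct filaments across a lattice edge;
myosin bridges anti-parallel filaments and, because anchored filaments
cannot slide, converts attachment time into elastic load
`E_load = Σᵢ W₃·tᵢ`. Detached filaments depolymerize instantly and their
load is redistributed homogeneously within their network — the cycle of
cooperative assembly, tension build-up and catastrophic collapse produces
autonomous whole-cortex oscillations in which tension is in anti-phase
with the number of networks.

Time is calibrated by dividing iterations by twice the grid area (one
*sweep-unit*) and pinning the actin-only equilibration of the reference
preset to 18 minutes, the in-vivo timescale for cortical F-actin network
equilibration.

## Worked example

```python
>>> import cortexmc as cm
>>> p = cm.preset("fig1")          # actin-only reference parameter set
>>> traj = cm.run(p, n_iterations=2_000_000, seed=1)
>>> traj.frame[["time_min", "occupancy_pct", "n_filaments"]].iloc[-1]
time_min          5.64
occupancy_pct    19.12
n_filaments      78.00
Name: 400, dtype: float64
>>> fils = cm.find_filaments(traj.final_state)
>>> len(fils), max(f.length for f in fils)
(78, 25)
```

After 400 sweep-units (5.64 calibrated minutes at the shipped κ) the
actin-only cortex holds ~19 % of its monomer slots, organized into 78
filaments up to 25 monomers long; the occupancy curve shows the
nucleation lag, near-linear polymerization and equilibrium plateau
regimes. The same run from the shell:

```
cortexmc run --preset fig1 -n 2000000 --seed 1 -o out/
cortexmc analyze out/timeseries.tsv
```

Presets named `fig1`, `fig2a`, …, `fig5bcd`, `fig6ab`, `s1`–`s4` encode
the published parameter rows (`cortexmc presets` lists them); `sweep`
runs parameter grids and `render` draws lattice snapshots (green actin,
blue ACs, red myosin).

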