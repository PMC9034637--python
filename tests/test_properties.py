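"""Figure-level phenomenology and global invariants.

These tests reproduce, at reduced grid sizes and iteration counts, the
qualitative behaviors the model is built to show: three-phase
polymerization, the critical G-actin concentration, treadmilling and its
parameter dependence, AC-driven network formation, network competition,
length homogenization, and the lattice/conservation invariants under
fuzzed sampling. Species counts are scaled with grid area so densities
match the reference conditions.
"""

import numpy as np
import pytest

from cortexmc import mc_kernel, observables
from cortexmc.calibration import preset
from cortexmc.mc_kernel import RngStream
from cortexmc.model_state import (ACTIN, GridState, SpeciesParams,
                                  check_conservation)
from cortexmc.observables import (chain_sizes, size_distribution,
                                  treadmilling_velocity)


def scaled(name, side, **overrides):
    """Preset with species counts scaled to a side x side grid."""
    p = preset(name, width=side, height=side)
    f = side * side / 2500.0

    def sc(sp):
        return SpeciesParams(sp.mu0, round(sp.N0 * f), sp.gamma, sp.E_link)

    return p.with_(actin=sc(p.actin), ac=sc(p.ac), myosin=sc(p.myosin),
                   **overrides)


def tail_mean(traj, col, frac=0.25):
    frame = traj.frame
    n = max(1, int(len(frame) * frac))
    return float(frame[col].iloc[-n:].mean())


# ---------------------------------------------------------------------------
# Polymerization dynamics
# ---------------------------------------------------------------------------


class TestPolymerizationPhases:
    def test_lag_growth_plateau(self):
        """Filament-bound actin shows nucleation lag, near-linear growth,
        then a plateau (three regimes)."""
        p = scaled("fig1", 24)
        stride = 2 * p.area
        traj = mc_kernel.run(p, n_iterations=700 * stride, seed=11,
                             record_stride=stride)
        infil = traj.frame["n_actin_filaments"].to_numpy(float)
        final = infil[-50:].mean()
        t10 = int(np.argmax(infil >= 0.1 * final))
        t80 = int(np.argmax(infil >= 0.8 * final))
        assert t10 >= 5, "nucleation lag phase missing"
        assert t80 > 3 * t10, "growth phase not separated from the lag"
        # near-linear mid segment
        seg = infil[t10:t80]
        x = np.arange(len(seg))
        slope, icpt = np.polyfit(x, seg, 1)
        r2 = 1 - ((seg - (slope * x + icpt)) ** 2).sum() / \
            ((seg - seg.mean()) ** 2).sum()
        assert r2 > 0.8, "mid phase not near-linear"
        # plateau: late slope much smaller than mid slope
        late = infil[-140:]
        late_slope = np.polyfit(np.arange(len(late)), late, 1)[0]
        assert abs(late_slope) < 0.3 * slope

    def test_size_distribution_regimes(self):
        """Early-regime filament sizes decay exponentially (log-linear fit);
        the equilibrium distribution peaks at an intermediate size."""
        from collections import Counter
        from cortexmc.model_state import load_snapshot
        early, late = Counter(), Counter()
        p = scaled("fig1", 24)
        stride = 2 * p.area
        for seed in (31, 32, 33):
            traj = mc_kernel.run(p, n_iterations=700 * stride, seed=seed,
                                 record_stride=stride, snapshot_stride=20)
            for it, recs in traj.snapshots:
                sweeps = it / stride
                target = early if 20 <= sweeps <= 80 else \
                    late if sweeps >= 550 else None
                if target is not None:
                    s = load_snapshot(recs, p)
                    for sz in chain_sizes(s, filaments_only=True):
                        target[sz] += 1
        ks = np.array(sorted(early))
        probs = np.array([early[k] for k in ks], float)
        probs /= probs.sum()
        coef = np.polyfit(ks, np.log(probs), 1)
        pred = np.polyval(coef, ks)
        r2 = 1 - ((np.log(probs) - pred) ** 2).sum() / \
            ((np.log(probs) - np.log(probs).mean()) ** 2).sum()
        assert coef[0] < 0 and r2 > 0.9, "early regime not exponential"
        mode = max(late, key=late.get)
        assert mode > 3, "equilibrium distribution should peak beyond the nucleus"


class TestCriticalConcentration:
    def test_free_monomer_plateau_above_threshold(self):
        """Above a critical total G-actin, the free-monomer pool saturates
        while total cortical actin keeps growing."""
        frees, totals = [], []
        for n0 in (150, 300, 600, 1200):
            p = scaled("fig1", 24).with_(
                actin=SpeciesParams(-5.0, n0, 2.0, 4.0))
            traj = mc_kernel.run(p, n_iterations=500 * 2 * p.area, seed=11)
            frees.append(tail_mean(traj, "n_free"))
            totals.append(tail_mean(traj, "n_actin_cortex"))
        d_total = totals[-1] - totals[-2]
        d_free = frees[-1] - frees[-2]
        assert d_total > 100, "total cortical actin should keep growing"
        assert abs(d_free) < 0.25 * d_total, "free pool should plateau"

    def test_occupancy_monotone_in_potential_and_anchor(self):
        """Equilibrium occupancy is non-decreasing in <mu1> and E1 on a
        coarse 3x3 grid of parameters."""
        occ = {}
        for mu0 in (-6.0, -5.0, -4.0):
            for e1 in (2.0, 3.0, 4.0):
                vals = []
                for seed in (1, 2):
                    p = scaled("fig2bc", 20).with_(
                        actin=SpeciesParams(mu0, 461, 2.0, e1))
                    traj = mc_kernel.run(p, n_iterations=500 * 2 * p.area,
                                         seed=seed)
                    vals.append(tail_mean(traj, "occupancy_pct"))
                occ[(mu0, e1)] = np.mean(vals)
        for mu0 in (-6.0, -5.0, -4.0):
            assert occ[(mu0, 2.0)] <= occ[(mu0, 3.0)] <= occ[(mu0, 4.0)]
        for e1 in (2.0, 3.0, 4.0):
            assert occ[(-6.0, e1)] <= occ[(-5.0, e1)] <= occ[(-4.0, e1)]


# ---------------------------------------------------------------------------
# Treadmilling
# ---------------------------------------------------------------------------


def _mean_speed(mu0, e1, seed):
    p = preset("fig3c", width=30, height=30).with_(
        actin=SpeciesParams(mu0, 1800, 1.0, e1))
    stride = 4 * 2 * p.area
    traj = mc_kernel.run(p, n_iterations=600 * 2 * p.area, seed=seed,
                         record_stride=stride, snapshot_stride=1)
    traj.snapshots = traj.snapshots[len(traj.snapshots) * 2 // 3:]
    df = treadmilling_velocity(traj)
    df = df[df["length"] >= 4]
    return float(df["speed"].mean())


class TestTreadmilling:
    def test_speed_decreases_with_anchor_energy(self):
        """Stronger membrane anchoring slows pointed-end loss and hence
        treadmilling; the drop is roughly e-fold per RT."""
        s3 = np.mean([_mean_speed(-3.0, 3.0, s) for s in (1, 2)])
        s5 = np.mean([_mean_speed(-3.0, 5.0, s) for s in (1, 2)])
        assert s3 > 2.0 * s5

    def test_speed_insensitive_to_potential(self):
        """Shifting <mu1> changes filament length, not speed: the relative
        speed change across mu is small compared with the E1 effect."""
        lo = np.mean([_mean_speed(-3.5, 4.0, s) for s in (1, 2)])
        hi = np.mean([_mean_speed(-2.5, 4.0, s) for s in (1, 2)])
        assert abs(hi - lo) / max(lo, hi) < 0.35


# ---------------------------------------------------------------------------
# Crosslinked networks
# ---------------------------------------------------------------------------


class TestNetworkFormation:
    def test_threshold_in_crosslinker_count(self):
        """Networks only form above a critical AC count."""
        sizes = []
        for n2 in (4, 140):
            p = scaled("fig4b", 24).with_(
                ac=SpeciesParams(-2.0, n2, 2.0, 3.0))
            traj = mc_kernel.run(p, n_iterations=500 * 2 * p.area, seed=21)
            sizes.append(tail_mean(traj, "largest_net"))
        assert sizes[1] > 4 * sizes[0]

    def test_network_size_peaks_at_intermediate_link_energy(self):
        """Weak links shuffle too fast, strong links freeze reorganization;
        the largest network is maximal at intermediate E2."""
        res = {}
        for e2 in (0.5, 3.0, 12.0):
            p = preset("fig4b").with_(ac=SpeciesParams(-2.0, 600, 2.0, e2))
            traj = mc_kernel.run(p, n_iterations=800 * 2 * p.area, seed=21)
            res[e2] = tail_mean(traj, "largest_net", frac=0.2)
        assert res[3.0] >= res[0.5]
        assert res[3.0] >= 1.1 * res[12.0]

    def test_largest_network_grows_at_expense_of_second(self):
        """Raising the AC:actin ratio, the largest network takes over and
        the runner-up shrinks (winner-takes-all competition)."""
        stats = []
        for n2 in (30, 400):
            L, S = [], []
            for seed in (41, 42):
                p = preset("fig4c", width=30, height=30).with_(
                    actin=SpeciesParams(-2.0, 1080, 2.0, 3.0),
                    ac=SpeciesParams(-2.0, n2, 2.0, 3.0))
                traj = mc_kernel.run(p, n_iterations=450 * 2 * p.area,
                                     seed=seed)
                L.append(tail_mean(traj, "largest_net"))
                S.append(tail_mean(traj, "second_net"))
            stats.append((np.mean(L), np.mean(S)))
        assert stats[1][0] > stats[0][0], "largest network should grow"
        assert stats[1][1] < stats[0][1], "second network should shrink"

    def test_crosslinkers_narrow_the_length_distribution(self):
        """ACs homogenize filament length: the relative width (CV) of the
        length distribution drops when ACs are present."""
        cvs = []
        for n2 in (0, 250):
            vals = []
            for seed in (51, 52):
                p = preset("fig4d", width=30, height=30).with_(
                    actin=SpeciesParams(-4.0, 2160, 2.0, 3.0),
                    ac=SpeciesParams(-4.0, n2, 2.0, 3.0))
                traj = mc_kernel.run(p, n_iterations=2000 * 2 * p.area,
                                     seed=seed)
                sizes = np.array(chain_sizes(traj.final_state,
                                             filaments_only=True))
                vals.append(sizes.std() / sizes.mean())
            cvs.append(np.mean(vals))
        assert cvs[1] < 0.85 * cvs[0]


# ---------------------------------------------------------------------------
# Oscillations
# ---------------------------------------------------------------------------


class TestOscillations:
    def test_tension_antiphase_with_network_count(self):
        """Tension rises while the cortex condenses into few networks and
        collapses when they detach: negative zero-lag correlation."""
        p = scaled("fig5bcd", 30)
        traj = mc_kernel.run(p, n_iterations=4000 * 2 * p.area, seed=7)
        f = traj.frame.iloc[len(traj.frame) // 4:]
        corr = observables.antiphase_correlation(f["tension_RT"],
                                                 f["n_networks"])
        assert corr < -0.1

    def test_actin_count_oscillates_with_dominant_peak(self):
        """The cortical actin count cycles between assembly and collapse
        with a spectral peak well above the background."""
        p = scaled("fig5bcd", 30)
        traj = mc_kernel.run(p, n_iterations=6000 * 2 * p.area, seed=7)
        a = traj.frame["n_actin_cortex"].to_numpy(float)[1:]
        burn = len(a) // 4
        osc = observables.oscillation_period(a[burn:], 1.0)
        assert osc["peak_significance"] > 5.0
        amp = np.percentile(a[burn:], 95) - np.percentile(a[burn:], 5)
        assert amp > 0.2 * a[burn:].mean(), "whole-cortex amplitude expected"

# ---------------------------------------------------------------------------
# Invariants under fuzzed sampling
# ---------------------------------------------------------------------------


def _integrity(state: GridState) -> None:
    # no same-axis overlap by construction of the arrays; chains consistent
    for slot, chain in enumerate(state.chain_by_slot):
        node, axis = slot >> 1, slot & 1
        arr = state.horz if axis else state.vert
        if chain is None:
            assert arr[node] == 0
        else:
            assert arr[node] == chain.ori and node in chain.cells
    for chain in state.chains.values():
        assert len(chain.cells) >= 1
        for cell in chain.cells:
            assert state.chain_by_slot[cell * 2 + chain.axis] is chain
    for edge, link in list(state.ac_edges.items()) + \
            list(state.myo_edges.items()):
        for s in (link.slot_a, link.slot_b):
            assert state.chain_by_slot[s] is not None, \
                "dangling link endpoint"


class TestFuzzedInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_conservation_and_lattice_integrity(self, seed):
        """Species conservation, slot exclusivity and link integrity hold
        along aggressive three-species trajectories."""
        p = preset("fig5a", width=10, height=10).with_(
            actin=SpeciesParams(-1.0, 120, 1.0, 1.0),
            ac=SpeciesParams(-1.0, 40, 1.0, 2.0),
            myosin=SpeciesParams(-1.0, 40, 1.0, 2.0),
            W3=20.0, detach_check_stride=23)
        state = GridState(p)
        rng = RngStream(seed)
        for i in range(30_000):
            mc_kernel.mc_step(state, p, rng)
            if i % 1500 == 0:
                assert check_conservation(state, p)
                _integrity(state)
        assert check_conservation(state, p)
        _integrity(state)

    def test_loads_never_negative_and_tension_matches_sum(self):
        p = preset("fig5bcd", width=12, height=12).with_(
            actin=SpeciesParams(-1.0, 150, 1.0, 1.0),
            ac=SpeciesParams(-2.0, 60, 1.0, 3.0),
            myosin=SpeciesParams(-2.0, 40, 1.0, 3.0), W3=5.0)
        state = GridState(p)
        rng = RngStream(9)
        for _ in range(40_000):
            mc_kernel.mc_step(state, p, rng)
        it, w3dt = state.iteration, state.w3_dt
        for c in state.chains.values():
            assert c.load(it, w3dt) >= -1e-9
        assert observables.total_tension(state) == pytest.approx(
            sum(c.load(it, w3dt) for c in state.chains.values()
                if len(c.cells) >= 3))
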