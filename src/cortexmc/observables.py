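"""Observables: occupancy, censuses, networks, tension, treadmilling and
oscillation analysis.

Everything here is a pure function of a grid state or of a recorded
trajectory; nothing mutates the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_state import (ACTIN, AC, MYOSIN, GlobalParams, GridState,
                          snapshot_records)

TIMESERIES_COLUMNS = [
    "iteration", "time_min", "n_actin_cortex", "n_actin_filaments", "n_free",
    "n_ac", "n_myosin", "n_filaments", "occupancy_pct", "n_networks",
    "largest_net", "second_net", "tension_RT",
]


# ---------------------------------------------------------------------------
# State-level observables
# ---------------------------------------------------------------------------


def occupancy(state: GridState) -> float:
    """Percentage of monomer slots occupied; capacity is 2 slots per node."""
    return 100.0 * state.n_grid[ACTIN] / (2.0 * state.n_nodes)


def size_distribution(sizes: Iterable[int], weighted: bool = False) -> dict:
    """Normalized histogram over chain sizes (monomer units).

    ``weighted=True`` weights each size class by its monomer content
    (fraction of monomers held in chains of that size)."""
    counts: dict[int, float] = {}
    for s in sizes:
        counts[s] = counts.get(s, 0.0) + (s if weighted else 1.0)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {s: c / total for s, c in sorted(counts.items())}


def chain_sizes(state: GridState, filaments_only: bool = False) -> list[int]:
    return [len(c.cells) for c in state.chains.values()
            if len(c.cells) >= (3 if filaments_only else 1)]


def find_networks(state: GridState) -> list[list[int]]:
    """Connected components of filaments joined by AC/myosin links.

    A *network* is a component of >= 2 filaments; returned as lists of
    chain ids, largest first."""
    from .myosin_rules import _filament_components
    comps = [sorted(c.cid for c in comp)
             for comp in _filament_components(state).values() if len(comp) >= 2]
    comps.sort(key=lambda c: (-len(c), c))
    return comps


def network_monomer_sizes(state: GridState) -> list[int]:
    """Network sizes in monomers, largest first."""
    from .myosin_rules import _filament_components
    sizes = [sum(len(c.cells) for c in comp)
             for comp in _filament_components(state).values() if len(comp) >= 2]
    return sorted(sizes, reverse=True)


def total_tension(state: GridState) -> float:
    """Sum of E_load over attached filaments, RT."""
    it, w3dt = state.iteration, state.w3_dt
    return sum(c.load(it, w3dt) for c in state.chains.values()
               if len(c.cells) >= 3)


def record_row(state: GridState, time_min: float) -> dict:
    n_fil_monomers = sum(len(c.cells) for c in state.chains.values()
                         if len(c.cells) >= 3)
    nets = network_monomer_sizes(state)
    return {
        "iteration": state.iteration,
        "time_min": time_min,
        "n_actin_cortex": state.n_grid[ACTIN],
        "n_actin_filaments": n_fil_monomers,
        "n_free": state.n_grid[ACTIN] - n_fil_monomers,
        "n_ac": state.n_grid[AC],
        "n_myosin": state.n_grid[MYOSIN],
        "n_filaments": sum(1 for c in state.chains.values()
                           if len(c.cells) >= 3),
        "occupancy_pct": occupancy(state),
        "n_networks": len(nets),
        "largest_net": nets[0] if nets else 0,
        "second_net": nets[1] if len(nets) > 1 else 0,
        "tension_RT": total_tension(state),
    }


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-indexed record of a run: one row per recording stride, optional
    full snapshots for filament tracking."""

    params: GlobalParams
    record_stride: int
    snapshot_stride: Optional[int]
    rows: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)   # (iteration, records)
    frame: Optional[pd.DataFrame] = None
    final_state: Optional[GridState] = None

    @classmethod
    def empty(cls, params: GlobalParams, record_stride: int,
              snapshot_stride: Optional[int]) -> "Trajectory":
        return cls(params, record_stride, snapshot_stride)

    @property
    def dt_min(self) -> float:
        """Calibrated minutes between consecutive records."""
        return self.record_stride / (2.0 * self.params.area) * self.params.kappa

    def time_of(self, iteration: int) -> float:
        return iteration / (2.0 * self.params.area) * self.params.kappa

    def record(self, state: GridState) -> None:
        self.rows.append(record_row(state, self.time_of(state.iteration)))

    def snapshot(self, state: GridState) -> None:
        self.snapshots.append((state.iteration, snapshot_records(state)))

    def finalize(self) -> pd.DataFrame:
        self.frame = pd.DataFrame(self.rows, columns=TIMESERIES_COLUMNS)
        return self.frame

    def to_tsv(self, path) -> None:
        """Pinned TSV format: tab separator, '.' decimal, LF endings."""
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n",
                          float_format="%.6g")


# ---------------------------------------------------------------------------
# Series analysis
# ---------------------------------------------------------------------------


def smooth_series(series: Sequence[float], window: int) -> np.ndarray:
    """Second-order centered moving average (applied twice); the window
    shrinks near the edges so output length equals input length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    for _ in range(2):
        s = s.rolling(window, center=True, min_periods=1).mean()
    return s.to_numpy()


def oscillation_period(series: Sequence[float], dt: float,
                       min_cycles: int = 1) -> dict:
    """Dominant Fourier period of a uniformly sampled series.

    Removes the mean, computes the one-sided power spectrum and returns the
    period (in the units of ``dt``) of the strongest non-zero-frequency
    peak together with its ratio to the median spectral power.
    ``min_cycles`` restricts the search to frequencies completing at least
    that many cycles in the window (a period claim needs >= 2 observed
    cycles to be resolvable; the default keeps every non-DC bin)."""
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=dt)
    lo = max(1, int(min_cycles))
    power, freqs = power[lo:], freqs[lo:]        # drop DC (+ unresolved bins)
    k = int(np.argmax(power))
    med = float(np.median(power))
    if power[k] == 0.0:
        significance = 1.0          # flat series: no peak at all
    elif med > 0:
        significance = float(power[k] / med)
    else:
        significance = float("inf")
    return {"period_min": float(1.0 / freqs[k]),
            "peak_significance": significance}


def antiphase_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Zero-lag Pearson correlation between two series (negative values
    mean anti-phase)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Treadmilling
# ---------------------------------------------------------------------------


def _filaments_from_records(records: list[dict]) -> list[dict]:
    out = []
    for rec in records:
        if rec["type"] == "chain" and len(rec["cells"]) >= 3:
            out.append({"orientation": rec["orientation"],
                        "cells": [tuple(c) for c in rec["cells"]]})
    return out


def _centroid(fil: dict, width: int, height: int) -> tuple[float, float]:
    # unwrap along the filament axis, anchored at the pointed end
    cells = fil["cells"]
    x0, y0 = cells[0]
    xs, ys = [float(x0)], [float(y0)]
    px, py = x0, y0
    for (x, y) in cells[1:]:
        dx = (x - px + width // 2) % width - width // 2
        dy = (y - py + height // 2) % height - height // 2
        xs.append(xs[-1] + dx)
        ys.append(ys[-1] + dy)
        px, py = x, y
    return sum(xs) / len(xs), sum(ys) / len(ys)


def _match(prev: list[dict], cur: list[dict]) -> list[tuple[int, int]]:
    """Greedy identity matching by maximal monomer-position overlap among
    same-orientation filaments; ties broken by pointed-end proximity."""
    scored = []
    for i, f in enumerate(prev):
        fset = set(f["cells"])
        for j, g in enumerate(cur):
            if g["orientation"] != f["orientation"]:
                continue
            ov = len(fset & set(g["cells"]))
            if ov:
                d = abs(f["cells"][0][0] - g["cells"][0][0]) + \
                    abs(f["cells"][0][1] - g["cells"][0][1])
                scored.append((-ov, d, i, j))
    scored.sort()
    used_i, used_j, pairs = set(), set(), []
    for _, _, i, j in scored:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            pairs.append((i, j))
    return pairs


def treadmilling_velocity(traj: Trajectory) -> pd.DataFrame:
    """Per-interval centroid speeds of filaments tracked across snapshots.

    Returns a tidy frame (time_min, speed, length) with speed in lattice
    units per calibrated minute; filament identity follows maximal position
    overlap with shared orientation."""
    if len(traj.snapshots) < 2:
        raise ValueError("need at least two snapshots")
    W, H = traj.params.width, traj.params.height
    rows = []
    prev_it, prev = traj.snapshots[0]
    prev_f = _filaments_from_records(prev)
    for it, recs in traj.snapshots[1:]:
        cur_f = _filaments_from_records(recs)
        dt = traj.time_of(it) - traj.time_of(prev_it)
        for i, j in _match(prev_f, cur_f):
            ax0, ay0 = _centroid(prev_f[i], W, H)
            ax1, ay1 = _centroid(cur_f[j], W, H)
            dx = (ax1 - ax0 + W / 2) % W - W / 2
            dy = (ay1 - ay0 + H / 2) % H - H / 2
            rows.append({"time_min": traj.time_of(it),
                         "speed": math.hypot(dx, dy) / dt,
                         "length": len(cur_f[j]["cells"])})
        prev_it, prev_f = it, cur_f
    return pd.DataFrame(rows, columns=["time_min", "speed", "length"])


def mean_treadmilling_speed(traj: Trajectory) -> float:
    df = treadmilling_velocity(traj)
    return float(df["speed"].mean()) if len(df) else 0.0


def analyze_timeseries(frame: pd.DataFrame, min_significance: float = 5.0) -> dict:
    """Summary of a recorded time series: oscillation period/significance,
    amplitude, and the tension/network anti-phase correlation."""
    t = frame["time_min"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    actin = frame["n_actin_cortex"].to_numpy(float)
    out: dict = {"n_samples": int(len(frame)), "dt_min": dt}
    if len(frame) >= 8 and actin.std() > 0:
        osc = oscillation_period(actin, dt)
        out.update(osc)
        out["oscillating"] = bool(osc["peak_significance"] >= min_significance)
        half = len(actin) // 2
        tail = actin[half:]
        out["amplitude"] = float(np.percentile(tail, 95) - np.percentile(tail, 5))
    else:
        out.update({"period_min": None, "peak_significance": None,
                    "oscillating": False, "amplitude": 0.0})
    if "tension_RT" in frame and "n_networks" in frame:
        out["tension_network_corr"] = antiphase_correlation(
            frame["tension_RT"], frame["n_networks"])
    return out
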