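"""Simulated flow-sorter gating and replication-timing profiles.

Snapshots of an asynchronous population are sorted by DNA content into G
gates (default 6; content maps affinely to the replicated fraction, so gate
boundaries live in (0, 1)). A bin's replication time is the count-weighted
average gate index: T = sum(g * c_g) / sum(c_g), so smaller values mean
earlier replication. Gate boundaries can be fitted to an empirical profile
by simulated annealing on the Euclidean distance between profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import BinnedTrack, GenomeIndex
from .replication_engine import PopulationResult, SnapshotStream

DEFAULT_N_GATES = 6

__all__ = [
    "DEFAULT_N_GATES",
    "GateSpec",
    "GateCounts",
    "gate_of",
    "accumulate",
    "timing_profile",
    "population_profile",
    "OptimizeResult",
    "optimize_gates",
]


@dataclass(frozen=True)
class GateSpec:
    """Strictly increasing replicated-fraction cut points in (0, 1);
    G gates have G-1 boundaries."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        arr = np.array(b)
        if len(arr) == 0:
            raise ValueError("at least one boundary required")
        if arr.min() <= 0 or arr.max() >= 1 or (np.diff(arr) <= 0).any():
            raise ValueError("boundaries must be strictly increasing within (0, 1)")

    @property
    def n_gates(self) -> int:
        return len(self.boundaries) + 1

    @classmethod
    def equidistant(cls, n_gates: int = DEFAULT_N_GATES) -> "GateSpec":
        if n_gates < 2:
            raise ValueError("need at least 2 gates")
        return cls(tuple(i / n_gates for i in range(1, n_gates)))


def gate_of(replicated_fraction: float, gates: GateSpec) -> int:
    """1-based gate index of the half-open interval (b_{g-1}, b_g] holding
    the fraction, with b_0 = 0 and b_G = 1."""
    f = float(replicated_fraction)
    if not 0 < f <= 1:
        raise ValueError("replicated fraction must be in (0, 1]; filter G-phase cells")
    return int(np.searchsorted(gates.boundaries, f, side="left")) + 1


@dataclass
class GateCounts:
    """Per-bin occurrence counts across gates: counts[g-1, bin] = number of
    snapshots in gate g in which the bin was replicated."""

    chroms: tuple[str, ...]
    offsets: tuple[int, ...]
    n_bins: int
    counts: np.ndarray  # (G, n_bins) int64

    @property
    def n_gates(self) -> int:
        return self.counts.shape[0]


def accumulate(stream: SnapshotStream, gates: GateSpec) -> GateCounts:
    """Gate every snapshot once by its replicated fraction and increment
    each replicated bin's count in that gate."""
    G = gates.n_gates
    counts = np.zeros((G, stream.n_bins), dtype=np.int64)
    if len(stream):
        gate_idx = np.searchsorted(gates.boundaries, stream.fractions, side="left")
        for g in range(G):
            sel = gate_idx == g
            if sel.any():
                counts[g] = stream.masks[sel].sum(axis=0)
    return GateCounts(stream.chroms, stream.offsets, stream.n_bins, counts)


def timing_profile(counts: GateCounts) -> np.ndarray:
    """Per-bin weighted-average gate index; NaN where a bin was never
    observed replicated."""
    g = np.arange(1, counts.n_gates + 1, dtype=float)[:, None]
    total = counts.counts.sum(axis=0)
    out = np.full(counts.n_bins, np.nan)
    nz = total > 0
    out[nz] = (g * counts.counts).sum(axis=0)[nz] / total[nz]
    return out


def population_profile(pop: PopulationResult, gates: GateSpec | None = None) -> BinnedTrack:
    """Timing profile of a whole simulated population as a genome track."""
    gates = gates or GateSpec.equidistant()
    data = {c: np.full(pop.genome.n_bins(c), np.nan) for c in pop.genome.names}
    for unit in pop.units:
        profile = timing_profile(accumulate(unit, gates))
        for chrom, off in zip(unit.chroms, unit.offsets):
            nb = pop.genome.n_bins(chrom)
            data[chrom] = profile[off : off + nb]
    return BinnedTrack(pop.genome, data)


# ---------------------------------------------------------------------------
# gate optimization


class _UnitEvaluator:
    """Fast timing-profile recomputation for one unit under moving gate
    boundaries.

    Snapshots are aggregated by their (discrete) replicated fraction into a
    cumulative mask-sum matrix, so the counts of any gate are a difference
    of two cumulative rows and one evaluation costs O(G * bins). The
    per-bin count total is invariant under boundary moves.
    """

    def __init__(self, stream: SnapshotStream, empirical: np.ndarray):
        if len(stream) == 0:
            raise ValueError("no snapshots to gate")
        self.uniq, inv = np.unique(stream.fractions, return_inverse=True)
        agg = np.zeros((len(self.uniq), stream.n_bins))
        np.add.at(agg, inv, stream.masks.astype(float))
        self.cum = np.vstack([np.zeros(stream.n_bins), np.cumsum(agg, axis=0)])
        self.total = self.cum[-1]
        self.valid = ~np.isnan(empirical) & (self.total > 0)
        self.empirical = empirical

    def profile(self, boundaries: np.ndarray) -> np.ndarray:
        edges = np.searchsorted(self.uniq, np.concatenate([boundaries, [1.0]]), side="right")
        edges = np.concatenate([[0], edges])
        w = np.zeros_like(self.total)
        for g in range(len(edges) - 1):
            w += (g + 1) * (self.cum[edges[g + 1]] - self.cum[edges[g]])
        out = np.full_like(self.total, np.nan)
        nz = self.total > 0
        out[nz] = w[nz] / self.total[nz]
        return out

    def sq_distance(self, boundaries: np.ndarray) -> float:
        prof = self.profile(boundaries)
        d = prof[self.valid] - self.empirical[self.valid]
        return float(d @ d)


@dataclass
class OptimizeResult:
    gates: GateSpec
    objective: float
    initial_objective: float
    n_accepted: int
    trace: np.ndarray  # best objective after each iteration


def optimize_gates(
    streams: SnapshotStream | Sequence[SnapshotStream],
    empirical: np.ndarray | BinnedTrack,
    init: GateSpec | None = None,
    n_iter: int = 2000,
    sigma: float = 0.01,
    t0: float | None = None,
    t_end_factor: float = 1e-4,
    seed: int = 0,
) -> OptimizeResult:
    """Fit gate boundaries to an empirical timing profile by simulated
    annealing.

    Each move perturbs one uniformly chosen boundary by a Normal(old, sigma)
    draw on the replicated-fraction scale (sigma = 0.01, i.e. one percentage
    point of DNA content); proposals violating ordering or range are
    rejected outright, others by the Metropolis criterion on the Euclidean
    distance between the regated simulated profile and the empirical one,
    under a geometric cooling schedule. The best-ever boundary vector is
    returned.
    """
    if isinstance(streams, SnapshotStream):
        streams = [streams]
    if isinstance(empirical, BinnedTrack):
        emp_vecs = [_unit_empirical(s, empirical) for s in streams]
    else:
        if len(streams) != 1:
            raise ValueError("pass a BinnedTrack empirical profile for multi-unit input")
        emp_vecs = [np.asarray(empirical, dtype=float)]
    init = init or GateSpec.equidistant()
    evs = [_UnitEvaluator(s, e) for s, e in zip(streams, emp_vecs)]
    if not any(ev.valid.any() for ev in evs):
        raise ValueError("no overlapping defined bins between profiles")

    def objective(boundaries: np.ndarray) -> float:
        return math.sqrt(sum(ev.sq_distance(boundaries) for ev in evs))

    rng = np.random.default_rng(seed)
    cur = np.array(init.boundaries)
    cur_obj = objective(cur)
    best, best_obj = cur.copy(), cur_obj
    initial_obj = cur_obj
    if t0 is None:
        t0 = max(0.1 * initial_obj, 1e-12)
    cooling = t_end_factor ** (1.0 / max(n_iter, 1))
    temp = t0
    n_accepted = 0
    trace = np.empty(n_iter)
    for it in range(n_iter):
        prop = cur.copy()
        j = int(rng.integers(len(cur)))
        prop[j] = rng.normal(cur[j], sigma)
        ok = 0.0 < prop[0] and prop[-1] < 1.0 and (np.diff(prop) > 0).all()
        if ok:
            obj = objective(prop)
            if obj < cur_obj or rng.random() < math.exp(-(obj - cur_obj) / temp):
                cur, cur_obj = prop, obj
                n_accepted += 1
                if obj < best_obj:
                    best, best_obj = prop.copy(), obj
        temp *= cooling
        trace[it] = best_obj
    return OptimizeResult(
        gates=GateSpec(tuple(best)),
        objective=best_obj,
        initial_objective=initial_obj,
        n_accepted=n_accepted,
        trace=trace,
    )


def _unit_empirical(stream: SnapshotStream, empirical: BinnedTrack) -> np.ndarray:
    """Empirical per-chromosome values arranged in the unit's concatenated
    bin order."""
    vec = np.full(stream.n_bins, np.nan)
    for chrom, off in zip(stream.chroms, stream.offsets):
        vals = empirical[chrom]
        vec[off : off + len(vals)] = vals
    return vec
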