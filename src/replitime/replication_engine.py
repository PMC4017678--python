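"""Stochastic replication engine.

A simulated cell cycles between a non-replicating G state and a replicating
S state. In S, each of ``N`` rate-limiting factors is either free or drives
one bidirectional replication bubble. Per step, every free factor selects a
uniformly random bin of its territory and, if the bin is unreplicated,
engages there with the probability the IPLS assigns to that bin (the
initiation probability at a location is thus the product of the chance of
selecting an unreplicated site, the IPLS value, and the number of free
factors). Engaged bubbles advance each unblocked fork edge by one bin per
step; an edge meeting replicated territory or a chromosome end blocks, and
a bubble with both edges blocked dissolves, returning its factor to the
pool. The genome is fully replicated when every bin is; the cell then
re-enters G.

Timing profiles emerge from periodic snapshots of many independent cycles
(the population is asynchronous because the G→S transition is a geometric
random wait and S-phase trajectories are stochastic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GenomeIndex
from .ipls import IPLS

# Fork-density regression: optimal factor count N grows linearly with
# chromosome length x (bases) as N = intercept + slope * x, i.e. about one
# fork per 1.3 Mb.
FORK_DENSITY_INTERCEPT = 10.24
FORK_DENSITY_SLOPE = 7.9e-7

DEFAULT_G_TO_S_PROB = 1.0 / 500.0
DEFAULT_SNAPSHOT_PERIOD = 10

__all__ = [
    "FORK_DENSITY_INTERCEPT",
    "FORK_DENSITY_SLOPE",
    "SimConfig",
    "CellState",
    "SnapshotStream",
    "PopulationResult",
    "estimate_forks",
    "make_territory",
    "new_cell",
    "step_cell",
    "run_cycle",
    "run_population",
    "save_population",
    "load_population",
]


def estimate_forks(chrom_length: int) -> int:
    """Factor count for a chromosome from the fork-density regression,
    clamped to at least 1."""
    if chrom_length < 0:
        raise ValueError("chromosome length must be nonnegative")
    return max(1, int(np.rint(FORK_DENSITY_INTERCEPT + FORK_DENSITY_SLOPE * chrom_length)))


@dataclass
class SimConfig:
    """Engine parameters.

    ``n_factors`` may be an integer (shared by every simulation unit) or
    ``"auto"`` to use :func:`estimate_forks` per chromosome. ``max_steps``
    defaults to ``50 * B / (2N)`` per unit; cycles hitting it are flagged
    incomplete and excluded from profiles.
    """

    ipls: IPLS
    n_factors: int | str = "auto"
    n_cycles: int = 100
    seed: int = 0
    snapshot_period: int = DEFAULT_SNAPSHOT_PERIOD
    g_to_s_prob: float = DEFAULT_G_TO_S_PROB
    max_steps: int | None = None
    shared_pool: bool = False
    record_initiations: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.n_factors, str):
            if self.n_factors != "auto":
                raise ValueError("n_factors must be a positive int or 'auto'")
        elif self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.snapshot_period < 1:
            raise ValueError("snapshot_period must be >= 1")
        if not 0 < self.g_to_s_prob <= 1:
            raise ValueError("g_to_s_prob must be in (0, 1]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")


@dataclass
class Territory:
    """Concatenated bin territory one cell replicates: one chromosome by
    default, or the whole genome for a shared factor pool. ``is_start``
    marks bins that begin a chromosome (fork edges block there).
    ``competent`` lists the bins a searching factor can select — every bin
    with nonzero initiation probability (all bins whenever the landscape
    has a positive background floor)."""

    chroms: tuple[str, ...]
    offsets: tuple[int, ...]  # start index of each chromosome's bins
    probs: np.ndarray  # per-bin initiation probability
    is_start: np.ndarray  # bool, True where a chromosome begins
    competent: np.ndarray  # indices of bins with probs > 0

    @property
    def n_bins(self) -> int:
        return len(self.probs)


def make_territory(ipls: IPLS, chroms: Sequence[str] | None = None) -> Territory:
    chroms = tuple(chroms) if chroms is not None else ipls.genome.names
    parts = [ipls.values(c) for c in chroms]
    probs = np.concatenate(parts)
    is_start = np.zeros(len(probs), dtype=bool)
    offsets = []
    pos = 0
    for p in parts:
        offsets.append(pos)
        is_start[pos] = True
        pos += len(p)
    return Territory(chroms, tuple(offsets), probs, is_start, np.flatnonzero(probs > 0))


@dataclass
class CellState:
    """One cell's replication bookkeeping.

    ``bubbles`` holds ``[left_edge, right_edge, left_blocked, right_blocked]``
    per engaged factor; ``free_factors + len(bubbles) == N`` throughout S.
    """

    n_factors: int
    replicated: np.ndarray
    bubbles: list = field(default_factory=list)
    free_factors: int = 0
    phase: str = "G"
    s_step: int = 0
    n_replicated: int = 0
    last_new_bins: int = 0
    last_initiations: list = field(default_factory=list)


def new_cell(n_factors: int, n_bins: int) -> CellState:
    return CellState(
        n_factors=n_factors,
        replicated=np.zeros(n_bins, dtype=bool),
        free_factors=n_factors,
        phase="S",
    )


def step_cell(cell: CellState, territory: Territory, rng: np.random.Generator) -> CellState:
    """Advance one S-phase step in place: elongate bubbles, dissolve
    collided ones, then give each free factor one initiation attempt."""
    replicated = cell.replicated
    is_start = territory.is_start
    B = territory.n_bins
    n_new = 0

    surviving = []
    for bub in cell.bubbles:
        l, r, lb, rb = bub
        if not lb:
            if is_start[l] or replicated[l - 1]:
                lb = True
            else:
                l -= 1
                replicated[l] = True
                n_new += 1
        if not rb:
            if r == B - 1 or is_start[r + 1] or replicated[r + 1]:
                rb = True
            else:
                r += 1
                replicated[r] = True
                n_new += 1
        if lb and rb:
            cell.free_factors += 1
        else:
            bub[0], bub[1], bub[2], bub[3] = l, r, lb, rb
            surviving.append(bub)
    cell.bubbles = surviving

    initiations = []
    n_free = cell.free_factors
    if n_free:
        draws = territory.competent[
            rng.integers(0, len(territory.competent), size=n_free)
        ]
        accept = rng.random(n_free)
        for target, u in zip(draws, accept):
            if not replicated[target] and u < territory.probs[target]:
                replicated[target] = True
                n_new += 1
                cell.bubbles.append([int(target), int(target), False, False])
                cell.free_factors -= 1
                initiations.append(int(target))

    cell.n_replicated += n_new
    cell.last_new_bins = n_new
    cell.last_initiations = initiations
    cell.s_step += 1
    return cell


@dataclass
class CycleResult:
    s_length: int
    completed: bool
    snapshot_steps: list
    snapshot_fractions: list
    snapshot_masks: list
    initiation_steps: np.ndarray | None = None  # (step, bin) pairs
    replicated_series: np.ndarray | None = None  # replicated count after each step


def run_cycle(
    territory: Territory,
    n_factors: int,
    rng: np.random.Generator,
    snapshot_period: int = DEFAULT_SNAPSHOT_PERIOD,
    g_to_s_prob: float = DEFAULT_G_TO_S_PROB,
    max_steps: int | None = None,
    record_initiations: bool = False,
) -> CycleResult:
    """Simulate one full cell cycle (geometric G wait, then S until the
    territory is replicated or ``max_steps``). Snapshots of the replicated
    mask are taken every ``snapshot_period`` steps on a population clock
    whose phase is set by the G wait; snapshots with nothing replicated yet
    are not emitted (a sorter would gate such a cell with G1 content)."""
    B = territory.n_bins
    if max_steps is None:
        max_steps = int(50 * max(1, B / (2 * n_factors)))
    g_wait = int(rng.geometric(g_to_s_prob))
    phase_offset = g_wait % snapshot_period

    cell = new_cell(n_factors, B)
    steps, fracs, masks = [], [], []
    init_events = [] if record_initiations else None
    series = [] if record_initiations else None
    completed = False
    while cell.s_step < max_steps:
        step_cell(cell, territory, rng)
        if record_initiations:
            for b in cell.last_initiations:
                init_events.append((cell.s_step, b))
            series.append(cell.n_replicated)
        if (cell.s_step + phase_offset) % snapshot_period == 0 and cell.n_replicated > 0:
            steps.append(cell.s_step)
            fracs.append(cell.n_replicated / B)
            masks.append(cell.replicated.copy())
        if cell.n_replicated == B:
            completed = True
            break
    cell.phase = "G"
    return CycleResult(
        s_length=cell.s_step,
        completed=completed,
        snapshot_steps=steps,
        snapshot_fractions=fracs,
        snapshot_masks=masks,
        initiation_steps=(
            np.array(init_events, dtype=np.int64).reshape(-1, 2)
            if record_initiations
            else None
        ),
        replicated_series=(
            np.array(series, dtype=np.int64) if record_initiations else None
        ),
    )


@dataclass
class SnapshotStream:
    """Periodic replication-state snapshots of one simulation unit,
    concatenated over cycles."""

    chroms: tuple[str, ...]
    offsets: tuple[int, ...]
    n_bins: int
    fractions: np.ndarray  # (n_snapshots,)
    masks: np.ndarray  # (n_snapshots, n_bins) bool
    cycle_ids: np.ndarray
    s_steps: np.ndarray

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass
class PopulationResult:
    """Aggregated output of :func:`run_population`."""

    genome: GenomeIndex
    units: list[SnapshotStream]
    s_lengths: np.ndarray  # completed cycles only, pooled over units
    n_incomplete: int
    n_factors_used: dict[str, int]
    initiations: list | None = None  # per unit: list of (step, bin) arrays
    replicated_series: list | None = None  # per unit: list of count series

    @property
    def n_snapshots(self) -> int:
        return sum(len(u) for u in self.units)


def _unit_rng(seed: int, unit_idx: int, cycle: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(unit_idx, cycle))
    )


def run_population(cfg: SimConfig) -> PopulationResult:
    """Simulate ``n_cycles`` independent cell cycles per unit.

    By default each chromosome is its own simulation unit with its own
    factor pool (``n_factors`` or the per-chromosome fork-density estimate);
    with ``shared_pool`` the whole genome is one unit sharing one pool.
    Cycle RNGs derive from ``(seed, unit, cycle)`` so results are
    reproducible and order-independent.
    """
    genome = cfg.ipls.genome
    if cfg.shared_pool:
        territories = [make_territory(cfg.ipls)]
        if cfg.n_factors == "auto":
            ns = [sum(estimate_forks(genome.length(c)) for c in genome.names)]
        else:
            ns = [int(cfg.n_factors)]
        n_used = {c: ns[0] for c in genome.names}
    else:
        territories = [make_territory(cfg.ipls, [c]) for c in genome.names]
        if cfg.n_factors == "auto":
            ns = [estimate_forks(genome.length(c)) for c in genome.names]
        else:
            ns = [int(cfg.n_factors)] * len(territories)
        n_used = dict(zip(genome.names, ns))

    units, s_lengths = [], []
    n_incomplete = 0
    all_inits = [] if cfg.record_initiations else None
    all_series = [] if cfg.record_initiations else None
    for ui, (terr, n_factors) in enumerate(zip(territories, ns)):
        steps, fracs, masks, cids = [], [], [], []
        unit_inits, unit_series = [], []
        for cycle in range(cfg.n_cycles):
            rng = _unit_rng(cfg.seed, ui, cycle)
            res = run_cycle(
                terr,
                n_factors,
                rng,
                snapshot_period=cfg.snapshot_period,
                g_to_s_prob=cfg.g_to_s_prob,
                max_steps=cfg.max_steps,
                record_initiations=cfg.record_initiations,
            )
            if not res.completed:
                n_incomplete += 1
                continue
            s_lengths.append(res.s_length)
            steps.extend(res.snapshot_steps)
            fracs.extend(res.snapshot_fractions)
            masks.extend(res.snapshot_masks)
            cids.extend([cycle] * len(res.snapshot_steps))
            if cfg.record_initiations:
                unit_inits.append(res.initiation_steps)
                unit_series.append(res.replicated_series)
        units.append(
            SnapshotStream(
                chroms=terr.chroms,
                offsets=terr.offsets,
                n_bins=terr.n_bins,
                fractions=np.array(fracs, dtype=float),
                masks=(
                    np.stack(masks) if masks else np.zeros((0, terr.n_bins), dtype=bool)
                ),
                cycle_ids=np.array(cids, dtype=np.int64),
                s_steps=np.array(steps, dtype=np.int64),
            )
        )
        if cfg.record_initiations:
            all_inits.append(unit_inits)
            all_series.append(unit_series)
    return PopulationResult(
        genome=genome,
        units=units,
        s_lengths=np.array(s_lengths, dtype=np.int64),
        n_incomplete=n_incomplete,
        n_factors_used=n_used,
        initiations=all_inits,
        replicated_series=all_series,
    )


# ---------------------------------------------------------------------------
# snapshot container (versioned npz; masks bit-packed)

_SNAPSHOT_FORMAT_VERSION = 1


def save_population(pop: PopulationResult, path) -> None:
    payload = {
        "format_version": np.array(_SNAPSHOT_FORMAT_VERSION),
        "bin_width": np.array(pop.genome.bin_width),
        "chrom_names": np.array(pop.genome.names),
        "chrom_lengths": np.array(pop.genome.lengths),
        "s_lengths": pop.s_lengths,
        "n_incomplete": np.array(pop.n_incomplete),
        "n_units": np.array(len(pop.units)),
        "factor_chroms": np.array(list(pop.n_factors_used)),
        "factor_counts": np.array(list(pop.n_factors_used.values())),
    }
    for i, u in enumerate(pop.units):
        payload[f"unit{i}_chroms"] = np.array(u.chroms)
        payload[f"unit{i}_offsets"] = np.array(u.offsets)
        payload[f"unit{i}_n_bins"] = np.array(u.n_bins)
        payload[f"unit{i}_fractions"] = u.fractions
        payload[f"unit{i}_masks"] = np.packbits(u.masks, axis=1) if len(u) else np.zeros((0, 0), dtype=np.uint8)
        payload[f"unit{i}_cycle_ids"] = u.cycle_ids
        payload[f"unit{i}_s_steps"] = u.s_steps
    np.savez_compressed(path, **payload)


def load_population(path) -> PopulationResult:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["format_version"])
        if version != _SNAPSHOT_FORMAT_VERSION:
            raise ValueError(f"unsupported snapshot format version {version}")
        genome = GenomeIndex(
            tuple(str(c) for c in z["chrom_names"]),
            tuple(int(x) for x in z["chrom_lengths"]),
            int(z["bin_width"]),
        )
        units = []
        for i in range(int(z["n_units"])):
            n_bins = int(z[f"unit{i}_n_bins"])
            packed = z[f"unit{i}_masks"]
            masks = (
                np.unpackbits(packed, axis=1)[:, :n_bins].astype(bool)
                if packed.size
                else np.zeros((packed.shape[0], n_bins), dtype=bool)
            )
            units.append(
                SnapshotStream(
                    chroms=tuple(str(c) for c in z[f"unit{i}_chroms"]),
                    offsets=tuple(int(x) for x in z[f"unit{i}_offsets"]),
                    n_bins=n_bins,
                    fractions=z[f"unit{i}_fractions"],
                    masks=masks,
                    cycle_ids=z[f"unit{i}_cycle_ids"],
                    s_steps=z[f"unit{i}_s_steps"],
                )
            )
        return PopulationResult(
            genome=genome,
            units=units,
            s_lengths=z["s_lengths"],
            n_incomplete=int(z["n_incomplete"]),
            n_factors_used=dict(
                zip(
                    (str(c) for c in z["factor_chroms"]),
                    (int(x) for x in z["factor_counts"]),
                )
            ),
        )
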