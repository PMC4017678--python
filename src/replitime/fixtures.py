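"""Deterministic synthetic genomes, landscapes, and pseudo-empirical
timing profiles.

Every generator is a pure function of its spec and seed, so each pipeline
stage is testable without downloads. The clustered site model emulates the
salient feature of real open-chromatin annotations — initiation sites
aggregated into domains separated by site-poor gaps — with cluster centers
placed deterministically so distance-to-nearest-site is computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome_io import BinnedTrack, GenomeIndex, IntervalSet
from .ipls import IPLS, build_ipls, score_ipls
from .flow_sorter import GateSpec, population_profile
from .replication_engine import SimConfig, run_population

__all__ = [
    "FixtureSpec",
    "IPLSFixture",
    "make_ipls_fixture",
    "make_pseudo_empirical",
    "make_sequence_fixture",
    "write_fasta",
]

G4_PLUS_MOTIF = "GGGTGGGTGGGTGGG"  # canonical 15-nt quadruplex seed
G4_MINUS_MOTIF = "CCCACCCACCCACCC"  # its reverse complement


@dataclass
class FixtureSpec:
    """Synthetic-landscape recipe.

    site models: ``uniform`` scatters ``n_sites`` bins uniformly;
    ``clustered`` places ``n_clusters`` evenly spaced cluster centers and
    draws ``sites_per_cluster`` site bins within ``cluster_width_bins`` of
    each; ``lone`` puts a single site at bin ``lone_bin``. Amplitudes are
    constant 1 or gamma-distributed (shape 2, mimicking skewed peak-score
    distributions).
    """

    n_chromosomes: int = 1
    n_bins: int = 2000
    bin_width: int = 500
    site_model: str = "clustered"
    n_sites: int = 50
    n_clusters: int = 5
    cluster_width_bins: int = 20
    sites_per_cluster: int = 10
    lone_bin: int = 0
    amplitude: str = "gamma"
    gamma_shape: float = 2.0
    background: float = 1e-4
    amplitude_map: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_model not in ("uniform", "clustered", "lone"):
            raise ValueError("site_model must be uniform|clustered|lone")
        if min(self.n_chromosomes, self.n_bins, self.bin_width) < 1:
            raise ValueError("all counts must be positive")


@dataclass
class IPLSFixture:
    ipls: IPLS
    genome: GenomeIndex
    sites: IntervalSet
    site_bins: dict[str, np.ndarray]
    cluster_centers: dict[str, np.ndarray] = field(default_factory=dict)

    def distance_to_nearest_site(self, chrom: str) -> np.ndarray:
        """Per-bin distance (in bins) to the nearest ground-truth site."""
        bins = np.arange(self.genome.n_bins(chrom))
        sites = np.sort(self.site_bins[chrom])
        idx = np.searchsorted(sites, bins)
        left = np.where(idx > 0, np.abs(bins - sites[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(idx < len(sites), np.abs(sites[np.minimum(idx, len(sites) - 1)] - bins), np.inf)
        return np.minimum(left, right)


def make_ipls_fixture(spec: FixtureSpec) -> IPLSFixture:
    """Seeded synthetic landscape plus its ground-truth site list."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"chrS{i + 1}" for i in range(spec.n_chromosomes))
    genome = GenomeIndex(
        names, tuple([spec.n_bins * spec.bin_width] * spec.n_chromosomes), spec.bin_width
    )
    site_bins: dict[str, np.ndarray] = {}
    centers: dict[str, np.ndarray] = {}
    records = []
    for chrom in names:
        if spec.site_model == "lone":
            bins = np.array([spec.lone_bin])
            centers[chrom] = bins.astype(float)
        elif spec.site_model == "uniform":
            bins = np.sort(rng.choice(spec.n_bins, size=spec.n_sites, replace=False))
            centers[chrom] = bins.astype(float)
        else:
            ctr = (np.arange(spec.n_clusters) + 0.5) * spec.n_bins / spec.n_clusters
            chosen = []
            half = spec.cluster_width_bins // 2
            for c in ctr:
                lo = max(0, int(c) - half)
                hi = min(spec.n_bins, int(c) + half + 1)
                chosen.append(
                    rng.choice(np.arange(lo, hi), size=spec.sites_per_cluster, replace=False)
                )
            bins = np.sort(np.concatenate(chosen))
            centers[chrom] = ctr
        site_bins[chrom] = bins
        if spec.amplitude == "constant" or spec.site_model == "lone":
            amps = np.ones(len(bins))
        else:
            amps = rng.gamma(spec.gamma_shape, 1.0, size=len(bins))
        w = spec.bin_width
        records.extend(
            (chrom, int(b) * w, int(b) * w + w, float(a)) for b, a in zip(bins, amps)
        )
    sites = IntervalSet.from_records(records)
    bg = 0.0 if spec.site_model == "lone" else spec.background
    lm = score_ipls(sites, genome, amplitude_map=spec.amplitude_map, background=bg)
    return IPLSFixture(lm, genome, sites, site_bins, centers)


def make_pseudo_empirical(
    ipls: IPLS,
    n_factors: int | str = "auto",
    cycles: int = 500,
    gates: GateSpec | None = None,
    seed: int = 0,
) -> BinnedTrack:
    """Reference timing profile from a real engine run at fixed seed — the
    self-target for gate-recovery and comparison tests."""
    cfg = SimConfig(ipls=ipls, n_factors=n_factors, n_cycles=cycles, seed=seed)
    return population_profile(run_population(cfg), gates or GateSpec.equidistant())


def make_sequence_fixture(
    n_bins: int = 40,
    bin_width: int = 500,
    g4_plus_bins: tuple[int, ...] = (),
    g4_minus_bins: tuple[int, ...] = (),
    gc_rich_bins: tuple[int, ...] = (),
    cpg_rich_bins: tuple[int, ...] = (),
    seed: int = 0,
    chrom: str = "chrSeq",
) -> tuple[dict[str, str], GenomeIndex]:
    """Random A/T background with literal motifs planted at known bins.

    G4 motifs land at each requested bin's start; GC-rich bins are filled
    with GCGCGC...; CpG-rich bins alternate CGCG... (high observed/expected).
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("AT"), size=n_bins * bin_width)
    for b in gc_rich_bins:
        block = ("GC" * bin_width)[:bin_width]
        seq[b * bin_width : (b + 1) * bin_width] = list(block)
    for b in cpg_rich_bins:
        block = ("CG" * bin_width)[:bin_width]
        seq[b * bin_width : (b + 1) * bin_width] = list(block)
    for b in g4_plus_bins:
        seq[b * bin_width : b * bin_width + len(G4_PLUS_MOTIF)] = list(G4_PLUS_MOTIF)
    for b in g4_minus_bins:
        seq[b * bin_width : b * bin_width + len(G4_MINUS_MOTIF)] = list(G4_MINUS_MOTIF)
    genome = GenomeIndex((chrom,), (n_bins * bin_width,), bin_width)
    return {chrom: "".join(seq)}, genome


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
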