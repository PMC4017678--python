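"""Initiation probability landscapes (IPLS).

An IPLS assigns each genomic bin the probability that a free rate-limiting
factor, having selected that bin, initiates replication there. Landscapes
are built from scored annotations (e.g. DNase-hypersensitive sites), TSS
lists, or sequence features (GC content, CpG observed/expected,
G-quadruplex motifs), scaled to ``x / max(x)`` and floored at a small
background probability (default 1e-4; 0 disables background initiation).

The relevant information carried by an annotation is the *location* of
sites: the amplitude-assignment function (linear / square / square-root /
constant) is exposed because timing predictions are largely insensitive
to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import BinnedTrack, GenomeIndex, IntervalSet, bin_intervals

DEFAULT_BACKGROUND = 1e-4
AMPLITUDE_MAPS = ("linear", "square", "sqrt", "constant")

__all__ = [
    "DEFAULT_BACKGROUND",
    "AMPLITUDE_MAPS",
    "IPLS",
    "build_ipls",
    "tss_ipls",
    "score_ipls",
    "gc_ipls",
    "cpg_ipls",
    "g4_ipls",
    "subtract_overlap",
    "subtract_random",
    "subsample",
    "fuse_translocation",
]


@dataclass
class IPLS:
    """Per-bin initiation probabilities in [0, 1] with a background floor."""

    track: BinnedTrack
    background: float = DEFAULT_BACKGROUND
    amplitude_map: str = "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.background < 1:
            raise ValueError("background must be in [0, 1)")
        allvals = self.track.concatenated()
        if np.isnan(allvals).any():
            raise ValueError("IPLS values must be defined for every bin")
        if allvals.min() < 0 or allvals.max() > 1:
            raise ValueError("IPLS values must lie in [0, 1]")
        if self.background > 0 and allvals.min() < self.background:
            raise ValueError("IPLS value below background floor")
        if not (allvals > self.background).any():
            raise ValueError("empty landscape: no bin above background")

    @property
    def genome(self) -> GenomeIndex:
        return self.track.genome

    def values(self, chrom: str) -> np.ndarray:
        return self.track[chrom]

    def subset(self, chroms: Sequence[str]) -> "IPLS":
        return IPLS(self.track.subset(chroms), self.background, self.amplitude_map)


def _apply_amplitude(scaled: np.ndarray, raw: np.ndarray, amplitude_map: str) -> np.ndarray:
    if amplitude_map == "linear":
        return scaled
    if amplitude_map == "square":
        return scaled**2
    if amplitude_map == "sqrt":
        return np.sqrt(scaled)
    if amplitude_map == "constant":
        return (raw > 0).astype(float)
    raise ValueError(f"amplitude_map must be one of {AMPLITUDE_MAPS}")


def build_ipls(
    raw: BinnedTrack,
    amplitude_map: str = "linear",
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """Scale a raw feature track to ``x / max(x)``, apply the amplitude map,
    and floor at the background probability.

    Missing bins are treated as zero signal before flooring. The maximum is
    taken genome-wide so relative amplitudes across chromosomes are kept.
    """
    if amplitude_map not in AMPLITUDE_MAPS:
        raise ValueError(f"amplitude_map must be one of {AMPLITUDE_MAPS}")
    data = {}
    peak = 0.0
    for chrom in raw.genome.names:
        v = np.nan_to_num(raw[chrom], nan=0.0)
        if v.min() < 0:
            raise ValueError("raw landscape values must be nonnegative")
        data[chrom] = v
        peak = max(peak, float(v.max()) if v.size else 0.0)
    if peak <= 0:
        raise ValueError("empty landscape: raw track has no positive value")
    out = {}
    for chrom, v in data.items():
        scaled = v / peak
        out[chrom] = np.maximum(_apply_amplitude(scaled, v, amplitude_map), background)
    return IPLS(BinnedTrack(raw.genome, out), background, amplitude_map)


def score_ipls(
    sites: IntervalSet,
    genome: GenomeIndex,
    bin_mode: str = "max",
    amplitude_map: str = "linear",
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """IPLS from a scored annotation (BED score column as amplitude)."""
    raw = bin_intervals(sites, genome, mode=bin_mode)
    return build_ipls(raw, amplitude_map, background)


def tss_ipls(
    tss: IntervalSet,
    genome: GenomeIndex,
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """Constant probability 1.0 for every bin containing a transcription
    start site; background elsewhere."""
    raw = bin_intervals(tss, genome, mode="count")
    return build_ipls(raw, "constant", background)


# ---------------------------------------------------------------------------
# sequence-derived landscapes


def _load_sequences(
    fasta: str | Path | Mapping[str, str], genome: GenomeIndex
) -> dict[str, str]:
    if isinstance(fasta, Mapping):
        seqs = {c: str(fasta[c]) for c in genome.names if c in fasta}
    else:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
        seqs = {c: str(fa[c][:]) for c in genome.names if c in fa}
    missing = [c for c in genome.names if c not in seqs]
    if missing:
        raise KeyError(f"chromosomes absent from FASTA: {missing}")
    for chrom, seq in seqs.items():
        if len(seq) < genome.length(chrom):
            raise ValueError(
                f"{chrom}: sequence shorter ({len(seq)}) than genome index "
                f"length ({genome.length(chrom)})"
            )
    return {c: s.upper() for c, s in seqs.items()}


def _per_bin_substrings(seq: str, genome: GenomeIndex, chrom: str):
    w = genome.bin_width
    for b in range(genome.n_bins(chrom)):
        yield b, seq[b * w : min((b + 1) * w, genome.length(chrom))]


def gc_ipls(
    fasta: str | Path | Mapping[str, str],
    genome: GenomeIndex,
    amplitude_map: str = "linear",
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """IPLS scaled to per-bin GC fraction."""
    seqs = _load_sequences(fasta, genome)
    raw = BinnedTrack.zeros(genome)
    for chrom in genome.names:
        out = raw[chrom]
        for b, sub in _per_bin_substrings(seqs[chrom], genome, chrom):
            if sub:
                out[b] = (sub.count("G") + sub.count("C")) / len(sub)
    return build_ipls(raw, amplitude_map, background)


def cpg_ipls(
    fasta: str | Path | Mapping[str, str],
    genome: GenomeIndex,
    amplitude_map: str = "linear",
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """IPLS scaled to per-bin CpG observed/expected ratio:
    ``#CG * L / (#C * #G)`` within the bin, 0 where ``#C * #G = 0``."""
    seqs = _load_sequences(fasta, genome)
    raw = BinnedTrack.zeros(genome)
    for chrom in genome.names:
        out = raw[chrom]
        for b, sub in _per_bin_substrings(seqs[chrom], genome, chrom):
            nc, ng = sub.count("C"), sub.count("G")
            if nc * ng:
                out[b] = sub.count("CG") * len(sub) / (nc * ng)
    return build_ipls(raw, amplitude_map, background)


def g4_pattern(min_run: int = 3, loop_min: int = 1, loop_max: int = 7, base: str = "G") -> re.Pattern:
    """Canonical intramolecular quadruplex motif: four runs of >= ``min_run``
    guanines separated by 1-7 base loops (C-runs mirror the minus strand)."""
    run = f"{base}{{{min_run},}}"
    loop = f"[ACGTN]{{{loop_min},{loop_max}}}"
    return re.compile(f"{run}(?:{loop}{run}){{3}}")


def g4_ipls(
    fasta: str | Path | Mapping[str, str],
    genome: GenomeIndex,
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    amplitude_map: str = "linear",
    background: float = DEFAULT_BACKGROUND,
) -> IPLS:
    """IPLS scaled to G-quadruplex motif length.

    Both strands are scanned (G-pattern on plus, C-pattern standing in for
    the minus strand) with a non-overlapping greedy scan; a bin's raw value
    is the length of the longest motif overlapping it.
    """
    seqs = _load_sequences(fasta, genome)
    raw = BinnedTrack.zeros(genome)
    w = genome.bin_width
    patterns = [
        g4_pattern(min_run, loop_min, loop_max, "G"),
        g4_pattern(min_run, loop_min, loop_max, "C"),
    ]
    for chrom in genome.names:
        out = raw[chrom]
        for pat in patterns:
            for m in pat.finditer(seqs[chrom]):
                first, last = m.start() // w, (m.end() - 1) // w
                length = m.end() - m.start()
                for b in range(first, min(last, len(out) - 1) + 1):
                    out[b] = max(out[b], length)
    return build_ipls(raw, amplitude_map, background)


# ---------------------------------------------------------------------------
# reduced / perturbed landscapes


def subtract_overlap(a: IntervalSet, b: IntervalSet, slop: int = 0) -> IntervalSet:
    """Remove from ``a`` every record overlapping >= 1 base of any record of
    ``b`` (records of ``b`` widened by ``slop`` bases on each side first)."""
    trees: dict[str, IntervalTree] = {}
    for r in b.df.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(
            max(0, r.start - slop), r.end + slop
        )
    keep = [
        not (r.chrom in trees and trees[r.chrom].overlaps(r.start, r.end))
        for r in a.df.itertuples(index=False)
    ]
    return IntervalSet(a.df[keep].reset_index(drop=True))


def subtract_random(a: IntervalSet, k: int, seed: int) -> IntervalSet:
    """Remove exactly ``k`` uniformly chosen records (seeded)."""
    if k > len(a):
        raise ValueError(f"cannot remove {k} records from a set of {len(a)}")
    rng = np.random.default_rng(seed)
    drop = rng.choice(len(a), size=k, replace=False)
    keep = np.setdiff1d(np.arange(len(a)), drop)
    return IntervalSet(a.df.iloc[keep].reset_index(drop=True))


def subsample(a: IntervalSet, keep_fraction: float, seed: int) -> IntervalSet:
    """Retain ``round(keep_fraction * |a|)`` records uniformly without
    replacement (seeded, original order preserved)."""
    if not 0 <= keep_fraction <= 1:
        raise ValueError("keep_fraction must be in [0, 1]")
    n_keep = int(round(keep_fraction * len(a)))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(a), size=n_keep, replace=False))
    return IntervalSet(a.df.iloc[keep].reset_index(drop=True))


def fuse_translocation(
    ipls_a: IPLS,
    ipls_b: IPLS,
    breakpoint_a: int,
    breakpoint_b: int,
    orientation: str = "AB",
    chrom_a: str | None = None,
    chrom_b: str | None = None,
    name: str = "der",
) -> tuple[IPLS, pd.DataFrame]:
    """Build the landscape of a derivative chromosome from a reciprocal
    translocation.

    ``AB`` joins ``a[0, bp_a)`` to ``b[bp_b, end)``; ``BA`` gives the
    reciprocal product ``b[0, bp_b) + a[bp_a, end)``. Returns the fused IPLS
    (single new chromosome, grid re-derived from the fused length) and a
    mapping table ``(fused_bin, source_chrom, source_bin)``. At a breakpoint
    inside a bin, that bin takes the value of the donor segment covering the
    majority of the bin.
    """
    if orientation not in ("AB", "BA"):
        raise ValueError("orientation must be 'AB' or 'BA'")
    if orientation == "BA":
        return fuse_translocation(
            ipls_b, ipls_a, breakpoint_b, breakpoint_a, "AB", chrom_b, chrom_a, name
        )
    chrom_a = chrom_a or ipls_a.genome.names[0]
    chrom_b = chrom_b or ipls_b.genome.names[0]
    len_a, len_b = ipls_a.genome.length(chrom_a), ipls_b.genome.length(chrom_b)
    if not 0 < breakpoint_a <= len_a:
        raise ValueError(f"breakpoint_a {breakpoint_a} outside (0, {len_a}]")
    if not 0 <= breakpoint_b < len_b:
        raise ValueError(f"breakpoint_b {breakpoint_b} outside [0, {len_b})")
    wa, wb = ipls_a.genome.bin_width, ipls_b.genome.bin_width
    if wa != wb:
        raise ValueError("bin widths differ between source landscapes")
    w = wa
    fused_len = breakpoint_a + (len_b - breakpoint_b)
    fused_genome = GenomeIndex((name,), (fused_len,), w)
    n_bins = fused_genome.n_bins(name)
    va, vb = ipls_a.values(chrom_a), ipls_b.values(chrom_b)

    vals = np.empty(n_bins)
    rows = []
    for k in range(n_bins):
        bin_start = k * w
        bin_len = min((k + 1) * w, fused_len) - bin_start
        a_bases = min(max(breakpoint_a - bin_start, 0), bin_len)
        if a_bases * 2 >= bin_len:  # donor A covers the majority (ties -> A)
            src_chrom, src_bin = chrom_a, bin_start // w
            vals[k] = va[src_bin]
        else:
            src_base = breakpoint_b + (max(bin_start, breakpoint_a) - breakpoint_a)
            src_chrom, src_bin = chrom_b, src_base // w
            vals[k] = vb[src_bin]
        rows.append((k, src_chrom, src_bin))
    mapping = pd.DataFrame(rows, columns=["fused_bin", "source_chrom", "source_bin"])
    track = BinnedTrack(fused_genome, {name: vals})
    background = min(ipls_a.background, ipls_b.background)
    return IPLS(track, background, ipls_a.amplitude_map), mapping
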