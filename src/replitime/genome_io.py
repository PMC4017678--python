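"""Genome coordinate bookkeeping, interval/track I/O, and fixed-grid binning.

All genomic inputs (BED, bedGraph, fixed-step WIG, chrom.sizes, TSV tracks)
are projected onto a fixed-width bin grid (default 500 bp). Coordinates are
0-based half-open throughout (BED convention); bin *k* covers
``[k*w, (k+1)*w)``, so an interval ending exactly at ``k*w`` does not touch
bin *k*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500

__all__ = [
    "DEFAULT_BIN_WIDTH",
    "GenomeIndex",
    "BinnedTrack",
    "IntervalSet",
    "read_chrom_sizes",
    "bin_intervals",
    "read_track",
    "write_track",
]


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths on a fixed bin grid."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome name")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("non-positive chromosome length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def length(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def subset(self, chroms: Sequence[str]) -> "GenomeIndex":
        missing = [c for c in chroms if c not in self.names]
        if missing:
            raise KeyError(f"unknown chromosomes: {missing}")
        return GenomeIndex(
            tuple(chroms),
            tuple(self.length(c) for c in chroms),
            self.bin_width,
        )


@dataclass
class BinnedTrack:
    """One float value per grid bin per chromosome; NaN marks missing data."""

    genome: GenomeIndex
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValueError(f"track missing chromosome {chrom!r}")
            arr = np.asarray(self.data[chrom], dtype=float)
            if arr.shape != (self.genome.n_bins(chrom),):
                raise ValueError(
                    f"{chrom}: expected {self.genome.n_bins(chrom)} bins, "
                    f"got {arr.shape}"
                )
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, genome: GenomeIndex) -> "BinnedTrack":
        return cls(genome, {c: np.zeros(genome.n_bins(c)) for c in genome.names})

    @classmethod
    def full(cls, genome: GenomeIndex, value: float) -> "BinnedTrack":
        return cls(genome, {c: np.full(genome.n_bins(c), float(value)) for c in genome.names})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, {c: v.copy() for c, v in self.data.items()})

    def concatenated(self) -> np.ndarray:
        """Genome-wide value vector in chromosome order."""
        return np.concatenate([self.data[c] for c in self.genome.names])

    def subset(self, chroms: Sequence[str]) -> "BinnedTrack":
        g = self.genome.subset(chroms)
        return BinnedTrack(g, {c: self.data[c].copy() for c in chroms})

    @property
    def max(self) -> float:
        return float(np.nanmax(self.concatenated()))


@dataclass
class IntervalSet:
    """BED-style records (chrom, start, end, score), 0-based half-open."""

    df: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "score")

    def __post_init__(self) -> None:
        df = self.df
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires column {col!r}")
        df = df[list(self.COLUMNS)].reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        if (df["score"] < 0).any():
            raise ValueError("negative interval score")
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "IntervalSet":
        rows = list(records)
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df)

    @classmethod
    def from_bed(cls, path: str | Path, score_col: int | None = None) -> "IntervalSet":
        """Read BED records with scores.

        ``score_col`` (1-based) picks the score column explicitly; by
        default the standard BED score field (column 5) is used, falling
        back to a numeric column 4 for ``chrom start end score`` files and
        to 1.0 for plain 3-column BED.
        """
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                try:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if score_col is not None:
                        score = float(parts[score_col - 1])
                    elif len(parts) >= 5:
                        score = float(parts[4])
                    elif len(parts) == 4:
                        try:
                            score = float(parts[3])
                        except ValueError:
                            score = 1.0
                    else:
                        score = 1.0
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}: malformed BED line {ln}: {line!r}") from exc
                rows.append((chrom, start, end, score))
        return cls.from_records(rows)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, r in enumerate(self.df.itertuples(index=False)):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tiv{i}\t{r.score:.10g}\n")

    def __len__(self) -> int:
        return len(self.df)

    def clipped(self, genome: GenomeIndex) -> "IntervalSet":
        """Clip intervals to chromosome bounds; drop records on unknown
        chromosomes (logged) and records emptied by clipping."""
        df = self.df.copy()
        known = df["chrom"].isin(genome.names)
        n_skipped = int((~known).sum())
        if n_skipped:
            logger.warning(
                "skipping %d interval(s) on chromosomes absent from genome index",
                n_skipped,
            )
        df = df[known].copy()
        if len(df):
            lengths = df["chrom"].map({c: genome.length(c) for c in genome.names})
            df["start"] = df["start"].clip(lower=0)
            df["end"] = np.minimum(df["end"], lengths)
            df = df[df["start"] < df["end"]]
        return IntervalSet(df.reset_index(drop=True))


def read_chrom_sizes(path: str | Path, bin_width: int = DEFAULT_BIN_WIDTH) -> GenomeIndex:
    """Read two-column whitespace-delimited ``name length`` text."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed chrom.sizes line {ln}: {line!r}")
            name, length = parts[0], int(parts[1])
            if name in names:
                raise ValueError(f"{path}: duplicate chromosome {name!r} (line {ln})")
            if length <= 0:
                raise ValueError(f"{path}: non-positive length for {name!r} (line {ln})")
            names.append(name)
            lengths.append(length)
    return GenomeIndex(tuple(names), tuple(lengths), bin_width)


_BIN_MODES = ("max", "sum", "mean", "count")


def bin_intervals(
    intervals: IntervalSet, genome: GenomeIndex, mode: str = "max"
) -> BinnedTrack:
    """Aggregate interval scores onto the bin grid.

    Every bin an interval overlaps by >= 1 base receives the interval's full
    score (``max``/``sum``/``mean``) or a count of 1 (``count``); untouched
    bins carry 0.
    """
    if mode not in _BIN_MODES:
        raise ValueError(f"mode must be one of {_BIN_MODES}")
    iv = intervals.clipped(genome)
    track = BinnedTrack.zeros(genome)
    w = genome.bin_width
    for chrom, sub in iv.df.groupby("chrom", sort=False):
        first = (sub["start"].to_numpy() // w).astype(np.int64)
        last = ((sub["end"].to_numpy() - 1) // w).astype(np.int64)
        scores = sub["score"].to_numpy(dtype=float)
        spans = last - first + 1
        idx = np.repeat(first, spans) + _within_span_offsets(spans)
        vals = np.repeat(scores, spans)
        out = track[chrom]
        if mode == "max":
            np.maximum.at(out, idx, vals)
        elif mode == "sum":
            np.add.at(out, idx, vals)
        elif mode == "count":
            np.add.at(out, idx, 1.0)
        else:  # mean of overlapping interval scores
            total = np.zeros_like(out)
            count = np.zeros_like(out)
            np.add.at(total, idx, vals)
            np.add.at(count, idx, 1.0)
            nz = count > 0
            out[nz] = total[nz] / count[nz]
    return track


def _within_span_offsets(spans: np.ndarray) -> np.ndarray:
    """[0..s0-1, 0..s1-1, ...] for the repeat-expansion of bin ranges."""
    if len(spans) == 0:
        return np.zeros(0, dtype=np.int64)
    ends = np.cumsum(spans)
    return np.arange(ends[-1], dtype=np.int64) - np.repeat(ends - spans, spans)


def read_track(path: str | Path, genome: GenomeIndex, fmt: str | None = None) -> BinnedTrack:
    """Read a value track (bedGraph / fixed-step WIG / 4-column TSV) onto
    the bin grid.

    Source intervals are averaged into bins weighted by overlap length; bins
    never covered by data are NaN (missing).
    """
    path = Path(path)
    if fmt is None:
        fmt = "wig" if path.suffix.lower() in (".wig", ".wiggle") else "bedgraph"
    if fmt == "wig":
        segments = _parse_wig(path)
    elif fmt in ("bedgraph", "tsv"):
        segments = _parse_bedgraph(path)
    else:
        raise ValueError(f"unknown track format {fmt!r}")

    w = genome.bin_width
    weighted = {c: np.zeros(genome.n_bins(c)) for c in genome.names}
    covered = {c: np.zeros(genome.n_bins(c)) for c in genome.names}
    n_skipped = 0
    for chrom, start, end, value in segments:
        if chrom not in genome:
            n_skipped += 1
            continue
        end = min(end, genome.length(chrom))
        if start >= end:
            continue
        first, last = start // w, (end - 1) // w
        for b in range(first, last + 1):
            ov = min(end, (b + 1) * w) - max(start, b * w)
            weighted[chrom][b] += value * ov
            covered[chrom][b] += ov
    if n_skipped:
        logger.warning("read_track: skipped %d segment(s) on unknown chromosomes", n_skipped)
    data = {}
    for chrom in genome.names:
        vals = np.full(genome.n_bins(chrom), np.nan)
        nz = covered[chrom] > 0
        vals[nz] = weighted[chrom][nz] / covered[chrom][nz]
        data[chrom] = vals
    return BinnedTrack(genome, data)


def _parse_bedgraph(path: Path):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {ln}: {line!r}")
            try:
                yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                if ln == 1 and parts[:3] == ["chrom", "start", "end"]:
                    continue  # TSV header row
                raise ValueError(f"{path}: malformed bedGraph line {ln}: {line!r}") from exc


def _parse_wig(path: Path):
    chrom, start, step, span = None, 0, None, None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}: variableStep WIG not supported (line {ln})")
            if chrom is None:
                raise ValueError(f"{path}: data before fixedStep header (line {ln})")
            try:
                value = float(line.split()[0])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed WIG line {ln}: {line!r}") from exc
            yield chrom, start, start + span, value
            start += step


def write_track(track: BinnedTrack, path: str | Path, fmt: str = "bedGraph") -> None:
    """Write per-bin values as bedGraph or TSV; NaN bins are omitted."""
    if fmt.lower() not in ("bedgraph", "tsv"):
        raise ValueError(f"unknown track format {fmt!r}")
    sep = "\t"
    w = track.genome.bin_width
    with open(path, "w") as fh:
        if fmt.lower() == "tsv":
            fh.write(f"chrom{sep}start{sep}end{sep}value\n")
        for chrom in track.genome.names:
            length = track.genome.length(chrom)
            vals = track[chrom]
            for b in range(len(vals)):
                if np.isnan(vals[b]):
                    continue
                end = min((b + 1) * w, length)
                fh.write(f"{chrom}{sep}{b * w}{sep}{end}{sep}{vals[b]:.12g}\n")
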