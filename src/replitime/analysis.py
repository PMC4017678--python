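"""Downstream statistics on timing profiles.

Profile comparison (per-chromosome Pearson correlation and its mean),
plasticity-region calling under a normal null on the difference profile,
the per-chromosome fork-count scan with its linear length fit, S-phase
length statistics and wall-clock conversion, robustness curves under site
deletion, the global initiation rate I(t), and all-pairs profile
correlation with hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .genome_io import BinnedTrack, GenomeIndex, IntervalSet
from .ipls import IPLS, score_ipls, subsample
from .flow_sorter import GateSpec, population_profile
from .replication_engine import PopulationResult, SimConfig, run_population

__all__ = [
    "ProfileComparison",
    "compare_profiles",
    "PlasticityRegion",
    "call_plasticity_regions",
    "plasticity_regions_to_bed",
    "ForkScanResult",
    "scan_fork_count",
    "fit_fork_density",
    "sphase_stats",
    "robustness_curve",
    "initiation_rate",
    "correlation_matrix",
]


# ---------------------------------------------------------------------------
# profile comparison


@dataclass
class ProfileComparison:
    per_chromosome: dict[str, float]
    mean: float
    sem: float


def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(a) & ~np.isnan(b)
    return a[ok], b[ok]


def compare_profiles(a: BinnedTrack, b: BinnedTrack, flip_b: bool = False) -> ProfileComparison:
    """Per-chromosome Pearson correlation over pairwise-complete bins, with
    the unweighted mean and its standard error across chromosomes.

    ``flip_b`` negates ``b`` for empirical tracks whose convention is
    higher = earlier (the simulator emits lower = earlier).
    """
    if a.genome.names != b.genome.names:
        raise ValueError("profiles are on different chromosome sets")
    per = {}
    for chrom in a.genome.names:
        x, y = _pairwise_complete(a[chrom], -b[chrom] if flip_b else b[chrom])
        if len(x) < 3:
            raise ValueError(f"{chrom}: fewer than 3 shared defined bins")
        per[chrom] = float(stats.pearsonr(x, y).statistic)
    vals = np.array(list(per.values()))
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return ProfileComparison(per, float(vals.mean()), sem)


# ---------------------------------------------------------------------------
# plasticity regions


@dataclass
class PlasticityRegion:
    """Run of >= min_run consecutive bins whose timing difference is
    extreme under the normal null."""

    chrom: str
    start_bin: int
    end_bin: int  # inclusive
    p_values: np.ndarray
    direction: int  # sign of the mean difference a - b

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def min_p(self) -> float:
        return float(self.p_values.min())


def call_plasticity_regions(
    a: BinnedTrack,
    b: BinnedTrack,
    alpha: float = 0.001,
    min_run: int = 3,
    robust: bool = False,
) -> list[PlasticityRegion]:
    """Call replication-plasticity regions between two timing profiles.

    The difference profile d = a - b is fitted with a single normal null
    over all defined bins (moment estimates; ``robust`` switches to
    median/MAD). Each bin gets a two-sided p-value from that null; maximal
    runs of at least ``min_run`` consecutive bins with p <= alpha become
    regions. Missing bins break runs.
    """
    if a.genome.names != b.genome.names:
        raise ValueError("profiles are on different chromosome sets")
    diffs = {c: a[c] - b[c] for c in a.genome.names}
    pooled = np.concatenate([d[~np.isnan(d)] for d in diffs.values()])
    if len(pooled) == 0:
        raise ValueError("no shared defined bins")
    if robust:
        mu = float(np.median(pooled))
        sigma = float(stats.median_abs_deviation(pooled, scale="normal"))
    else:
        mu, sigma = float(pooled.mean()), float(pooled.std())
    if sigma == 0:
        raise ValueError("degenerate difference profile (zero variance)")

    regions: list[PlasticityRegion] = []
    for chrom, d in diffs.items():
        p = np.full_like(d, np.nan)
        defined = ~np.isnan(d)
        p[defined] = 2 * stats.norm.sf(np.abs(d[defined] - mu) / sigma)
        hit = defined & (p <= alpha)
        start = None
        for i in range(len(d) + 1):
            if i < len(d) and hit[i]:
                if start is None:
                    start = i
            elif start is not None:
                if i - start >= min_run:
                    seg = slice(start, i)
                    regions.append(
                        PlasticityRegion(
                            chrom=chrom,
                            start_bin=start,
                            end_bin=i - 1,
                            p_values=p[seg].copy(),
                            direction=int(np.sign(np.nanmean(d[seg]))) or 1,
                        )
                    )
                start = None
    return regions


def plasticity_regions_to_bed(
    regions: Sequence[PlasticityRegion], genome: GenomeIndex, path
) -> None:
    """BED5: chrom, start, end, name, -log10(min p)."""
    w = genome.bin_width
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            end = min((r.end_bin + 1) * w, genome.length(r.chrom))
            score = -np.log10(max(r.min_p, 1e-300))
            fh.write(f"{r.chrom}\t{r.start_bin * w}\t{end}\tplasticity{i}\t{score:.4g}\n")


# ---------------------------------------------------------------------------
# fork-count scan


@dataclass
class ForkScanResult:
    candidate_ns: tuple[int, ...]
    correlations: dict[str, np.ndarray]  # per chromosome, one r per candidate N
    optimal_n: dict[str, int]
    slope: float
    intercept: float
    fit_r: float


def fit_fork_density(lengths: Sequence[float], optima: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of optimal factor count on chromosome length;
    returns (slope, intercept, Pearson r)."""
    res = stats.linregress(np.asarray(lengths, float), np.asarray(optima, float))
    return float(res.slope), float(res.intercept), float(res.rvalue)


def scan_fork_count(
    ipls: IPLS,
    empirical: BinnedTrack,
    candidate_ns: Sequence[int],
    cycles: int = 200,
    seed: int = 0,
    gates: GateSpec | None = None,
    flip_empirical: bool = False,
) -> ForkScanResult:
    """Per chromosome, simulate at every candidate N, correlate with the
    empirical profile, and pick the argmax (ties -> smallest N); then fit
    optimal N against chromosome length by OLS."""
    candidate_ns = tuple(int(n) for n in candidate_ns)
    gates = gates or GateSpec.equidistant()
    genome = ipls.genome
    correlations = {c: np.empty(len(candidate_ns)) for c in genome.names}
    optimal = {}
    for chrom in genome.names:
        sub = ipls.subset([chrom])
        for j, n in enumerate(candidate_ns):
            cfg = SimConfig(ipls=sub, n_factors=n, n_cycles=cycles, seed=seed)
            prof = population_profile(run_population(cfg), gates)
            x, y = _pairwise_complete(
                prof[chrom], -empirical[chrom] if flip_empirical else empirical[chrom]
            )
            correlations[chrom][j] = stats.pearsonr(x, y).statistic if len(x) >= 3 else np.nan
        optimal[chrom] = candidate_ns[int(np.nanargmax(correlations[chrom]))]
    if len(genome.names) >= 2:
        slope, intercept, fit_r = fit_fork_density(
            [genome.length(c) for c in genome.names],
            [optimal[c] for c in genome.names],
        )
    else:
        slope = intercept = fit_r = float("nan")
    return ForkScanResult(candidate_ns, correlations, optimal, slope, intercept, fit_r)


# ---------------------------------------------------------------------------
# S-phase statistics


def sphase_stats(
    s_lengths: Sequence[int],
    bin_width: int = 500,
    fork_speed_bases_per_s: float = 50.0,
) -> dict[str, float]:
    """Median/mean S length in steps, plus the median in wall-clock hours.

    One step advances two fork edges, so a step covers
    ``bin_width / (2 * fork_speed)`` seconds of real time:
    hours = median_steps * bin_width / (fork_speed * 2) / 3600.
    """
    s_lengths = np.asarray(list(s_lengths), dtype=float)
    if s_lengths.size == 0:
        raise ValueError("no S-phase lengths supplied")
    median_steps = float(np.median(s_lengths))
    hours = median_steps * bin_width / (fork_speed_bases_per_s * 2) / 3600
    return {
        "median_steps": median_steps,
        "mean_steps": float(s_lengths.mean()),
        "median_hours": hours,
    }


# ---------------------------------------------------------------------------
# robustness under site deletion


def robustness_curve(
    base_sites: IntervalSet,
    genome: GenomeIndex,
    fractions: Sequence[float],
    reference: BinnedTrack,
    n_factors: int | str = "auto",
    cycles: int = 200,
    seed: int = 0,
    gates: GateSpec | None = None,
    background: float = 1e-4,
    amplitude_map: str = "linear",
) -> dict[float, float]:
    """Mean profile correlation against ``reference`` after keeping only a
    fraction of the annotation sites, for each keep-fraction (seeded)."""
    gates = gates or GateSpec.equidistant()
    out = {}
    for frac in fractions:
        kept = subsample(base_sites, frac, seed=seed + int(round(frac * 1e6)) % (2**20))
        lm = score_ipls(kept, genome, amplitude_map=amplitude_map, background=background)
        cfg = SimConfig(ipls=lm, n_factors=n_factors, n_cycles=cycles, seed=seed)
        prof = population_profile(run_population(cfg), gates)
        out[float(frac)] = compare_profiles(prof, reference).mean
    return out


# ---------------------------------------------------------------------------
# global initiation rate


def initiation_rate(pop: PopulationResult) -> pd.DataFrame:
    """Global initiation rate I(t) over S-phase age t (steps).

    I(t) = (initiations at step t, summed over cycles) divided by the
    unreplicated bins available entering step t, summed over the cycles
    still in S at t. Requires a population run with
    ``record_initiations=True``.
    """
    if pop.initiations is None:
        raise ValueError("population was run without record_initiations")
    init_counts: dict[int, int] = {}
    unrepl: dict[int, int] = {}
    for unit, unit_inits, unit_series in zip(pop.units, pop.initiations, pop.replicated_series):
        B = unit.n_bins
        for events, series in zip(unit_inits, unit_series):
            for t in range(1, len(series) + 1):
                avail = B - (series[t - 2] if t >= 2 else 0)
                if avail <= 0:
                    break
                unrepl[t] = unrepl.get(t, 0) + int(avail)
            for t, _bin in events:
                init_counts[int(t)] = init_counts.get(int(t), 0) + 1
    ts = sorted(unrepl)
    rate = [init_counts.get(t, 0) / unrepl[t] for t in ts]
    return pd.DataFrame({"t": ts, "initiations_per_unreplicated_bin": rate})


# ---------------------------------------------------------------------------
# correlation matrix


def correlation_matrix(
    profiles: Sequence[BinnedTrack], labels: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[int]]:
    """All-pairs genome-wide Pearson correlation (pairwise-complete bins)
    and the leaf order of average-linkage clustering on 1 - r."""
    labels = list(labels) if labels is not None else [f"profile{i}" for i in range(len(profiles))]
    n = len(profiles)
    vecs = [p.concatenated() for p in profiles]
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = _pairwise_complete(vecs[i], vecs[j])
            if len(x) < 3:
                raise ValueError(f"profiles {labels[i]} and {labels[j]}: <3 shared bins")
            r[i, j] = r[j, i] = stats.pearsonr(x, y).statistic
    if n > 2:
        order = list(leaves_list(average(squareform(1 - r, checks=False))))
    else:
        order = list(range(n))
    return pd.DataFrame(r, index=labels, columns=labels), order
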