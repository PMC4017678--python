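# replitime

A stochastic, mechanistic simulator of metazoan DNA replication timing.

Genome-wide replication timing in human cells is remarkably reproducible,
yet individual initiation events are stochastic: even the most efficient
origins fire in only a fraction of cell cycles. `replitime` implements a
minimal mechanistic model in which the timing program *emerges* from the
spatial distribution of initiation-competent sites, with no per-origin
firing times and essentially one biological parameter:

- **IPLS** — an *initiation probability landscape* assigns every 500-bp bin
  the probability that a searching factor initiates replication there.
  Landscapes are built from scored annotations (e.g. DNase-hypersensitive
  sites, with score scaled to `x / max(x)` and floored at a background of
  1e-4), TSS lists, or sequence features (GC fraction, CpG observed/expected,
  G-quadruplex motifs).
- **N rate-limiting factors** per chromosome each either search — picking a
  competent bin uniformly at random each step and engaging with probability
  `IPLS(x)` if the bin is unreplicated — or drive one bidirectional
  replication bubble, advancing each fork edge one bin per step. A fork
  meeting replicated territory or a chromosome end blocks; when both edges
  of a bubble are blocked its factor returns to the pool. `N` scales
  linearly with chromosome length `x` as `N = 10.24 + 7.9e-7 x`
  (about one fork per 1.3 Mb).
- **Flow-sorter emulation** — an asynchronous population (geometric G→S
  waits) is snapshotted periodically; each snapshot is sorted by DNA content
  into `G` gates (default 6), and a bin's replication time is the
  count-weighted mean gate index `T = Σ g·c_g / Σ c_g` (lower = earlier).
  Gate boundaries can be fitted to an empirical profile by simulated
  annealing on the Euclidean distance between profiles.

On top of the engine the package provides the derived analyses: profile
comparison (per-chromosome Pearson r), replication-plasticity region
calling (normal null on the difference profile, runs of ≥3 bins at
p ≤ 0.001), per-chromosome fork-count scans with the linear length fit,
S-phase statistics and wall-clock conversion, robustness curves under site
deletion, in-silico translocation of landscapes, the global initiation
rate I(t), and deterministic synthetic fixtures for all of the above.

## Worked example

```python
import numpy as np
from replitime import (FixtureSpec, make_ipls_fixture, SimConfig,
                       run_population, GateSpec, sphase_stats)
from replitime.flow_sorter import population_profile

# clustered synthetic landscape: 2000 bins, 5 site clusters
fix = make_ipls_fixture(FixtureSpec(seed=42))
pop = run_population(SimConfig(ipls=fix.ipls, n_factors=8, n_cycles=500, seed=7))
prof = population_profile(pop, GateSpec.equidistant(6))["chrS1"]

d = fix.distance_to_nearest_site("chrS1")
print(f"in-cluster mean timing: {np.nanmean(prof[d == 0]):.2f}")
print(f"far (>50 bins) mean timing: {np.nanmean(prof[d > 50]):.2f}")
print(sphase_stats(pop.s_lengths))
```

prints

```
in-cluster mean timing: 4.39
far (>50 bins) mean timing: 5.27
{'median_steps': 422.5, 'mean_steps': 432.236, 'median_hours': 0.5868055555555556}
```

Bins inside site clusters replicate earlier (smaller gate index) than bins
far from any site — the early/late timing pattern emerges purely from site
locations. At 500-bp bins and 50 b/s forks, one simulation step is 5 s of
wall-clock time, so the 2000-bin toy chromosome finishes S phase in about
0.59 h; a human-genome-scale run with a median S of 5,965 steps corresponds
to 8.3 h.

The same pipeline is scriptable from the shell:

```bash
replitime make-fixture --out-dir fix/
replitime build-ipls --bed fix/sites.bed --chrom-sizes fix/chrom.sizes --out ipls.bedGraph
replitime simulate --ipls ipls.bedGraph --chrom-sizes fix/chrom.sizes \
    --forks auto --cycles 500 --seed 7 --out snapshots.npz
replitime profile --snapshots snapshots.npz --out timing.bedGraph
replitime optimize-gates --snapshots snapshots.npz --empirical timing.bedGraph \
    --iters 2000 --seed 3 --out gates.json
```

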