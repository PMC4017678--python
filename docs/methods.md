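# Methods

## Model

A simulated cell is either in a non-replicating G state or a replicating S
state. The G→S transition is a geometric random wait with per-step
probability `g_to_s_prob` (default 1/500), which desynchronizes the
population. In S, the cell's territory — one chromosome by default, or the
concatenated genome when a shared factor pool is requested — is an array of
fixed-width bins (default 500 bp) with an initiation probability per bin
(the IPLS).

Each of `N` rate-limiting factors is free or engaged. Per step:

1. Every engaged bubble advances each unblocked fork edge by one bin,
   marking it replicated. An edge meeting an already-replicated bin or a
   chromosome end becomes blocked; a bubble with both edges blocked
   dissolves and returns its factor to the free pool.
2. Every free factor makes one attempt: it draws a bin uniformly at random
   from the *competent* bins of the territory (those with nonzero IPLS —
   all bins whenever the landscape carries a positive background floor) and,
   if that bin is unreplicated, engages there with probability `IPLS(bin)`.
   Engagement replicates the bin immediately and creates a bubble with both
   edges on it; otherwise the factor stays free. A draw landing on a
   replicated bin wastes the attempt, so the effective initiation rate
   falls with the density of unreplicated competent sites — this, together
   with the dynamically changing free-factor count, produces a rising-then-
   falling global initiation rate I(t) without any explicit time dependence
   in the landscape.

The probability of initiating at location x in a step is therefore the
product of the chance of selecting an unreplicated competent site, the
landscape value at x, and the number of free factors. The cycle completes
when every bin is replicated; restricting the search to competent bins is
what makes the single-origin closed form exact (see below). Initiation
replicates the chosen bin in the same step; elongation starts the following
step. Consequently a lone zero-background origin at bin m of B bins yields
an S length of exactly `1 + max(m, B−1−m)` steps, which the tests use as a
closed-form oracle.

`N` defaults to the per-chromosome fork-density estimate
`round(10.24 + 7.9e-7·length)`, clamped to ≥1 (about one fork per 1.3 Mb);
a genome-shared pool over a concatenated territory (fork edges block at
chromosome boundaries) is available as an option.

## Landscapes

Raw feature tracks are scaled `x / max(x)` (maximum taken genome-wide so
relative amplitudes across chromosomes are preserved), passed through an
amplitude map (linear, square, square-root, or constant-on-sites), and
floored at the background probability (default 1e-4; 0 restricts initiation
to annotated sites). Missing bins count as zero signal before flooring. An
all-zero landscape is rejected. Interval annotations are binned with each
interval contributing its full score to every bin it overlaps (max by
default — a peak score is a site property, not a density; mean is
available). Sequence landscapes: per-bin GC fraction; per-bin CpG
observed/expected `#CG·L/(#C·#G)` counted within the bin's subsequence
(dinucleotides spanning a bin boundary are ignored — negligible at 500-bp
bins); G-quadruplex motifs matched on both strands with
`G{3,}([ACGTN]{1,7}G{3,}){3}` and its C-strand mirror, non-overlapping
greedy scan, a bin's raw value being the longest overlapping motif length.

Reduced landscapes: `subtract_overlap` removes records overlapping ≥1 base
of a second set (a slop option widens the second set first);
`subtract_random` removes an equal number of uniformly chosen records so
the two reductions are size-matched; `subsample` keeps a rounded fraction.
`fuse_translocation` concatenates two landscapes at base-pair breakpoints
into a derivative chromosome; a breakpoint bin takes the value of the donor
covering the majority of the bin (ties to the left-hand donor), avoiding
fabricated probabilities, and a mapping table back to source bins is
returned.

## Flow sorting and profiles

Snapshots are taken every `snapshot_period` steps (default 10) on a
population clock whose phase is set by the G wait. Snapshots in which
nothing is replicated yet are not recorded: such a cell has G1 DNA content
and a sorter would not place it in an S gate. Each snapshot is gated once
by its replicated fraction into the half-open interval `(b_{g−1}, b_g]`
(DNA content maps affinely onto the fraction, so boundaries live in (0,1));
every replicated bin's count in that gate increments. A bin's timing is the
weighted mean gate index, normalized by its total count so values stay in
`[1, G]`; unobserved bins are missing. The per-bin count total is invariant
under boundary moves.

Gate optimization is simulated annealing: each move perturbs one uniformly
chosen boundary by a Normal(old, σ) draw with σ = 0.01 on the fraction
scale (one percentage point of DNA content; σ of one full unit would be
non-local), rejects proposals violating ordering or range, and accepts by
the Metropolis criterion on the Euclidean distance between the regated
simulated profile and the empirical profile (missing bins dropped
pairwise), under a geometric cooling schedule (T0 = 0.1 × initial
objective, final temperature 1e-4 × T0 over the schedule; chosen for
reliable recovery of known gates across seeds in the self-target harness).
The best-ever boundary vector is returned. Snapshots are pre-aggregated by
their discrete replicated fraction into a cumulative matrix so one
objective evaluation costs O(G × bins).

## Analyses

- **Comparison**: Pearson r per chromosome over pairwise-complete bins,
  unweighted mean and SEM across chromosomes; a flip option negates tracks
  whose convention is higher = earlier.
- **Plasticity regions**: the difference profile is fitted with a single
  normal null by moment estimates over *all* defined bins (a median/MAD
  robust option is off by default); two-sided p per bin; maximal runs of
  ≥3 consecutive bins at p ≤ 0.001 become regions, missing bins break
  runs. With these defaults the expected false-region count on pure noise
  is ≈ bins × (0.001)³ per maximal run — far below one region per genome.
  A zero-variance difference profile is rejected as degenerate.
- **Fork scan**: per chromosome, simulate at each candidate N, correlate
  against the empirical profile, take the argmax (ties to the smallest N);
  then OLS of optimal N on chromosome length.
- **S-phase statistics**: hours = median steps × bin width /(2 × fork
  speed)/3600, two forks moving in opposite directions per step; defaults
  500 bp and 50 b/s.
- **Initiation rate**: I(t) = initiations at S-age t over unreplicated bins
  entering t, summed over cycles; requires event recording.
- **Correlation matrix**: all-pairs genome-wide Pearson with
  average-linkage clustering on 1 − r.

## Synthetic data

The fixture generator emulates the one feature of real open-chromatin
annotations the model's behavior hinges on: initiation sites aggregated
into clusters separated by site-poor gaps, with skewed (gamma, shape 2)
peak amplitudes. Cluster centers are placed deterministically so
distance-to-nearest-site is computable; all generators are pure functions
of (spec, seed). Defaults (one 1-Mb chromosome of 2000 × 500-bp bins, 5
clusters of 10 sites) keep the full test suite in tens of seconds on one
CPU. The generator does not emulate real peak widths, chromosome-scale
domain structure, mappability gaps, or measurement noise in empirical
timing profiles, so passing tests demonstrate the engine's internal
correctness and the emergent-ordering, recovery, and robustness properties
of the method — not predictive accuracy on real genomes, which depends on
the user-supplied annotation quality.

Pseudo-empirical profiles (reference targets for gate-recovery, fork-scan
and robustness tests) are produced by the real engine at a fixed seed, so
recovery tests are self-consistency checks with known ground truth.
Fork-count recovery uses zero-background clustered landscapes: with a
positive background the correlation-versus-N curve is nearly flat above a
threshold (timing ordering saturates once every cluster can run in
parallel), whereas fork-limited, sites-only dynamics make N sharply
identifiable.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open (BED); bin k covers [k·w, (k+1)·w), so
  an interval ending exactly at k·w does not touch bin k. The last bin of a
  chromosome may be partial.
- Bubbles elongate before free factors attempt initiation within a step;
  bubbles are processed in creation order, so an edge can be blocked by
  territory replicated earlier in the same step (per-step throughput is
  still ≤ 2N bins).
- Per-cycle RNGs derive from `SeedSequence(seed, spawn_key=(unit, cycle))`,
  making populations reproducible and order-independent.
- Cycles hitting `max_steps` (default 50 × B/(2N)) are flagged incomplete,
  excluded from profiles, and counted in logs.
- Track values are length-weighted means when source resolution differs
  from the grid; write-then-read round-trips are exact to float precision.
- `gate_of` rejects fractions ≤ 0 (G-phase cells must be filtered by the
  caller); fraction exactly 1 falls in gate G.
- Duplicate chromosome names, non-positive lengths, inverted intervals,
  breakpoints outside the source chromosome, and subsampling more records
  than exist all raise immediately with specific messages.

## Known limitations

The engine does not model licensing/firing separation (the landscape
subsumes both), fork stalling, variable fork speed, replication factories,
or sub-diffusive factor motion. Timing profiles are emitted in lower =
earlier gate units; converting empirical S/G1-normalized signals into
comparable units is left to the user (only an orientation flip is
provided). The annealer optimizes boundaries for a fixed gate count G;
choosing G is the user's modeling decision (default 6, matching standard
Repli-seq fractionation).
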