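# Methods

## Statistical model and procedure

The pipeline treats a normalized log2 expression matrix (probesets ×
samples) with replicate groups at each scheduled day as its input. All
inference is two-group and per-probe; no longitudinal model is fitted.
This is deliberate: with 20 time points and profiles that mix pulses,
steps, dips and drifts, a single parametric curve family under-fits
badly, whereas dense replication (n = 10 per day) gives simple
two-sample tests high power per interval.

### Differential calls

For days *a* < *b* with replicate values x̄ₐ, x̄ᵦ, sample variances s²,
the Welch statistic is

    t = (x̄_b − x̄_a) / sqrt(s_a²/n_a + s_b²/n_b)

with Welch–Satterthwaite degrees of freedom and a two-tailed p from the
t distribution. The direction convention is later-minus-earlier, so
"up" means higher at the later day. A call requires both p ≤ α
(default α = 0.01 per test; 0.001 supported for the conservative
variant) and |Δlog2| ≥ log2 1.5 (the exact value 0.58496…, not its
two-decimal display). No multiplicity correction is applied to the
calls themselves — the design fixes the per-test false-positive
probability and reports the implied expected false-positive count
instead; a Benjamini–Hochberg column is emitted per contrast purely for
reference. The fold-change filter applies identically in both contrast
schemes (a switch disables it, used by the calibration tests).

Zero-variance probe/contrast combinations cannot arise from real
normalized arrays but can from degenerate synthetic input; they are
flagged (`degenerate`), given the conventional values (t = 0, p = 1
when means agree; p = 0 otherwise) and excluded from summary counts.

### Episode detection

Let Sᵢ be the set of probes significant (up or down) in adjacent
contrast *i*. For consecutive contrasts the paired 2×2 counts
a = |Sᵢ ∩ Sᵢ₊₁|, b = |Sᵢ \ Sᵢ₊₁|, c = |Sᵢ₊₁ \ Sᵢ|, d = rest. McNemar's
statistic with continuity correction is (|b−c|−1)²/(b+c) against χ²₁;
when b + c < 25 the exact two-sided binomial(b+c, ½) tail is used
instead (doubled upper tail, capped at 1), and |b−c| ≤ 1 clamps p to 1
under either method. Pairing per probe is the only construction
consistent with comparing "the numbers of significant probesets" of two
adjacent contrasts while respecting that the same probes are measured
in both.

With k adjacent contrasts there are k − 1 comparisons (18 on the
reference schedule) Bonferroni-controlled at family α = 0.05, so a
comparison is flagged when its two-sided p falls strictly below
α/(k−1) = 0.0028 (at printed rounding) *and* the discordance direction
matches the requested mode (increase by default; decrease mode exists
because a loss of significant probes is equally interpretable). The
first adjacent contrast has no predecessor: it is reported
descriptively and never flagged.

### Temporal structure summaries

From the baseline (day-0) call matrix: per-day up/down counts with the
grand total of significant results and the count of unique significant
probes; each probe's earliest significant day and the resulting
cumulative discovery curve (non-decreasing, terminating at the unique
count); and the histogram of per-probe significant-contrast counts
(mass equal to the unique count). These conservation identities are
asserted in tests.

### Time-point clustering

Day profiles are replicate means per (probe, day). The distance between
two days is 1 − Pearson's r computed across probes. Every probe is an
observation for this correlation, including probes constant across
days — their expression level still informs the column correlation, and
dropping them would silently change the metric; only a day column
constant across probes (correlation undefined) is an error. Trees are
built by unweighted average linkage (UPGMA): merge the closest pair at
its current distance; the merged cluster's distance to another cluster
is the size-weighted mean of member distances, which equals the
unweighted mean over all cross leaf pairs. Merge heights are therefore
monotone and the dendrogram ultrametric.

Ties are broken by the lexicographically smallest pair of cluster
representatives (each cluster represented by its earliest day). Any
fixed rule would do; this one is platform-independent and reproducible,
which matters because resampled support counts identical bipartitions
across thousands of trees.

Support: (i) ordinary bootstrap — probes resampled with replacement at
full size, support of each full-data bipartition = fraction of
bootstrap trees containing it; (ii) jackknife consensus — ⌊P/2⌋ probes
kept per iteration without replacement (1000 iterations by default),
majority rule (> 0.5) over all observed bipartitions. Majority clades
from a common tree set are necessarily pairwise compatible, so the
consensus is a tree; its node heights are the mean merge heights over
the trees containing each clade, and in the degenerate case (one
iteration keeping all probes) the consensus equals the full-data tree
with unit support. The multiscale "approximately unbiased" bootstrap is
intentionally not implemented: the ordinary proportion and the
jackknife consensus certify the same splits, and the AU machinery is a
separate method with its own estimation error.

### Overrepresentation

For a hit list of n genes from a universe of N annotated genes, a set
with K members in the universe and k in the hit list scores
p = P(X ≥ k), X ~ Hypergeometric(N, K, n); q-values are
Benjamini–Hochberg across sets and significance is q ≤ 0.05. Probe
lists collapse to genes permissively (a gene is hit if any of its
probes is), and the universe is all genes with annotation on the
platform. This replaces web-service ORA deliberately: the statistic is
the standard one, the inputs (GMT + annotation table) are explicit, and
the result is reproducible offline. GO-DAG propagation and ortholog
mapping are out of scope.

## Synthetic data generator

The generator's defaults are the reference study conditions: the 20-day
schedule (0, 0.5, 1, 1.5, 2, 3, 4, 5, 7, 9, 10, 12, 14, 16, 18, 20, 22,
24, 26, 28 DPA), 10 replicates per day, effect size 1.0 log2, noise sd
0.5 log2, group-effect sd 0.5 log2, baselines uniform on 4–12 log2
(typical microarray dynamic range; t tests on differences are
insensitive to the exact values). The source data do not quantify
per-gene effect sizes or noise; these defaults were chosen once to make
recovery well-powered at n = 10 — the joint (p ∧ fold-change) detection
probability of a 1-log2 step is ≈ 0.92 — and are not tuned thereafter.

Archetypes (profiles relative to baseline, boundary days configurable
via the `step@<day>` syntax):

| archetype | shape | emulates |
|---|---|---|
| `flat` | constant 0 | null probes |
| `immediate_early` | pulse at 0.5 DPA decaying (τ = 0.75 d), re-pulse at 7 DPA (τ = 2 d) | fos/egr1-like immediate-early signature |
| `step`, `step@d` | 0 before day *d*, effect from *d* on | persistent shifts at episode boundaries |
| `ramp` | linear rise after day 2 | gradually recruited programs |
| `dip_9_10` | piecewise dip, minimum −effect at day 10 | ECM genes at the pre-bud→early-bud transition |
| `late_ramp_22_24` | rise only after day 22 | palette-stage genes |
| `muscle_decline` | linear fall to −2·effect by day 12, then flat | muscle histolysis |
| `gradual_drift` | linear over the whole series | slow drift |

Each cell is baseline + scale·profile(day) + group effect + N(0,
noise_sd²). `muscle_decline` probes form one group sharing a single
N(0, group_effect_sd) draw per sample, reproducing replicate estimates
that co-vary across the group's genes; with both sds at 0.5 the
within-group correlation of replicate deviations is the intraclass
share g²/(g²+σ²) = 0.5. Per-probe `scale` is drawn uniformly from
`scale_choices` (default all 1.0; e.g. `(1, −1)` produces the
two-regime structure used for clustering tests).

One seeded generator drives everything with a fixed draw order
(baselines, scales, group effects, noise); archetype assignment is a
deterministic largest-remainder apportionment of the mix, so two seeds
share identical truth structure and differ only in the draws. The
ground truth records, per adjacent interval, the probes whose noiseless
means differ by at least a threshold (default log2 1.5, matching the
call criterion).

What the generator does **not** emulate: probe-level summarization
noise, batch/array effects, heteroscedasticity across time (real
profiles show time-varying spread; an optional per-day sd multiplier
was considered and left out as it changes no tested conclusion),
intensity-dependent variance, and correlated gene modules beyond the
single muscle group. Passing recovery tests therefore demonstrate the
statistical machinery under the design's assumptions, not robustness to
array artefacts — those are the job of upstream QC and normalization,
which this package consumes rather than performs.

## Numerical choices and degenerate inputs

- Threshold comparisons: p ≤ α for differential calls; strict p <
  α/(k−1) for episode flags (matching the phrasing of the respective
  criteria).
- The exact-binomial switch at b + c < 25 follows common practice for
  McNemar's test; both methods agree with their oracles to 1e-12 and
  the χ² path to the distribution tail exactly.
- Distances are symmetrized and clipped to [0, 2] after `corrcoef` to
  absorb floating-point asymmetry of order 1e-16.
- Results tables serialize floats at 6 significant digits so reruns
  diff byte-for-byte; the matrix writer uses 10 digits so a write/read
  round trip is exact to that precision.
- The pipeline expands its run seed through `SeedSequence.spawn` into
  substreams (simulation, jackknife, bootstrap), so a stage can be
  rerun in isolation with identical draws.

## Problem sizes used by the checks

The acceptance script and the heavier tests use 5000 probes for episode
recovery (300 step probes at each injected boundary, matching the
design's scale), 1000–2000 probes for null calibration and clustering,
200 (tests) or 100 (script) seeds for the null family-wise rate, and
1000 jackknife iterations — the study's own resampling depth.

## Known limitations

- Real-array benchmark values depend on the upstream normalization
  dialect; the benchmark harness reports exact and ±10% agreement and
  requires the deposited series to be supplied locally.
- Per-test α with a fold filter, by construction, does not control FDR;
  the emitted BH column is for reading, not calling.
- The consensus tree reports topology, support and mean merge heights;
  it is not itself an ultrametric dendrogram.
- Probe→gene collapse is the most permissive rule; platforms with many
  cross-hybridizing probes will inflate hit lists.
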