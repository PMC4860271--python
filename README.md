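# regenchron

Analysis of densely sampled, replicated expression time courses — built
around the statistical design used to profile axolotl (*Ambystoma
mexicanum*) forelimb regeneration on microarrays: 20 time points over
0–28 days post-amputation (DPA) with 10 biological replicates each.

The package is for transcriptomics researchers who have a normalized
log2 expression matrix from a dense time course and want to answer two
questions: *when does the transcriptional program change, and is the
change gradual or punctuated?*

## What it computes

**Per-interval differential expression.** For each probeset, two-tailed
Welch (unequal-variance) t tests on log2 intensities under two contrast
schemes — every post-amputation day versus day 0 (divergence from the
uninjured state), and every pair of adjacent days (local change). A
probe is called up/down when p ≤ 0.01 (per test, uncorrected by design)
and the mean difference passes a 1.5-fold cutoff (|Δlog2| ≥ log2 1.5 ≈
0.58).

**Punctuated episodes.** Consecutive adjacent contrasts are compared
probe-by-probe with McNemar's test on the paired significance calls
(continuity-corrected χ², exact binomial when discordants < 25). On the
reference schedule this gives 18 comparisons, Bonferroni-controlled at
α = 0.05, i.e. a per-comparison threshold of 0.05/18 ≈ 0.0028. An
interval where significantly more probes become significant than in the
preceding interval is a *punctuated transcriptional episode*.

**Temporal structure.** Per-day up/down divergence counts, the
cumulative curve of first-detection times, and the histogram of how
many contrasts each probe is significant in.

**Clustering of time points.** Average-linkage (UPGMA) trees on
1 − Pearson's r between replicate-averaged day profiles (correlation
across probes), with ordinary bootstrap proportions and a jackknife
majority-rule consensus (half the probes removed per iteration, 1000
iterations) as bipartition support. Trees are exported as Newick with
supports as internal labels.

**Gene-set overrepresentation.** One-tailed hypergeometric tests of
interval gene lists against a GMT collection over the annotated-array
universe, Benjamini–Hochberg corrected, significant at q ≤ 0.05.

**Synthetic data.** A generator that emulates the study's statistical
structure — trajectory archetypes (immediate-early pulses, persistent
steps, a dip bottoming at 10 DPA, late ramps, correlated muscle
decline), Gaussian log2 noise, shared per-sample group effects — and
emits ground-truth labels so every stage is testable end to end.

## Worked example

```python
from regenchron import SimConfig, simulate_timecourse, run_adjacent_contrasts, detect_episodes

config = SimConfig(
    n_probes=3000,
    archetype_mix={"flat": 0.8, "step@3": 0.1, "step@20": 0.1},
    seed=11,
)
matrix, samples, truth = simulate_timecourse(config)
adjacent = run_adjacent_contrasts(matrix, samples)
print(adjacent.summaries.loc[3:6, ["contrast", "n_up", "n_down", "n_sig"]])

for call in detect_episodes(adjacent.calls):
    if call.flagged:
        print(f"episode {call.contrast_later}: b={call.b} c={call.c} "
              f"p={call.p_value:.3g} (threshold {call.adjusted_threshold:.4f})")
```

prints

```
  contrast  n_up  n_down  n_sig
3    1.5-2     8       7     15
4      2-3   285       6    291
5      3-4     5       7     12
6      4-5     9       9     18
episode 2-3: b=14 c=290 p=4.82e-56 (threshold 0.0028)
episode 18-20: b=13 c=290 p=1.28e-56 (threshold 0.0028)
```

300 probes carry a persistent +1 log2 step arriving at day 3 and 300
more at day 20. The 2–3 DPA contrast finds 285 of the first group
(plus background false positives at the null rate), roughly twenty times
the neighbouring intervals. McNemar's test on the (1.5–2, 2–3) pair sees
290 probes significant only in the later contrast against 14 only in the
earlier one and flags the interval far below the Bonferroni threshold;
the 18–20 boundary is recovered the same way, and no null interval is
flagged.

The same stages run from the shell:

```
regenchron simulate --config sim.yaml --out-prefix sim --seed 1
regenchron de --matrix sim_matrix.tsv --samples sim_samples.tsv --scheme adjacent --out de/
regenchron episodes --calls de/calls.tsv --out episodes/
regenchron cluster --matrix sim_matrix.tsv --samples sim_samples.tsv --out trees/
regenchron run --config pipeline.yaml       # everything, with a manifest
```

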