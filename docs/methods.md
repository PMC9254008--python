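# Methods

## The trap model simulator

`tetrap.invasion_sim` is a forward Wright-Fisher simulator of a
transposable-element (TE) invasion halted by piRNA-cluster silencing. The
biological picture: a TE family invades a diploid host population by
transposition; the host genome contains piRNA clusters, loci whose
transcripts are processed into TE-silencing piRNAs. When a TE copy jumps
into a cluster, the individual carrying that insertion mounts a piRNA
response that silences the whole family in that individual ("transposon
trap"). Because cluster insertions segregate like any other allele, the
invasion only stops population-wide once cluster insertions are common
enough that essentially every individual carries at least one.

### State and parameters

* **Genome** — chromosome arms laid end to end on one 0-based bp axis
  (default: five arms of 32.4 Mb, 162 Mb total). piRNA clusters are
  half-open intervals, by default one 850-kb terminal cluster per arm
  (4.25 Mb, 2.62% of the genome — Drosophila-scale). A uniform
  recombination rate `r` in cM/Mb (default 4) gives
  `r x L / 100` Morgans per arm (1.296 for the default arm).
* **Population** — `N` diploids (default study size 230), each two
  haplotypes holding insertion positions; stored internally as one flat
  CSR-like array for speed.
* **Founders** — `M` insertions (study value 396) placed uniformly at
  random, each on one random haplotype, i.e. allele frequency `1/(2N)`;
  the founder mean is exactly `M/(2N)` = 0.86 copies/haploid for the
  defaults. Founder positions may fall inside clusters.
* **Transposition** — per generation each *non-cluster* insertion of an
  unsilenced zygote spawns a new copy with probability `u`; silenced
  zygotes use the residual rate `u_r` (default 0). New copies land
  uniformly on the genome (cluster hits allowed; a hit does not suppress
  the burst that produced it). Cluster insertions are never templates:
  they are transcribed into piRNA precursors rather than active
  transposase sources. Without silencing this yields the geometric growth
  `n_t = n_0 (1+u)^t` that the rate estimator inverts.
* **Silencing** — an individual is silenced iff it carries >= 1 cluster
  insertion. Silencing is zygotic and instantaneous by default; an
  optional `silencing_lag` (generations a cluster insertion must age
  before it silences) models a delayed piRNA response and defaults to 0.
* **Selection** — fitness is linear, `w = max(0, 1 - sum of effects)` over
  non-cluster insertions; cluster insertions are neutral (this avoids a
  transposition-selection-cluster equilibrium and keeps the model a pure
  trap model). Effects are a constant `x` per copy or, in DFE mode, drawn
  per insertion from a discrete distribution (e.g. equal mass on
  {0, 0.005, 0.01, 0.015, 0.02}). Individuals with `w = 0` never
  reproduce; if all fitnesses are zero the run aborts with a
  population-collapse error.

### Generation cycle

1. fitness of every adult;
2. `2N` parents drawn with replacement, probability proportional to
   fitness (monoecious random mating, selfing allowed);
3. one recombinant gamete per parent draw: per arm, a Poisson number of
   crossovers with uniform positions and an independent starting
   haplotype (arms assort independently) — implemented by evaluating
   crossover parity directly at each insertion position, which is exactly
   equivalent to materialising the crossover mosaic;
4. transposition in the zygote at the rate set by the zygote's own
   (inherited) cluster insertions.

The scalar functions `fitness`, `make_gamete` and `transpose` express the
model one individual at a time; `step_generation` advances the entire
population with vectorised numpy operations. Both paths implement the same
probabilistic model; the test suite pins the engine to its analytic
signatures (neutral copy-number martingale, Mendelian transmission,
Haldane recombinant fractions, `(1+u)^t` growth without clusters).

New insertion positions that collide with an occupied site on the same
haplotype are re-drawn (at bp resolution this fires about once per few
hundred simulated generations). Positions are integers, intervals
half-open, and all randomness flows from one `numpy` Generator per
replicate, spawned deterministically from a master seed, so equal seeds
give byte-identical trajectories.

### Reading the plateau

Simulated trajectories do not become exactly flat: after the bulk of the
population is silenced, rare cluster-free segregants keep transposing, so
the copy number keeps drifting upward slowly until cluster insertions
drift to fixation. The "plateau level" must therefore be read where the
curve bends. `rate_stats.plateau_summary` defines:

* smooth the replicate-averaged copies/haploid with a centred moving
  average (21 generations);
* *onset* = first generation, after per-generation growth has peaked, at
  which the smoothed relative growth drops below 0.25%/generation — an
  order of magnitude below invasion-phase growth and at the scale of the
  residual post-silencing creep;
* *level* = the highest smoothed copy number within the 50 generations
  after onset, i.e. the level the early plateau attains rather than the
  value at the bend itself.

The same rule reads both shapes the model produces: for neutral invasions
(rise, then near-flat creep) it reads the top of the early plateau; for
invasions under selection (rise, peak, slow decline) the window max is the
peak. Cluster insertions per diploid and the silenced fraction are
averaged over the same window. With ~10 replicates the Monte Carlo error
of the level is roughly 5-10%; the onset detector needs the wide
smoothing window because a first crossing of a noisy derivative is biased
early.

With the default study conditions this measures: neutral plateau ~65-75
copies/haploid at `u = 0.154` versus ~45-53 at `u = 0.051` — a three-fold
rate change moving the plateau by well under a factor of two, the model's
central point — and, with `x = 0.01` and matched effective rates
`u' = u - x`, plateaus of ~14-16 (hot) and ~9-11 (cold) copies/haploid,
with ~4 cluster insertions per diploid at the neutral hot plateau.

### Known limitations

* No sequence evolution, internal deletions, paramutation, maternal piRNA
  inheritance, or gonadal-dysgenesis/fitness coupling.
* Cluster-size scaling is strong in this implementation: enlarging the
  clusters to 20% of the genome drops the neutral-hot plateau to ~7
  copies/haploid at onset (~10-12 asymptotically), i.e. roughly inversely
  with cluster fraction. Published trap-model results suggest a weaker
  dependence (~15 copies/haploid at 20%); the discrepancy is unresolved
  and the corresponding acceptance check is left failing rather than
  re-tuned (see the per-target notes in the repository's test suite).
* The plateau reading is an estimator choice; levels quoted for creeping
  curves can differ by ~10% depending on where on the bend they are read.

## Invasion statistics (`rate_stats`)

* `transposition_rate(n_k, n_{k+t}, t) = (n_{k+t}/n_k)^(1/t) - 1` inverts
  geometric growth; negative rates (copy loss) are reported, not clamped.
  `rates_from_trajectory` applies it over consecutive sampling intervals
  (default 10 generations, matching a typical assay cadence).
* `effective_rate(u, x) = u - x`: under selection only the net rate is
  observable.
* `gd_percentage` = `100 x (dysgenic + intermediate/2) / total` — the
  standard scoring of gonadal-dysgenesis assays with half-weight for
  intermediate ovaries.
* `enrichment(o, f, t) = o / (f x t)` — observed insertions in a feature
  over the uniform expectation; `count_in_features` treats insertions as
  points (0-based position), merges overlapping feature intervals before
  computing the genomic fraction `f`, and is exact (searchsorted on merged
  intervals, no binning).

## Ping-pong statistics (`smallrna_stats`)

Reads are rows of (reference, 5' position, strand, length, count); minus-
strand reads store their **rightmost** reference base as the 5' position.
The overlap of a sense 5' end `s` and an antisense 5' end `a` is defined
`d = a - s + 1`, so the canonical ping-pong geometry (5' ends overlapping
by 10 nt) gives `d = 10`:

```
sense   5' s >>>>>>>>>>--->
antisense    <---<<<<<<<<<< a 5'      d = a - s + 1 = 10
```

Pairs are weighted by the product of the two read counts ("fraction of
pairs"); a `weighted=False` flag collapses to unique 5' positions.
Distances outside 1..20 are ignored (not renormalised). `h` is the
normalised weight vector; `z = (h10 - mean(h, d != 10)) / sd(h, d != 10)`
with the sample standard deviation (denominator 18), mapped to a p-value
by the standard normal upper tail (z = 3.09 ~ p = 0.001). A z-score is
only reported from >= 100 weighted pairs (configurable); fewer raise an
insufficient-data error. Highly abundant artefactual 5' positions can be
excluded before pairing — positions are given 1-based at the CLI (as
printed in tables; e.g. 1162,1164 for the P-element) and converted to the
0-based internal convention.

## Cluster detection (`cluster_detect`)

Reads are binned by 5' position (500-bp bins), normalised to piRNAs per
million sequenced miRNAs (ppm), and scored
`min(count, max_bin_score) - threshold` (defaults: cap 100, threshold
10). piRNA clusters are the all-maximal-scoring subsequences of this
score sequence in the Ruzzo-Tompa sense, computed with the linear-time
stack algorithm and verified in the tests against an exhaustive
definition-driven search. The cap stops a single extreme bin from
stitching unrelated regions; normalisation precedes capping (the cap is
in ppm units — the reverse order is equally defensible and this choice is
deliberate and documented). Segments are reported as bin-aligned BED
intervals; optional gap-tolerant merging (`merge_gap`, default off) joins
segments separated by at most a given number of bp.

## Synthetic data (`synthetic_data`)

Generators emulate every input table of the pipeline with recorded ground
truth (a `.truth.json` sidecar per output):

* **Trajectories** — `n_0 (1+u)^g` with a hard plateau and mean-one
  multiplicative lognormal noise (configurable CV, default 5%): copy
  numbers estimated from pooled sequencing have roughly multiplicative
  errors. Defaults mirror a hot invasion (u=0.154 from 0.86/haploid,
  10-generation sampling).
* **Small-RNA reads** — uniform background on both strands of a
  P-element-sized reference (2907 bp); a planted fraction of reads emitted
  as exact-10-nt-overlap ping-pong pairs; optional planted cluster
  intervals with fold-density enrichment; lengths uniform on 23-29 nt.
  What is *not* emulated: sequence content, the 1U/10A nucleotide biases,
  non-uniform background coverage, multi-mapping artefacts. Passing
  recovery tests therefore demonstrate estimator correctness, not
  robustness to alignment artefacts.
* **Insertions** — each insertion falls in feature i with probability
  `e_i x f_i` (uniform within), uniform on the complement otherwise, so
  measured enrichment recovers `e_i` in expectation; infeasible configs
  (`e x f > 1`) are rejected.
* **GD counts** — multinomial ovary classification.

Every generator is deterministic given a seed, and every downstream
estimator has a recovery test against the recorded truth (rate within
2 SE, enrichment within 2 SE, planted ping-pong fraction detected at
z > 3.09, planted clusters recovered at Jaccard >= 0.9).

## Numerical choices

* Transposition draws are Bernoulli per insertion (binomial per
  individual), not Poisson per genome; the difference is O(u^2).
* Fitness floored at zero; all-zero fitness aborts the replicate.
* Crossover breakpoints are continuous uniforms, so ties with integer
  insertion positions have probability zero; a crossover between integer
  positions b and b+1 separates them.
* The rate estimator requires `n_start > 0` and `t >= 1`; intervals
  starting at zero copies are skipped by the trajectory scanner.
* All intervals are half-open 0-based at every interface; 1-based printed
  coordinates are converted explicitly at the CLI boundary.
* Problem sizes used by the shipped analyses: 10-30 replicates and
  200-450 generations per configuration, chosen to put Monte Carlo error
  comfortably below the ~20% sampling tolerance of the plateau
  comparisons.
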