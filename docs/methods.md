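# Methods

This note documents the statistical models behind `mirlink`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Differential expression

**Model.** Counts for feature *f* in sample *s* are negative binomial with
mean μ_fs = q_fg · N_s and dispersion φ_f (Var = μ + φμ²), where *g* is
the sample's group (tumor/normal) and N_s the effective library size (raw
library size × TMM-style factor). The test statistic is the likelihood
ratio of group-specific rates (q_f,tumor, q_f,normal) against a shared
rate q_f, with the dispersion held fixed, referred to χ² with 1 df. Rate
MLEs are found by a vectorized Newton iteration on the log rate (the
Poisson closed form seeds the iteration and is exact at φ = 0); a feature
with all-zero counts contributes a zero statistic and p = 1.

**Normalization.** Factors are trimmed means of per-feature log2
abundance ratios (M) against a reference sample — the one whose
upper-quartile CPM is closest to the mean upper quartile — after trimming
30% of each M tail and 5% of each A (average log abundance) tail, then
rescaled to geometric mean 1. A sample sharing no expressed feature with
the reference gets factor 1 with a warning; a single-feature matrix falls
back to unit factors. Pure depth differences are absorbed by the library
size, so factors stay at 1; note that planted or real DE carrying a large
share of library mass legitimately moves factors away from 1 — that is
the compositional effect TMM exists to correct.

**Dispersion.** Per feature, a method-of-moments estimate from
depth-scaled within-group residuals, pooled across the two groups by
their degrees of freedom and floored at zero, then shrunk toward the
median raw dispersion with weight w = d₀/(d₀ + df), prior weight d₀ = 10.
This moderates the noisy per-feature estimates exactly enough to keep the
null χ²(1) reference honest: on 2,000 simulated null NB features
(φ = 0.1, 10 vs 10) the type-I error at p < 0.01 is measured at
0.012–0.018 and the p-value distribution passes a KS uniformity test.

**Filtering and classification.** The low-expression filter keeps a
feature when ≥ ⌈cpm_frac · n⌉ samples reach cpm_min CPM (defaults 0.5 and
10 — the "10 CPM in at least half the samples" rule); it is applied to
miRNA matrices by default and off for mRNA. Classification is
**up** iff log2FC > 2 ∧ p_raw < 0.01 ∧ p_BH < 0.01 (symmetrically
**down**), with log2FC = log2((mean tumor CPM + 0.5)/(mean normal CPM +
0.5)); the 0.5 prior count only guards the ratio and never enters the
likelihood. Both p thresholds are enforced because the source table
prints two adjusted-p columns without explaining their difference; the
packaged fixture stores them as `p_raw`/`p_adj` verbatim.

**Benjamini–Hochberg.** q_(i) = min_{j≥i} (m/j) p_(j), clipped at 1, ties
broken by input position. Note BH is *not* idempotent (p = [0.1, 0.9]
maps to [0.2, 0.9] and again to [0.4, 0.9]); the suite checks exact
agreement with a brute-force oracle, monotonicity, and elementwise
domination of the input instead.

**Latent factors.** As a lightweight stand-in for surrogate-variable
adjustment, the group-mean-centred log2(CPM+1) matrix is decomposed by
SVD and the factor count chosen by parallel analysis: each singular value
must exceed the 95th percentile of its rank-matched value over 20
independent row-wise permutations, counted from the top until the first
failure. The permutations are applied to the *raw* log-CPM rows and then
group-centred — permuting the centred residuals and re-centring loses
variance and inflates false detections several-fold. Fitted factor
contributions are folded into per-feature offsets for the NB test.
Under unequal sequencing depth the procedure may report a factor that
tracks depth-dependent noise variance; that structure is real in log
space, so it is not suppressed.

## Network propagation (NPES)

**Graph.** mirna_target edges define each miRNA's seed set; only tf_gene
edges (gene→gene) take part in propagation, as a column-normalized
adjacency W.

**Walk.** p ← (1−r)(W p + (d·p) p₀) + r p₀, where p₀ is uniform over the
seed targets, d flags dangling genes (their mass re-enters at the seeds),
restart r = 0.5 by default, iterated to L1 change < 1e-10 (cap 1000
iterations; non-convergence is an error). The result is a probability
vector; the suite verifies agreement with an independent dense
linear-solve oracle to 1e-8 L1 and the closed-form two-node cycle
(seed gene 2/3, other 1/3 at r = 0.5).

**Score.** Genes are ranked by −log10(p_raw) · sign(log2FC) (ties broken
by ID; p clipped at 1e-300). Walking top→bottom, an influenced gene
(influence > ε = 1/(10N), which excludes numerically negligible
influence) adds its influence share; any other gene subtracts 1/(N−|H|).
The raw score S is the signed extremum of the running sum; leading-edge
genes are the influenced genes at or before a positive extremum, or after
a negative one.

**Orientation.** An over-expressed miRNA pushes its targets *down* the
signed ranking, which on the plain ranking yields a strongly negative S —
invisible to the right-tail test. `npes(..., flip=True)` (and the
direction map accepted by `npes_screen`) therefore scores an "up" miRNA
against the reversed ranking. The pipeline orients by the *sign* of each
miRNA's log2FC rather than its full DE call: orientation is a hypothesis
about effect direction, and requiring triple-threshold significance left
borderline drivers scored in the wrong direction. With no direction map
the plain ranking is used.

**Normalization.** S is compared with the scores of `n_perm` (default
1000) random seed sets of identical size drawn uniformly without
replacement from the graph's genes: NPES = (S − mean)/sd, right-tail
empirical p with the add-one correction (p ≥ 1/(B+1), never 0), BH across
miRNAs with ≥ 3 mapped targets. Records with a degenerate null (sd = 0)
are kept but excluded from the FDR. Each miRNA's null stream is keyed by
(seed, CRC32 of its ID), so scores are independent of screen composition
and order. Both published significance cut-offs ("adjusted p < 0.05" and
"FDR < 0.1") are applied to the same BH-adjusted empirical p, since no
second correction is defined; the enriched flag additionally requires
NPES > 2. Family-level aggregation is out of scope; scoring is per-miRNA.

## Pair discovery

Candidates require: miRNA DE, gene DE, opposite directions, and a
validated mirna_target edge. Expression for correlation is log2(CPM+1)
with per-matrix TMM factors, over the intersection of sample IDs in the
miRNA matrix's order (constant vectors drop the pair with a logged
reason). The permutation test shuffles the miRNA matrix's sample
alignment against the mRNA matrix — one joint shuffle per permutation,
shared by all pairs, which preserves each assay's internal structure and
the inter-pair dependence of the global count. Per pair,
p = (1 + #{r_b ≤ r_obs})/(1 + B), significant iff p < α and r_obs < 0;
the global p compares the observed significant count K with the counts
obtained by applying the same left-tail rule within the null ensemble.
Defaults B = 10,000, α = 0.05. Correlations use all shared samples; a
tumors-only analysis can be had by subsetting the matrices first.

## Synthetic data

The generator reproduces the statistical structure the pipeline is built
to detect, at desk scale:

* **Design**: 17 tumor vs 4 normal samples by default (the miRNA arm of
  the emulated study); `SimConfig.mrna_arm()` presets 28 vs 5.
* **Counts**: per-feature baselines log-normal (log2 mean 5, sd 2),
  library sizes log-normal around 1e6 (miRNA) and 2e7 (mRNA) with 0.25
  log2 sd, NB dispersion 0.2 — values typical of bulk small-RNA/mRNA
  assays.
* **Planted structure**: 5 driver miRNAs up at log2FC 3; each driver's
  targets repressed by −1.5 log2 per driver, summed and capped at −4;
  10% independent DE genes at ±3. A per-sample driver-activity variable
  (group effect + 0.5 log2 sd noise) scales each driver up and its
  targets down, so planted pairs anti-correlate across samples and not
  merely between groups — the signal the pairing stage tests.
* **Batch** (optional): a random 30% of features shifted by
  `batch_shift` log2 units in alternating samples spanning both groups.
* **Determinism**: one seed, byte-identical outputs.

What it does **not** emulate: compositionality is not renormalized after
planting effects (so, as in real data, strong planted effects shift
library composition and realized CPM fold changes sit slightly below the
planted values — per-feature realized minus planted log-ratios have
median |error| < 0.5 at 8 vs 8 but individual features can exceed it);
no sequence-level structure, no miRNA families, no dropout or
single-cell sparsity, no correlated gene programs beyond the planted
coupling. Passing tests therefore demonstrate calibration and recovery
under an idealized NB world, not performance on any particular real
dataset.

## Problem sizes and numerical choices

Calibration and recovery suites run at desk scale chosen for tight,
fast feedback: 2,000-feature DE nulls, 30-node RWR oracle graphs,
20-replicate NPES benchmarks with 200 gene-set permutations, 100
pair-null replicates with 1,000 shuffles. RWR tolerance 1e-10 (L1),
Newton tolerance 1e-12 on the log rate, p-values clipped at 1e-300
before log-ranking, empirical p-values always add-one corrected.
Ranking ties break lexicographically; BH ties break by input position;
all permutation streams derive from explicit integer seeds.

## Limitations

* The DE engine handles exactly two groups plus optional latent-factor
  offsets — no general design matrices or quasi-likelihood dispersion
  trends.
* NPES depends on the supplied regulatory prior; missing or spurious
  edges translate directly into missing or spurious influence.
* The permutation pair test needs enough shared samples (≥ 3 hard
  minimum; ~10+ for useful power) and assumes samples are exchangeable
  under the null — batch-confounded designs should adjust first.
* The published-table fixture is transcription, not computation: it
  validates classification logic, not the upstream alignment/counting
  that produced the published values.
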