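# Methods

This note documents the models, conventions, and numerical choices behind
`bipscan`, and what the synthetic-data tests do and do not establish.

## Gene models and divergent pairs

GFF3 input is 1-based inclusive; every internal interval is 0-based
half-open, converted once on load. Only `gene` features are used: the TSS
is taken as the strand-aware gene boundary, with no UTR or isoform model.

A divergent pair is a minus-strand gene `a` and a plus-strand gene `b` to
its right on the same chromosome such that the intergenic gap
`b.start − a.end` is non-negative (overlapping gene bodies are excluded by
default — there is no intergenic region to clone), at most `max_gap`, and no
third gene intersects the intergenic interval `[a.end, b.start)`. The
intrusion condition subsumes adjacency: any gene lying wholly between the
two would intersect the interval. A gene nested inside another gene's body
does not block a pair. `max_gap` defaults to 1000 bp, the conventional
bidirectional-promoter definition; it is configurable everywhere it is
used, including conservation calls.

We label the minus-strand (left) member the **5′ gene** and the plus-strand
(right) member the **3′ gene**: in head-to-head geometry both 5′ ends face
the shared intergenic region, so both promoters live there.

Detection is verified against an independent O(n²) brute-force scan on
random annotations (including heavily overlapping ones), and is invariant
under coordinate mirroring with strand flipping.

## Expression screening

Per source, each gene is summarized by min/max/mean over non-missing
samples; missing cells are NaN, never zero. Correlations (Pearson by
default, Spearman alongside) are computed on raw expression values over
jointly non-missing samples, with no log transform (an optional
`log2(x+1)` preprocessing can be applied upstream); a coefficient is absent
when fewer than `min_corr_samples` (default 37) samples remain or either
vector is constant. The 37-sample floor encodes the judgment that ~36
microarray samples are too few for reliable correlation while ~95 RNA-seq
samples are enough; it sits one above the rejected count.

A pair is a candidate iff, with strict inequalities:

* pair maximum > 10 in at least one RNA-seq source,
* pair maximum > 5000 in at least one microarray source,
* correlation > 0.4 in at least one RNA-seq source meeting the sample floor.

The **pair maximum** is the larger of the two genes' maxima, not a per-gene
requirement. This reading is forced by the validated set itself: one
selected pair has a 5′-gene microarray maximum of 4000.9 — below 5000 —
while its partner clears the bar, so only the pair-maximum interpretation
reproduces the selection. Likewise sources combine as "any source passes"
within each kind, since one selected pair has no data at all in one RNA-seq
source. Both choices are encoded in `screen_summaries` / `screen_pairs` and
pinned by tests.

A summary mode (`screen_summaries`) evaluates pre-computed per-source pair
summaries, so the selection logic can be applied to a published report
table without the underlying matrices.

## Background promoters

The reference set for enrichment is sampled upstream of the TSS of genes
that belong to no divergent pair, with lengths resampled from the observed
intergenic lengths (a fixed-length list may be supplied instead).
Candidates that run off the chromosome or overlap any divergent intergenic
interval are rejected and redrawn. Minus-strand promoters are
reverse-complemented so all background sequences read toward their TSS;
since scanning is double-stranded this is a presentation choice, not a
statistical one.

## Motif model

Motifs are position weight matrices over ACGT scored as log₂ odds against a
0-order background estimated from the scanned sequence set (uniform by
configuration). PWMs are built from counts with background-proportional
pseudocounts, `pc = 0.1` by default: `p[i,a] ∝ counts[i,a] + pc·bg[a]`.

**Exact p-values.** Per-position scores are rounded to a grid of
`granularity` bits (default 10⁻³) and the distribution of the integerized
score of a random background word is built by position-wise convolution.
A scanned window's integer score then looks up `P(S ≥ s)` directly, so the
p-value is exact for the discretized score rather than estimated by
sampling — necessary for thresholds like 10⁻⁸, which no feasible empirical
null reaches. The convolution is verified against exhaustive enumeration of
all 4^w words for small widths, and refining the grid tenfold changes
queried p-values by less than 10⁻³ relative at width 8. Windows containing
N are skipped; minus-strand windows are scored on the reverse complement
and reported at forward-strand offsets.

**ZOOPS EM discovery.** Each sequence carries zero or one motif occurrence:
with prior probability γ a site sits at a uniform position. The E-step
computes per-window site posteriors against the "no site" alternative; the
M-step re-estimates the letter probabilities from posterior-weighted counts
and γ from the mean posterior mass per sequence. The per-restart
log-likelihood (relative to the background-only model) is non-decreasing
across iterations, which is asserted in tests. Initialization is
subsequence-driven in two stages, as in classical motif discovery: many
candidate w-mers from the data are smoothed toward the background
(0.7·indicator + 0.3·background), screened with two EM iterations, and the
best `n_restarts` (default 8) by likelihood are optimized fully; the best
final likelihood wins. Subsequent motifs are found after probabilistic
erasure: each position covered by a window with site posterior `z` has its
weight multiplied by `(1 − z)`, and a window's prior weight for the next
motif is the product of its positions' weights. Discovery is deterministic
given the seed. The default width is 8; the discovered motifs are treated
qualitatively (e.g. G/C-rich vs A/T-rich composition), not as
base-identical logos of any published figure.

**Enrichment.** For each motif, sequences are dichotomized as with/without
a hit at the exact-p-value threshold, and the foreground-vs-background 2×2
table is tested with a one-sided Fisher exact test (alternative:
foreground enrichment). Hits per kilobase are reported descriptively; the
odds ratio uses a Haldane 0.5 correction when a cell is zero. The test is
verified against the hypergeometric closed form.

## Conservation calls

For a source pair and a comparison species, the call is **c-BIP** iff some
ortholog of the 5′ gene and some ortholog of the 3′ gene form a divergent
pair in that species (same `max_gap` as discovery, configurable per
species). Orthology is many-to-many and the criterion is existential; the
two orthologs may appear in either role, since a whole-locus inversion
preserves head-to-head geometry. Anything else is **n-BIP** with the most
specific reason, evaluated in the order: ortholog missing → orthologs not
adjacent (no combination sits side-by-side within the gap) → orthologs not
divergent (adjacent but wrongly oriented). Missing orthologs are n-BIP
rather than a third class, matching the binary published dichotomy. The
conserved-species count of a profile includes the source species, which is
conserved by construction (identity orthologs on its own annotation).

The packaged six-grass scenario reproduces all 24 published calls. The
published table's cell annotation beyond the c-BIP/n-BIP label (a "C/C"
notation) is undefined in the source and is ignored; the specific breakdown
mode behind each n-BIP cell (inversion, insertion, translocation, missing
ortholog) is a synthetic choice, as only the binary label is authoritative.

## Reporter quantification

Relative expression uses the 2^(−ΔΔCt) method: technical replicates are
averaged on the Ct scale (not the linear scale), ΔCt = Ct_target −
Ct_control per sample, ΔΔCt referenced to a calibrator sample whose fold is
1 by construction. GUS specific activity is `pmol 4-MU / minutes /
protein_mg`; fluorometric and Bradford calibration to pmol and mg happens
upstream and is out of scope. Transgenic lines are grouped (default two
lines per biological replicate, in order or seeded-random); the summary SE
is `sd/√n` over replicate means.

Group letters come from one-way ANOVA followed by all-pairs Tukey HSD at
α = 0.05 (the conventional machinery behind compact letter displays; the
test is pluggable, as the original procedure behind such letterings is
rarely stated). Letters label the maximal cliques of the
"not-significantly-different" graph, ordered by descending group mean from
"a"; two groups share a letter iff their pairwise comparison is
non-significant, which is asserted as a property. If the ANOVA is
non-significant, or all values are identical, every group shares "a".

## Synthetic data: what it emulates, and what it does not

`simulate_genome` lays out non-overlapping genes with a configured fraction
arranged head-to-head within the divergent gap (intergenic lengths uniform
in 200–800 bp); all other adjacencies are separated by more than `max_gap`,
so the truth table enumerates exactly the detectable pairs. Sequence
content is i.i.d. uniform DNA.

`simulate_expression` emulates the screening conditions: 95 exchangeable
samples, lognormal margins (log-mean uniform in [1.5, 3.5], log-sd 0.6)
whose maxima clear the 10-unit RNA-seq threshold, a ×500 scale for
microarray values so the 5000-unit threshold is equally exercised, and
co-expressed pairs at target Pearson r = 0.7. Correlation is induced by a
Gaussian copula whose correlation ρ is calibrated analytically so the
lognormal-scale Pearson correlation equals the target exactly in
expectation: `ρ = log(1 + r·√((e^{σ₁²}−1)(e^{σ₂²}−1))) / (σ₁σ₂)`. A
Monte-Carlo test confirms the mean sample correlation lands within ±0.05 of
the target.

`plant_motif` implants one PWM-sampled site per sequence with a given
probability at a uniform position, recording truth offsets.

What passing these tests shows: the detection, screening, discovery, and
classification machinery recovers known structure at realistic sample sizes
and effect sizes. What it does not show: robustness to features of real
data that the generators deliberately omit — GC isochores and repeats,
batch structure and platform-specific noise in expression, probe effects,
correlated or clustered motif occurrences, transcript-level TSS
uncertainty, and fragmented annotations. Conclusions about real genomes
still require the real inputs.

## Problem sizes and determinism

Default verification sizes were chosen to give stable pass/fail behavior at
interactive runtimes: 200 replicates for screening recovery (10 planted
pairs at r = 0.7 vs 40 decoys, 95 samples), 20 seeded EM runs for motif
recovery (50 × 300-bp promoters, site probability 0.9, width 8, recovery
scored as mean per-position total-variation distance < 0.25 after aligning
registers within ±2 columns and reverse complement), 100 random annotations
for the detection oracle. All generators and EM runs are bit-reproducible
given (seed, config); every randomized entry point takes an explicit seed.

## Known limitations

* Gene-level only: no isoform-resolved TSS, so intergenic boundaries are
  gene-body boundaries.
* The EM implements OOPS/ZOOPS but not multiple occurrences per sequence
  (TCM); strong multi-copy motifs are partially captured through erasure.
* E-values and width selection are not calibrated against published MEME;
  widths are a user choice (default 8).
* The exact p-value background is 0-order; higher-order backgrounds are out
  of scope.
* Enrichment uses per-sequence presence, discarding multiplicity beyond the
  descriptive hits/kb.
* Orthology is taken as given (user-supplied tables); no synteny-block or
  sequence-level conservation scoring.
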