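# bipscan

Discovery and characterization of **bidirectional promoters** in annotated
plant genomes.

A bidirectional promoter is the intergenic region between two adjacent genes
transcribed in opposite directions (a head-to-head, `(-, +)` divergent pair);
it can drive both flanking genes at once, which makes such promoters valuable
for stacking transgenes with matched expression patterns. This package
implements, as a tested pipeline, the computational side of a
select-clone-characterize workflow for rice-style genomes:

1. **Divergent pair detection** — parse gene models from GFF3 and find every
   adjacent `(-, +)` pair whose intergenic gap is at most `max_gap`
   (default 1 kb) with no third gene intruding.
2. **Expression screening** — integrate RNA-seq and cDNA-microarray matrices
   and select candidate pairs where the pair expression maximum
   `max(max(x₅), max(x₃))` exceeds 10 in an RNA-seq source **and** 5000 in a
   microarray source, **and** the pair correlation `r(x₅, x₃) > 0.4` over
   ≥ 37 RNA-seq samples (all inequalities strict).
3. **Promoter extraction** — intergenic sequences of selected pairs, plus
   length-matched background promoters sampled upstream of non-divergent
   genes for use as a reference set.
4. **Motif analysis** — ZOOPS (zero-or-one occurrence per sequence) EM motif
   discovery with seeded restarts and probabilistic erasure between motifs;
   PWM scanning with **exact** p-values computed by dynamic programming
   (discretized position-wise convolution of the log-odds score
   distribution, so thresholds like p < 10⁻⁸ are exact rather than sampled);
   one-sided Fisher exact test for overrepresentation in candidate vs
   background promoters.
5. **Conservation** — classify each pair per comparison species as **c-BIP**
   (some ortholog of each member still forms a divergent pair there) or
   **n-BIP**, with reason codes (ortholog missing / not adjacent /
   not divergent).
6. **Reporter quantification** — 2^(−ΔΔCt) relative expression for qPCR,
   GUS specific activity (pmol 4-MU·min⁻¹·mg⁻¹), aggregation of transgenic
   lines into biological replicates, and compact letter displays from
   one-way ANOVA + Tukey HSD.

A first-class synthetic-data module (`bipscan.simulate`) generates toy
genomes with planted divergent pairs, expression matrices with calibrated
pair correlations (Gaussian copula over lognormal margins), and
motif-planted promoter sets — every stage is testable against known truth
without downloads. `bipscan.fixtures` carries the published per-source
expression summaries and the six-grass conservation scenario for the four
experimentally validated rice promoters BIP1–BIP4.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
published summaries and on a simulated workspace (bulky intermediates go to
`scratch/`, tables to `results/`):

```bash
python analysis/01_simulate_workspace.py
python analysis/02_screen_candidates.py
python analysis/03_discover_motifs.py
python analysis/04_conservation.py
python analysis/05_reporter_quant.py
```

Output (seed 11):

```
published summaries: 4 pairs screened, 4 selected: BIP1, BIP2, BIP3, BIP4
simulated workspace: 12 divergent pairs found, 4 selected (truth: 4 co-expressed)
motif_1: consensus GGCGCCGC, fg 3.55 hits/kb vs bg 0.19, odds ratio 46.0, enrichment p = 1.47e-11
motif_2: consensus TAATATTT, fg 2.47 hits/kb vs bg 0.14, odds ratio 44.3, enrichment p = 1.14e-10
BIP1: c-BIP in 4/6 species (O_sativa, S_bicolor, B_distachyon, Z_mays)
BIP2: c-BIP in 2/6 species (O_sativa, T_aestivum)
BIP3: c-BIP in 4/6 species (O_sativa, S_bicolor, S_italica, B_distachyon)
BIP4: c-BIP in 3/6 species (O_sativa, S_bicolor, S_italica)
```

Reading this: applying the three screening criteria to the published
expression summaries selects exactly the four validated promoters; on the
simulated genome the screen returns precisely the four co-expressed planted
pairs and none of the eight expression decoys; the two motifs planted into
the candidate promoters (one G/C-rich, one A/T-rich) are re-discovered de
novo and are strongly overrepresented relative to background promoters; and
the conservation calls match the published pattern — BIP1 and BIP3 conserved
in four of six grasses, BIP4 in three, BIP2 in two.

In code, the screening step looks like:

```python
from bipscan.annotation import load_gene_models, find_divergent_pairs
from bipscan.expression import load_expression_matrix, screen_pairs

genes = load_gene_models("annotation.gff3")
pairs = find_divergent_pairs(genes, max_gap=1000)
mats = [
    load_expression_matrix("rnaseq.tsv", "MSU", "rnaseq"),
    load_expression_matrix("microarray.tsv", "CREP", "microarray"),
]
candidates = [r for r in screen_pairs(pairs, mats) if r.passed]
```

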