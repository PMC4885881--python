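import numpy as np
import pytest

from bipscan.annotation import DivergentPair, GeneModel
from bipscan.motifs import pwm_from_counts


def make_gene(gene_id, start, end, strand, chrom="chr1"):
    return GeneModel(chrom=chrom, start=start, end=end, gene_id=gene_id, strand=strand)


def make_pair(i, chrom="chr1", g5=(0, 100), g3=(300, 400)):
    return DivergentPair(
        gene5=make_gene(f"p{i}_5", *g5, "-", chrom),
        gene3=make_gene(f"p{i}_3", *g3, "+", chrom),
        pair_id=f"pair_{i}",
    )


def random_annotation(rng, n_genes, n_chroms=3, span=50_000, max_len=2000):
    """Random (possibly overlapping) gene models for oracle comparisons."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
        start = int(rng.integers(span))
        length = int(rng.integers(100, max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(chrom, start, start + length, f"g{i}", strand))
    return genes


def brute_force_divergent_pairs(genes, max_gap=1000, allow_overlap=False):
    """O(n^2) oracle: every (-,+) ordered combination, intrusion checked
    against the full gene list."""
    found = set()
    for a in genes:
        if a.strand != "-":
            continue
        for b in genes:
            if b is a or b.strand != "+" or b.chrom != a.chrom:
                continue
            gap = b.start - a.end
            if gap > max_gap:
                continue
            if not allow_overlap and gap < 0:
                continue
            if allow_overlap and b.start < a.start:
                continue
            gs, ge = min(a.end, b.start), b.start
            intruded = any(
                c is not a and c is not b and c.chrom == a.chrom
                and c.start < ge and c.end > gs
                for c in genes
            )
            if not intruded:
                found.add((a.gene_id, b.gene_id))
    return found


def consensus_pwm(word, strength=20.0, pseudocount=0.5, motif_id=None):
    """Sharp PWM whose consensus is the given word."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(word), 4))
    for i, ch in enumerate(word):
        counts[i, idx[ch]] = strength
    return pwm_from_counts(counts, pseudocount=pseudocount, motif_id=motif_id or word)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
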