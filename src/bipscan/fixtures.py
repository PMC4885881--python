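"""Published-table fixtures: the four selected rice divergent gene pairs.

Two small, fully in-package datasets:

* the per-source expression summary of the four selected pairs (BIP1-BIP4):
  min/max/mean of each gene plus Pearson/Spearman correlations, from two
  RNA-seq sources (MSU, RAP; 95 samples) and one cDNA microarray source
  (CREP; 36 samples, too few for reliable correlation);
* a six-grass orthology/arrangement scenario (O. sativa, S. bicolor,
  S. italica, B. distachyon, Z. mays, T. aestivum) whose classification
  reproduces the published conserved/non-conserved (c-BIP/n-BIP) matrix.

Genomic coordinates and ortholog gene ids are synthetic — only the locus
ids, the expression summaries, and the conservation labels are real.
"""

from __future__ import annotations

from .annotation import DivergentPair, GeneModel
from .conservation import OrthologMap
from .expression import GeneExprStats, PairExpressionSummary

__all__ = [
    "SPECIES",
    "SOURCE_SPECIES",
    "table1_pairs",
    "table1_summaries",
    "table1_gff3_text",
    "bip1_msu_gene5_values",
    "table3_scenario",
    "TABLE3_CALLS",
]

SOURCE_SPECIES = "O_sativa"
SPECIES = ("O_sativa", "S_bicolor", "S_italica", "B_distachyon", "Z_mays", "T_aestivum")

# pair_id -> (5' gene, 3' gene, chrom); coordinates below are synthetic
_PAIR_GENES = {
    "BIP1": ("LOC_Os02g42314", "LOC_Os02g42320", "Chr2"),
    "BIP2": ("LOC_Os05g27940", "LOC_Os05g27950", "Chr5"),
    "BIP3": ("LOC_Os02g47000", "LOC_Os02g47010", "Chr2"),
    "BIP4": ("LOC_Os03g22880", "LOC_Os03g22890", "Chr3"),
}

_PAIR_COORDS = {
    # pair_id -> (gene5 start, gene5 end, gene3 start, gene3 end)
    "BIP1": (10_000, 12_500, 13_300, 15_200),
    "BIP2": (40_000, 42_100, 42_700, 44_900),
    "BIP3": (60_000, 62_400, 63_000, 65_500),
    "BIP4": (25_000, 27_800, 28_500, 30_600),
}

# pair, source, kind, g5 (min, max, mean), g3 (min, max, mean), pearson, spearman
_TABLE1 = [
    ("BIP1", "MSU", "rnaseq", (0.6, 21.57, 7.88), (0.0, 31.16, 11.0), 0.67, 0.62),
    ("BIP1", "RAP", "rnaseq", (1.65, 35.33, 10.35), (0.0, 10.25, 3.8), 0.58, 0.51),
    ("BIP1", "CREP", "microarray", (2143.75, 9118.85, 5662.15), (6009.55, 15236.5, 9940.64), None, None),
    ("BIP2", "MSU", "rnaseq", (1.58, 88.59, 17.19), (0.38, 40.61, 8.91), 0.45, 0.5),
    ("BIP2", "CREP", "microarray", (2472.2, 22698.9, 13559.4), (1381.8, 7987.6, 4900.6), None, None),
    ("BIP3", "MSU", "rnaseq", (0.0, 30.11, 13.56), (0.37, 16.17, 4.96), 0.51, 0.49),
    ("BIP3", "RAP", "rnaseq", (0.05, 639.27, 19.56), (0.23, 720.79, 45.81), 0.84, 0.93),
    ("BIP3", "CREP", "microarray", (568.4, 4000.9, 1680.54), (709.45, 7154.35, 3080.98), None, None),
    ("BIP4", "MSU", "rnaseq", (0.0, 69.12, 9.42), (0.0, 184.71, 15.17), 0.65, 0.78),
    ("BIP4", "RAP", "rnaseq", (0.16, 21.51, 3.8), (1.31, 142.75, 12.44), 0.74, 0.81),
    ("BIP4", "CREP", "microarray", (274.55, 13458.05, 4949.52), (1065.65, 14857.15, 7410.79), None, None),
]

_N_SAMPLES = {"MSU": 95, "RAP": 95, "CREP": 36}


def table1_pairs() -> list[DivergentPair]:
    """The four selected divergent pairs as located gene models (synthetic
    coordinates, real locus ids)."""
    pairs = []
    for pid, (g5, g3, chrom) in _PAIR_GENES.items():
        s5, e5, s3, e3 = _PAIR_COORDS[pid]
        pairs.append(
            DivergentPair(
                gene5=GeneModel(chrom=chrom, start=s5, end=e5, gene_id=g5, strand="-"),
                gene3=GeneModel(chrom=chrom, start=s3, end=e3, gene_id=g3, strand="+"),
                pair_id=pid,
            )
        )
    return pairs


def table1_gff3_text() -> str:
    """GFF3 (1-based inclusive) encoding the eight genes of the four pairs."""
    lines = ["##gff-version 3"]
    for pair in table1_pairs():
        for g in (pair.gene5, pair.gene3):
            lines.append(
                f"{g.chrom}\tfixture\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
            )
    return "\n".join(lines) + "\n"


def table1_summaries() -> list[PairExpressionSummary]:
    """The published per-source expression summary rows of BIP1-BIP4."""
    out = []
    for pid, src, kind, g5, g3, pe, sp in _TABLE1:
        g5_id, g3_id, _ = _PAIR_GENES[pid]
        n = _N_SAMPLES[src]
        out.append(
            PairExpressionSummary(
                pair_id=pid,
                source_id=src,
                kind=kind,
                gene5_stats=GeneExprStats(g5_id, src, *g5, n_samples=n),
                gene3_stats=GeneExprStats(g3_id, src, *g3, n_samples=n),
                pearson=pe,
                spearman=sp,
            )
        )
    return out


def bip1_msu_gene5_values(n_samples: int = 95) -> list[float]:
    """A 95-sample expression vector realizing the published BIP1 5'-gene
    MSU summary (min 0.6, max 21.57, mean 7.88): the extremes appear once
    each and the remaining samples share the value that fixes the mean."""
    lo, hi, mean = 0.6, 21.57, 7.88
    filler = (n_samples * mean - lo - hi) / (n_samples - 2)
    return [lo, hi] + [filler] * (n_samples - 2)


# ---------------------------------------------------------------------------
# Conservation scenario
# ---------------------------------------------------------------------------

# published matrix: pair -> species -> c-BIP / n-BIP
TABLE3_CALLS = {
    "BIP1": {"O_sativa": "c-BIP", "S_bicolor": "c-BIP", "S_italica": "n-BIP",
             "B_distachyon": "c-BIP", "Z_mays": "c-BIP", "T_aestivum": "n-BIP"},
    "BIP2": {"O_sativa": "c-BIP", "S_bicolor": "n-BIP", "S_italica": "n-BIP",
             "B_distachyon": "n-BIP", "Z_mays": "n-BIP", "T_aestivum": "c-BIP"},
    "BIP3": {"O_sativa": "c-BIP", "S_bicolor": "c-BIP", "S_italica": "c-BIP",
             "B_distachyon": "c-BIP", "Z_mays": "n-BIP", "T_aestivum": "n-BIP"},
    "BIP4": {"O_sativa": "c-BIP", "S_bicolor": "c-BIP", "S_italica": "c-BIP",
             "B_distachyon": "n-BIP", "Z_mays": "n-BIP", "T_aestivum": "n-BIP"},
}

# how each non-conserved cell breaks down (synthetic choice; the published
# table gives only the binary label)
_NBIP_MODE = {
    ("BIP1", "S_italica"): "inverted",
    ("BIP1", "T_aestivum"): "translocated",
    ("BIP2", "S_bicolor"): "inserted",
    ("BIP2", "S_italica"): "missing",
    ("BIP2", "B_distachyon"): "convergent",
    ("BIP2", "Z_mays"): "translocated",
    ("BIP3", "Z_mays"): "missing",
    ("BIP3", "T_aestivum"): "inverted",
    ("BIP4", "B_distachyon"): "inserted",
    ("BIP4", "Z_mays"): "convergent",
    ("BIP4", "T_aestivum"): "missing",
}

# conserved loci that are whole-locus inversions in the target species (the
# 5' ortholog sits right on the plus strand) — still head-to-head
_CONSERVED_INVERTED = {("BIP1", "S_bicolor"), ("BIP3", "B_distachyon")}


def _species_locus(species: str, pid: str, mode: str, offset: int):
    """Gene models + ortholog rows for one pair's locus in one species."""
    prefix = f"{species}_{pid}"
    o5, o3 = f"{prefix}_a", f"{prefix}_b"
    glen, gap = 2000, 500
    chrom = f"{species}_chr1"
    genes, orths = [], []
    g5_src, g3_src, _ = _PAIR_GENES[pid]

    def gm(gid, chrom_, start, strand):
        return GeneModel(chrom=chrom_, start=start, end=start + glen, gene_id=gid, strand=strand)

    if mode == "missing":
        # only the 5' gene has an ortholog
        genes.append(gm(o5, chrom, offset, "-"))
        orths.append((g5_src, o5))
        return genes, orths
    orths.extend([(g5_src, o5), (g3_src, o3)])
    if mode == "conserved":
        genes.append(gm(o5, chrom, offset, "-"))
        genes.append(gm(o3, chrom, offset + glen + gap, "+"))
    elif mode == "conserved_inverted":
        genes.append(gm(o3, chrom, offset, "-"))
        genes.append(gm(o5, chrom, offset + glen + gap, "+"))
    elif mode == "inverted":
        # one member flipped: tandem (- -), no longer head-to-head
        genes.append(gm(o5, chrom, offset, "-"))
        genes.append(gm(o3, chrom, offset + glen + gap, "-"))
    elif mode == "convergent":
        genes.append(gm(o5, chrom, offset, "+"))
        genes.append(gm(o3, chrom, offset + glen + gap, "-"))
    elif mode == "inserted":
        # an unrelated gene intrudes between the orthologs
        genes.append(gm(o5, chrom, offset, "-"))
        genes.append(gm(f"{prefix}_ins", chrom, offset + glen + 100, "+"))
        genes.append(gm(o3, chrom, offset + 2 * glen + 300, "+"))
    elif mode == "translocated":
        genes.append(gm(o5, chrom, offset, "-"))
        genes.append(gm(o3, f"{species}_chr2", offset, "+"))
    else:
        raise ValueError(mode)
    return genes, orths


def table3_scenario(max_gap: int = 1000):
    """Per-species (OrthologMap, gene list) inputs reproducing the published
    conservation matrix for BIP1-BIP4 across six grasses.

    The source species carries identity orthologs onto the real annotation
    fixture, so it is conserved by construction.  Returns
    ``{species: (OrthologMap, [GeneModel])}``.
    """
    inputs: dict[str, tuple[OrthologMap, list[GeneModel]]] = {}
    src_pairs = table1_pairs()

    omap = OrthologMap(species_id=SOURCE_SPECIES)
    src_genes = []
    for p in src_pairs:
        for g in (p.gene5, p.gene3):
            omap.add(g.gene_id, g.gene_id)
            src_genes.append(g)
    inputs[SOURCE_SPECIES] = (omap, sorted(src_genes))

    for species in SPECIES[1:]:
        omap = OrthologMap(species_id=species)
        genes: list[GeneModel] = []
        offset = 10_000
        for pid in TABLE3_CALLS:
            if TABLE3_CALLS[pid][species] == "c-BIP":
                mode = "conserved_inverted" if (pid, species) in _CONSERVED_INVERTED else "conserved"
            else:
                mode = _NBIP_MODE[(pid, species)]
            locus_genes, locus_orths = _species_locus(species, pid, mode, offset)
            genes.extend(locus_genes)
            for q, o in locus_orths:
                omap.add(q, o)
            offset += 20_000  # loci far apart: > max_gap between them
        inputs[species] = (omap, sorted(genes))
    return inputs
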