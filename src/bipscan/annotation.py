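"""Gene models, divergent (head-to-head) pair detection, and promoter extraction.

A bidirectional promoter is the intergenic region between two adjacent genes
transcribed in opposite directions, with their 5' ends facing each other:
strand pattern (-, +) in left-to-right coordinate order.  The minus-strand
(left) member is called the 5' gene and the plus-strand (right) member the
3' gene; both promoters lie in the shared intergenic interval.

All internal coordinates are 0-based half-open.  GFF3 input (1-based,
inclusive) is converted on load.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from gffutils.feature import feature_from_line

__all__ = [
    "GeneModel",
    "DivergentPair",
    "PromoterSequence",
    "GFF3ParseError",
    "load_gene_models",
    "find_divergent_pairs",
    "extract_intergenic",
    "sample_background_promoters",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 line; the message names the line number."""


@dataclass(frozen=True, order=True)
class GeneModel:
    """A located, stranded gene (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    gene_id: str = field(compare=False)
    strand: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start position, taken as the strand-aware gene boundary."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class DivergentPair:
    """Two adjacent opposite-strand genes sharing an intergenic interval.

    ``gene5`` is the minus-strand (left) member, ``gene3`` the plus-strand
    (right) member; the intergenic interval ``[gene5.end, gene3.start)`` holds
    both promoters.
    """

    gene5: GeneModel
    gene3: GeneModel
    pair_id: str

    def __post_init__(self) -> None:
        if self.gene5.strand != "-" or self.gene3.strand != "+":
            raise ValueError(f"pair {self.pair_id}: strand pattern must be (-, +)")
        if self.gene5.chrom != self.gene3.chrom:
            raise ValueError(f"pair {self.pair_id}: genes on different chromosomes")

    @property
    def chrom(self) -> str:
        return self.gene5.chrom

    @property
    def intergenic_start(self) -> int:
        return min(self.gene5.end, self.gene3.start)

    @property
    def intergenic_end(self) -> int:
        return self.gene3.start

    @property
    def intergenic_length(self) -> int:
        return max(0, self.gene3.start - self.gene5.end)


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter fragment: either a pair's intergenic region or a background
    region sampled upstream of a non-divergent gene."""

    seq_id: str
    sequence: str
    origin: str  # "intergenic" | "background"
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.seq_id}: sequence length {len(self.sequence)} != interval "
                f"length {self.end - self.start}"
            )
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"{self.seq_id}: sequence contains non-ACGTN letters")


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Read gene-level records from a GFF3 file.

    Only features of type ``gene`` are kept; 1-based inclusive coordinates are
    converted to 0-based half-open.  Records lacking a strand are rejected
    with a warning.  Returns genes sorted by (chrom, start, end).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GFF3ParseError(
                    f"malformed GFF3 at line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GFF3ParseError(f"malformed GFF3 at line {lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            if feat.strand not in ("+", "-"):
                warnings.warn(
                    f"line {lineno}: gene record without strand rejected", stacklevel=2
                )
                continue
            gene_id = feat.attributes.get("ID", [None])[0] or feat.id
            if gene_id is None:
                raise GFF3ParseError(f"line {lineno}: gene record lacks an ID attribute")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in {gff3_path}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    gene_id=gene_id,
                    strand=feat.strand,
                )
            )
    genes.sort()
    return genes


def _by_chrom(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for lst in out.values():
        lst.sort()
    return out


def find_divergent_pairs(
    genes: Sequence[GeneModel],
    max_gap: int = 1000,
    allow_overlap: bool = False,
) -> list[DivergentPair]:
    """Detect head-to-head divergent gene pairs.

    A pair is a minus-strand gene ``a`` and a plus-strand gene ``b`` to its
    right on the same chromosome such that the intergenic gap
    ``b.start - a.end`` is at most ``max_gap`` and no third gene intersects
    the intergenic interval (which also enforces adjacency).  With
    ``allow_overlap`` False (default) pairs whose gene bodies overlap
    (negative gap) are excluded — no intergenic region exists to clone.

    Genes on distinct chromosomes are handled independently.  Duplicate
    gene ids raise ``ValueError``.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_id(s): {dup}")

    pairs: list[DivergentPair] = []
    for chrom, chrom_genes in sorted(_by_chrom(genes).items()):
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        starts_list = starts.tolist()
        n = len(chrom_genes)
        for i, a in enumerate(chrom_genes):
            if a.strand != "-":
                continue
            lo = a.start if allow_overlap else a.end
            # candidate partners: plus-strand genes starting in [lo, a.end + max_gap]
            j0 = bisect_left(starts_list, lo)
            for j in range(j0, n):
                b = chrom_genes[j]
                if b.start - a.end > max_gap:
                    break
                if j == i or b.strand != "+":
                    continue
                if not allow_overlap and b.start < a.end:
                    continue
                gs, ge = min(a.end, b.start), b.start
                # third-gene intrusion into the intergenic interval [gs, ge)
                mask = (starts < ge) & (ends > gs)
                mask[i] = mask[j] = False
                if mask.any():
                    continue
                pairs.append(
                    DivergentPair(gene5=a, gene3=b, pair_id=f"{a.gene_id}|{b.gene_id}")
                )
    pairs.sort(key=lambda p: (p.chrom, p.gene5.start, p.gene3.start))
    return pairs


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` from a FASTA handle (pyfaidx.Fasta, Bio dict,
    or a plain mapping of chrom -> string)."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
    seq = record if isinstance(record, str) else record[:]
    seq = str(seq.seq) if hasattr(seq, "seq") else str(seq)
    if end > len(seq):
        raise IndexError(
            f"interval [{start}, {end}) exceeds {chrom} length {len(seq)}"
        )
    return seq[start:end].upper()


def extract_intergenic(pair: DivergentPair, genome) -> PromoterSequence:
    """Extract the forward-strand intergenic sequence of a divergent pair."""
    start, end = pair.intergenic_start, pair.intergenic_end
    if end <= start:
        warnings.warn(f"pair {pair.pair_id}: zero-length intergenic region", stacklevel=2)
        start = end
    seq = _fetch(genome, pair.chrom, start, end)
    return PromoterSequence(
        seq_id=pair.pair_id,
        sequence=seq,
        origin="intergenic",
        chrom=pair.chrom,
        start=start,
        end=end,
    )


def sample_background_promoters(
    genes: Sequence[GeneModel],
    pairs: Sequence[DivergentPair],
    genome,
    n: int,
    lengths: Sequence[int] | None = None,
    seed: int = 0,
) -> list[PromoterSequence]:
    """Sample ``n`` random background promoters for enrichment reference.

    Regions are taken immediately upstream of the TSS of randomly chosen
    genes that belong to no divergent pair, with lengths resampled from the
    observed intergenic lengths (or drawn from ``lengths`` when given).
    Candidate regions overlapping any divergent intergenic interval, or
    falling off the chromosome, are rejected and redrawn.  Minus-strand
    promoters are reverse-complemented so every returned sequence reads
    toward its TSS.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    member_ids = {p.gene5.gene_id for p in pairs} | {p.gene3.gene_id for p in pairs}
    eligible = [g for g in genes if g.gene_id not in member_ids]
    if len(eligible) < 1:
        raise ValueError(
            f"no eligible background genes: all {len(genes)} genes belong to "
            "divergent pairs"
        )
    if lengths is None:
        lengths = [p.intergenic_length for p in pairs if p.intergenic_length > 0]
    if not lengths:
        raise ValueError("no positive lengths available to sample from")

    chrom_len: dict[str, int] = {}
    intergenic = [(p.chrom, p.intergenic_start, p.intergenic_end) for p in pairs]
    rng = np.random.default_rng(seed)
    out: list[PromoterSequence] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError(
                f"could not place {n} background promoters "
                f"({len(out)} placed, {n - len(out)} short) — too few eligible genes"
            )
        g = eligible[int(rng.integers(len(eligible)))]
        length = int(lengths[int(rng.integers(len(lengths)))])
        if g.chrom not in chrom_len:
            rec = genome[g.chrom]
            s = rec if isinstance(rec, str) else rec[:]
            chrom_len[g.chrom] = len(str(s.seq) if hasattr(s, "seq") else str(s))
        if g.strand == "+":
            start, end = g.start - length, g.start
        else:
            start, end = g.end, g.end + length
        if start < 0 or end > chrom_len[g.chrom]:
            continue
        if any(c == g.chrom and start < ie and end > is_ for c, is_, ie in intergenic):
            continue
        seq = _fetch(genome, g.chrom, start, end)
        if g.strand == "-":
            seq = reverse_complement(seq)
        out.append(
            PromoterSequence(
                seq_id=f"bg_{len(out)}_{g.gene_id}",
                sequence=seq,
                origin="background",
                chrom=g.chrom,
                start=start,
                end=end,
            )
        )
    return out
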