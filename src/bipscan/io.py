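"""File-format plumbing: GFF3/FASTA/BED/TSV writers and MEME minimal motifs."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import DivergentPair, GeneModel, PromoterSequence
from .motifs import ALPHABET, MotifHit, PositionWeightMotif

__all__ = [
    "write_gff3",
    "write_fasta",
    "read_fasta",
    "write_pairs_bed",
    "write_pairs_tsv",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "write_hits_tsv",
    "write_meme_minimal",
    "read_meme_minimal",
]


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes):
            fh.write(
                f"{g.chrom}\tbipscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_pairs_bed(pairs: Sequence[DivergentPair], path) -> None:
    """Intergenic intervals as BED (name = pair_id)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.chrom}\t{p.intergenic_start}\t{p.intergenic_end}\t{p.pair_id}\n")


def write_pairs_tsv(pairs: Sequence[DivergentPair], path) -> None:
    rows = [
        {
            "pair_id": p.pair_id,
            "gene5": p.gene5.gene_id,
            "gene3": p.gene3.gene_id,
            "chrom": p.chrom,
            "intergenic_start": p.intergenic_start,
            "intergenic_end": p.intergenic_end,
            "intergenic_length": p.intergenic_length,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_promoters_fasta(seqs: Sequence[PromoterSequence], path) -> None:
    write_fasta({s.seq_id: s.sequence for s in seqs}, path)


def read_promoters_fasta(path, origin: str = "intergenic") -> list[PromoterSequence]:
    return [
        PromoterSequence(
            seq_id=name, sequence=seq, origin=origin, chrom=name, start=0, end=len(seq)
        )
        for name, seq in read_fasta(path).items()
    ]


def write_hits_tsv(hits: Sequence[MotifHit], path, width: int = 1) -> None:
    """Tabular motif hits (seq_id, start, stop, strand, score, p-value)."""
    rows = [
        {
            "motif_id": h.motif_id,
            "seq_id": h.seq_id,
            "start": h.offset,
            "stop": h.offset + width,
            "strand": h.strand,
            "score": h.score,
            "p_value": h.p_value,
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows, columns=["motif_id", "seq_id", "start", "stop", "strand", "score", "p_value"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_meme_minimal(motifs: Sequence[PositionWeightMotif], path) -> None:
    """Write motifs in MEME minimal text format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(ALPHABET)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {max(m.nsites, 1)} E= 0\n"
            )
            for row in m.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> list[PositionWeightMotif]:
    motifs: list[PositionWeightMotif] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            header = lines[i].strip()
            fields = dict(
                zip(header.split(":")[1].split()[::2], header.split(":")[1].split()[1::2])
            )
            w = int(fields["w="])
            nsites = int(fields.get("nsites=", 1))
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            probs = np.array(rows)
            probs /= probs.sum(axis=1, keepdims=True)
            probs = np.clip(probs, 1e-9, None)
            probs /= probs.sum(axis=1, keepdims=True)
            motifs.append(
                PositionWeightMotif(
                    motif_id=motif_id, probs=probs, background=background, nsites=nsites
                )
            )
        i += 1
    return motifs
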