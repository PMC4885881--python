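"""Synthetic genomes, expression matrices, and motif-planted promoter sets.

Every generator is bit-reproducible given (seed, config) and returns a truth
table alongside the data, so detection, screening, and discovery can be
scored against known ground truth:

* ``simulate_genome`` — random DNA with non-overlapping genes, a configured
  number of them arranged head-to-head (-, +) within the divergent-pair gap;
  all other inter-gene gaps exceed ``max_gap`` so the planted pairs are
  exactly the detectable ones;
* ``simulate_expression`` — RNA-seq-like and microarray-like matrices over
  exchangeable samples; co-expressed pairs draw from a Gaussian copula whose
  correlation is calibrated so the lognormal-scale Pearson correlation hits
  the target; decoy pairs are independent;
* ``plant_motif`` — implants one PWM-sampled site per sequence with a given
  probability, recording true positions;
* ``random_promoters`` — i.i.d. background sequence with configurable base
  composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import DivergentPair, GeneModel, PromoterSequence
from .expression import ExpressionMatrix
from .motifs import ALPHABET, PositionWeightMotif

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_expression",
    "plant_motif",
    "random_promoters",
    "calibrated_copula_rho",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the screening setting being emulated: 95 exchangeable
    expression samples, a target pair correlation of 0.7 for co-expressed
    pairs, lognormal marginals whose maxima clear the selection thresholds,
    and microarray values scaled x500 relative to RNA-seq so the 10 / 5000
    thresholds are both exercised.
    """

    seed: int = 0
    n_genes: int = 100
    n_chroms: int = 3
    fraction_divergent: float = 0.2
    gene_length: tuple[int, int] = (500, 1500)
    intergenic_length: tuple[int, int] = (200, 800)
    locus_gap: tuple[int, int] = (1200, 3000)  # between loci; > max_gap
    max_gap: int = 1000
    n_samples: int = 95
    planted_r: float = 0.7
    log_mu_range: tuple[float, float] = (1.5, 3.5)
    log_sigma: float = 0.6
    microarray_scale: float = 500.0
    motif_site_prob: float = 0.9
    chrom_length: int | None = None  # fixed length; None = sized to fit

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_divergent <= 1:
            raise ValueError("fraction_divergent must lie in [0, 1]")
        if not 0 <= self.planted_r < 1:
            raise ValueError("planted_r must lie in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _random_dna(rng: np.random.Generator, length: int, probs=None) -> str:
    probs = np.full(4, 0.25) if probs is None else np.asarray(probs, float)
    return "".join(np.array(list(ALPHABET))[rng.choice(4, size=length, p=probs)])


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Generate (genome, genes, truth) with planted divergent pairs.

    ``fraction_divergent`` of the genes are laid out as head-to-head pairs
    with intergenic gaps drawn inside ``intergenic_length``; every other
    adjacency is separated by more than ``max_gap``, so the truth table
    enumerates exactly the detectable pairs.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pairs = int(round(cfg.n_genes * cfg.fraction_divergent / 2))
    n_single = cfg.n_genes - 2 * n_pairs
    units: list[str] = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(units)

    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth_rows = []
    per_chrom = np.array_split(np.arange(len(units)), cfg.n_chroms)
    gi = pi = 0
    for ci, unit_idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(*cfg.locus_gap))
        for ui in unit_idx:
            if units[ui] == "pair":
                l5 = int(rng.integers(*cfg.gene_length))
                l3 = int(rng.integers(*cfg.gene_length))
                gap = int(rng.integers(*cfg.intergenic_length))
                g5 = GeneModel(chrom, cursor, cursor + l5, f"g{gi}", "-")
                g3 = GeneModel(chrom, cursor + l5 + gap, cursor + l5 + gap + l3, f"g{gi + 1}", "+")
                genes.extend([g5, g3])
                truth_rows.append(
                    {
                        "pair_id": f"planted_{pi}",
                        "chrom": chrom,
                        "gene5": g5.gene_id,
                        "gene3": g3.gene_id,
                        "intergenic_start": g5.end,
                        "intergenic_end": g3.start,
                    }
                )
                gi += 2
                pi += 1
                cursor = g3.end + int(rng.integers(*cfg.locus_gap))
            else:
                length = int(rng.integers(*cfg.gene_length))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(chrom, cursor, cursor + length, f"g{gi}", strand))
                gi += 1
                cursor += length + int(rng.integers(*cfg.locus_gap))
        needed = cursor + 100
        if cfg.chrom_length is not None:
            if needed > cfg.chrom_length:
                raise ValueError(
                    f"infeasible packing: {chrom} needs {needed} bp but "
                    f"chrom_length is {cfg.chrom_length}"
                )
            needed = cfg.chrom_length
        genomes[chrom] = _random_dna(rng, needed)
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "chrom", "gene5", "gene3", "intergenic_start", "intergenic_end"],
    )
    return genomes, sorted(genes), truth


def calibrated_copula_rho(target_r: float, sigma1: float, sigma2: float) -> float:
    """Gaussian-copula correlation giving Pearson ``target_r`` between two
    lognormal margins with the given log-scale sigmas (exact for lognormals)."""
    if target_r == 0:
        return 0.0
    span = np.sqrt(np.expm1(sigma1**2) * np.expm1(sigma2**2))
    rho = np.log1p(target_r * span) / (sigma1 * sigma2)
    if not -1 <= rho <= 1:
        raise ValueError(
            f"target Pearson {target_r} unreachable with sigmas {sigma1}, {sigma2}"
        )
    return float(rho)


def simulate_expression(
    coexpressed_pairs: list[tuple[str, str]],
    null_pairs: list[tuple[str, str]],
    cfg: SimulationConfig,
    kinds: tuple[str, ...] = ("rnaseq", "microarray"),
) -> dict[str, ExpressionMatrix]:
    """Expression matrices with planted pairwise correlation.

    Genes of ``coexpressed_pairs`` draw from a bivariate Gaussian copula
    whose correlation is calibrated so the lognormal-scale Pearson
    correlation equals ``cfg.planted_r``; genes of ``null_pairs`` are
    independent.  Each gene's lognormal location is drawn once and shared
    across source kinds (the same gene is expressed similarly in both
    platforms); microarray values are scaled by ``cfg.microarray_scale``.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.log_sigma
    rho = calibrated_copula_rho(cfg.planted_r, sigma, sigma)
    all_pairs = [(g5, g3, True) for g5, g3 in coexpressed_pairs] + [
        (g5, g3, False) for g5, g3 in null_pairs
    ]
    gene_ids = [g for g5, g3, _ in all_pairs for g in (g5, g3)]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids must be unique across pairs")
    mus = rng.uniform(*cfg.log_mu_range, size=len(gene_ids))

    out: dict[str, ExpressionMatrix] = {}
    for kind in kinds:
        scale = cfg.microarray_scale if kind == "microarray" else 1.0
        rows = {}
        k = 0
        for g5, g3, linked in all_pairs:
            z = rng.standard_normal((2, cfg.n_samples))
            if linked:  # Cholesky of the 2x2 copula correlation
                z[1] = rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]
            rows[g5] = scale * np.exp(mus[k] + sigma * z[0])
            rows[g3] = scale * np.exp(mus[k + 1] + sigma * z[1])
            k += 2
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [f"sample_{j}" for j in range(cfg.n_samples)]
        out[kind] = ExpressionMatrix(source_id=f"sim_{kind}", kind=kind, values=df)
    return out


def plant_motif(
    seqs: list[PromoterSequence],
    pwm: PositionWeightMotif,
    site_prob: float = 0.9,
    seed: int = 0,
) -> tuple[list[PromoterSequence], pd.DataFrame]:
    """Implant one PWM-sampled site per sequence with probability
    ``site_prob`` at a uniform position; truth records planted offsets
    (-1 = no site).  Sequences shorter than the motif are skipped with a
    warning.  Deterministic given the seed."""
    if not 0 <= site_prob <= 1:
        raise ValueError("site_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = pwm.width
    out: list[PromoterSequence] = []
    rows = []
    letters = np.array(list(ALPHABET))
    for s in seqs:
        if len(s.sequence) < w:
            warnings.warn(f"{s.seq_id}: shorter than motif width {w}, skipped",
                          stacklevel=2)
            out.append(s)
            rows.append({"seq_id": s.seq_id, "offset": -1})
            continue
        if rng.random() < site_prob:
            off = int(rng.integers(len(s.sequence) - w + 1))
            site = "".join(
                letters[rng.choice(4, p=pwm.probs[i])] for i in range(w)
            )
            seq = s.sequence[:off] + site + s.sequence[off + w :]
            out.append(replace(s, sequence=seq))
            rows.append({"seq_id": s.seq_id, "offset": off})
        else:
            out.append(s)
            rows.append({"seq_id": s.seq_id, "offset": -1})
    return out, pd.DataFrame(rows, columns=["seq_id", "offset"])


def write_demo_workspace(
    outdir,
    cfg: SimulationConfig = SimulationConfig(),
    n_coexpressed: int | None = None,
) -> dict:
    """Materialize a complete demo workspace on disk: genome FASTA, GFF3
    annotation, RNA-seq and microarray expression TSVs, and the truth table.

    The first ``n_coexpressed`` planted divergent pairs (default: one fifth of
    them) are co-expressed at ``cfg.planted_r``; the rest are expression
    decoys (independent genes).  Returns the file paths and the truth table.
    """
    from pathlib import Path

    from .expression import write_expression_matrix
    from .io import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(cfg)
    if n_coexpressed is None:
        n_coexpressed = max(1, len(truth) // 5)
    truth = truth.assign(coexpressed=[i < n_coexpressed for i in range(len(truth))])
    pair_genes = [(r.gene5, r.gene3) for r in truth.itertuples()]
    co = pair_genes[:n_coexpressed]
    null = pair_genes[n_coexpressed:]
    singles = [
        (g.gene_id,)
        for g in genes
        if g.gene_id not in {x for p in pair_genes for x in p}
    ]
    # unpaired genes enter as independent "pairs" of convenience so every
    # gene has expression; pair them up arbitrarily
    flat = [g for (g,) in singles]
    extra_null = list(zip(flat[0::2], flat[1::2]))
    mats = simulate_expression(co, null + extra_null, cfg)

    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "rnaseq": outdir / "rnaseq.tsv",
        "microarray": outdir / "microarray.tsv",
        "truth": outdir / "truth_pairs.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(genes, paths["annotation"])
    write_expression_matrix(mats["rnaseq"], paths["rnaseq"])
    write_expression_matrix(mats["microarray"], paths["microarray"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {"paths": paths, "truth": truth, "genes": genes}


def random_promoters(
    n: int,
    length: int = 300,
    seed: int = 0,
    base_probs=None,
    origin: str = "background",
) -> list[PromoterSequence]:
    """n i.i.d. random promoter sequences of the given length."""
    rng = np.random.default_rng(seed)
    return [
        PromoterSequence(
            seq_id=f"{origin}_{i}",
            sequence=_random_dna(rng, length, base_probs),
            origin=origin,
            chrom="sim",
            start=0,
            end=length,
        )
    for i in range(n)
    ]
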