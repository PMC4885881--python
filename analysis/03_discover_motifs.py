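#!/usr/bin/env python
"""Shared cis-sequence discovery in candidate promoters.

Emulates the situation of interest — bidirectional promoters sharing two
conserved cis-sequences, one G/C-rich and one A/T-rich — by planting both
motifs into the candidate intergenic promoters extracted in the screening
stage, then running ZOOPS EM discovery (width 8, two motifs with erasure),
scanning candidates and length-matched background promoters at an exact
p-value threshold, and testing per-motif overrepresentation with a
one-sided Fisher exact test on per-sequence presence.
"""

import argparse
from pathlib import Path

from bipscan.io import read_promoters_fasta, write_promoters_fasta
from bipscan.motifs import pwm_from_counts
from bipscan.pipeline import run_motifs
from bipscan.simulate import plant_motif, random_promoters

import numpy as np

ROOT = Path(__file__).resolve().parents[1]

GC_RICH = "GGCGCCGC"
AT_RICH = "AATATTTA"


def consensus_pwm(word, strength=20.0):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(word), 4))
    for i, ch in enumerate(word):
        counts[i, idx[ch]] = strength
    return pwm_from_counts(counts, pseudocount=0.5, motif_id=word)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    screen = ROOT / "scratch" / "screen"
    if not screen.exists():
        raise SystemExit("run 02_screen_candidates.py first")

    # candidate promoters are few in the demo; pad with extra simulated
    # bidirectional promoters so discovery has a realistic foreground size
    fg = read_promoters_fasta(screen / "candidates.fasta", origin="intergenic")
    fg += random_promoters(30 - len(fg), 300, seed=args.seed + 1, origin="intergenic")
    fg, _ = plant_motif(fg, consensus_pwm(GC_RICH), site_prob=0.9, seed=args.seed + 2)
    fg, _ = plant_motif(fg, consensus_pwm(AT_RICH), site_prob=0.9, seed=args.seed + 3)
    motif_dir = ROOT / "scratch" / "motifs"
    motif_dir.mkdir(parents=True, exist_ok=True)
    write_promoters_fasta(fg, motif_dir / "candidates_planted.fasta")
    bg = read_promoters_fasta(screen / "background.fasta", origin="background")
    bg += random_promoters(60 - len(bg), 300, seed=args.seed + 4)
    write_promoters_fasta(bg, motif_dir / "background.fasta")

    report = run_motifs(
        {
            "candidates": str(motif_dir / "candidates_planted.fasta"),
            "background": str(motif_dir / "background.fasta"),
            "outdir": str(motif_dir / "run"),
            "width": 8,
            "n_motifs": 2,
            "p_threshold": 1e-4,
            "seed": args.seed,
        }
    )
    report.to_csv(results / "motif_enrichment.tsv", sep="\t", index=False)
    for row in report.itertuples():
        print(
            f"{row.motif_id}: consensus {row.consensus}, "
            f"fg {row.fg_hits_per_kb:.2f} hits/kb vs bg {row.bg_hits_per_kb:.2f}, "
            f"odds ratio {row.odds_ratio:.1f}, enrichment p = {row.p_value:.2e}"
        )


if __name__ == "__main__":
    main()
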