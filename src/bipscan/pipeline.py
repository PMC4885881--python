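"""End-to-end stage orchestration over files, with a reproducibility manifest.

Each stage reads only files named in its configuration and writes its outputs
plus a JSON manifest (config snapshot, input/output content digests, seed),
so any stage can be rerun standalone from the previous stage's files.  The
numbered scripts under ``analysis/`` are thin drivers over these functions.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import pyfaidx

from . import __version__
from .annotation import (
    extract_intergenic,
    find_divergent_pairs,
    load_gene_models,
    sample_background_promoters,
)
from .conservation import conservation_profile, load_ortholog_map, profiles_to_frame
from .expression import (
    SelectionCriteria,
    candidates_to_frame,
    load_expression_matrix,
    screen_pairs,
)
from .io import (
    read_promoters_fasta,
    write_hits_tsv,
    write_meme_minimal,
    write_pairs_bed,
    write_pairs_tsv,
    write_promoters_fasta,
)
from .motifs import discover_motifs, enrichment_test, scan_sequences

__all__ = ["ConfigurationError", "DataError", "load_config", "run_screen",
           "run_motifs", "run_conservation"]


class ConfigurationError(ValueError):
    """Bad or incomplete configuration (missing files, wrong keys)."""


class DataError(ValueError):
    """Inputs exist but their content is invalid."""


def load_config(path) -> dict:
    """Read a TOML configuration file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _require_files(config: Mapping[str, Any], keys: list[str]) -> None:
    for key in keys:
        if key not in config:
            raise ConfigurationError(f"config key {key!r} is required")
        paths = config[key] if isinstance(config[key], (list, tuple)) else [config[key]]
        for p in paths:
            if not Path(p).exists():
                raise ConfigurationError(f"{key}: file {p} does not exist")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, config: Mapping, inputs: list, outputs: list,
                    seed: int | None = None) -> None:
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": {str(p): _digest(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_screen(config: Mapping[str, Any]) -> pd.DataFrame:
    """Find pairs -> summarize -> screen -> extract, writing a candidate
    report, intergenic BED/TSV/FASTA, and background promoters.

    Required config keys: annotation (GFF3), genome (FASTA), rnaseq (list of
    TSV), microarray (list of TSV), outdir.  Optional: max_gap, criteria
    thresholds, n_background, seed.
    """
    _require_files(config, ["annotation", "genome"])
    for kind in ("rnaseq", "microarray"):
        if kind not in config or not config[kind]:
            raise ConfigurationError(f"at least one {kind} matrix is required")
    _require_files(config, ["rnaseq", "microarray"])
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    genes = load_gene_models(config["annotation"])
    pairs = find_divergent_pairs(genes, max_gap=int(config.get("max_gap", 1000)))
    if not genes:
        warnings.warn("empty annotation: writing an empty report", stacklevel=2)
    matrices = [
        load_expression_matrix(p, source_id=Path(p).stem, kind="rnaseq")
        for p in config["rnaseq"]
    ] + [
        load_expression_matrix(p, source_id=Path(p).stem, kind="microarray")
        for p in config["microarray"]
    ]
    criteria = SelectionCriteria(
        rnaseq_max_threshold=float(config.get("rnaseq_max_threshold", 10.0)),
        microarray_max_threshold=float(config.get("microarray_max_threshold", 5000.0)),
        corr_threshold=float(config.get("corr_threshold", 0.4)),
        corr_method=config.get("corr_method", "pearson"),
        min_corr_samples=int(config.get("min_corr_samples", 37)),
    )
    records = screen_pairs(pairs, matrices, criteria) if pairs else []
    report = candidates_to_frame(records)
    report_path = outdir / "candidates.tsv"
    report.to_csv(report_path, sep="\t", index=False)

    genome = pyfaidx.Fasta(str(config["genome"]))
    selected = [p for p, r in zip(pairs, records) if r.passed]
    promoters = [extract_intergenic(p, genome) for p in selected if p.intergenic_length > 0]
    outputs = [report_path]
    write_pairs_bed(pairs, outdir / "pairs.bed")
    write_pairs_tsv(pairs, outdir / "pairs.tsv")
    write_promoters_fasta(promoters, outdir / "candidates.fasta")
    outputs += [outdir / "pairs.bed", outdir / "pairs.tsv", outdir / "candidates.fasta"]
    n_bg = int(config.get("n_background", 0))
    if n_bg > 0:
        bg = sample_background_promoters(genes, pairs, genome, n=n_bg, seed=seed)
        write_promoters_fasta(bg, outdir / "background.fasta")
        outputs.append(outdir / "background.fasta")
    inputs = [config["annotation"], config["genome"], *config["rnaseq"], *config["microarray"]]
    _write_manifest(outdir, "screen", config, inputs, outputs, seed)
    return report


def run_motifs(config: Mapping[str, Any]) -> pd.DataFrame:
    """Discover motifs in candidate promoters, scan candidates and background
    at the exact-p-value threshold, and test enrichment per motif.

    Required config keys: candidates (FASTA), background (FASTA), outdir.
    Optional: width, n_motifs, p_threshold, n_restarts, seed.
    """
    _require_files(config, ["candidates", "background"])
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    fg = read_promoters_fasta(config["candidates"], origin="intergenic")
    bg = read_promoters_fasta(config["background"], origin="background")
    if len(fg) < 2:
        raise DataError(f"motif discovery needs >= 2 candidate sequences, got {len(fg)}")
    width = int(config.get("width", 8))
    p_threshold = float(config.get("p_threshold", 1e-8))
    motifs = discover_motifs(
        fg,
        width=width,
        n_motifs=int(config.get("n_motifs", 2)),
        n_restarts=int(config.get("n_restarts", 8)),
        seed=seed,
    )
    write_meme_minimal(motifs, outdir / "motifs.meme")
    rows = []
    all_hits = []
    for m in motifs:
        hits_fg = scan_sequences(m, fg, p_threshold=p_threshold)
        hits_bg = scan_sequences(m, bg, p_threshold=p_threshold)
        all_hits += hits_fg + hits_bg
        res = enrichment_test(hits_fg, fg, hits_bg, bg, motif_id=m.motif_id)
        rows.append(
            {
                "motif_id": m.motif_id,
                "consensus": m.consensus,
                "width": m.width,
                "fg_hits_per_kb": res.fg_frequency,
                "bg_hits_per_kb": res.bg_frequency,
                "fg_seqs_with_hit": res.fg_seqs_with_hit,
                "fg_seqs": res.fg_seqs,
                "bg_seqs_with_hit": res.bg_seqs_with_hit,
                "bg_seqs": res.bg_seqs,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    write_hits_tsv(all_hits, outdir / "hits.tsv", width=width)
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    _write_manifest(
        outdir,
        "motifs",
        config,
        [config["candidates"], config["background"]],
        [outdir / "motifs.meme", outdir / "hits.tsv", outdir / "enrichment.tsv"],
        seed,
    )
    return report


def run_conservation(config: Mapping[str, Any]) -> pd.DataFrame:
    """Classify every pair's arrangement in each comparison species.

    Required config keys: pairs (TSV from run_screen), annotation (source
    GFF3), species (mapping species_id -> {annotation, orthologs}), outdir.
    """
    _require_files(config, ["pairs", "annotation"])
    if "species" not in config or not config["species"]:
        raise ConfigurationError("at least one comparison species is required")
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    max_gap = int(config.get("max_gap", 1000))

    genes = load_gene_models(config["annotation"])
    by_id = {g.gene_id: g for g in genes}
    pair_table = pd.read_csv(config["pairs"], sep="\t", dtype=str)
    from .annotation import DivergentPair

    pairs = []
    for _, row in pair_table.iterrows():
        try:
            pairs.append(
                DivergentPair(
                    gene5=by_id[row["gene5"]], gene3=by_id[row["gene3"]],
                    pair_id=row["pair_id"],
                )
            )
        except KeyError as exc:
            raise DataError(f"pair {row['pair_id']}: gene {exc} not in annotation") from exc

    species_inputs = {}
    inputs = [config["pairs"], config["annotation"]]
    for sid, entry in config["species"].items():
        for key in ("annotation", "orthologs"):
            if key not in entry or not Path(entry[key]).exists():
                raise ConfigurationError(f"species {sid}: missing {key} file")
        species_inputs[sid] = (
            load_ortholog_map(entry["orthologs"], species_id=sid),
            load_gene_models(entry["annotation"]),
        )
        inputs += [entry["annotation"], entry["orthologs"]]

    profiles = [conservation_profile(p, species_inputs, max_gap=max_gap) for p in pairs]
    report = profiles_to_frame(profiles)
    report.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    _write_manifest(outdir, "conservation", config, inputs, [outdir / "conservation.tsv"])
    return report
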