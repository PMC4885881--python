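"""Cross-species conservation of bidirectional promoter arrangement.

A divergent pair is regulated by a conserved bidirectional promoter (c-BIP)
in a comparison species when some ortholog of each member still forms a
divergent (head-to-head) pair in that species' annotation; otherwise the
promoter is non-conserved there (n-BIP), with a reason code recording how
the arrangement broke down: orthologs missing, orthologs no longer adjacent,
or adjacent but no longer divergently oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotation import DivergentPair, GeneModel, find_divergent_pairs

__all__ = [
    "OrthologMap",
    "ConservationCall",
    "ConservationProfile",
    "classify_pair_in_species",
    "conservation_profile",
    "load_ortholog_map",
]

C_BIP = "c-BIP"
N_BIP = "n-BIP"

REASONS = (
    "bidirectional_arrangement",
    "ortholog_missing",
    "orthologs_not_adjacent",
    "orthologs_not_divergent",
)


@dataclass
class OrthologMap:
    """Many-to-many orthology between a query species and ``species_id``."""

    species_id: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def add(self, query_gene: str, ortholog_gene: str) -> None:
        if not query_gene or not ortholog_gene:
            raise ValueError("gene ids must be non-empty")
        self.pairs.add((query_gene, ortholog_gene))

    def orthologs_of(self, query_gene: str) -> set[str]:
        return {o for q, o in self.pairs if q == query_gene}


def load_ortholog_map(tsv_path, species_id: str | None = None) -> OrthologMap:
    """Read an ortholog TSV with columns species_id, query_gene, ortholog_gene
    (filtered to ``species_id`` when given)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"species_id", "query_gene", "ortholog_gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"{tsv_path}: expected columns {sorted(required)}")
    if species_id is not None:
        df = df[df["species_id"] == species_id]
        sid = species_id
    else:
        species = df["species_id"].unique()
        if len(species) != 1:
            raise ValueError(
                f"{tsv_path} holds several species {list(species)}; pass species_id"
            )
        sid = species[0]
    omap = OrthologMap(species_id=sid)
    for _, row in df.iterrows():
        omap.add(row["query_gene"], row["ortholog_gene"])
    return omap


@dataclass(frozen=True)
class ConservationCall:
    pair_id: str
    species_id: str
    call: str  # c-BIP | n-BIP
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.call == C_BIP) != (self.reason == "bidirectional_arrangement"):
            raise ValueError("call is c-BIP iff reason is bidirectional_arrangement")


def _adjacent(a: GeneModel, b: GeneModel, genes: Sequence[GeneModel], max_gap: int) -> bool:
    """Strand-blind adjacency: same chrom, gap <= max_gap, nothing intruding
    into the interval between the two gene bodies."""
    if a.chrom != b.chrom:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = right.start - left.end
    if gap < 0 or gap > max_gap:
        return False
    gs, ge = left.end, right.start
    for c in genes:
        if c.gene_id in (a.gene_id, b.gene_id) or c.chrom != a.chrom:
            continue
        if c.start < ge and c.end > gs:
            return False
    return True


def classify_pair_in_species(
    pair: DivergentPair,
    orthologs: OrthologMap,
    species_genes: Sequence[GeneModel],
    max_gap: int = 1000,
) -> ConservationCall:
    """Classify one pair in one comparison species.

    c-BIP iff ANY ortholog of the 5' gene and ANY ortholog of the 3' gene
    form a divergent pair (either member may take either role — a whole-locus
    inversion preserves head-to-head geometry).  Otherwise n-BIP with the
    most specific reason, evaluated missing -> not adjacent -> not divergent.
    """
    orths5 = orthologs.orthologs_of(pair.gene5.gene_id)
    orths3 = orthologs.orthologs_of(pair.gene3.gene_id)
    if not orths5 or not orths3:
        return ConservationCall(pair.pair_id, orthologs.species_id, N_BIP, "ortholog_missing")
    by_id = {g.gene_id: g for g in species_genes}
    present5 = [by_id[g] for g in orths5 if g in by_id]
    present3 = [by_id[g] for g in orths3 if g in by_id]
    if not present5 or not present3:
        return ConservationCall(pair.pair_id, orthologs.species_id, N_BIP, "ortholog_missing")

    divergent = find_divergent_pairs(species_genes, max_gap=max_gap)
    target_ids = {(p.gene5.gene_id, p.gene3.gene_id) for p in divergent}
    ids5 = {g.gene_id for g in present5}
    ids3 = {g.gene_id for g in present3}
    for g5_id, g3_id in target_ids:
        if (g5_id in ids5 and g3_id in ids3) or (g5_id in ids3 and g3_id in ids5):
            return ConservationCall(
                pair.pair_id, orthologs.species_id, C_BIP, "bidirectional_arrangement"
            )
    any_adjacent = any(
        _adjacent(a, b, species_genes, max_gap) for a in present5 for b in present3
    )
    reason = "orthologs_not_divergent" if any_adjacent else "orthologs_not_adjacent"
    return ConservationCall(pair.pair_id, orthologs.species_id, N_BIP, reason)


@dataclass(frozen=True)
class ConservationProfile:
    pair_id: str
    calls: tuple[ConservationCall, ...]

    @property
    def n_conserved(self) -> int:
        return sum(1 for c in self.calls if c.call == C_BIP)

    def call_for(self, species_id: str) -> ConservationCall:
        for c in self.calls:
            if c.species_id == species_id:
                return c
        raise KeyError(species_id)


def conservation_profile(
    pair: DivergentPair,
    species_inputs: dict[str, tuple[OrthologMap, Sequence[GeneModel]]],
    max_gap: int = 1000,
) -> ConservationProfile:
    """Per-species calls for one pair; the source species (identity orthologs
    onto its own annotation) is c-BIP by construction and contributes to the
    conserved-species count."""
    if not species_inputs:
        raise ValueError("at least one species must be supplied")
    calls = [
        classify_pair_in_species(pair, omap, genes, max_gap=max_gap)
        for omap, genes in species_inputs.values()
    ]
    return ConservationProfile(pair_id=pair.pair_id, calls=tuple(calls))


def profiles_to_frame(profiles: Sequence[ConservationProfile]) -> pd.DataFrame:
    """Report table: rows = pairs, columns = species (call and reason),
    plus the conserved-species count."""
    rows = []
    for prof in profiles:
        row: dict[str, object] = {"pair_id": prof.pair_id}
        for call in prof.calls:
            row[call.species_id] = call.call
            row[f"{call.species_id}_reason"] = call.reason
        row["n_conserved"] = prof.n_conserved
        rows.append(row)
    return pd.DataFrame(rows)
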