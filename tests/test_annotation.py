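"""Gene-model parsing, divergent-pair detection, and promoter extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bipscan.annotation import (
    GFF3ParseError,
    GeneModel,
    extract_intergenic,
    find_divergent_pairs,
    load_gene_models,
    sample_background_promoters,
)
from bipscan.fixtures import table1_gff3_text

from conftest import brute_force_divergent_pairs, make_gene, make_pair, random_annotation


class TestLoadGeneModels:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("")
        assert load_gene_models(path) == []

    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "one.gff3"
        path.write_text("chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (gene,) = load_gene_models(path)
        assert (gene.gene_id, gene.chrom, gene.start, gene.end, gene.strand) == (
            "g1", "chr1", 100, 200, "+",
        )

    def test_selected_pairs_fixture_loads_eight_genes(self, tmp_path):
        path = tmp_path / "pairs.gff3"
        path.write_text(table1_gff3_text())
        genes = load_gene_models(path)
        assert len(genes) == 8
        ids = {g.gene_id for g in genes}
        assert "LOC_Os02g42314" in ids and "LOC_Os03g22890" in ids
        strands = {g.gene_id: g.strand for g in genes}
        assert strands["LOC_Os02g42314"] == "-"
        assert strands["LOC_Os02g42320"] == "+"

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\nnot-a-gff-line\n")
        with pytest.raises(GFF3ParseError, match="line 2"):
            load_gene_models(path)

    def test_missing_strand_rejected_with_warning(self, tmp_path):
        path = tmp_path / "nostrand.gff3"
        path.write_text("chr1\t.\tgene\t101\t200\t.\t.\t.\tID=g1\n")
        with pytest.warns(UserWarning, match="strand"):
            assert load_gene_models(path) == []

    def test_non_gene_features_ignored(self, tmp_path):
        path = tmp_path / "mixed.gff3"
        path.write_text(
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\t.\texon\t101\t150\t.\t+\t.\tParent=t1\n"
        )
        assert len(load_gene_models(path)) == 1


class TestFindDivergentPairs:
    def test_minimal_positive_case(self):
        genes = [make_gene("g1", 0, 100, "-"), make_gene("g2", 300, 400, "+")]
        (pair,) = find_divergent_pairs(genes, max_gap=1000)
        assert (pair.intergenic_start, pair.intergenic_end) == (100, 300)
        assert pair.gene5.gene_id == "g1" and pair.gene3.gene_id == "g2"

    def test_convergent_pair_excluded(self):
        genes = [make_gene("g1", 0, 100, "+"), make_gene("g2", 300, 400, "-")]
        assert find_divergent_pairs(genes, max_gap=1000) == []

    def test_tandem_pair_excluded(self):
        genes = [make_gene("g1", 0, 100, "+"), make_gene("g2", 300, 400, "+")]
        assert find_divergent_pairs(genes, max_gap=1000) == []

    def test_gap_threshold(self):
        genes = [make_gene("g1", 0, 100, "-"), make_gene("g2", 1200, 1400, "+")]
        assert find_divergent_pairs(genes, max_gap=1000) == []
        assert len(find_divergent_pairs(genes, max_gap=1100)) == 1

    def test_intervening_gene_blocks_pair(self):
        genes = [
            make_gene("g1", 0, 100, "-"),
            make_gene("mid", 150, 250, "+"),
            make_gene("g2", 300, 400, "+"),
        ]
        pairs = {(p.gene5.gene_id, p.gene3.gene_id) for p in find_divergent_pairs(genes, max_gap=1000)}
        # g1+mid form a legitimate divergent pair, but mid blocks g1+g2
        assert ("g1", "g2") not in pairs
        assert pairs == {("g1", "mid")}

    def test_overlapping_genes_excluded_by_default(self):
        genes = [make_gene("g1", 0, 200, "-"), make_gene("g2", 150, 400, "+")]
        assert find_divergent_pairs(genes, max_gap=1000) == []
        pairs = find_divergent_pairs(genes, max_gap=1000, allow_overlap=True)
        assert len(pairs) == 1 and pairs[0].intergenic_length == 0

    def test_duplicate_gene_id_rejected(self):
        genes = [make_gene("g1", 0, 100, "-"), make_gene("g1", 300, 400, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            find_divergent_pairs(genes)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = random_annotation(rng, 200)
        pairs = find_divergent_pairs(genes, max_gap=1000)
        got = {(p.gene5.gene_id, p.gene3.gene_id) for p in pairs}
        assert got == brute_force_divergent_pairs(genes, max_gap=1000)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mirror_symmetry(self, seed):
        """Mirroring coordinates and flipping strands maps divergent pairs to
        divergent pairs (same count)."""
        rng = np.random.default_rng(seed)
        genes = random_annotation(rng, 60, n_chroms=1, span=20_000)
        span = max(g.end for g in genes) + 10
        flip = {"+": "-", "-": "+"}
        mirrored = [
            GeneModel(g.chrom, span - g.end, span - g.start, g.gene_id, flip[g.strand])
            for g in genes
        ]
        assert len(find_divergent_pairs(genes)) == len(find_divergent_pairs(mirrored))

    def test_intergenic_disjoint_from_gene_bodies(self, rng):
        genes = random_annotation(rng, 300)
        for p in find_divergent_pairs(genes, max_gap=1000):
            for g in genes:
                if g.gene_id in (p.gene5.gene_id, p.gene3.gene_id) or g.chrom != p.chrom:
                    continue
                assert not (g.start < p.intergenic_end and g.end > p.intergenic_start)


class TestExtractIntergenic:
    def test_length_matches_interval(self):
        genome = {"chr1": "A" * 1000}
        pair = make_pair(0, g5=(0, 100), g3=(300, 400))
        seq = extract_intergenic(pair, genome)
        assert len(seq.sequence) == 200 == pair.intergenic_length

    def test_zero_length_intergenic_warns(self):
        genome = {"chr1": "A" * 1000}
        pair = make_pair(0, g5=(0, 300), g3=(300, 400))
        with pytest.warns(UserWarning, match="zero-length"):
            seq = extract_intergenic(pair, genome)
        assert seq.sequence == ""

    def test_matches_direct_slice(self, rng):
        letters = np.array(list("ACGT"))
        chrom_seq = "".join(letters[rng.integers(0, 4, 2000)])
        genome = {"chr1": chrom_seq}
        pair = make_pair(0, g5=(50, 400), g3=(700, 900))
        assert extract_intergenic(pair, genome).sequence == chrom_seq[400:700]

    def test_out_of_range_errors(self):
        pair = make_pair(0, g5=(0, 100), g3=(300, 400))
        with pytest.raises(IndexError):
            extract_intergenic(pair, {"chr1": "ACGT" * 50})
        with pytest.raises(KeyError):
            extract_intergenic(pair, {"chr9": "A" * 1000})


class TestBackgroundPromoters:
    @staticmethod
    def _setting(rng):
        genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60_000)])}
        genes, pairs = [], []
        pos = 1000
        for i in range(6):
            g5 = make_gene(f"d{i}_5", pos, pos + 500, "-")
            g3 = make_gene(f"d{i}_3", pos + 800, pos + 1300, "+")
            genes += [g5, g3]
            pairs.append(make_pair(i, g5=(pos, pos + 500), g3=(pos + 800, pos + 1300)))
            pos += 3000
        for i in range(20):
            genes.append(make_gene(f"s{i}", pos, pos + 600, "+" if i % 2 else "-"))
            pos += 1800
        return genome, genes, pairs

    def test_seed_determinism(self, rng):
        genome, genes, pairs = self._setting(rng)
        a = sample_background_promoters(genes, pairs, genome, n=5, seed=7)
        b = sample_background_promoters(genes, pairs, genome, n=5, seed=7)
        assert [(s.seq_id, s.sequence) for s in a] == [(s.seq_id, s.sequence) for s in b]

    def test_no_eligible_genes_errors(self, rng):
        genome, genes, pairs = self._setting(rng)
        members = [g for g in genes if g.gene_id.startswith("d")]
        with pytest.raises(ValueError, match="eligible"):
            sample_background_promoters(members, pairs, genome, n=3, seed=0)

    def test_no_overlap_with_divergent_intergenic(self, rng):
        genome, genes, pairs = self._setting(rng)
        out = sample_background_promoters(genes, pairs, genome, n=100, seed=1)
        assert len(out) == 100
        for s in out:
            for p in pairs:
                if p.chrom == s.chrom:
                    assert not (s.start < p.intergenic_end and s.end > p.intergenic_start)

    def test_lengths_resampled_from_intergenic(self, rng):
        genome, genes, pairs = self._setting(rng)
        observed = {p.intergenic_length for p in pairs}
        out = sample_background_promoters(genes, pairs, genome, n=30, seed=3)
        assert {len(s.sequence) for s in out} <= observed
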