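"""Per-gene summary columns: sizes, spacers, start/stop classification.

The published annotations of the two reference genomes serve as
desk-scale inputs: every size and spacer derived from their printed
coordinates must match the printed columns (where the printed table is
itself consistent with its coordinates).
"""

import pytest

from mitochar import (FeatureRecord, build_summary_table, classify_start_codon,
                      classify_stop_codon, feature_length, intergenic_spacer)
from mitochar import reference_data as ref
from mitochar.annotation_summary import write_summary_tsv


class TestFeatureLength:
    @pytest.mark.parametrize("start,end,expected", [
        (1463, 2990, 1528),   # cox1
        (6355, 8076, 1722),   # nad5, minority strand
        (1, 1, 1),
    ])
    def test_non_wrapping(self, start, end, expected):
        f = FeatureRecord("x", "other", "F", start, end)
        assert feature_length(f, 15282) == expected

    def test_wrapping_counts_through_origin(self):
        f = FeatureRecord("x", "other", "F", 15280, 5)
        assert feature_length(f, 15282) == 8

    def test_published_sizes_all_match_coordinates(self):
        """Every printed size column equals end - start + 1."""
        for rows, n in [(ref.A_RUBIGINOSA_FEATURES, ref.A_RUBIGINOSA_LENGTH),
                        (ref.R_MENCIANA_FEATURES, ref.R_MENCIANA_LENGTH)]:
            for name, klass, strand, start, end, *_ in rows:
                f = FeatureRecord(name, klass, strand, start, end)
                assert feature_length(f, n) == end - start + 1


class TestIntergenicSpacer:
    def test_spacer_between_separated_genes(self):
        prev = FeatureRecord("trnQ", "tRNA", "R", 130, 198, "TTG")
        nxt = FeatureRecord("nad2", "PCG", "F", 255, 1266)
        assert intergenic_spacer(prev, nxt, 15282) == 56

    def test_overlap_is_negative(self):
        prev = FeatureRecord("atp8", "PCG", "F", 3882, 4043)
        nxt = FeatureRecord("atp6", "PCG", "F", 4037, 4714)
        assert intergenic_spacer(prev, nxt, 15282) == -7

    def test_abutting_genes_give_zero(self):
        prev = FeatureRecord("a", "other", "F", 1, 10)
        nxt = FeatureRecord("b", "other", "F", 11, 20)
        assert intergenic_spacer(prev, nxt, 100) == 0

    def test_circular_closure(self):
        prev = FeatureRecord("ctrl", "control", "F", 14884, 15282)
        nxt = FeatureRecord("trnM", "tRNA", "F", 1, 68, "CAT")
        assert intergenic_spacer(prev, nxt, 15282) == 0

    def test_identical_feature_rejected(self):
        f = FeatureRecord("a", "other", "F", 1, 10)
        with pytest.raises(ValueError):
            intergenic_spacer(f, f, 100)


class TestStartCodon:
    @pytest.mark.parametrize("cds,codon,canonical", [
        ("CGAGCTAAA", "CGA", True),    # conserved cox1 initiator
        ("ATGAAA", "ATG", True),
        ("ATTAAA", "ATT", True),
        ("GTGAAA", "GTG", False),
    ])
    def test_classification(self, cds, codon, canonical):
        assert classify_start_codon(cds) == (codon, canonical)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            classify_start_codon("AT")


class TestStopCodon:
    @pytest.mark.parametrize("cds,expected,flagged", [
        ("ATGAAATAA", "TAA", False),
        ("ATGAAATAG", "TAG", False),
        ("ATG" + "AAA" * 226 + "T", "T", False),       # 682 nt: incomplete T
        ("ATT" + "AAA" * 578 + "TA", "TA", False),     # 1739 nt: incomplete TA
        ("ATGAAAA", "A", False),                       # incomplete A
        ("ATGAAAAGG", "OTHER", True),                  # no recognizable stop
        ("ATGAAAAG", "OTHER", True),                   # len%3==2 but not TA
    ])
    def test_classification(self, cds, expected, flagged):
        assert classify_stop_codon(cds) == (expected, flagged)

    def test_cox2_geometry(self):
        # a 682-nt CDS (cox2 coordinates 3059-3740) ends on a lone T
        assert (3740 - 3059 + 1) % 3 == 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            classify_stop_codon("TAA")


class TestBuildSummaryTable:
    @pytest.mark.parametrize("species", ["A_rubiginosa", "R_menciana"])
    def test_published_sizes_row_for_row(self, species):
        genome = ref.reference_genome(species)
        rows = build_summary_table(genome)
        printed = {"A_rubiginosa": ref.A_RUBIGINOSA_FEATURES,
                   "R_menciana": ref.R_MENCIANA_FEATURES}[species]
        assert len(rows) == 38
        by_gene = {r.gene: r for r in rows}
        for name, _klass, strand, start, end, *_ in printed:
            r = by_gene[name]
            assert (r.direction, r.start, r.end) == (strand, start, end)
            assert r.size_nt == end - start + 1

    def test_published_intergenic_values(self, ar_genome):
        """Spacer column recomputed from the printed coordinates."""
        rows = {r.gene: r for r in build_summary_table(ar_genome)}
        expected = {"trnM": 0, "trnI": -3, "trnQ": 56, "nad2": 0, "trnW": -8,
                    "trnY": 6, "cox1": 0, "trnK": 2, "atp8": -7, "cox3": 2,
                    "trnS1": 9, "trnE": -2, "trnF": 27, "nad5": 15,
                    "nad4L": 4, "trnT": -1, "cob": -1, "trnS2": 21,
                    "AT_rich_region": 0}
        for gene, gap in expected.items():
            assert rows[gene].intergenic_nt == gap, gene

    @pytest.mark.parametrize("species,length", [
        ("A_rubiginosa", 15282), ("R_menciana", 15636)])
    def test_sizes_plus_spacers_close_the_circle(self, species, length):
        rows = build_summary_table(ref.reference_genome(species))
        assert sum(r.size_nt + r.intergenic_nt for r in rows) == length

    def test_synthetic_circle_closure(self, synthetic_pair):
        genome, _ = synthetic_pair
        rows = build_summary_table(genome)
        assert sum(r.size_nt + r.intergenic_nt for r in rows) == len(genome)

    def test_single_feature_genome_spacer_closes_circle(self):
        from mitochar import AnnotatedGenome
        g = AnnotatedGenome("one", "ACGT" * 25,
                            [FeatureRecord("a", "other", "F", 11, 20)])
        rows = build_summary_table(g)
        assert len(rows) == 1
        assert rows[0].size_nt + rows[0].intergenic_nt == 100

    def test_codon_columns_match_planted_truth(self, synthetic_pair):
        genome, truth = synthetic_pair
        rows = {r.gene: r for r in build_summary_table(genome)}
        for gene, codon in truth.start_codons.items():
            assert rows[gene].start_codon == codon
            assert rows[gene].start_canonical
        for gene, codon in truth.stop_codons.items():
            assert rows[gene].stop_codon == codon
            assert rows[gene].stop_flag is False

    def test_non_wrapping_row_geometry(self, rm_genome):
        for r in build_summary_table(rm_genome):
            if r.end >= r.start:
                assert r.size_nt + r.start - 1 == r.end


def test_summary_tsv_has_printed_shape(ar_genome):
    tsv = write_summary_tsv(build_summary_table(ar_genome))
    lines = tsv.strip().splitlines()
    assert lines[0].split("\t") == ["gene", "direction", "location", "size",
                                    "anticodon", "start_codon", "stop_codon",
                                    "intergenic_nt"]
    assert len(lines) == 39
    assert lines[1].startswith("trnM\tF\t1-68\t68\tCAT")
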