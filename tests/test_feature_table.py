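"""Coordinate arithmetic on mitogenome feature maps."""

import pytest

from mitocomp import (
    GeneFeature,
    MitogenomeAnnotation,
    adjacency_profile,
    extract_gene_sequence,
    genome_length,
    igs_summary,
    load_feature_tsv,
    load_fixture,
    locate_OL,
    overlap_summary,
    pcg_length_stats,
    strand_census,
    write_feature_tsv,
)
from mitocomp.feature_table import AnnotationError, normalize_gene_name


def toy(features, length=None, circular=True, sequence=None, label="toy"):
    return MitogenomeAnnotation(
        label=label, length=length, features=features,
        circular=circular, sequence=sequence,
    )


def rr(name, start, end, strand="H"):
    return GeneFeature(name, "rRNA", strand, start, end)


class TestFixtures:
    @pytest.mark.parametrize(
        "key, length, igs, overlap",
        [
            ("GF", 16673, (13, 87), (5, 23)),
            ("GE", 16728, (16, 157), (2, 14)),
            ("GD", 16871, (12, 167), (4, 22)),
        ],
    )
    def test_published_census(self, key, length, igs, overlap):
        ann = load_fixture(key)
        assert genome_length(ann) == length
        assert igs_summary(ann) == igs
        assert overlap_summary(ann) == overlap

    @pytest.mark.parametrize("key, ol", [("GF", 35), ("GE", 37), ("GD", 36)])
    def test_light_strand_origin_spacer(self, key, ol):
        result = locate_OL(load_fixture(key))
        assert result.spacing == ol and result.is_spacer

    def test_atp8_atp6_overlap(self, gf):
        rec = next(r for r in adjacency_profile(gf) if r.upstream == "ATP8")
        assert rec.downstream == "ATP6" and rec.spacing == -10

    def test_longest_spacer_is_ile_gln_in_gd(self, gd):
        best = max(adjacency_profile(gd), key=lambda r: r.spacing)
        assert (best.upstream, best.downstream, best.spacing) == (
            "tRNA-Ile", "tRNA-Gln", 40,
        )

    def test_gd_trna_ile_size(self, gd):
        assert gd.feature("tRNA-Ile").size == 71

    def test_nd6_is_light_strand(self, gf):
        nd6 = gf.feature("ND6")
        assert (nd6.strand, nd6.start, nd6.end) == ("L", 13847, 14368)

    def test_strand_census(self, gf):
        census = strand_census(gf)
        assert census.per_strand("L") == 9
        assert census.counts[("L", "PCG")] == 1
        assert census.counts[("L", "tRNA")] == 8
        assert [census.per_category(c) for c in ("PCG", "tRNA", "rRNA", "control")] \
            == [13, 22, 2, 1]

    @pytest.mark.parametrize(
        "key, total, percent",
        [("GF", 11430, 68.55), ("GE", 11427, 68.31), ("GD", 11429, 67.74)],
    )
    def test_pcg_length_stats(self, key, total, percent):
        assert pcg_length_stats(load_fixture(key)) == (total, percent)

    @pytest.mark.parametrize("key", ["GF", "GE", "GD"])
    def test_tiling_identity(self, key):
        """Sizes + gaps − overlaps reconstruct the molecule length exactly."""
        ann = load_fixture(key)
        sizes = sum(f.size for f in ann.features)
        _, gaps = igs_summary(ann)
        _, overlaps = overlap_summary(ann)
        assert sizes + gaps - overlaps == genome_length(ann)

    @pytest.mark.parametrize("key", ["GF", "GE", "GD"])
    def test_nonzero_spacings_partition(self, key):
        ann = load_fixture(key)
        nonzero = sum(1 for r in adjacency_profile(ann) if r.spacing != 0)
        assert igs_summary(ann)[0] + overlap_summary(ann)[0] == nonzero

    def test_roundtrip_tsv(self, gf, tmp_path):
        path = tmp_path / "gf.tsv"
        write_feature_tsv(gf, path)
        back = load_feature_tsv(path)
        assert back.label == gf.label and back.length == gf.length
        assert back.features == gf.features


class TestAdjacency:
    def test_abutting_features_have_zero_spacing(self):
        ann = toy([rr("a", 1, 10), rr("b", 11, 20)], length=20, circular=False)
        assert adjacency_profile(ann) == adjacency_profile(ann)
        assert adjacency_profile(ann)[0].spacing == 0

    def test_circular_origin_pair_included(self):
        ann = toy([rr("a", 3, 10), rr("b", 12, 18)], length=20)
        recs = adjacency_profile(ann)
        assert len(recs) == 2
        assert recs[-1].spacing == (20 - 18) + (3 - 1)  # wrap gap

    def test_perfectly_tiled_toy(self):
        ann = toy([rr("a", 1, 10), rr("b", 11, 20)], length=20)
        assert igs_summary(ann) == (0, 0)
        assert overlap_summary(ann) == (0, 0)

    def test_single_overlap_magnitude(self):
        ann = toy([rr("a", 1, 10), rr("b", 4, 20)], length=20, circular=False)
        assert overlap_summary(ann) == (1, 7)

    def test_nested_feature_excluded_with_warning(self):
        ann = toy([rr("a", 1, 100), rr("b", 10, 20), rr("c", 101, 120)],
                  length=120, circular=False)
        with pytest.warns(UserWarning, match="nested"):
            recs = adjacency_profile(ann)
        assert [(r.upstream, r.downstream) for r in recs] == [("a", "c")]

    def test_missing_trna_errors(self):
        ann = toy([GeneFeature("tRNA-Asn", "tRNA", "L", 1, 70)], length=70)
        with pytest.raises(AnnotationError, match="tRNA-Cys"):
            locate_OL(ann)


class TestLoaders:
    def test_length_falls_back_to_max_end(self):
        assert genome_length(toy([rr("a", 1, 100)])) == 100

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#label=x length=100 circular=1\nA\trRNA\tH\t50\t10\n")
        with pytest.raises(AnnotationError, match="start"):
            load_feature_tsv(path)

    def test_empty_feature_list_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("#label=x length=100 circular=1\n")
        with pytest.raises(AnnotationError, match="no features"):
            load_feature_tsv(path)

    def test_duplicate_names_rejected_except_leu_ser(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#label=x length=300 circular=1\n"
            "ND1\tPCG\tH\t1\t99\n"
            "ND1\tPCG\tH\t100\t199\n"
        )
        with pytest.raises(AnnotationError, match="duplicate"):
            load_feature_tsv(path)
        ok = tmp_path / "leu.tsv"
        ok.write_text(
            "#label=x length=300 circular=1\n"
            "tRNA-Leu\ttRNA\tH\t1\t70\tTAA\n"
            "tRNA-Leu\ttRNA\tH\t100\t170\tTAG\n"
        )
        assert len(load_feature_tsv(ok).features) == 2

    @pytest.mark.parametrize(
        "raw, canonical",
        [("COI", "COXI"), ("cox1", "COXI"), ("cob", "CYTB"), ("NAD4L", "ND4L"),
         ("trna-phe", "tRNA-Phe"), ("control region", "D-loop")],
    )
    def test_name_normalization(self, raw, canonical):
        assert normalize_gene_name(raw) == canonical


MINIMAL_GENBANK = """\
LOCUS       toy                       60 bp    DNA     circular VRT 01-JAN-2020
DEFINITION  toy record.
ACCESSION   toy
VERSION     toy
KEYWORDS    .
SOURCE      .
  ORGANISM  .
FEATURES             Location/Qualifiers
     CDS             1..30
                     /gene="ND1"
     rRNA            complement(31..60)
                     /gene="12S rRNA"
ORIGIN
        1 atgaaaccca tgaaacccat gaaacccatg aaacccatga aacccatgaa acccatgaaa
//
"""


class TestGenbankLoader:
    def test_minimal_two_gene_record(self, tmp_path):
        from mitocomp import load_genbank

        path = tmp_path / "toy.gb"
        path.write_text(MINIMAL_GENBANK)
        ann = load_genbank(path)
        assert [f.name for f in ann.features] == ["ND1", "12S-rRNA"]
        assert [f.strand for f in ann.features] == ["H", "L"]
        assert (ann.features[1].start, ann.features[1].end) == (31, 60)
        assert ann.length == 60 and ann.sequence.startswith("ATGAAA")
        assert ann.circular

    def test_malformed_record_rejected(self, tmp_path):
        from mitocomp import load_genbank

        path = tmp_path / "bad.gb"
        path.write_text("not a genbank record\n")
        with pytest.raises(AnnotationError):
            load_genbank(path)


class TestExtraction:
    SEQ = "ATGCCCTAA"

    def test_h_strand_identity(self):
        ann = toy([GeneFeature("g", "rRNA", "H", 1, 9)], length=9,
                  sequence=self.SEQ, circular=False)
        assert extract_gene_sequence(ann, "g") == "ATGCCCTAA"

    def test_l_strand_reverse_complement(self):
        ann = toy([GeneFeature("g", "rRNA", "L", 1, 9)], length=9,
                  sequence=self.SEQ, circular=False)
        assert extract_gene_sequence(ann, "g") == "TTAGGGCAT"

    def test_origin_wrap(self):
        ann = toy([GeneFeature("g", "rRNA", "H", 8, 3)], length=9,
                  sequence=self.SEQ)
        assert extract_gene_sequence(ann, "g") == "AAATG"

    def test_requires_sequence(self, gf):
        with pytest.raises(AnnotationError, match="sequence"):
            extract_gene_sequence(gf, "ND1")

    def test_planted_sequence_recovered(self, synthetic_genome):
        annotation, truth = synthetic_genome
        for gene in ("ND1", "COXI", "CYTB", "ND6"):
            assert extract_gene_sequence(annotation, gene) \
                == truth.gene_sequences[gene]
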