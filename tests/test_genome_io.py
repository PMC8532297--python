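"""Record parsing, gene-name canonicalization and alignment I/O."""

import io

import numpy as np
import pytest

from mitocomp.genome_io import (AlignmentBlock, GeneFeature, MitoRecord,
                                MitoParseError, MitoValidationError,
                                Taxonomy, canonicalize_gene_name,
                                extract_gene, load_taxonomy, parse_genbank,
                                read_aligned_fasta, reverse_complement,
                                write_fasta, write_genbank)


@pytest.mark.parametrize("raw, expected", [
    ("COI", "cox1"),
    ("cox1", "cox1"),
    ("ND4L", "nad4l"),
    ("ND2", "nad2"),
    ("CYTB", "cob"),
    ("16S", "rrnL"),
    ("l-rRNA", "rrnL"),
    ("12S rRNA", "rrnS"),
    ("tRNA-Leu(UUR)", "trnL2"),
    ("tRNA-Leu(CUN)", "trnL1"),
    ("tRNA-Ser(AGN)", "trnS1"),
    ("tRNA-Ser(UCN)", "trnS2"),
    ("tRNA-Trp", "trnW"),
    ("trnM", "trnM"),
    ("trnL2", "trnL2"),
    ("hypothetical", "unknown"),
    ("", "unknown"),
])
def test_canonicalize_gene_name(raw, expected):
    assert canonicalize_gene_name(raw) == expected


def test_canonicalize_untagged_leucine_is_ambiguous():
    # no anticodon, no degeneracy tag: placeholder that validation rejects
    assert canonicalize_gene_name("tRNA-Leu") == "trnL"


def _toy_record(features, length=120, circular=True):
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return MitoRecord(sample_id="toy", sequence=seq, circular=circular,
                      complete=False, features=features)


class TestParseGenbank:
    def test_roundtrip_single_cds(self, tmp_path):
        rec = _toy_record([GeneFeature("cox1", "PCG", 1, 90, "+")])
        path = tmp_path / "toy.gb"
        write_genbank(rec, path)
        parsed = parse_genbank(path.read_text())
        assert parsed.sequence == rec.sequence
        assert len(parsed.features) == 1
        feat = parsed.features[0]
        assert (feat.name, feat.type, feat.start, feat.end, feat.strand) == \
            ("cox1", "PCG", 1, 90, "+")

    def test_parse_is_fixed_point(self, tmp_path, study_sim):
        rec = study_sim.records[0]
        p1 = tmp_path / "a.gb"
        p2 = tmp_path / "b.gb"
        write_genbank(rec, p1)
        once = parse_genbank(p1.read_text())
        write_genbank(once, p2)
        twice = parse_genbank(p2.read_text())
        assert once.sequence == twice.sequence
        assert once.features == twice.features

    def test_duplicate_untagged_trnl_rejected(self, tmp_path):
        rec = _toy_record([GeneFeature("trnL1", "tRNA", 1, 66, "+"),
                           GeneFeature("trnL2", "tRNA", 70, 120, "+")])
        path = tmp_path / "dup.gb"
        write_genbank(rec, path)
        text = path.read_text().replace("trnL1", "trnL").replace(
            "trnL2", "trnL")
        with pytest.raises(MitoValidationError):
            parse_genbank(text)

    def test_malformed_input_raises_parse_error(self):
        with pytest.raises(MitoParseError):
            parse_genbank("not a genbank record")


class TestMitoRecordInvariants:
    def test_feature_outside_sequence(self):
        with pytest.raises(MitoValidationError, match="outside"):
            _toy_record([GeneFeature("cox1", "PCG", 1, 500, "+")])

    def test_wrap_requires_circular(self):
        with pytest.raises(MitoValidationError, match="circular"):
            _toy_record([GeneFeature("cox1", "PCG", 100, 10, "+")],
                        circular=False)

    def test_complete_length_bounds(self):
        with pytest.raises(MitoValidationError, match="sanity range"):
            MitoRecord(sample_id="x", sequence="ACGT" * 100, circular=True,
                       complete=True, features=[])

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(MitoValidationError, match="disallowed"):
            MitoRecord(sample_id="x", sequence="ACGTRY", circular=False,
                       complete=False, features=[])

    def test_duplicate_gene_rejected(self):
        with pytest.raises(MitoValidationError, match="duplicate"):
            _toy_record([GeneFeature("cox1", "PCG", 1, 30, "+"),
                         GeneFeature("cox1", "PCG", 40, 70, "+")])


class TestExtractGene:
    def test_plus_strand_slice(self):
        rec = MitoRecord("x", "ATGAAACCC", False, False,
                         [GeneFeature("trnA", "tRNA", 1, 6, "+")])
        assert extract_gene(rec, "trnA") == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        rec = MitoRecord("x", "ATGAAACCC", False, False,
                         [GeneFeature("trnA", "tRNA", 1, 6, "-")])
        assert extract_gene(rec, "trnA") == "TTTCAT"

    def test_circular_wrap(self):
        # length 10, feature 9..2 -> bases 9,10,1,2
        seq = "ACGTACGTAC"
        rec = MitoRecord("x", seq, True, False,
                         [GeneFeature("trnA", "tRNA", 9, 2, "+")])
        assert extract_gene(rec, "trnA") == seq[8:] + seq[:2]

    def test_missing_gene_raises(self):
        rec = MitoRecord("x", "ACGT", False, False, [])
        with pytest.raises(KeyError):
            extract_gene(rec, "cox1")

    def test_length_and_involution(self):
        rec = MitoRecord("x", "ACGTACGTACGT", False, False,
                         [GeneFeature("trnA", "tRNA", 3, 9, "+")])
        seq = extract_gene(rec, "trnA")
        assert len(seq) == 9 - 3 + 1
        assert reverse_complement(reverse_complement(seq)) == seq


class TestTaxonomy:
    HEADER = "sample_id\tsubfamily\ttribe\tgenus\tspecies\tindividual\n"

    def test_valid_table(self):
        tsv = self.HEADER + "s1\tA\tT1\tG\tsp\ti1\ns2\tA\tT1\tG\tsp\ti2\n"
        tax = load_taxonomy(io.StringIO(tsv))
        assert len(tax) == 2
        assert tax["s1"].tribe == "T1"

    def test_empty_rank_rejected(self):
        tsv = self.HEADER + "s1\tA\t\tG\tsp\ti1\n"
        with pytest.raises((MitoParseError, MitoValidationError)):
            load_taxonomy(io.StringIO(tsv))

    def test_duplicate_sample_rejected(self):
        tsv = self.HEADER + "s1\tA\tT\tG\tsp\ti1\ns1\tA\tT\tG\tsp\ti1\n"
        with pytest.raises(MitoValidationError):
            load_taxonomy(io.StringIO(tsv))

    def test_missing_column_rejected(self):
        tsv = "sample_id\tsubfamily\ttribe\tgenus\tspecies\ns1\tA\tT\tG\tsp\n"
        with pytest.raises(MitoParseError, match="missing"):
            load_taxonomy(io.StringIO(tsv))


class TestAlignedFasta:
    def test_read_block(self):
        fasta = ">a\nACGT-A\n>b\nACGTTA\n>c\nANGTTA\n"
        blk = read_aligned_fasta(io.StringIO(fasta), "g1")
        assert blk.matrix.shape == (3, 6)
        assert blk.samples == ["a", "b", "c"]

    def test_ragged_rejected(self):
        fasta = ">a\nACGT\n>b\nACG\n"
        with pytest.raises(MitoParseError, match="ragged"):
            read_aligned_fasta(io.StringIO(fasta), "g1")

    def test_bad_symbol_named(self):
        fasta = ">a\nACXT\n"
        with pytest.raises(MitoParseError, match="column 3"):
            read_aligned_fasta(io.StringIO(fasta), "g1")

    def test_roundtrip_random_block(self, tmp_path):
        from conftest import random_block
        rng = np.random.default_rng(42)
        blk = random_block(rng, gene="g1", gap_frac=0.1)
        path = tmp_path / "g1.fasta"
        write_fasta(blk, str(path))
        back = read_aligned_fasta(str(path), "g1")
        assert back.samples == blk.samples
        assert np.array_equal(back.matrix, blk.matrix)

    def test_coding_frame_invariant(self):
        with pytest.raises(MitoValidationError):
            AlignmentBlock(gene="g", samples=["a"],
                           matrix=np.array([list("ACG")]),
                           reading_frame_offset=5)
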