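"""Record parsing, round trips, parental subtraction and catalog files."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kosig.taxonomy import SUBSTITUTION_96
from kosig.variant_io import (
    IndelRecord,
    RearrangementRecord,
    SignatureCatalog,
    SubstitutionRecord,
    VariantIOError,
    read_indels,
    read_rearrangements,
    read_signature_catalog,
    read_substitutions,
    subtract_parental,
    write_rearrangements,
    write_signature_catalog,
    write_tsv,
    write_vcf,
)


def _write(path, text):
    path.write_text(text)
    return str(path)


VCF_HEADER = "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n" \
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


class TestSubstitutionReading:
    def test_vcf_row_maps_to_record(self, tmp_path):
        p = _write(tmp_path / "a.vcf", VCF_HEADER + "chr1\t100\t.\tC\tA\t.\t.\t.\n")
        recs = read_substitutions(p)
        assert list(recs) == [SubstitutionRecord("chr1", 100, "C", "A")]

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path / "a.vcf", VCF_HEADER)
        assert list(read_substitutions(p)) == []

    def test_indel_allele_rejected_with_line_number(self, tmp_path):
        p = _write(tmp_path / "a.vcf",
                   VCF_HEADER + "chr1\t100\t.\tC\tA\t.\t.\t.\n"
                   "chr1\t200\t.\tCT\tC\t.\t.\t.\n")
        with pytest.raises(VariantIOError, match="line 5"):
            read_substitutions(p)
        recs = read_substitutions(p, on_error="collect")
        assert len(recs) == 1 and len(recs.rejects) == 1
        assert recs.rejects[0].line == 5

    def test_no_row_silently_dropped(self, tmp_path):
        rows = ["chr1\t10\t.\tC\tA\t.\t.\t.", "chr1\t20\t.\tGG\tG\t.\t.\t.",
                "chr1\t30\t.\tT\tG\t.\t.\t.", "chr1\t40\t.\tA\tA\t.\t.\t."]
        p = _write(tmp_path / "a.vcf", VCF_HEADER + "\n".join(rows) + "\n")
        recs = read_substitutions(p, on_error="collect")
        assert len(recs) + len(recs.rejects) == len(rows)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_substitutions("/nonexistent/x.vcf")

    def test_tsv_dialect(self, tmp_path):
        p = _write(tmp_path / "a.tsv", "chrom\tpos\tref\talt\nchr2\t55\tT\tG\n")
        assert list(read_substitutions(p, dialect="tsv")) == [
            SubstitutionRecord("chr2", 55, "T", "G")]


class TestIndelReading:
    @pytest.mark.parametrize("ref,alt,check", [
        ("CA", "C", lambda r: r.is_deletion and r.deleted == "A"),
        ("C", "CAG", lambda r: r.is_insertion and r.inserted == "AG"),
        ("CAT", "CGG", lambda r: r.is_complex),
    ])
    def test_row_shapes(self, tmp_path, ref, alt, check):
        p = _write(tmp_path / "a.vcf",
                   VCF_HEADER + f"chr1\t200\t.\t{ref}\t{alt}\t.\t.\t.\n")
        (rec,) = read_indels(p)
        assert check(rec)

    def test_snv_rejected_from_indel_reader(self, tmp_path):
        p = _write(tmp_path / "a.vcf", VCF_HEADER + "chr1\t200\t.\tC\tA\t.\t.\t.\n")
        with pytest.raises(VariantIOError, match="substitution"):
            read_indels(p)


class TestRearrangementReading:
    def test_interchromosomal_defaults_to_translocation(self, tmp_path):
        p = _write(tmp_path / "a.bedpe",
                   "chrom1\tpos1\tchrom2\tpos2\nchr1\t1000\tchr2\t5000\n")
        (rec,) = read_rearrangements(p)
        assert rec.svclass == "translocation"

    def test_unlabeled_intrachromosomal_is_error(self, tmp_path):
        p = _write(tmp_path / "a.bedpe",
                   "chrom1\tpos1\tchrom2\tpos2\nchr1\t1000\tchr1\t5000\n")
        with pytest.raises(VariantIOError, match="svclass"):
            read_rearrangements(p)

    def test_ordering_violation(self, tmp_path):
        p = _write(tmp_path / "a.bedpe",
                   "chrom1\tpos1\tchrom2\tpos2\tsvclass\n"
                   "chr1\t1000\tchr1\t900\tdeletion\n")
        with pytest.raises(VariantIOError, match="pos2 > pos1"):
            read_rearrangements(p)

    def test_span_arithmetic(self, tmp_path):
        p = _write(tmp_path / "a.bedpe",
                   "chrom1\tpos1\tchrom2\tpos2\tsvclass\n"
                   "chr3\t10\tchr3\t100000\ttandem-duplication\n")
        (rec,) = read_rearrangements(p)
        assert rec.span == 99_990


class TestRoundTrips:
    def test_vcf_round_trip_substitutions(self, tmp_path):
        recs = [SubstitutionRecord("chr1", 10, "C", "T"),
                SubstitutionRecord("chr1", 99, "G", "A"),
                SubstitutionRecord("chr2", 5, "T", "G")]
        p = tmp_path / "x.vcf"
        write_vcf(recs, p)
        assert list(read_substitutions(str(p))) == sorted(recs)

    def test_vcf_round_trip_indels(self, tmp_path):
        recs = [IndelRecord("chr1", 10, "CAT", "C"),
                IndelRecord("chr1", 50, "G", "GTT"),
                IndelRecord("chr2", 7, "AT", "AG")]
        p = tmp_path / "x.vcf"
        write_vcf(recs, p)
        assert list(read_indels(str(p))) == sorted(recs)

    def test_tsv_round_trip(self, tmp_path):
        recs = [SubstitutionRecord("chr1", 10, "C", "T"),
                SubstitutionRecord("chr1", 20, "A", "C")]
        p = tmp_path / "x.tsv"
        write_tsv(recs, p)
        assert list(read_substitutions(str(p), dialect="tsv")) == sorted(recs)

    def test_bedpe_round_trip(self, tmp_path):
        recs = [RearrangementRecord("chr1", 100, "chr1", 9000, "deletion"),
                RearrangementRecord("chr1", 5, "chr2", 6, "translocation")]
        p = tmp_path / "x.bedpe"
        write_rearrangements(recs, p)
        assert list(read_rearrangements(str(p))) == sorted(recs)


class TestSubtractParental:
    A = SubstitutionRecord("chr1", 1000, "C", "A")
    B = SubstitutionRecord("chr1", 2000, "C", "T")
    C = SubstitutionRecord("chr2", 3000, "T", "G")

    def test_set_difference(self):
        assert list(subtract_parental([self.A, self.B, self.C], [self.B])) == \
            [self.A, self.C]

    def test_identical_lists_empty(self):
        assert list(subtract_parental([self.A, self.B], [self.A, self.B])) == []

    def test_mixed_classes_rejected(self):
        with pytest.raises(VariantIOError, match="one mutation class"):
            subtract_parental([self.A, IndelRecord("chr1", 5, "CT", "C")], [])

    @pytest.mark.parametrize("offset,kept", [(50, False), (500, True)])
    def test_rearrangement_tolerance(self, offset, kept):
        sub = RearrangementRecord("chr1", 10_000 + offset, "chr1",
                                  50_000 + offset, "deletion")
        par = RearrangementRecord("chr1", 10_000, "chr1", 50_000, "deletion")
        out = subtract_parental([sub], [par], match_tolerance=100)
        assert (len(out) == 1) == kept

    @given(st.sets(st.integers(1, 50), max_size=12),
           st.sets(st.integers(1, 50), max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, sub_pos, par_pos):
        sub = [SubstitutionRecord("c", p * 10, "C", "A") for p in sub_pos]
        par = [SubstitutionRecord("c", p * 10, "C", "A") for p in par_pos]
        once = subtract_parental(sub, par)
        twice = subtract_parental(list(once), par)
        assert list(once) == list(twice)


class TestReferenceAndTracks:
    def test_fasta_reference_round_trip(self, tmp_path):
        from kosig.variant_io import load_reference, write_fasta

        seqs = {"c1": "ACGTACGTTTACGT", "c2": "GGGCCCAAA"}
        p = tmp_path / "ref.fa"
        write_fasta(seqs, p, width=5)
        ref = load_reference(p)
        assert set(ref.contigs) == {"c1", "c2"}
        assert ref.fetch("c1", 1, 4) == "ACGT"
        assert ref.fetch("c2", 7, 9) == "AAA"
        assert ref.contig_length("c1") == 14

    def test_bed_track_round_trip_and_vocabulary(self, tmp_path):
        from kosig.variant_io import read_bed_track, write_bed_track

        intervals = [("c1", 0, 100, "+"), ("c1", 200, 300, "-")]
        p = tmp_path / "genes.bed"
        write_bed_track(intervals, p)
        track = read_bed_track(p, "strand")
        assert track.label_at("c1", 50) == "+"   # BED start is 0-based
        assert track.label_at("c1", 150) is None
        assert track.label_lengths() == {"+": 100, "-": 100}
        bad = tmp_path / "bad.bed"
        write_bed_track([("c1", 0, 10, "leading")], bad)
        with pytest.raises(VariantIOError, match="vocabulary"):
            read_bed_track(bad, "strand")


class TestSignatureCatalogIO:
    def test_round_trip_and_renormalization(self, tmp_path, rng):
        w = rng.random((96, 5)) * 0.98  # columns deliberately not unit-sum
        cat = SignatureCatalog(SUBSTITUTION_96, [f"S{i}" for i in range(5)], w)
        assert np.allclose(cat.matrix.sum(axis=0), 1.0, atol=1e-9)
        p = tmp_path / "cat.tsv"
        write_signature_catalog(cat, p)
        back = read_signature_catalog(p, "substitution")
        assert back.names == cat.names
        assert np.allclose(back.matrix, cat.matrix, atol=1e-6)

    def test_missing_channel_is_error(self, tmp_path):
        cat = SignatureCatalog(SUBSTITUTION_96, ["S1"], np.ones((96, 1)))
        p = tmp_path / "cat.tsv"
        write_signature_catalog(cat, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")  # drop the last channel row
        with pytest.raises(VariantIOError, match="channel labels"):
            read_signature_catalog(p, "substitution")
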