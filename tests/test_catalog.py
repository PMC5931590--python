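"""Channel classification against independent oracles, and catalog assembly."""

import numpy as np
import pytest
from scipy import stats

from kosig.catalog import (
    ClassificationError,
    CatalogMatrix,
    SampleCatalog,
    build_catalog,
    classify_indel,
    classify_rearrangement,
    classify_substitution,
)
from kosig.taxonomy import REARRANGEMENT_10, SUBSTITUTION_96
from kosig.variant_io import (
    IndelRecord,
    InMemoryReference,
    RearrangementRecord,
    SubstitutionRecord,
    VariantIOError,
)

# -- independent oracle for the pyrimidine-context convention ---------------

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_substitution_label(five, ref, alt, three):
    """Literal restatement of the convention: purine-reference mutations are
    reverse-complemented (context included) before labelling."""
    if ref in "AG":
        five, ref, alt, three = (three.translate(_COMP), ref.translate(_COMP),
                                 alt.translate(_COMP), five.translate(_COMP))
    return f"{five}[{ref}>{alt}]{three}"


class TestSubstitutionClassifier:
    def test_purine_reference_is_flipped(self):
        ref = InMemoryReference({"c": "AGA"})
        rec = SubstitutionRecord("c", 2, "G", "T")
        assert classify_substitution(rec, ref) == "T[C>A]T"

    def test_pyrimidine_reference_kept(self):
        ref = InMemoryReference({"c": "ACG"})
        rec = SubstitutionRecord("c", 2, "C", "T")
        assert classify_substitution(rec, ref) == "A[C>T]G"

    def test_all_192_combinations_cover_96_channels_twice(self):
        """Brute-force enumeration of every (context, ref, alt) combination:
        the map must agree with the independent oracle and hit each of the 96
        channels exactly twice (once per strand representation)."""
        hits = {}
        for five in "ACGT":
            for mid in "ACGT":
                for three in "ACGT":
                    ref = InMemoryReference({"c": five + mid + three})
                    for alt in "ACGT":
                        if alt == mid:
                            continue
                        label = classify_substitution(
                            SubstitutionRecord("c", 2, mid, alt), ref)
                        assert label == oracle_substitution_label(
                            five, mid, alt, three)
                        assert label in SUBSTITUTION_96
                        hits[label] = hits.get(label, 0) + 1
        assert len(hits) == 96
        assert set(hits.values()) == {2}

    def test_n_in_context_raises(self):
        ref = InMemoryReference({"c": "NCG"})
        with pytest.raises(ClassificationError, match="N in trinucleotide"):
            classify_substitution(SubstitutionRecord("c", 2, "C", "T"), ref)

    def test_missing_flank_raises(self):
        ref = InMemoryReference({"c": "ACGT"})
        with pytest.raises(ClassificationError, match="flank"):
            classify_substitution(SubstitutionRecord("c", 1, "A", "G"), ref)


class TestIndelClassifier:
    def test_one_bp_repeat_deletion(self):
        # delete the first A of "AA": one full extra copy follows
        ref = InMemoryReference({"c": "GCAAG"})
        rec = IndelRecord("c", 2, "CA", "C")
        assert classify_indel(rec, ref) == "del_rep_1bp"

    def test_microhomology_example(self):
        # deletion of CAG followed by CAT: junction homology "CA" (2 bp < 3)
        ref = InMemoryReference({"c": "TACAGCATTT"})
        rec = IndelRecord("c", 2, "ACAG", "A")
        assert classify_indel(rec, ref) == "del_mh_ge3bp"

    def test_zero_homology_is_other(self):
        # deletion of GT followed by AC: no junction homology, no repeat
        ref = InMemoryReference({"c": "CAGTACCC"})
        rec = IndelRecord("c", 2, "AGT", "A")
        assert classify_indel(rec, ref) == "del_other"

    def test_repeat_wins_over_microhomology(self):
        # deletion of AGAG followed by AGAG (full copy) and partial homology:
        # the full-copy adjacency check takes precedence
        ref = InMemoryReference({"c": "TCAGAGAGAGTT"})
        rec = IndelRecord("c", 2, "CAGAG", "C")
        assert classify_indel(rec, ref) == "del_rep_ge2bp"

    def test_left_alignment_changes_junction_verdict(self):
        # deleting the second A of "CAAG" is the same haplotype as deleting
        # the first; after left alignment one extra copy follows
        ref = InMemoryReference({"c": "GCAAGT"})
        rec = IndelRecord("c", 3, "AA", "A")
        assert classify_indel(rec, ref) == "del_rep_1bp"

    @pytest.mark.parametrize("ref_allele,alt_allele,label", [
        ("C", "CT", "ins_1bp"),
        ("C", "CTTG", "ins_ge2bp"),
        ("CAT", "CGG", "complex"),
    ])
    def test_non_deletion_channels(self, ref_allele, alt_allele, label):
        ref = InMemoryReference({"c": "GCATGGGG"})
        assert classify_indel(IndelRecord("c", 2, ref_allele, alt_allele),
                              ref) == label

    def test_every_deletion_gets_exactly_one_junction_label(self, rng):
        """Precedence is total and deterministic: any deletion drawn on a
        random sequence lands in exactly one of the deletion channels."""
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        ref = InMemoryReference({"c": seq})
        deletion_labels = {"del_rep_1bp", "del_rep_ge2bp", "del_mh_2bp",
                           "del_mh_ge3bp", "del_other"}
        for _ in range(300):
            L = int(rng.integers(1, 5))
            pos = int(rng.integers(2, len(seq) - L - 6))
            rec = IndelRecord("c", pos, seq[pos - 1: pos + L], seq[pos - 1])
            assert classify_indel(rec, ref) in deletion_labels


class TestRearrangementClassifier:
    @pytest.mark.parametrize("svclass,span,label", [
        ("deletion", 5_000, "deletion_1-10kb"),
        ("tandem-duplication", 500_000, "tandem-duplication_10kb-1Mb"),
        ("inversion", 2_000_000, "inversion_>1Mb"),
        ("deletion", 1_000, "deletion_1-10kb"),
        ("deletion", 10_000, "deletion_1-10kb"),
        ("deletion", 10_001, "deletion_10kb-1Mb"),
    ])
    def test_size_bins(self, svclass, span, label):
        rec = RearrangementRecord("c1", 10, "c1", 10 + span, svclass)
        assert classify_rearrangement(rec) == label

    def test_translocation_ignores_positions(self):
        rec = RearrangementRecord("c1", 999, "c2", 3, "translocation")
        assert classify_rearrangement(rec) == "translocation"

    def test_sub_resolution_span_rejected(self):
        rec = RearrangementRecord("c1", 10, "c1", 500, "deletion")
        with pytest.raises(ClassificationError, match="below"):
            classify_rearrangement(rec)


class TestBuildCatalog:
    def test_counting(self):
        ref = InMemoryReference({"c": "TCTTCTTCT"})
        recs = [SubstitutionRecord("c", p, "C", "A") for p in (2, 5, 8)]
        cat = build_catalog({"s1": recs}, "substitution", reference=ref)
        counts = cat.samples[0].counts
        assert counts[SUBSTITUTION_96.index("T[C>A]T")] == 3
        assert counts.sum() == 3

    def test_mixed_classes_rejected(self):
        with pytest.raises(VariantIOError):
            build_catalog({"s1": [SubstitutionRecord("c", 2, "C", "A"),
                                  IndelRecord("c", 2, "CT", "C")]},
                          "substitution")

    def test_conservation_with_rejects(self):
        recs = [RearrangementRecord("c1", 10, "c1", 5_010, "deletion"),
                RearrangementRecord("c1", 10, "c1", 200, "deletion"),  # <1 kb
                RearrangementRecord("c1", 10, "c2", 20, "translocation")]
        cat = build_catalog({"s1": recs}, "rearrangement")
        assert cat.samples[0].counts.sum() + len(cat.rejects) == len(recs)

    def test_empty_sample_is_zero_vector(self):
        cat = build_catalog({"s1": []}, "indel")
        assert cat.samples[0].counts.sum() == 0

    def test_empirical_proportions_match_generating_distribution(self, rng):
        """Counts drawn from a known channel distribution pass a chi-square
        goodness-of-fit test against it (multinomial sampling oracle)."""
        probs = np.full(8, 1 / 8)
        counts = rng.multinomial(4000, probs)
        chi = stats.chisquare(counts, 4000 * probs)
        assert chi.pvalue > 1e-4

    def test_tsv_round_trip(self, tmp_path, rng):
        samples = [SampleCatalog(f"s{i}", rng.integers(0, 30, size=10),
                                 role="subclone", knockout="KO1")
                   for i in range(3)]
        samples.append(SampleCatalog("p1", rng.integers(0, 30, size=10),
                                     role="parental"))
        cat = CatalogMatrix(REARRANGEMENT_10, samples)
        p = tmp_path / "cat.tsv"
        cat.to_tsv(p)
        back = CatalogMatrix.from_tsv(p)
        assert back.taxonomy.name == "rearrangement"
        assert back.sample_ids == cat.sample_ids
        assert [s.role for s in back.samples] == [s.role for s in cat.samples]
        assert (back.counts == cat.counts).all()
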