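import numpy as np
import pytest

from conftest import make_variant
from oracles import random_cds_snv, random_transcript, translation_oracle
from rscan.variant_filter import (
    FilterParams,
    TranscriptModel,
    candidate_compound_het,
    candidate_hemizygous_x,
    candidate_homozygous,
    classify_consequence,
    quality_filter,
    remove_known,
)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "vclass,mq,kept",
        [
            ("snp", 26.0, True),
            ("snp", 25.0, False),
            ("indel", 11.0, True),
            ("indel", 10.0, False),
        ],
    )
    def test_strict_thresholds(self, vclass, mq, kept):
        alt = "AT" if vclass == "indel" else "T"
        v = make_variant(variant_class=vclass, alt=alt, mq=mq)
        assert (quality_filter([v]) == [v]) is kept

    def test_missing_mq_dropped(self):
        assert quality_filter([make_variant(mq=None)]) == []

    def test_empty_input(self):
        assert quality_filter([]) == []


class TestRemoveKnown:
    def test_exact_allele_matching(self):
        variants = [make_variant(pos=100 + i) for i in range(10)]
        catalog = {v.key for v in variants[:4]}
        out = remove_known(variants, catalog)
        assert out == variants[4:]
        # same position, different alt allele is retained
        other = make_variant(pos=100, alt="G")
        assert remove_known([other], catalog) == [other]

    def test_idempotence(self):
        variants = [make_variant(pos=100 + i) for i in range(6)]
        catalog = {variants[0].key, variants[3].key}
        once = remove_known(variants, catalog)
        assert remove_known(once, catalog) == once

    def test_order_independence_with_quality(self):
        variants = [
            make_variant(pos=100 + i, mq=float(m))
            for i, m in enumerate([30, 20, 40, 26, 25])
        ]
        catalog = {variants[0].key, variants[2].key}
        a = remove_known(quality_filter(variants), catalog)
        b = quality_filter(remove_known(variants, catalog))
        assert [v.key for v in a] == [v.key for v in b]


def _single_exon_model(strand="+"):
    # CDS: ATG AAA CCC GGG TAA at positions 101..115
    return TranscriptModel(
        gene="G1", chromosome="1", strand=strand, exons=[(101, 115)],
        cds_start=101, cds_end=115, sequence="ATGAAACCCGGGTAA",
    )


def _two_exon_model():
    seq = "ATGAAACCCG" + "gtatcatcag" + "GGTAAxxxxx"[:10]
    return TranscriptModel(
        gene="G2", chromosome="1", strand="+", exons=[(101, 110), (121, 130)],
        cds_start=101, cds_end=125, sequence=seq,
    )


class TestClassifyConsequence:
    def test_synonymous_third_position(self):
        # codon 2 is AAA (Lys); 106 A->G gives AAG (Lys)
        v = make_variant(pos=106, ref="A", alt="G")
        assert classify_consequence(v, _single_exon_model()) == "coding_synonymous"

    def test_nonsynonymous_first_position(self):
        # codon 2 AAA -> CAA (Lys -> Gln)
        v = make_variant(pos=104, ref="A", alt="C")
        assert classify_consequence(v, _single_exon_model()) == "coding_nonsynonymous"

    def test_one_bp_deletion_is_frameshift(self):
        v = make_variant(pos=104, ref="AA", alt="A", variant_class="indel")
        assert classify_consequence(v, _single_exon_model()) == "frameshift"

    def test_three_bp_deletion_is_inframe_protein_altering(self):
        v = make_variant(pos=104, ref="AAAC", alt="A", variant_class="indel")
        assert classify_consequence(v, _single_exon_model()) == "coding_nonsynonymous"

    def test_donor_plus_one_is_splice_site(self):
        v = make_variant(pos=111, ref="G", alt="A")
        assert classify_consequence(v, _two_exon_model()) == "splice_site"

    def test_acceptor_minus_two_is_splice_site(self):
        v = make_variant(pos=119, ref="A", alt="C")
        assert classify_consequence(v, _two_exon_model()) == "splice_site"

    def test_deep_intron_is_noncoding(self):
        v = make_variant(pos=115, ref="C", alt="T")
        assert classify_consequence(v, _two_exon_model()) == "noncoding"

    def test_outside_transcript_is_noncoding(self):
        v = make_variant(pos=500, ref="A", alt="T")
        assert classify_consequence(v, _single_exon_model()) == "noncoding"

    def test_translation_oracle_agreement(self, rng):
        """Single-codon classification agrees with whole-CDS translation."""
        mismatches = []
        for _ in range(300):
            model = random_transcript(rng)
            v = random_cds_snv(rng, model, make_variant)
            got = classify_consequence(v, model)
            want = translation_oracle(v, model)
            if got != want:
                mismatches.append((model, v, got, want))
        assert not mismatches, mismatches[:2]


def _planted_exome():
    """700 common benign + 30 rare deleterious of which 5 homozygous."""
    variants = []
    for i in range(700):
        variants.append(
            make_variant(
                pos=1000 + i, gene=f"BG{i}", consequence="coding_synonymous",
                known=True, genotypes={"P1": "het"},
            )
        )
    for i in range(30):
        gt = "hom_alt" if i < 5 else "het"
        variants.append(
            make_variant(
                pos=10_000 + i, gene=f"RD{i}", consequence="coding_nonsynonymous",
                known=False, genotypes={"P1": gt},
            )
        )
    return variants


class TestCandidateStreams:
    def test_homozygous_stream_planted_counts(self):
        got = candidate_homozygous(_planted_exome(), "P1")
        assert len(got) == 5
        assert all(v.genotypes["P1"] == "hom_alt" for v in got)

    def test_het_and_common_excluded_from_hom_stream(self):
        vs = [
            make_variant(pos=1, genotypes={"P1": "het"}),
            make_variant(pos=2, known=True, genotypes={"P1": "hom_alt"}),
        ]
        assert candidate_homozygous(vs, "P1") == []

    def test_missing_proband_is_error(self):
        with pytest.raises(ValueError):
            candidate_homozygous([make_variant(genotypes={"X": "het"})], "P1")

    def test_compound_het_gene_rules(self):
        vs = [
            make_variant(pos=1, gene="A", genotypes={"P1": "het"}),
            make_variant(pos=2, gene="A", genotypes={"P1": "het"}),
            make_variant(pos=3, gene="B", genotypes={"P1": "het"}),
            make_variant(pos=4, gene="B", known=True, genotypes={"P1": "het"}),
            make_variant(pos=5, gene="C", genotypes={"P1": "hom_alt"}),
            make_variant(pos=6, gene="C", genotypes={"P1": "het"}),
        ]
        got = candidate_compound_het(vs, "P1")
        assert set(got) == {"A"}  # B: one rare het only; C: hom stream owns it

    def test_hemizygous_stream(self):
        vs = [
            make_variant(chrom="X", pos=1, genotypes={"P1": "hemi_alt"}),
            make_variant(chrom="X", pos=2, genotypes={"P1": "hemi_ref"}),
            make_variant(chrom="X", pos=3, consequence="splice_site",
                         genotypes={"P1": "hemi_alt"}),
        ]
        got = candidate_hemizygous_x(vs, "P1", "male")
        assert [v.position_bp for v in got] == [1, 3]
        assert got[1].consequence == "splice_site"

    def test_female_proband_empty_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert candidate_hemizygous_x([], "P1", "female") == []
        assert "non-male" in caplog.text

    def test_streams_are_disjoint(self):
        vs = _planted_exome() + [
            make_variant(chrom="X", pos=50, gene="XG", genotypes={"P1": "hemi_alt"}),
            make_variant(pos=60, gene="CH", genotypes={"P1": "het"}),
            make_variant(pos=61, gene="CH", genotypes={"P1": "het"}),
        ]
        hom = {v.key for v in candidate_homozygous(vs, "P1")}
        chet = {
            v.key for g in candidate_compound_het(vs, "P1").values() for v in g
        }
        hemi = {v.key for v in candidate_hemizygous_x(vs, "P1", "male")}
        assert not (hom & chet) and not (hom & hemi) and not (chet & hemi)
        rare_deleterious = {
            v.key
            for v in vs
            if not v.known_variant and v.consequence in FilterParams().deleterious_classes
        }
        assert (hom | chet | hemi) <= rare_deleterious
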