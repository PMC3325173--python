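import numpy as np
import pytest

from conftest import make_map, make_matrix, make_variant, trio_pedigree
from rscan import io as rio
from rscan.core import (
    ControlCounts,
    FormatError,
    GenotypeMatrix,
    Individual,
    Pedigree,
    ValidationEntry,
    ValidationTable,
)


class TestPedigreeInvariants:
    def test_dangling_parent_rejected(self):
        with pytest.raises(ValueError, match="not in family"):
            Pedigree("F1", [Individual("kid", "ghost", None, "male", "affected")])

    def test_wrong_parent_sex_rejected(self):
        with pytest.raises(ValueError, match="has sex"):
            Pedigree(
                "F1",
                [
                    Individual("dad", None, None, "female", "unknown"),
                    Individual("kid", "dad", None, "male", "affected"),
                ],
            )

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="own ancestor"):
            Pedigree(
                "F1",
                [
                    Individual("a", "b", None, "male", "unknown"),
                    Individual("b", "a", None, "male", "unknown"),
                ],
            )

    def test_het_on_male_x_rejected(self):
        with pytest.raises(ValueError, match="male X"):
            make_matrix({"boy": [0, 1, 2]}, chrom="X", sex={"boy": "male"})


class TestPedMap:
    PED = (
        "FAM1 dad 0 0 1 1  A A  G G\n"
        "FAM1 mom 0 0 2 1  A C  G T\n"
        "FAM1 kid dad mom 1 2  C C  0 0\n"
    )
    MAP = "1 rs1 0.0 1000\n1 rs2 1.5 5000\n"

    def _write(self, tmp_path):
        ped = tmp_path / "f.ped"
        mp = tmp_path / "f.map"
        ped.write_text(self.PED)
        mp.write_text(self.MAP)
        return ped, mp

    def test_direct_transcription(self, tmp_path):
        peds, matrix = rio.read_ped_map(*self._write(tmp_path))
        assert matrix.sample_ids == ["dad", "mom", "kid"]
        # marker rs1: alleles {A, C} sorted -> A=ref; rs2: {G, T} -> G=ref
        assert matrix.row("dad").tolist() == [0, 0]
        assert matrix.row("mom").tolist() == [1, 1]
        assert matrix.row("kid").tolist() == [2, -1]  # "0 0" is missing
        fam = peds[0]
        kid = fam.by_id()["kid"]
        assert kid.father_id == "dad" and kid.affection == "affected"
        assert fam.by_id()["dad"].sex == "male"

    def test_column_count_mismatch(self, tmp_path):
        ped = tmp_path / "f.ped"
        ped.write_text("FAM1 x 0 0 1 1 A A\n")  # one genotype, map has two
        mp = tmp_path / "f.map"
        mp.write_text(self.MAP)
        with pytest.raises(FormatError, match="expected"):
            rio.read_ped_map(ped, mp)

    def test_triallelic_marker_dropped(self, tmp_path):
        ped = tmp_path / "f.ped"
        ped.write_text(
            "FAM1 a 0 0 1 1 A A G G\nFAM1 b 0 0 1 1 C C G G\nFAM1 c 0 0 1 1 T T G T\n"
        )
        mp = tmp_path / "f.map"
        mp.write_text(self.MAP)
        _, matrix = rio.read_ped_map(ped, mp)
        assert len(matrix.map) == 1 and matrix.map.marker_ids[0] == "rs2"

    def test_round_trip(self, tmp_path, rng):
        n, m = 4, 30
        calls = rng.choice([-1, 0, 1, 2], size=(n, m), p=[0.1, 0.4, 0.3, 0.2])
        calls[0, :] = 0
        calls[1, :] = 2  # both alleles observed at every marker
        matrix = GenotypeMatrix(
            sample_ids=["F", "M", "P1", "S1"],
            map=make_map(m),
            calls=calls.astype(np.int8),
            sex={"F": "male", "M": "female", "P1": "male", "S1": "female"},
        )
        ped = trio_pedigree()
        rio.write_ped_map([ped], matrix, tmp_path / "o.ped", tmp_path / "o.map")
        peds2, matrix2 = rio.read_ped_map(tmp_path / "o.ped", tmp_path / "o.map")
        assert np.array_equal(matrix.calls, matrix2.calls)
        assert list(matrix2.map.marker_ids) == list(matrix.map.marker_ids)
        assert np.allclose(matrix2.map.position_cM, matrix.map.position_cM)
        assert [m.individual_id for m in peds2[0].members] == [
            m.individual_id for m in ped.members
        ]


class TestVariantIO:
    def test_vcf_trio_genotypes(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tP1\n"
            "1\t100\t.\tA\tG\t.\t.\tGENE=G1;CSQ=coding_nonsynonymous;MQ=40\tGT\t0/1\t0/1\t1/1\n"
            "X\t500\t.\tC\tT\t.\t.\tGENE=G2;CSQ=coding_nonsynonymous;MQ=40\tGT\t0\t0/1\t1\n"
        )
        recs = rio.read_variants(vcf, "vcf", sex={"P1": "male", "F": "male"})
        assert recs[0].genotypes == {"F": "het", "M": "het", "P1": "hom_alt"}
        assert recs[1].genotypes["P1"] == "hemi_alt"
        assert recs[1].genotypes["F"] == "hemi_ref"
        assert recs[0].mapping_quality == 40

    def test_unknown_sample_warns_but_keeps(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tstranger\n"
            "1\t100\t.\tA\tG\t.\t.\tMQ=40\tGT\t0/1\n"
        )
        with pytest.warns(UserWarning, match="stranger"):
            recs = rio.read_variants(vcf, "vcf", pedigrees=[trio_pedigree()])
        assert recs[0].genotypes["stranger"] == "het"

    def test_tsv_round_trip(self, tmp_path, rng):
        recs = [
            make_variant(
                pos=int(p),
                gene=f"G{i}",
                genotypes={"F": "het", "M": "hom_ref", "P1": "hom_alt"},
                annotations={"brain_expressed": bool(i % 2)},
                control_counts=ControlCounts(i, 1344, 0),
            )
            for i, p in enumerate(rng.integers(1, 10**6, size=15))
        ]
        path = tmp_path / "v.tsv"
        rio.write_variants_tsv(recs, path)
        back = rio.read_variants(path, "tsv")
        for a, b in zip(recs, back):
            assert a.key == b.key
            assert a.genotypes == b.genotypes
            assert a.consequence == b.consequence
            assert a.annotations.get("brain_expressed") == b.annotations.get("brain_expressed")
            assert a.control_counts == b.control_counts

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chromosome\tposition_bp\n1\t5\n")
        with pytest.raises(FormatError, match="missing required columns"):
            rio.read_variants(path, "tsv")

    def test_roh_bed_round_trip(self, tmp_path):
        from rscan.roh import ROHSegment

        segs = [
            ROHSegment("P1", "4", 10, 80, 2.5, 11.75, 2_500_001, 11_750_001, 71, 3),
            ROHSegment("P1", "9", 5, 60, 0.0, 8.0, 1, 8_000_001, 56, 1),
        ]
        path = tmp_path / "r.bed"
        rio.write_roh_bed(segs, path)
        back = rio.read_roh_bed(path)
        for a, b in zip(segs, back):
            assert (a.chromosome, a.start_bp, a.end_bp, a.sample_id, a.n_markers) == (
                b.chromosome, b.start_bp, b.end_bp, b.sample_id, b.n_markers
            )
            assert a.start_cM == pytest.approx(b.start_cM, abs=1e-4)
        rio.write_roh_bed(back, tmp_path / "r2.bed")
        assert (tmp_path / "r.bed").read_text() == (tmp_path / "r2.bed").read_text()


class TestApplyValidation:
    @staticmethod
    def _table(entries):
        t = ValidationTable()
        for key, sample, entry in entries:
            t.add(key, sample, entry)
        return t

    def test_contradiction_flagged_and_removed(self):
        v = make_variant(genotypes={"P1": "hom_alt", "F": "het"})
        table = self._table(
            [(v.key, "P1", ValidationEntry("designed", "ran", "het"))]
        )
        kept, removed = rio.apply_validation([v], table, proband="P1")
        assert kept == []
        assert removed[0].annotations["not_validated"]
        assert removed[0].genotypes["P1"] == "het"  # validation call replaces exome

    def test_confirmation_retained(self):
        v = make_variant(genotypes={"P1": "hom_alt"})
        table = self._table(
            [(v.key, "P1", ValidationEntry("designed", "ran", "hom_alt"))]
        )
        kept, removed = rio.apply_validation([v], table, proband="P1")
        assert len(kept) == 1 and not removed

    def test_cascade_counts_toy_32_27_22_10(self):
        """32 exome calls; 5 fail design, 5 fail the run, 12 contradict: 10 survive."""
        variants = [
            make_variant(pos=100 + i, genotypes={"P1": "hom_alt"}) for i in range(32)
        ]
        entries = []
        for i, v in enumerate(variants):
            if i < 5:
                entries.append((v.key, "P1", ValidationEntry("design_failed")))
            elif i < 10:
                entries.append((v.key, "P1", ValidationEntry("designed", "failed")))
            elif i < 22:
                entries.append((v.key, "P1", ValidationEntry("designed", "ran", "het")))
            else:
                entries.append((v.key, "P1", ValidationEntry("designed", "ran", "hom_alt")))
        kept, removed = rio.apply_validation(variants, self._table(entries), "P1")
        assert len(kept) == 10
        assert len(removed) == 22
        assert sum(1 for r in removed if r.annotations.get("not_validated")) == 12

    def test_unknown_variant_warns(self):
        v = make_variant(genotypes={"P1": "hom_alt"})
        table = self._table(
            [(("9", 999, "A", "C"), "P1", ValidationEntry("designed", "ran", "het"))]
        )
        with pytest.warns(UserWarning, match="unknown variant"):
            kept, _ = rio.apply_validation([v], table, "P1")
        assert len(kept) == 1


def test_catalog_reader_both_dialects(tmp_path):
    tsv = tmp_path / "c.tsv"
    tsv.write_text("1\t100\tA\tG\nX\t5\tC\tT\n")
    vcf = tmp_path / "c.vcf"
    vcf.write_text("##x\n#CHROM\tPOS\tID\tREF\tALT\n1\t100\trs1\tA\tG\n")
    assert rio.read_catalog(tsv) == {("1", 100, "A", "G"), ("X", 5, "C", "T")}
    assert rio.read_catalog(vcf) == {("1", 100, "A", "G")}
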