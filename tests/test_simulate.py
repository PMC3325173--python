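import numpy as np
import pytest

from conftest import make_map
from rscan.roh import ROHParams, detect_roh
from rscan.simulate import (
    ImplantError,
    SimulationConfig,
    build_pedigree,
    inbreeding_coefficient,
    kinship,
    meiosis,
    simulate_family,
    truth_autozygous_fraction,
)


class TestInbreedingCoefficient:
    def test_first_cousin_offspring(self):
        ped = build_pedigree(SimulationConfig(topology="first_cousin"))
        assert inbreeding_coefficient(ped, "P1") == 0.0625

    def test_second_cousin_offspring(self):
        ped = build_pedigree(SimulationConfig(topology="second_cousin"))
        assert inbreeding_coefficient(ped, "P1") == 0.015625

    def test_second_cousin_matches_path_counting(self):
        # one path per shared great-grandparent, each with 3 meioses on the
        # paternal side and 3 on the maternal: F = 2 x (1/2)^(3+3+1) = 1/64
        ped = build_pedigree(SimulationConfig(topology="second_cousin"))
        assert inbreeding_coefficient(ped, "P1") == pytest.approx(2 * 0.5 ** 7)

    def test_outbred_offspring_zero(self):
        ped = build_pedigree(SimulationConfig(topology="outbred"))
        assert inbreeding_coefficient(ped, "P1") == 0.0

    def test_founder_zero(self):
        ped = build_pedigree(SimulationConfig(topology="first_cousin"))
        assert inbreeding_coefficient(ped, "GGF") == 0.0

    def test_kinship_self_of_outbred(self):
        ped = build_pedigree(SimulationConfig(topology="outbred"))
        assert kinship(ped, "F", "F") == 0.5


class TestMeiosis:
    def _haps(self, n, rng):
        a0 = np.zeros(n, dtype=np.uint8)
        a1 = np.ones(n, dtype=np.uint8)
        o0 = np.zeros(n, dtype=np.int64)
        o1 = np.ones(n, dtype=np.int64)
        return [(a0, o0), (a1, o1)]

    def test_zero_length_map_returns_whole_haplotype(self, rng):
        gmap = make_map(1)
        al, orig = meiosis(self._haps(1, rng), gmap, rng)
        assert orig[0] in (0, 1) and al[0] == orig[0]

    def test_crossover_count_matches_poisson_mean(self, rng):
        gmap = make_map(1001, spacing_cM=0.1)  # 100 cM
        haps = self._haps(1001, rng)
        switches = 0
        draws = 10_000
        for _ in range(draws):
            _, orig = meiosis(haps, gmap, rng)
            switches += int(np.sum(orig[1:] != orig[:-1]))
        mean = switches / draws
        se = np.sqrt(1.0 / draws)
        assert abs(mean - 1.0) < 3 * se + 0.01  # small allowance for same-interval pairs

    def test_gamete_alleles_come_from_parent(self, rng):
        gmap = make_map(200, spacing_cM=0.5)
        h0 = (rng.integers(0, 2, 200).astype(np.uint8), np.zeros(200, dtype=np.int64))
        h1 = (rng.integers(0, 2, 200).astype(np.uint8), np.ones(200, dtype=np.int64))
        al, orig = meiosis([h0, h1], gmap, rng)
        src = np.where(orig == 0, h0[0], h1[0])
        assert np.array_equal(al, src)


class TestSimulateFamily:
    def test_same_seed_is_deterministic(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_family(cfg)
        b = simulate_family(cfg)
        assert np.array_equal(a.matrix.calls, b.matrix.calls)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        assert a.causal_keys == b.causal_keys
        assert a.truth_autozygous == b.truth_autozygous

    def test_outbred_truth_autozygosity_zero(self):
        fam = simulate_family(
            SimulationConfig(topology="outbred", causal_model=None, seed=1)
        )
        for child in ("P1", "P2", "S1"):
            assert fam.truth_autozygous[child] == []

    def test_first_cousin_truth_fraction(self):
        fractions = [
            truth_autozygous_fraction(
                simulate_family(
                    SimulationConfig(
                        topology="first_cousin", causal_model=None,
                        marker_spacing_cM=0.4, seed=1000 + i,
                    )
                ),
                "P1",
            )
            for i in range(60)
        ]
        mean, se = np.mean(fractions), np.std(fractions) / np.sqrt(60)
        assert abs(mean - 0.0625) < 3.5 * se

    def test_second_cousin_truth_fraction(self):
        fractions = [
            truth_autozygous_fraction(
                simulate_family(
                    SimulationConfig(
                        topology="second_cousin", causal_model=None,
                        marker_spacing_cM=0.4, seed=2000 + i,
                    )
                ),
                "P1",
            )
            for i in range(60)
        ]
        mean, se = np.mean(fractions), np.std(fractions) / np.sqrt(60)
        assert abs(mean - 0.015625) < 3.5 * se

    def test_genotypes_mendelian_consistent(self):
        fam = simulate_family(SimulationConfig(seed=5, causal_model=None))
        byid = fam.pedigree.by_id()
        calls = {s: fam.matrix.row(s) for s in fam.matrix.sample_ids}
        for m in fam.pedigree.members:
            if m.father_id is None:
                continue
            child, fa, mo = calls[m.individual_id], calls[m.father_id], calls[m.mother_id]
            # a homozygous child requires each parent to carry that allele
            bad = ((child == 2) & ((fa == 0) | (mo == 0))) | (
                (child == 0) & ((fa == 2) | (mo == 2))
            )
            assert not bad.any()

    def test_error_and_missing_rates_applied(self):
        cfg = SimulationConfig(seed=9, causal_model=None, missing_rate=0.05)
        fam = simulate_family(cfg)
        frac_missing = float((fam.matrix.calls == -1).mean())
        assert 0.04 < frac_missing < 0.06

    def test_implant_hom_recessive_pattern(self):
        fam = simulate_family(SimulationConfig(seed=21))
        causal = next(v for v in fam.variants if v.key in set(fam.causal_keys))
        assert causal.genotypes["P1"] == "hom_alt"
        assert causal.genotypes["P2"] == "hom_alt"
        assert causal.genotypes["F"] == "het" and causal.genotypes["M"] == "het"
        assert causal.genotypes["S1"] != "hom_alt"

    def test_implant_compound_het_pattern(self):
        fam = simulate_family(
            SimulationConfig(
                topology="outbred", causal_model="compound_het",
                causal_placement="random", seed=22,
            )
        )
        va, vb = [v for v in fam.variants if v.key in set(fam.causal_keys)]
        assert va.genotypes["P1"] == "het" and vb.genotypes["P1"] == "het"
        carriers_f = {v.genotypes["F"] for v in (va, vb)}
        carriers_m = {v.genotypes["M"] for v in (va, vb)}
        assert "het" in carriers_f and "het" in carriers_m

    def test_implant_x_linked_pattern(self):
        fam = simulate_family(
            SimulationConfig(
                topology="outbred", causal_model="x_linked",
                causal_placement="random", seed=23,
            )
        )
        causal = next(v for v in fam.variants if v.key in set(fam.causal_keys))
        assert causal.chromosome == "X"
        assert causal.genotypes["P1"] == "hemi_alt"
        assert causal.genotypes["M"] == "het"
        assert causal.genotypes["F"] == "hemi_ref"

    def test_outbred_hom_in_segment_implant_fails(self):
        cfg = SimulationConfig(
            topology="outbred", causal_model="hom_recessive",
            causal_placement="in_autozygous_segment", seed=3,
        )
        with pytest.raises(ImplantError):
            simulate_family(cfg, max_attempts=3)

    def test_roh_detector_recovers_truth_segments(self):
        """Detected ROHs cover >=95% of truth-IBD length in segments >5 cM."""
        for seed in (31, 32, 33):
            fam = simulate_family(
                SimulationConfig(topology="first_cousin", causal_model=None, seed=seed)
            )
            segs = detect_roh(fam.matrix, "P1", ROHParams())
            covered = np.zeros(len(fam.matrix.map), dtype=bool)
            for s in segs:
                covered[s.first_marker_index : s.last_marker_index + 1] = True
            cm = fam.matrix.map.position_cM
            total = recovered = 0.0
            for chrom, a, b in fam.truth_autozygous["P1"]:
                length = cm[b] - cm[a]
                if length <= 5.0:
                    continue
                total += length
                inside = covered[a : b + 1]
                recovered += length * inside.mean()
            if total > 0:
                assert recovered / total >= 0.95
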