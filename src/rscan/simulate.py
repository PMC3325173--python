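"""Synthetic family data: consanguineous pedigrees, gene-dropping with
recombination, implanted recessive causal variants, and an exact pedigree
inbreeding-coefficient calculator.

The generator emulates the substrate of a homozygosity-mapping study:
multi-sibling nuclear families whose parents are optionally connected
through a first- or second-cousin loop, genotyped on a dense SNP map.
Meiosis follows the Haldane model — crossover counts per chromosome are
Poisson(length/100) with positions uniform in genetic distance, no
interference, one sex-averaged map.  Founder haplotypes are drawn i.i.d.
per marker from a configurable minor-allele-frequency spectrum and carry
unique labels, so autozygosity (both haplotypes descending from one founder
haplotype) is traced exactly and recorded as ground truth before any
genotyping error or missingness is applied.

Exome-style variant tables contain a configurable number of background
variants (a mix of common/known and rare founder-haplotype-borne variants
across consequence classes) plus, when requested, an implanted causal
variant placed so that every affected child matches the chosen inheritance
model and no unaffected child does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    ControlCounts,
    GeneticMap,
    GenotypeMatrix,
    HET,
    HOM_REF,
    MISSING,
    Individual,
    Pedigree,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    topology: str = "first_cousin"  # outbred | first_cousin | second_cousin
    n_affected_sibs: int = 2
    n_unaffected_sibs: int = 1
    map_length_cM: float = 3500.0
    marker_spacing_cM: float = 0.1
    n_chromosomes: int = 22
    x_length_cM: float = 180.0
    founder_maf: tuple[float, float] = (0.05, 0.5)
    causal_gene: str = "GENE_CAUSAL"
    causal_placement: str = "in_autozygous_segment"  # or "random"
    causal_model: Optional[str] = "hom_recessive"  # compound_het | x_linked | None
    causal_min_segment_cM: float = 6.0
    n_background_variants: int = 700
    background_common_fraction: float = 0.7
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.genotype_error_rate, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.marker_spacing_cM <= 0:
            raise ValueError("marker spacing must be positive")
        if self.topology not in ("outbred", "first_cousin", "second_cousin"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    matrix: GenotypeMatrix
    variants: list[VariantRecord]
    causal_keys: list[tuple]
    #: per individual: list of (chromosome, first_idx, last_idx) truth-IBD runs
    truth_autozygous: dict[str, list[tuple[str, int, int]]]
    catalog: set[tuple[str, int, str, str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# pedigree topologies


def build_pedigree(config: SimulationConfig, family_id: str = "FAM1") -> Pedigree:
    """Nuclear family with the requested consanguinity loop.

    Affected children are male when the causal model is X-linked; otherwise
    child sexes alternate.
    """
    members: list[Individual] = []

    def add(iid, father, mother, sex, aff="unknown"):
        members.append(Individual(iid, father, mother, sex, aff))

    if config.topology == "outbred":
        add("F", None, None, "male")
        add("M", None, None, "female")
    elif config.topology == "first_cousin":
        add("GGF", None, None, "male")
        add("GGM", None, None, "female")
        add("U1", "GGF", "GGM", "male")
        add("U2", "GGF", "GGM", "female")
        add("SP1", None, None, "female")
        add("SP2", None, None, "male")
        add("F", "U1", "SP1", "male")
        add("M", "SP2", "U2", "female")
    else:  # second_cousin
        add("GGGF", None, None, "male")
        add("GGGM", None, None, "female")
        add("A1", "GGGF", "GGGM", "male")
        add("A2", "GGGF", "GGGM", "female")
        add("SPA", None, None, "female")
        add("SPB", None, None, "male")
        add("B1", "A1", "SPA", "male")
        add("B2", "SPB", "A2", "female")
        add("SPC", None, None, "female")
        add("SPD", None, None, "male")
        add("F", "B1", "SPC", "male")
        add("M", "SPD", "B2", "female")

    x_linked = config.causal_model == "x_linked"
    for i in range(config.n_affected_sibs):
        sex = "male" if x_linked else ("male" if i % 2 == 0 else "female")
        add(f"P{i + 1}", "F", "M", sex, "affected")
    for i in range(config.n_unaffected_sibs):
        sex = "female" if x_linked else ("female" if i % 2 == 0 else "male")
        add(f"S{i + 1}", "F", "M", sex, "unaffected")
    return Pedigree(family_id=family_id, members=members)


# ---------------------------------------------------------------------------
# genetic map


def build_map(config: SimulationConfig) -> GeneticMap:
    """Evenly spaced markers over equal-length autosomes (plus X when the
    causal model is X-linked); 1 cM is mapped to 1 Mb of physical distance."""
    chroms, ids, cms, bps = [], [], [], []
    per_chrom = config.map_length_cM / config.n_chromosomes
    n_per = int(round(per_chrom / config.marker_spacing_cM)) + 1
    chrom_names = [str(c) for c in range(1, config.n_chromosomes + 1)]
    lengths = {c: per_chrom for c in chrom_names}
    if config.causal_model == "x_linked":
        chrom_names.append("X")
        lengths["X"] = config.x_length_cM
    for chrom in chrom_names:
        n = int(round(lengths[chrom] / config.marker_spacing_cM)) + 1
        for j in range(n):
            cm = j * config.marker_spacing_cM
            chroms.append(chrom)
            ids.append(f"m{chrom}_{j}")
            cms.append(cm)
            bps.append(int(round(cm * 1_000_000)) + 1)
    return GeneticMap(
        marker_ids=np.array(ids, dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        position_bp=np.array(bps, dtype=np.int64),
        position_cM=np.array(cms, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# meiosis


def meiosis(parent_haplotypes, gmap: GeneticMap, rng: np.random.Generator,
            chromosomes: Optional[list[str]] = None):
    """One gamete from a pair of parental haplotypes.

    ``parent_haplotypes`` is a pair of (alleles, origins) arrays over the
    map.  Per chromosome the number of crossovers is Poisson(length_cM/100),
    crossover positions are uniform in cM, and the gamete switches source
    haplotype at each crossover starting from a random one.
    Returns (alleles, origins) arrays for the gamete.
    """
    (al0, or0), (al1, or1) = parent_haplotypes
    alleles = np.empty(len(gmap), dtype=np.uint8)
    origins = np.empty(len(gmap), dtype=np.int64)
    for chrom, sl in gmap.chromosome_slices().items():
        if chromosomes is not None and chrom not in chromosomes:
            alleles[sl] = al0[sl]
            origins[sl] = or0[sl]
            continue
        cm = gmap.position_cM[sl]
        length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        n_x = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(cm[0], cm[-1], size=n_x)) if n_x else np.empty(0)
        # source haplotype index per marker: parity of crossovers passed
        source = (np.searchsorted(cuts, cm, side="right") + rng.integers(2)) % 2
        take1 = source.astype(bool)
        alleles[sl] = np.where(take1, al1[sl], al0[sl])
        origins[sl] = np.where(take1, or1[sl], or0[sl])
    return alleles, origins


# ---------------------------------------------------------------------------
# inbreeding coefficient


def kinship(pedigree: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient by the recursive (tabular) algorithm."""
    byid = pedigree.by_id()
    depth: dict[str, int] = {}
    for m in pedigree.topological_order():
        parents = [p for p in (m.father_id, m.mother_id) if p is not None]
        depth[m.individual_id] = 1 + max((depth[p] for p in parents), default=-1)

    cache: dict[frozenset, float] = {}

    def phi(x: str, y: str) -> float:
        key = frozenset((x, y))
        if key in cache:
            return cache[key]
        if x == y:
            m = byid[x]
            f = (
                phi(m.father_id, m.mother_id)
                if m.father_id is not None and m.mother_id is not None
                else 0.0
            )
            val = 0.5 * (1 + f)
        else:
            # recurse through the parents of the later-generation individual
            x_, y_ = (x, y) if depth[x] >= depth[y] else (y, x)
            m = byid[x_]
            val = 0.0
            for pid in (m.father_id, m.mother_id):
                val += 0.5 * phi(pid, y_) if pid is not None else 0.0
        cache[key] = val
        return val

    return phi(a, b)


def inbreeding_coefficient(pedigree: Pedigree, individual: str) -> float:
    """F = kinship of the individual's parents (0 for a founder)."""
    m = pedigree.by_id()[individual]
    if m.father_id is None or m.mother_id is None:
        return 0.0
    return kinship(pedigree, m.father_id, m.mother_id)


# ---------------------------------------------------------------------------
# gene dropping


def _drop_haplotypes(pedigree: Pedigree, gmap: GeneticMap, config: SimulationConfig,
                     rng: np.random.Generator):
    """Founder draws + descent; returns per-individual [(alleles, origins) x2].

    On the X chromosome males carry a single haplotype, stored twice; a
    father transmits his X to daughters unrecombined and nothing to sons.
    """
    n = len(gmap)
    p_alt = rng.uniform(*config.founder_maf, size=n)
    x_mask = gmap.chromosomes == "X"
    has_x = bool(x_mask.any())

    haps: dict[str, list] = {}
    next_origin = 0
    for m in pedigree.topological_order():
        iid = m.individual_id
        if m.father_id is None:
            pair = []
            for _ in range(2):
                al = (rng.random(n) < p_alt).astype(np.uint8)
                orig = np.full(n, next_origin, dtype=np.int64)
                next_origin += 1
                pair.append((al, orig))
            if has_x and m.sex == "male":
                # single X: mirror haplotype 0 on the X in the second slot
                al1, or1 = pair[1]
                al1[x_mask] = pair[0][0][x_mask]
                or1[x_mask] = pair[0][1][x_mask]
            haps[iid] = pair
        else:
            father_h, mother_h = haps[m.father_id], haps[m.mother_id]
            pat = meiosis(father_h, gmap, rng)
            mat = meiosis(mother_h, gmap, rng)
            if has_x:
                if m.sex == "male":
                    # X from the mother only; paternal X slot mirrors it
                    pat[0][x_mask] = mat[0][x_mask]
                    pat[1][x_mask] = mat[1][x_mask]
                else:
                    # father's X passes without recombination
                    pat[0][x_mask] = father_h[0][0][x_mask]
                    pat[1][x_mask] = father_h[0][1][x_mask]
            haps[iid] = [pat, mat]
    return haps


def _autozygous_runs(pedigree: Pedigree, gmap: GeneticMap, haps
                     ) -> dict[str, list[tuple[str, int, int]]]:
    """Truth-IBD runs: maximal intervals where both haplotype origins match."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for m in pedigree.members:
        (al0, or0), (al1, or1) = haps[m.individual_id]
        same = or0 == or1
        runs: list[tuple[str, int, int]] = []
        for chrom, sl in gmap.chromosome_slices().items():
            if chrom == "X":
                continue  # trivially matched for males; excluded throughout
            g = same[sl]
            if not g.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], g.astype(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2] - 1):
                runs.append((chrom, sl.start + int(a), sl.start + int(b)))
        out[m.individual_id] = runs
    return out


def _genotype_matrix(pedigree: Pedigree, gmap: GeneticMap, haps,
                     config: SimulationConfig, rng: np.random.Generator
                     ) -> GenotypeMatrix:
    sample_ids = [m.individual_id for m in pedigree.members]
    sex = {m.individual_id: m.sex for m in pedigree.members}
    calls = np.empty((len(sample_ids), len(gmap)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        (al0, _), (al1, _) = haps[sid]
        calls[i] = (al0 + al1).astype(np.int8)
    x_mask = gmap.chromosomes == "X"
    if config.genotype_error_rate > 0:
        err = rng.random(calls.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
        # errors must not create het calls on the male X
        for i, sid in enumerate(sample_ids):
            if sex[sid] == "male" and x_mask.any():
                bad = x_mask & (calls[i] == HET)
                calls[i, bad] = HOM_REF
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)
    return GenotypeMatrix(sample_ids=sample_ids, map=gmap, calls=calls, sex=sex)


# ---------------------------------------------------------------------------
# variant tables


def _variant_genotypes(pedigree: Pedigree, haps, marker: int, carrier_origins: set,
                       chrom: str) -> dict[str, str]:
    gts = {}
    for m in pedigree.members:
        (al0, or0), (al1, or1) = haps[m.individual_id]
        n_alt = int(or0[marker] in carrier_origins) + int(or1[marker] in carrier_origins)
        if chrom == "X" and m.sex == "male":
            gts[m.individual_id] = "hemi_alt" if n_alt else "hemi_ref"
        else:
            gts[m.individual_id] = ("hom_ref", "het", "hom_alt")[n_alt]
    return gts


def _random_snv(rng) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


_CSQ_MIX = (
    ("coding_nonsynonymous", 0.60),
    ("coding_synonymous", 0.30),
    ("splice_site", 0.05),
    ("frameshift", 0.05),
)


def _background_variants(pedigree: Pedigree, gmap: GeneticMap, haps,
                         config: SimulationConfig, rng: np.random.Generator,
                         founder_hap_origins: list[int],
                         exclude_markers: set[int]
                         ) -> tuple[list[VariantRecord], set]:
    """Background exome variation: common catalogued variants plus rare
    founder-haplotype-borne ones, with a fixed consequence mix."""
    n_genes = max(1, int(0.9 * config.n_background_variants))
    autos = np.flatnonzero(gmap.chromosomes != "X")
    gene_marker = {
        g: int(rng.choice(autos)) for g in range(n_genes)
    }
    csq_names = [c for c, _ in _CSQ_MIX]
    csq_p = np.array([p for _, p in _CSQ_MIX])
    catalog: set = set()
    records: list[VariantRecord] = []
    used_bp: set[tuple[str, int]] = set()
    for _ in range(config.n_background_variants):
        gene = int(rng.integers(n_genes))
        marker = gene_marker[gene]
        if marker in exclude_markers:
            continue
        chrom = str(gmap.chromosomes[marker])
        base_bp = int(gmap.position_bp[marker])
        bp = base_bp + int(rng.integers(1, 90_000))
        while (chrom, bp) in used_bp:
            bp += 1
        used_bp.add((chrom, bp))
        ref, alt = _random_snv(rng)
        csq = str(rng.choice(csq_names, p=csq_p))
        vclass = "indel" if csq == "frameshift" else "snp"
        common = rng.random() < config.background_common_fraction
        if common:
            freq = rng.uniform(0.05, 0.5)
            carriers = {
                o for o in founder_hap_origins if rng.random() < freq
            }
            if not carriers:
                carriers = {int(rng.choice(founder_hap_origins))}
            ctrl_alt = int(rng.binomial(1400, freq))
            ctrl_hom = int(rng.binomial(700, freq * freq))
        else:
            carriers = {int(rng.choice(founder_hap_origins))}
            freq = rng.uniform(0.0, 0.003)
            ctrl_alt = int(rng.binomial(1400, freq))
            ctrl_hom = 0
        gts = _variant_genotypes(pedigree, haps, marker, carriers, chrom)
        rec = VariantRecord(
            chromosome=chrom,
            position_bp=bp,
            ref_allele=ref,
            alt_allele=alt,
            gene=f"GENE{gene:04d}",
            consequence=csq,
            variant_class=vclass,
            mapping_quality=float(rng.uniform(20, 60)),
            known_variant=common,
            genotypes=gts,
            annotations={
                "brain_expressed": bool(rng.random() < 0.5),
                "known_disorder_gene": bool(rng.random() < 0.1),
            },
            control_counts=ControlCounts(
                alt_alleles=min(ctrl_alt, 1400),
                total_chromosomes=1400,
                homozygotes=ctrl_hom,
            ),
        )
        records.append(rec)
        if common:
            catalog.add(rec.key)
    return records, catalog


class ImplantError(RuntimeError):
    """No marker satisfies the causal-placement constraints."""


def _implant_site_hom(pedigree: Pedigree, gmap: GeneticMap, haps,
                      config: SimulationConfig, rng) -> tuple[int, set]:
    """Marker + carrier origin for a homozygous-recessive causal variant."""
    aff = [m.individual_id for m in pedigree.affected()]
    unaff = [m.individual_id for m in pedigree.unaffected()]
    ors = {s: (haps[s][0][1], haps[s][1][1]) for s in pedigree.by_id()}

    o0 = np.stack([ors[s][0] for s in aff])
    o1 = np.stack([ors[s][1] for s in aff])
    autoz = np.all(o0 == o0[0], axis=0) & np.all(o1 == o0[0], axis=0)
    autoz &= gmap.chromosomes != "X"

    if config.causal_placement == "in_autozygous_segment":
        # restrict to shared autozygous runs long enough to be detectable
        keep = np.zeros(len(gmap), dtype=bool)
        for chrom, sl in gmap.chromosome_slices().items():
            g = autoz[sl]
            edges = np.flatnonzero(np.diff(np.concatenate(([0], g.astype(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2] - 1):
                if gmap.position_cM[sl.start + b] - gmap.position_cM[sl.start + a] \
                        >= config.causal_min_segment_cM:
                    # exclude the terminal marker so the variant position
                    # (placed between this marker and the next) stays inside
                    keep[sl.start + a : sl.start + b] = True
        candidates = np.flatnonzero(keep)
    else:
        candidates = np.flatnonzero(autoz)

    father = pedigree.by_id()[aff[0]].father_id
    mother = pedigree.by_id()[aff[0]].mother_id
    good = []
    for m in candidates:
        h = int(o0[0][m])
        fo = [int(ors[father][i][m]) for i in range(2)]
        mo = [int(ors[mother][i][m]) for i in range(2)]
        if fo.count(h) != 1 or mo.count(h) != 1:
            continue
        if any(
            ors[u][0][m] == h and ors[u][1][m] == h for u in unaff
        ):
            continue
        good.append((m, h))
    if not good:
        raise ImplantError("no shared autozygous site compatible with the model")
    return good[int(rng.integers(len(good)))]


def implant_causal(pedigree: Pedigree, gmap: GeneticMap, haps,
                   config: SimulationConfig, rng) -> list[VariantRecord]:
    """Create the causal variant record(s) for the configured model."""
    model = config.causal_model
    aff = [m.individual_id for m in pedigree.affected()]
    unaff = [m.individual_id for m in pedigree.unaffected()]
    byid = pedigree.by_id()
    father = byid[aff[0]].father_id
    mother = byid[aff[0]].mother_id

    def make(marker, carriers, csq="coding_nonsynonymous", suffix=""):
        chrom = str(gmap.chromosomes[marker])
        ref, alt = _random_snv(rng)
        return VariantRecord(
            chromosome=chrom,
            position_bp=int(gmap.position_bp[marker]) + 50_000 + len(suffix),
            ref_allele=ref,
            alt_allele=alt,
            gene=config.causal_gene,
            consequence=csq,
            variant_class="snp",
            mapping_quality=55.0,
            known_variant=False,
            genotypes=_variant_genotypes(pedigree, haps, marker, carriers, chrom),
            annotations={"brain_expressed": True, "known_disorder_gene": False},
            control_counts=ControlCounts(alt_alleles=1, total_chromosomes=1344, homozygotes=0),
        )

    if model == "hom_recessive":
        marker, h = _implant_site_hom(pedigree, gmap, haps, config, rng)
        return [make(marker, {h})]

    if model == "compound_het":
        autos = np.flatnonzero(gmap.chromosomes != "X")
        order = rng.permutation(autos)
        for m in order:
            m = int(m)
            pat = {s: int(haps[s][0][1][m]) for s in aff}
            mat = {s: int(haps[s][1][1][m]) for s in aff}
            if len(set(pat.values())) != 1 or len(set(mat.values())) != 1:
                continue
            oF, oM = pat[aff[0]], mat[aff[0]]
            if oF == oM:
                continue
            f_ors = [int(haps[father][i][1][m]) for i in range(2)]
            m_ors = [int(haps[mother][i][1][m]) for i in range(2)]
            if f_ors.count(oF) != 1 or m_ors.count(oM) != 1:
                continue
            bad = False
            for u in unaff:
                u_ors = {int(haps[u][i][1][m]) for i in range(2)}
                if oF in u_ors and oM in u_ors:
                    bad = True
                    break
            if bad:
                continue
            va = make(m, {oF})
            vb = make(m, {oM}, suffix="b")
            return [va, vb]
        raise ImplantError("no site compatible with a trans compound-het implant")

    if model == "x_linked":
        x_idx = np.flatnonzero(gmap.chromosomes == "X")
        if len(x_idx) == 0:
            raise ImplantError("x_linked model requires an X chromosome in the map")
        order = rng.permutation(x_idx)
        for m in order:
            m = int(m)
            sons = [s for s in aff if byid[s].sex == "male"]
            if not sons:
                raise ImplantError("x_linked model requires affected males")
            ox = {int(haps[s][0][1][m]) for s in sons}
            if len(ox) != 1:
                continue
            h = ox.pop()
            m_ors = [int(haps[mother][i][1][m]) for i in range(2)]
            if m_ors.count(h) != 1:
                continue
            f_ors = [int(haps[father][i][1][m]) for i in range(2)]
            if h in f_ors:
                continue
            bad = False
            for u in unaff:
                if byid[u].sex == "male" and int(haps[u][0][1][m]) == h:
                    bad = True
                    break
            if bad:
                continue
            return [make(m, {h})]
        raise ImplantError("no X site compatible with the x_linked implant")

    raise ValueError(f"unknown causal model {model!r}")


# ---------------------------------------------------------------------------
# top level


def simulate_family(config: SimulationConfig, family_id: str = "FAM1",
                    max_attempts: int = 100) -> SimulatedFamily:
    """Simulate one family end to end; reproducible from ``config.seed``.

    When a causal implant is requested, descent is re-simulated (up to
    ``max_attempts`` times) until a compatible site exists.
    """
    rng = np.random.default_rng(config.seed)
    pedigree = build_pedigree(config, family_id)
    gmap = build_map(config)
    founders = pedigree.founders()
    if config.topology != "outbred" and config.causal_model == "hom_recessive" \
            and config.causal_placement == "in_autozygous_segment" and len(founders) < 4:
        raise ValueError("a cousin loop needs at least four founders")

    last_err: Optional[Exception] = None
    for _ in range(max_attempts):
        haps = _drop_haplotypes(pedigree, gmap, config, rng)
        causal: list[VariantRecord] = []
        if config.causal_model is not None:
            try:
                causal = implant_causal(pedigree, gmap, haps, config, rng)
            except ImplantError as e:
                last_err = e
                continue
        break
    else:
        raise ImplantError(
            f"no compatible causal site after {max_attempts} attempts "
            f"({last_err}); consider more affected sibs or a longer map"
        )

    founder_hap_origins = []
    for f in founders:
        for h in range(2):
            founder_hap_origins.append(int(haps[f.individual_id][h][1][0]))
    founder_hap_origins = sorted(set(founder_hap_origins))

    causal_markers = set()
    for v in causal:
        sl = gmap.chromosome_slices()[v.chromosome]
        local = np.searchsorted(gmap.position_bp[sl], v.position_bp) - 1
        causal_markers.add(sl.start + max(int(local), 0))

    background, catalog = _background_variants(
        pedigree, gmap, haps, config, rng, founder_hap_origins, causal_markers
    )
    variants = background + causal
    variants.sort(key=lambda v: (v.chromosome, v.position_bp))

    matrix = _genotype_matrix(pedigree, gmap, haps, config, rng)
    truth = _autozygous_runs(pedigree, gmap, haps)
    return SimulatedFamily(
        pedigree=pedigree,
        matrix=matrix,
        variants=variants,
        causal_keys=[v.key for v in causal],
        truth_autozygous=truth,
        catalog=catalog,
    )


def truth_autozygous_fraction(family: SimulatedFamily, individual: str) -> float:
    """Fraction of the autosomal map length inside truth-IBD runs."""
    gmap = family.matrix.map
    total = gmap.total_cM(exclude=("X",))
    if total <= 0:
        raise ValueError("degenerate map")
    cm = gmap.position_cM
    covered = sum(
        float(cm[b] - cm[a]) for _, a, b in family.truth_autozygous[individual]
    )
    return covered / total
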