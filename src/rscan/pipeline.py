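"""End-to-end orchestration: simulate or load a family, detect shared runs
of homozygosity, filter and segregate exome variants, prioritize candidate
genes, and assemble the per-family cascade report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as rio
from .core import GenotypeMatrix, Pedigree, VariantRecord
from .prioritize import (
    CandidateGene,
    CascadeReport,
    apply_exclusions,
    build_candidates,
    final_report,
    overlay_roh,
)
from .relatedness import pairwise_relatedness
from .roh import ROHParams, ROHSegment, detect_roh, shared_roh, summarize_homozygosity
from .segregation import (
    SegregationVerdict,
    phase_compound_het,
    segregate_hom_recessive,
    segregate_x_linked,
)
from .simulate import SimulatedFamily, SimulationConfig, simulate_family
from .variant_filter import (
    FilterParams,
    candidate_compound_het,
    candidate_hemizygous_x,
    candidate_homozygous,
    quality_filter,
    remove_known,
)

log = logging.getLogger(__name__)


@dataclass
class FamilyResult:
    family_id: str
    report: CascadeReport
    candidates: list[CandidateGene]
    shared_segments: list[ROHSegment]
    hom_verdicts: list[tuple[VariantRecord, SegregationVerdict]]
    chet_verdicts: dict[str, SegregationVerdict] = field(default_factory=dict)
    x_verdicts: list[tuple[VariantRecord, SegregationVerdict]] = field(default_factory=list)

    @property
    def surviving_genes(self) -> list[str]:
        return [c.gene for c in self.report.survivors]


def run_family(pedigree: Pedigree, matrix: GenotypeMatrix,
               variants: list[VariantRecord],
               catalog: set = frozenset(),
               roh_params: ROHParams = ROHParams(),
               filter_params: FilterParams = FilterParams(),
               control_freq_ceiling_pct: float = 0.5,
               proband: Optional[str] = None) -> FamilyResult:
    """Filtration → segregation → shared-ROH overlay → exclusions for one family."""
    affected = [m.individual_id for m in pedigree.affected()]
    unaffected = [m.individual_id for m in pedigree.unaffected()]
    if not affected:
        raise ValueError(f"family {pedigree.family_id} has no affected member")
    proband = proband or affected[0]
    sex = pedigree.by_id()[proband].sex

    passing = quality_filter(variants, filter_params)
    rare = remove_known(passing, set(catalog))

    hom_stream = candidate_homozygous(rare, proband, filter_params)
    hom_verdicts = [(v, segregate_hom_recessive(v, pedigree)) for v in hom_stream]

    chet_stream = candidate_compound_het(rare, proband, filter_params)
    chet_verdicts = {
        gene: phase_compound_het(vs, pedigree) for gene, vs in chet_stream.items()
    }

    x_verdicts: list[tuple[VariantRecord, SegregationVerdict]] = []
    if sex == "male":
        for v in candidate_hemizygous_x(rare, proband, sex, filter_params):
            x_verdicts.append((v, segregate_x_linked(v, pedigree)))

    shared = shared_roh(matrix, affected, unaffected, roh_params)

    candidates = build_candidates(hom_verdicts, pedigree.family_id)
    overlay_roh(candidates, shared)
    apply_exclusions(candidates, control_freq_ceiling_pct)

    n_segregating = sum(
        1
        for _, v in hom_verdicts
        if v.verdict in ("segregates", "segregates_incomplete")
    )
    report = final_report(
        pedigree.family_id,
        candidates,
        n_wes=len(hom_stream),
        n_designed=len(hom_stream),
        n_ran=len(hom_stream),
        n_validated=len(hom_stream),
        n_segregating=n_segregating,
    )
    return FamilyResult(
        family_id=pedigree.family_id,
        report=report,
        candidates=candidates,
        shared_segments=shared,
        hom_verdicts=hom_verdicts,
        chet_verdicts=chet_verdicts,
        x_verdicts=x_verdicts,
    )


def run_simulated_batch(base_config: SimulationConfig, n_families: int,
                        roh_params: ROHParams = ROHParams(),
                        filter_params: FilterParams = FilterParams()
                        ) -> list[tuple[SimulatedFamily, FamilyResult]]:
    """Independent replicate families with per-family derived seeds."""
    rng = np.random.default_rng(base_config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_families)
    out = []
    for i, s in enumerate(seeds):
        from dataclasses import replace

        cfg = replace(base_config, seed=int(s))
        fam = simulate_family(cfg, family_id=f"FAM{i + 1}")
        res = run_family(
            fam.pedigree, fam.matrix, fam.variants, fam.catalog,
            roh_params, filter_params,
        )
        out.append((fam, res))
    return out


def write_outputs(outdir: Path, fam: SimulatedFamily, res: FamilyResult) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_ped_map(
        [fam.pedigree], fam.matrix,
        outdir / f"{res.family_id}.ped", outdir / f"{res.family_id}.map",
    )
    rio.write_variants_tsv(fam.variants, outdir / f"{res.family_id}.variants.tsv")
    rio.write_roh_bed(res.shared_segments, outdir / f"{res.family_id}.shared_roh.bed")
    cascade = {
        "family": res.family_id,
        "counts": {
            "wes": res.report.n_wes,
            "designed": res.report.n_designed,
            "ran": res.report.n_ran,
            "validated": res.report.n_validated,
            "segregating": res.report.n_segregating,
            "in_roh": res.report.n_in_roh,
        },
        "rates": res.report.percentages(),
        "survivors": [
            {
                "gene": c.gene,
                "in_shared_roh": c.in_shared_roh,
                "roh_size_cM": c.roh_size_cM,
                "control_allele_freq_pct": c.control_allele_freq,
                "control_homozygotes": c.control_homozygotes,
            }
            for c in res.report.survivors
        ],
        "excluded": [
            {"gene": c.gene, "exclusion": c.exclusion, "all": c.all_exclusions}
            for c in res.candidates
            if c.exclusion != "none"
        ],
    }
    with open(outdir / f"{res.family_id}.cascade.json", "w") as fh:
        json.dump(cascade, fh, indent=2, sort_keys=True)


def relatedness_table(matrix: GenotypeMatrix, pedigrees: list[Pedigree],
                      pairs: list[tuple[str, str]]) -> list[dict]:
    rows = []
    for a, b in pairs:
        r = pairwise_relatedness(matrix, a, b, pedigrees=pedigrees)
        rows.append(
            {
                "pair": f"{a},{b}",
                "IBS0": r.ibs0,
                "IBS1": r.ibs1,
                "IBS2": r.ibs2,
                "IBS2*": r.ibs2_star,
                "IBS2*_ratio": r.ibs2_star_ratio,
                "pct_informative": r.pct_informative,
                "Z0": r.z0,
                "Z1": r.z1,
                "Z2": r.z2,
                "PI_HAT": r.pi_hat,
            }
        )
    return rows
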