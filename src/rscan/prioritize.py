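"""Candidate-gene prioritization: overlay segregating variants on shared
runs of homozygosity, apply control-prevalence and annotation exclusions in
a fixed order, and assemble per-family cascade reports.

Exclusion order is fixed — shared-ROH membership, control prevalence,
brain expression, known involvement in another disorder, noncanonical
splice annotation — and the first failing criterion is recorded as *the*
exclusion reason (all failing criteria are additionally retained for the
JSON export).  Unknown annotations never exclude a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import ControlCounts, VariantRecord
from .roh import ROHSegment
from .segregation import SegregationVerdict

EXCLUSION_ORDER = (
    "not_in_roh",
    "prevalent_in_controls",
    "not_brain_expressed",
    "known_other_disorder",
    "noncanonical_splice",
)


@dataclass
class CandidateGene:
    gene: str
    variants: list[VariantRecord]
    family_id: str
    verdict: SegregationVerdict
    in_shared_roh: bool = False
    roh_size_cM: Optional[float] = None
    control_allele_freq: Optional[float] = None  # percent of chromosomes
    control_homozygotes: Optional[int] = None
    exclusion: str = "none"
    all_exclusions: list[str] = field(default_factory=list)


def overlay_roh(candidates: list[CandidateGene],
                shared_intervals: list[ROHSegment]) -> list[CandidateGene]:
    """Mark each candidate by whether its variant(s) fall inside a shared ROH.

    A candidate is inside when every one of its variants lies within some
    shared interval (bp coordinates); the recorded ROH size is that of the
    covering interval.
    """
    for c in candidates:
        sizes = []
        inside_all = True
        for v in c.variants:
            hit = next(
                (
                    seg
                    for seg in shared_intervals
                    if seg.chromosome == v.chromosome
                    and seg.start_bp <= v.position_bp <= seg.end_bp
                ),
                None,
            )
            if hit is None:
                inside_all = False
            else:
                sizes.append(hit.length_cM)
        c.in_shared_roh = inside_all and bool(c.variants)
        c.roh_size_cM = max(sizes) if (c.in_shared_roh and sizes) else None
    return candidates


def control_prevalence(variant: VariantRecord,
                       control_genotypes: Optional[dict[str, str]] = None
                       ) -> tuple[float, int]:
    """(alt-allele frequency as percent of control chromosomes, homozygotes).

    Counts come from ``variant.control_counts`` when present, otherwise from
    a supplied control genotype dictionary.
    """
    cc = variant.control_counts
    if cc is None and control_genotypes is not None:
        alt = {"het": 1, "hom_alt": 2, "hemi_alt": 1}
        chroms = {"hom_ref": 2, "het": 2, "hom_alt": 2, "hemi_ref": 1, "hemi_alt": 1}
        cc = ControlCounts(
            alt_alleles=sum(alt.get(g, 0) for g in control_genotypes.values()),
            total_chromosomes=sum(chroms.get(g, 0) for g in control_genotypes.values()),
            homozygotes=sum(g == "hom_alt" for g in control_genotypes.values()),
        )
    if cc is None or cc.total_chromosomes == 0:
        raise ValueError("no control chromosomes available")
    return 100.0 * cc.alt_alleles / cc.total_chromosomes, cc.homozygotes


def apply_exclusions(candidates: list[CandidateGene],
                     control_freq_ceiling_pct: float = 0.5) -> list[CandidateGene]:
    """Record exclusion reasons; candidates with ``exclusion == 'none'`` survive.

    Control prevalence excludes when any control homozygote exists or the
    allele frequency exceeds the ceiling (percent of chromosomes).
    """
    for c in candidates:
        failures = []
        if not c.in_shared_roh:
            failures.append("not_in_roh")

        freqs, homs = [], []
        for v in c.variants:
            if v.control_counts is not None and v.control_counts.total_chromosomes > 0:
                f, h = control_prevalence(v)
                freqs.append(f)
                homs.append(h)
        if freqs:
            c.control_allele_freq = max(freqs)
            c.control_homozygotes = max(homs)
            if c.control_homozygotes > 0 or c.control_allele_freq > control_freq_ceiling_pct:
                failures.append("prevalent_in_controls")

        def ann(key):
            vals = [v.annotations.get(key) for v in c.variants]
            vals = [x for x in vals if x is not None]
            return vals

        be = ann("brain_expressed")
        if be and not any(be):
            failures.append("not_brain_expressed")
        kd = ann("known_disorder_gene")
        if kd and any(kd):
            failures.append("known_other_disorder")
        nc = ann("noncanonical_splice")
        if nc and all(nc):
            failures.append("noncanonical_splice")

        c.all_exclusions = sorted(failures, key=EXCLUSION_ORDER.index)
        c.exclusion = c.all_exclusions[0] if c.all_exclusions else "none"
    return candidates


def build_candidates(variants_with_verdicts: list[tuple[VariantRecord, SegregationVerdict]],
                     family_id: str) -> list[CandidateGene]:
    """Group segregating variants into per-gene candidates."""
    by_gene: dict[str, CandidateGene] = {}
    for v, verdict in variants_with_verdicts:
        if verdict.verdict not in ("segregates", "segregates_incomplete"):
            continue
        c = by_gene.get(v.gene)
        if c is None:
            by_gene[v.gene] = CandidateGene(
                gene=v.gene, variants=[v], family_id=family_id, verdict=verdict
            )
        else:
            c.variants.append(v)
    return list(by_gene.values())


# ---------------------------------------------------------------------------
# cascade report


@dataclass
class CascadeReport:
    """Per-family counts at each stage of the filtration cascade, in the
    order exome calls → assays designed → assays run → validated →
    segregating → inside a shared ROH, plus the surviving gene list."""

    family_id: str
    n_wes: int
    n_designed: int
    n_ran: int
    n_validated: int
    n_segregating: int
    n_in_roh: int
    survivors: list[CandidateGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        stages = [self.n_wes, self.n_designed, self.n_ran, self.n_validated,
                  self.n_segregating, self.n_in_roh]
        if any(b > a for a, b in zip(stages, stages[1:])):
            raise ValueError("cascade counts must be non-increasing")

    def percentages(self) -> dict[str, Optional[int]]:
        """Stage-to-stage success rates as whole percents (design rate =
        designed/exome calls, run rate = run/designed, validation rate =
        validated/run).  Rounded to the nearest percent with exact halves
        toward zero, in integer arithmetic."""

        def pct(num, den):
            if not den:
                return None
            # ceil((100*num - den/2) / den) == round-half-down
            a = 200 * num - den
            return -((-a) // (2 * den))

        return {
            "design_rate": pct(self.n_designed, self.n_wes),
            "run_rate": pct(self.n_ran, self.n_designed),
            "validation_rate": pct(self.n_validated, self.n_ran),
        }


def final_report(family_id: str, candidates: list[CandidateGene],
                 n_wes: int, n_designed: int, n_ran: int, n_validated: int,
                 n_segregating: int) -> CascadeReport:
    survivors = [c for c in candidates if c.exclusion == "none"]
    n_in_roh = sum(1 for c in candidates if c.in_shared_roh)
    return CascadeReport(
        family_id=family_id,
        n_wes=n_wes,
        n_designed=n_designed,
        n_ran=n_ran,
        n_validated=n_validated,
        n_segregating=n_segregating,
        n_in_roh=min(n_in_roh, n_segregating),
        survivors=survivors,
    )
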