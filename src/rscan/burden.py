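"""Case/control recessive burden analysis.

An individual is a recessive carrier for a gene set when, in any gene of
the set, they are homozygous-alt for a qualifying variant or heterozygous
for at least two distinct qualifying variants (unphased compound
heterozygosity — the screen cohort has no parents, so trans configuration
cannot be established and is not required).  Qualifying variants are the
missense/deleterious classes with cohort allele frequency at or below the
ceiling (5% by default, computed in the combined case+control cohort).
Enrichment of carriers in cases is tested with a one-tailed Fisher's exact
test, evaluated in log-space via the hypergeometric tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .core import VariantRecord

log = logging.getLogger(__name__)

QUALIFYING_CLASSES = frozenset({"coding_nonsynonymous", "frameshift", "splice_site"})


@dataclass(frozen=True)
class BurdenResult:
    gene_set: tuple[str, ...]
    n_cases: int
    n_controls: int
    carriers_cases: int
    carriers_controls: int
    pct_cases: float
    pct_controls: float
    p_one_tailed: float


def _cohort_allele_freq(v: VariantRecord, cohort: list[str]) -> float:
    alt = {"het": 1, "hom_alt": 2, "hemi_alt": 1}
    chroms = {"hom_ref": 2, "het": 2, "hom_alt": 2, "hemi_ref": 1, "hemi_alt": 1}
    n_alt = n_chrom = 0
    for s in cohort:
        g = v.genotypes.get(s, "missing")
        n_alt += alt.get(g, 0)
        n_chrom += chroms.get(g, 0)
    return n_alt / n_chrom if n_chrom else 0.0


def qualifying_variants(variants: list[VariantRecord], cohort: list[str],
                        gene_set: list[str], maf_ceiling: float = 0.05
                        ) -> list[VariantRecord]:
    genes = set(gene_set)
    return [
        v
        for v in variants
        if v.gene in genes
        and v.consequence in QUALIFYING_CLASSES
        and _cohort_allele_freq(v, cohort) <= maf_ceiling
    ]


def count_recessive_carriers(variants: list[VariantRecord], cohort: list[str],
                             gene_set: list[str], maf_ceiling: float = 0.05,
                             *, full_cohort: list[str] | None = None) -> int:
    """Number of cohort members carrying a qualifying recessive genotype.

    ``full_cohort`` is the population over which allele frequencies are
    computed (defaults to ``cohort``); an individual is counted at most once
    regardless of how many genes qualify.
    """
    if not cohort:
        raise ValueError("empty cohort")
    qual = qualifying_variants(variants, full_cohort or cohort, gene_set, maf_ceiling)
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in qual:
        by_gene.setdefault(v.gene, []).append(v)

    carriers = 0
    for s in cohort:
        for gene, vs in by_gene.items():
            hom = any(v.genotypes.get(s) in ("hom_alt", "hemi_alt") for v in vs)
            het_keys = {v.key for v in vs if v.genotypes.get(s) == "het"}
            if hom or len(het_keys) >= 2:
                carriers += 1
                break
    return carriers


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher's exact p for enrichment of the top-left cell.

    Table layout: rows = cases/controls, columns = carriers/non-carriers::

        a  b      a = case carriers
        c  d      c = control carriers

    Returns P(X >= a) for X hypergeometric with the observed margins,
    summed in log-space for numerical stability.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0

    lg = math.lgamma

    def log_comb(nn: int, kk: int) -> float:
        return lg(nn + 1) - lg(kk + 1) - lg(nn - kk + 1)

    denom = log_comb(n, col1)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    # log-sum-exp over the upper tail x = a..hi
    terms = [
        log_comb(row1, x) + log_comb(n - row1, col1 - x) - denom
        for x in range(max(a, lo), hi + 1)
    ]
    if not terms:
        return 0.0
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    return min(p, 1.0)


def burden_test(variants: list[VariantRecord], cases: list[str], controls: list[str],
                gene_set: list[str], maf_ceiling: float = 0.05) -> BurdenResult:
    """Pooled gene-set recessive burden with a one-tailed Fisher's exact test."""
    if not cases or not controls:
        raise ValueError("both cohorts must be non-empty")
    present = {v.gene for v in variants}
    for g in gene_set:
        if g not in present:
            log.warning("gene %s absent from the variant table; zero carriers", g)
    full = list(cases) + list(controls)
    cc = count_recessive_carriers(variants, cases, gene_set, maf_ceiling, full_cohort=full)
    ct = count_recessive_carriers(variants, controls, gene_set, maf_ceiling, full_cohort=full)
    p = fisher_one_tailed(cc, len(cases) - cc, ct, len(controls) - ct)
    return BurdenResult(
        gene_set=tuple(gene_set),
        n_cases=len(cases),
        n_controls=len(controls),
        carriers_cases=cc,
        carriers_controls=ct,
        pct_cases=100.0 * cc / len(cases),
        pct_controls=100.0 * ct / len(controls),
        p_one_tailed=p,
    )
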