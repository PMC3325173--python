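"""Per-family inheritance-model tests.

Three models are checked against the observed family genotypes:

* homozygous recessive — every affected child homozygous-alt, both parents
  heterozygous carriers, no unaffected sibling homozygous-alt;
* compound heterozygous — at least one pair of gene variants in trans (one
  transmitted from each parent), shared by all affected siblings, with no
  unaffected sibling carrying both members of the pair;
* X-linked hemizygous — affected males hemizygous-alt, mother a
  heterozygous carrier, father hemizygous-reference (or untyped), no
  unaffected brother hemizygous-alt.

A genotype configuration that is impossible under Mendelian transmission
(e.g. a homozygous-alt child of a homozygous-reference parent) yields
``mendel_error``.  Missing genotypes in required members demote the verdict
to ``segregates_incomplete`` rather than silently passing or failing;
monozygotic-twin groups contribute a single informative genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Individual, Pedigree, VariantRecord

VERDICTS = ("segregates", "segregates_incomplete", "fails", "unphaseable", "mendel_error")


@dataclass(frozen=True)
class SegregationVerdict:
    variants: tuple[tuple, ...]  # variant keys
    model: str  # "hom_recessive" | "compound_het" | "x_linked"
    verdict: str
    detail: dict = field(default_factory=dict, hash=False, compare=False)


def _dedupe_mz(members: list[Individual], pedigree: Pedigree) -> list[Individual]:
    """Collapse each monozygotic-twin group to its first member."""
    seen_groups: set[frozenset] = set()
    out = []
    for m in members:
        grp = next((g for g in pedigree.mz_twin_groups if m.individual_id in g), None)
        if grp is not None:
            if grp in seen_groups:
                continue
            seen_groups.add(grp)
        out.append(m)
    return out


def _parents_of_affected(pedigree: Pedigree) -> tuple[str, str]:
    aff = pedigree.affected()
    if not aff:
        raise ValueError(f"family {pedigree.family_id} has no affected member")
    fids = {m.father_id for m in aff}
    mids = {m.mother_id for m in aff}
    if len(fids) != 1 or len(mids) != 1 or None in fids or None in mids:
        raise ValueError("affected members must share both genotyped parents")
    return fids.pop(), mids.pop()


def segregate_hom_recessive(variant: VariantRecord, pedigree: Pedigree) -> SegregationVerdict:
    """Test the homozygous-recessive model for one autosomal variant."""
    father, mother = _parents_of_affected(pedigree)
    gt = variant.genotypes
    detail = {m.individual_id: gt.get(m.individual_id, "missing") for m in pedigree.members}

    # Mendelian impossibility: hom_alt child with a hom_ref parent
    for child in pedigree.members:
        if child.father_id == father and child.mother_id == mother:
            if gt.get(child.individual_id) == "hom_alt" and (
                gt.get(father) == "hom_ref" or gt.get(mother) == "hom_ref"
            ):
                return SegregationVerdict(
                    (variant.key,), "hom_recessive", "mendel_error", detail
                )

    affected = _dedupe_mz(pedigree.affected(), pedigree)
    unaffected = pedigree.unaffected()

    incomplete = False
    for m in affected:
        g = gt.get(m.individual_id, "missing")
        if g == "missing":
            incomplete = True
        elif g != "hom_alt":
            return SegregationVerdict((variant.key,), "hom_recessive", "fails", detail)
    for pid in (father, mother):
        g = gt.get(pid, "missing")
        if g == "missing":
            incomplete = True
        elif g != "het":
            return SegregationVerdict((variant.key,), "hom_recessive", "fails", detail)
    for m in unaffected:
        if gt.get(m.individual_id) == "hom_alt":
            return SegregationVerdict((variant.key,), "hom_recessive", "fails", detail)

    verdict = "segregates_incomplete" if incomplete else "segregates"
    return SegregationVerdict((variant.key,), "hom_recessive", verdict, detail)


def _carries(g: str | None) -> bool:
    return g in ("het", "hom_alt", "hemi_alt")


def phase_compound_het(gene_variants: list[VariantRecord], pedigree: Pedigree
                       ) -> SegregationVerdict:
    """Trio-phase candidate compound-heterozygous pairs within one gene.

    Every unordered pair of variants het in all affected siblings is tested
    for trans configuration: one member transmitted by the father only, the
    other by the mother only.  The gene segregates if any pair passes; a
    pair with both variants from the same parent is cis (fails); pairs whose
    parental origin cannot be resolved are unphaseable.
    """
    father, mother = _parents_of_affected(pedigree)
    keys = tuple(v.key for v in gene_variants)
    affected = _dedupe_mz(pedigree.affected(), pedigree)
    unaffected = pedigree.unaffected()
    detail: dict = {"gene": gene_variants[0].gene if gene_variants else None}

    if len({v.key for v in gene_variants}) < 2:
        return SegregationVerdict(keys, "compound_het", "fails", detail)

    any_unphaseable = False
    parent_typed = False
    for i in range(len(gene_variants)):
        for j in range(i + 1, len(gene_variants)):
            va, vb = gene_variants[i], gene_variants[j]
            if va.key == vb.key:
                continue
            if not all(
                all(v.genotypes.get(m.individual_id) == "het" for m in affected)
                for v in (va, vb)
            ):
                continue

            fa, fb = va.genotypes.get(father), vb.genotypes.get(father)
            ma, mb = va.genotypes.get(mother), vb.genotypes.get(mother)
            if any(g not in (None, "missing") for g in (fa, fb, ma, mb)):
                parent_typed = True

            def origin(gf, gm):
                f, m = _carries(gf), _carries(gm)
                if f and not m:
                    return "father"
                if m and not f:
                    return "mother"
                if not f and not m:
                    if gf in (None, "missing") or gm in (None, "missing"):
                        return "unknown"
                    return "untransmitted"
                return "ambiguous"

            oa, ob = origin(fa, ma), origin(fb, mb)
            if "unknown" in (oa, ob) or "ambiguous" in (oa, ob):
                any_unphaseable = True
                continue
            if "untransmitted" in (oa, ob):
                continue  # apparent de novo; outside this model
            if oa == ob:
                continue  # cis: both from one parent
            # trans pair: reject if any unaffected sibling carries both
            if any(
                _carries(va.genotypes.get(u.individual_id))
                and _carries(vb.genotypes.get(u.individual_id))
                for u in unaffected
            ):
                continue
            detail["trans_pair"] = (va.key, vb.key)
            return SegregationVerdict(keys, "compound_het", "segregates", detail)

    if not parent_typed:
        return SegregationVerdict(keys, "compound_het", "unphaseable", detail)
    if any_unphaseable:
        return SegregationVerdict(keys, "compound_het", "unphaseable", detail)
    return SegregationVerdict(keys, "compound_het", "fails", detail)


def segregate_x_linked(variant: VariantRecord, pedigree: Pedigree) -> SegregationVerdict:
    """Test the X-linked hemizygous model for one X variant in a male proband."""
    if variant.chromosome != "X":
        raise ValueError("X-linked model requires an X-chromosome variant")
    father, mother = _parents_of_affected(pedigree)
    gt = variant.genotypes
    byid = pedigree.by_id()
    detail = {m.individual_id: gt.get(m.individual_id, "missing") for m in pedigree.members}
    keys = (variant.key,)

    affected_males = [
        m for m in _dedupe_mz(pedigree.affected(), pedigree) if m.sex == "male"
    ]
    if not affected_males:
        raise ValueError("X-linked model requires an affected male")

    if gt.get(mother) == "hom_ref" and any(
        gt.get(m.individual_id) == "hemi_alt" for m in affected_males
    ):
        # possible de novo or cell-line artifact; flagged, not segregating
        return SegregationVerdict(keys, "x_linked", "mendel_error", detail)

    incomplete = False
    for m in affected_males:
        g = gt.get(m.individual_id, "missing")
        if g == "missing":
            incomplete = True
        elif g != "hemi_alt":
            return SegregationVerdict(keys, "x_linked", "fails", detail)
    gm = gt.get(mother, "missing")
    if gm == "missing":
        incomplete = True
    elif gm != "het":
        return SegregationVerdict(keys, "x_linked", "fails", detail)
    gf = gt.get(father, "missing")
    if gf not in ("missing", "hemi_ref", None):
        return SegregationVerdict(keys, "x_linked", "fails", detail)
    for u in pedigree.unaffected():
        if byid[u.individual_id].sex == "male" and gt.get(u.individual_id) == "hemi_alt":
            return SegregationVerdict(keys, "x_linked", "fails", detail)

    verdict = "segregates_incomplete" if incomplete else "segregates"
    return SegregationVerdict(keys, "x_linked", verdict, detail)
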