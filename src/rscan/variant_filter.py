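"""Per-exome variant filtration: quality thresholds, common-variant removal,
consequence classification, and extraction of the three candidate streams
(homozygous-recessive, compound-heterozygous, X-hemizygous).

Quality thresholds are strict: a SNP survives only with mapping quality
above 25, an indel only above 10.  "Rare" at this stage means absent from
the supplied common-variant catalog; control-cohort frequency is applied
later during prioritization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core import VariantRecord

log = logging.getLogger(__name__)

DELETERIOUS_DEFAULT = frozenset({"coding_nonsynonymous", "frameshift", "splice_site"})


@dataclass(frozen=True)
class FilterParams:
    mq_min_snp: float = 25.0
    mq_min_indel: float = 10.0
    deleterious_classes: frozenset = DELETERIOUS_DEFAULT
    splice_window_bp: int = 2

    def __post_init__(self) -> None:
        if self.mq_min_snp < 0 or self.mq_min_indel < 0 or self.splice_window_bp < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class TranscriptModel:
    """A single-transcript gene model with its reference sequence.

    Coordinates are 1-based inclusive.  ``sequence`` is the plus-strand
    reference over [exons[0][0], exons[-1][1]].  Exons must be sorted and
    non-overlapping; the CDS lies within the exon span.
    """

    gene: str
    chromosome: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap or are unsorted")
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS outside exon span")
        span = self.exons[-1][1] - self.exons[0][0] + 1
        if len(self.sequence) != span:
            raise ValueError("sequence length does not match transcript span")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def base_at(self, pos: int) -> str:
        return self.sequence[pos - self.tx_start]

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases, ascending."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            out.extend(range(lo, hi + 1))
        return out

    def cds_sequence(self) -> str:
        seq = "".join(self.base_at(p) for p in self.cds_positions())
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq


# ---------------------------------------------------------------------------
# cascade steps


def quality_filter(variants: list[VariantRecord], params: FilterParams = FilterParams()
                   ) -> list[VariantRecord]:
    """Keep SNPs with MQ strictly above ``mq_min_snp`` and indels strictly
    above ``mq_min_indel``; variants lacking MQ are dropped with a warning."""
    out = []
    for v in variants:
        if v.mapping_quality is None:
            log.warning("variant %s lacks mapping quality; dropped", v.key)
            continue
        threshold = params.mq_min_snp if v.variant_class == "snp" else params.mq_min_indel
        if v.mapping_quality > threshold:
            out.append(v)
    return out


def remove_known(variants: list[VariantRecord],
                 catalog: set[tuple[str, int, str, str]]) -> list[VariantRecord]:
    """Drop exact-allele matches to the common-variant catalog (idempotent).

    Variants already flagged ``known_variant`` are dropped as well, so
    pre-annotated tables work without a sites file.
    """
    return [v for v in variants if not v.known_variant and v.key not in catalog]


def _in_splice_window(pos: int, model: TranscriptModel, window: int) -> bool:
    """True when pos lies in the intron within `window` bp of a junction."""
    for i, (s, e) in enumerate(model.exons):
        if i > 0 and e >= pos:  # acceptor side: intron bases just before exon start
            if s - window <= pos < s:
                return True
        if i < len(model.exons) - 1:  # donor side: intron bases just after exon end
            if e < pos <= e + window:
                return True
    return False


def classify_consequence(variant: VariantRecord, model: TranscriptModel,
                         params: FilterParams = FilterParams()) -> str:
    """Predicted consequence of a variant on one transcript model.

    Splice-site takes precedence (canonical ±2 bp intronic window by
    default); CDS indels are frameshift when the net length change is not a
    multiple of three, otherwise in-frame protein-altering; CDS SNVs are
    classified by translating the affected codon on the coding strand.
    Everything else — UTR, deep intron, outside the transcript — is
    noncoding.
    """
    if variant.chromosome != model.chromosome:
        return "noncoding"
    pos = variant.position_bp
    if pos < model.tx_start or pos > model.tx_end:
        return "noncoding"
    if _in_splice_window(pos, model, params.splice_window_bp):
        return "splice_site"

    cds_pos = model.cds_positions()
    cds_set = set(cds_pos)

    if variant.variant_class == "indel":
        ref_span = range(pos, pos + len(variant.ref_allele))
        if any(p in cds_set for p in ref_span):
            shift = len(variant.alt_allele) - len(variant.ref_allele)
            return "frameshift" if shift % 3 != 0 else "coding_nonsynonymous"
        return "noncoding"

    if pos not in cds_set:
        return "noncoding"
    idx = cds_pos.index(pos)
    if model.strand == "-":
        idx = len(cds_pos) - 1 - idx
    codon_i = idx // 3
    within = idx % 3
    cds = model.cds_sequence()
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:  # trailing partial codon on a malformed model
        return "coding_nonsynonymous"
    alt_base = variant.alt_allele
    if model.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "coding_synonymous" if aa_ref == aa_alt else "coding_nonsynonymous"


# ---------------------------------------------------------------------------
# candidate streams


def _rare_deleterious(variants, params: FilterParams):
    return [
        v
        for v in variants
        if not v.known_variant and v.consequence in params.deleterious_classes
    ]


def candidate_homozygous(variants: list[VariantRecord], proband: str,
                         params: FilterParams = FilterParams()) -> list[VariantRecord]:
    """Rare deleterious autosomal variants homozygous-alt in the proband."""
    if not any(proband in v.genotypes for v in variants):
        raise ValueError(f"proband {proband!r} absent from variant table")
    return [
        v
        for v in _rare_deleterious(variants, params)
        if v.chromosome != "X" and v.genotypes.get(proband) == "hom_alt"
    ]


def candidate_compound_het(variants: list[VariantRecord], proband: str,
                           params: FilterParams = FilterParams()
                           ) -> dict[str, list[VariantRecord]]:
    """Genes carrying >=2 distinct rare deleterious het variants in the proband.

    Genes with a rare deleterious homozygous-alt variant belong to the
    homozygous stream and are not reported here (the streams are disjoint).
    """
    rare = _rare_deleterious(variants, params)
    hom_genes = {
        v.gene for v in rare if v.genotypes.get(proband) in ("hom_alt", "hemi_alt")
    }
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in rare:
        if v.chromosome != "X" and v.genotypes.get(proband) == "het":
            by_gene.setdefault(v.gene, []).append(v)
    return {
        g: vs
        for g, vs in by_gene.items()
        if len({v.key for v in vs}) >= 2 and g not in hom_genes
    }


def candidate_hemizygous_x(variants: list[VariantRecord], proband: str, sex: str,
                           params: FilterParams = FilterParams()) -> list[VariantRecord]:
    """Rare deleterious X variants hemizygous-alt in a male proband."""
    if sex != "male":
        log.warning("X-hemizygous stream requested for non-male proband %s", proband)
        return []
    return [
        v
        for v in _rare_deleterious(variants, params)
        if v.chromosome == "X" and v.genotypes.get(proband) == "hemi_alt"
    ]
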