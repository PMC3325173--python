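"""Core data model: pedigrees, genetic maps, genotype matrices, variants.

Every downstream analysis module (ROH detection, relatedness, filtration,
segregation, prioritization, burden testing) consumes only the types defined
here.  Genotype calls in a :class:`GenotypeMatrix` are coded as small integers
(``MISSING=-1``, ``HOM_REF=0``, ``HET=1``, ``HOM_ALT=2``); per-variant exome
genotypes are coded as strings because they additionally distinguish
hemizygous states on the male X.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

# ---------------------------------------------------------------------------
# genotype call codes (array form)

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: string states used in per-variant genotype dictionaries
GT_STATES = ("hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt", "missing")

#: consequence categories assigned by the annotation step
CONSEQUENCES = (
    "coding_synonymous",
    "coding_nonsynonymous",
    "frameshift",
    "splice_site",
    "noncoding",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affection: str  # "affected" | "unaffected" | "unknown"


@dataclass
class Pedigree:
    """A single family: members with parent links, sex and affection status.

    Invariants checked at construction: parent references are either null
    (founder) or resolve within the family, the parent graph is acyclic, and
    fathers are male / mothers female wherever sex is known.
    """

    family_id: str
    members: list[Individual]
    #: optional monozygotic-twin groups; each group is treated as one
    #: informative genotype by segregation analysis
    mz_twin_groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate individual ids in family {self.family_id}")
        byid = self.by_id()
        for m in self.members:
            for pid, role, want_sex in (
                (m.father_id, "father", "male"),
                (m.mother_id, "mother", "female"),
            ):
                if pid is None:
                    continue
                if pid not in byid:
                    raise ValueError(
                        f"{role} {pid!r} of {m.individual_id!r} not in family "
                        f"{self.family_id}"
                    )
                parent = byid[pid]
                if parent.sex not in (want_sex, "unknown"):
                    raise ValueError(
                        f"{role} {pid!r} of {m.individual_id!r} has sex {parent.sex}"
                    )
        # acyclicity: walk ancestors of every member
        for m in self.members:
            seen: set[str] = set()
            stack = [m.individual_id]
            while stack:
                cur = byid[stack.pop()]
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid == m.individual_id:
                        raise ValueError(
                            f"{m.individual_id!r} is its own ancestor in family "
                            f"{self.family_id}"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def by_id(self) -> dict[str, Individual]:
        return {m.individual_id: m for m in self.members}

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def children_of(self, father_id: str, mother_id: str) -> list[Individual]:
        return [
            m
            for m in self.members
            if m.father_id == father_id and m.mother_id == mother_id
        ]

    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection == "affected"]

    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.affection == "unaffected"]

    def topological_order(self) -> list[Individual]:
        """Members ordered so that every parent precedes its children."""
        byid = self.by_id()
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.members)
        while pending:
            progressed = False
            rest = []
            for m in pending:
                ok = all(
                    pid is None or pid in placed
                    for pid in (m.father_id, m.mother_id)
                )
                if ok:
                    order.append(m)
                    placed.add(m.individual_id)
                    progressed = True
                else:
                    rest.append(m)
            if not progressed:  # unreachable for a validated (acyclic) pedigree
                raise ValueError("pedigree contains a cycle")
            pending = rest
        return order


# ---------------------------------------------------------------------------
# genetic map and genotype matrix


@dataclass
class GeneticMap:
    """Marker coordinates: chromosome, physical (bp) and genetic (cM) position.

    Markers must be grouped by chromosome and, within a chromosome, sorted by
    ``position_bp`` with non-decreasing ``position_cM``.
    """

    marker_ids: np.ndarray  # object/str
    chromosomes: np.ndarray  # object/str, "1".."22", "X"
    position_bp: np.ndarray  # int64
    position_cM: np.ndarray  # float64

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.position_cM = np.asarray(self.position_cM, dtype=np.float64)
        for arr in (self.chromosomes, self.position_bp, self.position_cM):
            if len(arr) != n:
                raise ValueError("map arrays have inconsistent lengths")
        if np.any(self.position_bp < 0) or np.any(self.position_cM < 0):
            raise ValueError("map positions must be non-negative")
        for chrom, sl in self.chromosome_slices().items():
            if np.any(np.diff(self.position_bp[sl]) < 0):
                raise ValueError(f"markers on chromosome {chrom} not sorted by bp")
            if np.any(np.diff(self.position_cM[sl]) < 0):
                raise ValueError(f"cM positions on chromosome {chrom} decrease")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in file order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                chrom = str(self.chromosomes[start])
                if chrom in out:
                    raise ValueError(f"chromosome {chrom} appears in two blocks")
                out[chrom] = slice(start, i)
                start = i
        return out

    def total_cM(self, exclude: Iterable[str] = ()) -> float:
        """Total genetic length: sum over chromosomes of last − first cM."""
        skip = set(exclude)
        total = 0.0
        for chrom, sl in self.chromosome_slices().items():
            if chrom in skip:
                continue
            cm = self.position_cM[sl]
            if len(cm) > 1:
                total += float(cm[-1] - cm[0])
        return total


@dataclass
class GenotypeMatrix:
    """Samples × biallelic markers, calls coded HOM_REF/HET/HOM_ALT/MISSING.

    ``sex`` (per sample) lets X-aware code treat male X calls as hemizygous:
    on the male X a stored HOM_REF/HOM_ALT means hemi_ref/hemi_alt and HET is
    invalid (rejected at construction).
    """

    sample_ids: list[str]
    map: GeneticMap
    calls: np.ndarray  # int8, shape (n_samples, n_markers)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.map)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.map)} markers"
            )
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if np.any(bad):
            raise ValueError("calls contain values outside the genotype alphabet")
        x = self.map.chromosomes == "X"
        if np.any(x):
            for i, sid in enumerate(self.sample_ids):
                if self.sex.get(sid) == "male" and np.any(self.calls[i, x] == HET):
                    raise ValueError(f"het call on male X for sample {sid}")

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None


# ---------------------------------------------------------------------------
# exome variants


@dataclass
class ControlCounts:
    alt_alleles: int
    total_chromosomes: int
    homozygotes: int

    def __post_init__(self) -> None:
        if self.alt_alleles > self.total_chromosomes:
            raise ValueError("alt allele count exceeds chromosome count")
        if min(self.alt_alleles, self.total_chromosomes, self.homozygotes) < 0:
            raise ValueError("control counts must be non-negative")


@dataclass
class VariantRecord:
    """One annotated exome variant with per-sample genotypes.

    ``genotypes`` maps sample id → one of :data:`GT_STATES`.  ``known_variant``
    marks presence in the common-variant catalog (the dbSNP/1000G-style step);
    ``annotations`` holds optional booleans ``brain_expressed`` and
    ``known_disorder_gene`` (absent key = unknown) plus free-form scores.
    """

    chromosome: str
    position_bp: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene: str
    consequence: str
    variant_class: str  # "snp" | "indel"
    mapping_quality: Optional[float]
    known_variant: bool
    genotypes: dict[str, str]
    annotations: dict = field(default_factory=dict)
    control_counts: Optional[ControlCounts] = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError("position_bp must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.variant_class not in ("snp", "indel"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        for s, g in self.genotypes.items():
            if g not in GT_STATES:
                raise ValueError(f"invalid genotype {g!r} for sample {s}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position_bp, self.ref_allele, self.alt_allele)

    def with_genotype(self, sample: str, call: str) -> "VariantRecord":
        gts = dict(self.genotypes)
        gts[sample] = call
        return replace(self, genotypes=gts)


# ---------------------------------------------------------------------------
# validation assays


@dataclass(frozen=True)
class ValidationEntry:
    assay_status: str  # "designed" | "design_failed"
    run_status: Optional[str] = None  # "ran" | "failed"; only when designed
    genotype_call: Optional[str] = None  # only when ran

    def __post_init__(self) -> None:
        if self.assay_status not in ("designed", "design_failed"):
            raise ValueError(f"bad assay_status {self.assay_status!r}")
        if self.assay_status == "design_failed" and self.run_status is not None:
            raise ValueError("run_status defined for an undesigned assay")
        if self.run_status not in (None, "ran", "failed"):
            raise ValueError(f"bad run_status {self.run_status!r}")
        if self.genotype_call is not None:
            if self.run_status != "ran":
                raise ValueError("genotype_call without a successful run")
            if self.genotype_call not in GT_STATES:
                raise ValueError(f"bad genotype_call {self.genotype_call!r}")


class ValidationTable:
    """Orthogonal-genotyping results keyed by (variant key, sample id)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[tuple[str, int, str, str], str], ValidationEntry] = {}

    def add(self, variant_key, sample_id: str, entry: ValidationEntry) -> None:
        self._entries[(tuple(variant_key), sample_id)] = entry

    def get(self, variant_key, sample_id: str) -> Optional[ValidationEntry]:
        return self._entries.get((tuple(variant_key), sample_id))

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)
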