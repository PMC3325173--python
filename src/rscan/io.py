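"""Readers and writers for PED/MAP, variant tables (TSV / minimal VCF),
common-variant catalogs and ROH BED output.

PED phenotype coding follows the PLINK text dialect: 2 = affected,
1 = unaffected, 0 or -9 = unknown.  Missing data in TSV output is "." and a
missing PED genotype is "0 0".  Variant positions are 1-based inclusive (VCF
convention); BED intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from collections import OrderedDict
from typing import Optional

import numpy as np

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ControlCounts,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
    ValidationEntry,
    ValidationTable,
    VariantRecord,
)

log = logging.getLogger(__name__)

_SEX = {"1": "male", "2": "female", "0": "unknown"}
_SEX_BACK = {"male": "1", "female": "2", "unknown": "0"}
_PHENO = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_PHENO_BACK = {"affected": "2", "unaffected": "1", "unknown": "0"}

#: columns of the variant TSV dialect, in order
VARIANT_TSV_COLUMNS = [
    "chromosome",
    "position_bp",
    "ref_allele",
    "alt_allele",
    "gene",
    "consequence",
    "variant_class",
    "mapping_quality",
    "known_variant",
    "brain_expressed",
    "known_disorder_gene",
    "control_alt_alleles",
    "control_total_chromosomes",
    "control_homozygotes",
]


# ---------------------------------------------------------------------------
# PED / MAP


def read_map(map_path) -> GeneticMap:
    chroms, ids, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns (chrom id cM bp)")
            chrom, mid, cm, bp = parts
            chroms.append(chrom.removeprefix("chr"))
            ids.append(mid)
            cms.append(float(cm))
            bps.append(int(bp))
    return GeneticMap(
        marker_ids=np.array(ids, dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        position_bp=np.array(bps, dtype=np.int64),
        position_cM=np.array(cms, dtype=np.float64),
    )


def read_ped_map(ped_path, map_path) -> tuple[list[Pedigree], GenotypeMatrix]:
    """Parse a PLINK-style text PED + MAP pair.

    The per-marker allele dictionary is built from the observed alleles,
    with codes assigned in sorted symbol order (deterministic ref/alt
    orientation).  Markers with more than two observed alleles are dropped
    with a warning (only biallelic SNPs are analyzed).
    """
    gmap = read_map(map_path)
    n_markers = len(gmap)

    rows = []  # (fam, ind, father, mother, sex, pheno, allele pairs)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)

    # allele dictionary per marker
    alleles: list[OrderedDict] = [OrderedDict() for _ in range(n_markers)]
    for parts in rows:
        for j in range(n_markers):
            for a in parts[6 + 2 * j : 8 + 2 * j]:
                if a != "0":
                    alleles[j].setdefault(a, None)

    multi = [j for j in range(n_markers) if len(alleles[j]) > 2]
    if multi:
        log.warning(
            "dropping %d marker(s) with >2 observed alleles: %s",
            len(multi),
            ", ".join(str(gmap.marker_ids[j]) for j in multi[:10]),
        )
    keep = np.array([j for j in range(n_markers) if j not in set(multi)], dtype=int)

    families: dict[str, list[Individual]] = {}
    sample_ids: list[str] = []
    sex: dict[str, str] = {}
    calls = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    for i, parts in enumerate(rows):
        fam, ind, father, mother, sx, ph = parts[:6]
        families.setdefault(fam, []).append(
            Individual(
                individual_id=ind,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX.get(sx, "unknown"),
                affection=_PHENO.get(ph, "unknown"),
            )
        )
        sample_ids.append(ind)
        sex[ind] = _SEX.get(sx, "unknown")
        for j in range(n_markers):
            a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
            if a1 == "0" or a2 == "0":
                continue
            d = alleles[j]
            if a1 not in d or a2 not in d:
                raise FormatError(
                    f"unknown allele symbol at marker {gmap.marker_ids[j]}"
                )
            # sorted symbols give a deterministic ref/alt orientation
            codes = {a: k for k, a in enumerate(sorted(d))}
            calls[i, j] = codes[a1] + codes[a2]

    if len(keep) < n_markers:
        gmap = GeneticMap(
            marker_ids=gmap.marker_ids[keep],
            chromosomes=gmap.chromosomes[keep],
            position_bp=gmap.position_bp[keep],
            position_cM=gmap.position_cM[keep],
        )
        calls = calls[:, keep]

    pedigrees = [Pedigree(family_id=f, members=ms) for f, ms in families.items()]
    matrix = GenotypeMatrix(sample_ids=sample_ids, map=gmap, calls=calls, sex=sex)
    return pedigrees, matrix


def write_ped_map(pedigrees: list[Pedigree], matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP with alleles coded A (ref) / B (alt)."""
    gmap = matrix.map
    with open(map_path, "w") as fh:
        for j in range(len(gmap)):
            fh.write(
                f"{gmap.chromosomes[j]}\t{gmap.marker_ids[j]}\t"
                f"{gmap.position_cM[j]:.6f}\t{gmap.position_bp[j]}\n"
            )
    member_of = {}
    for ped in pedigrees:
        for m in ped.members:
            member_of[m.individual_id] = (ped.family_id, m)
    pair = {HOM_REF: ("A", "A"), HET: ("A", "B"), HOM_ALT: ("B", "B"), MISSING: ("0", "0")}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.sample_ids):
            fam, m = member_of[sid]
            cols = [
                fam,
                sid,
                m.father_id or "0",
                m.mother_id or "0",
                _SEX_BACK[m.sex],
                _PHENO_BACK[m.affection],
            ]
            for c in matrix.calls[i]:
                cols.extend(pair[int(c)])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# variants


def _bool_field(s: str) -> Optional[bool]:
    if s == ".":
        return None
    return s.lower() in ("1", "true", "t", "yes")


def read_variants(path, dialect: str, pedigrees: Optional[list[Pedigree]] = None,
                  sex: Optional[dict[str, str]] = None) -> list[VariantRecord]:
    """Read a variant table in ``tsv`` or minimal ``vcf`` dialect.

    Samples present in the file but absent from the supplied pedigrees produce
    a warning; the sample is kept.
    """
    if dialect == "tsv":
        records = _read_variants_tsv(path)
    elif dialect == "vcf":
        records = _read_variants_vcf(path, sex or {})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if pedigrees is not None:
        known = {m.individual_id for p in pedigrees for m in p.members}
        extra = {s for r in records for s in r.genotypes} - known
        if extra:
            warnings.warn(
                f"samples not in any pedigree kept as-is: {sorted(extra)}",
                stacklevel=2,
            )
    return records


def _read_variants_tsv(path) -> list[VariantRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing_cols = [c for c in VARIANT_TSV_COLUMNS if c not in header]
        if missing_cols:
            raise FormatError(f"variant TSV missing required columns: {missing_cols}")
        col = {c: header.index(c) for c in VARIANT_TSV_COLUMNS}
        sample_cols = [
            (name.removeprefix("gt:"), i)
            for i, name in enumerate(header)
            if name.startswith("gt:")
        ]
        records = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(header):
                raise FormatError(f"{path}:{lineno}: column count mismatch")
            cc = None
            if f[col["control_total_chromosomes"]] != ".":
                cc = ControlCounts(
                    alt_alleles=int(f[col["control_alt_alleles"]]),
                    total_chromosomes=int(f[col["control_total_chromosomes"]]),
                    homozygotes=int(f[col["control_homozygotes"]]),
                )
            ann = {}
            be = _bool_field(f[col["brain_expressed"]])
            kd = _bool_field(f[col["known_disorder_gene"]])
            if be is not None:
                ann["brain_expressed"] = be
            if kd is not None:
                ann["known_disorder_gene"] = kd
            records.append(
                VariantRecord(
                    chromosome=f[col["chromosome"]].removeprefix("chr"),
                    position_bp=int(f[col["position_bp"]]),
                    ref_allele=f[col["ref_allele"]],
                    alt_allele=f[col["alt_allele"]],
                    gene=f[col["gene"]],
                    consequence=f[col["consequence"]],
                    variant_class=f[col["variant_class"]],
                    mapping_quality=(
                        None if f[col["mapping_quality"]] == "." else float(f[col["mapping_quality"]])
                    ),
                    known_variant=bool(_bool_field(f[col["known_variant"]])),
                    genotypes={s: f[i] for s, i in sample_cols},
                    annotations=ann,
                    control_counts=cc,
                )
            )
        return records


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    samples = sorted({s for r in records for s in r.genotypes})
    header = VARIANT_TSV_COLUMNS + [f"gt:{s}" for s in samples]

    def b(v):
        return "." if v is None else ("1" if v else "0")

    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            cc = r.control_counts
            row = [
                r.chromosome,
                str(r.position_bp),
                r.ref_allele,
                r.alt_allele,
                r.gene,
                r.consequence,
                r.variant_class,
                "." if r.mapping_quality is None else f"{r.mapping_quality:g}",
                "1" if r.known_variant else "0",
                b(r.annotations.get("brain_expressed")),
                b(r.annotations.get("known_disorder_gene")),
                "." if cc is None else str(cc.alt_alleles),
                "." if cc is None else str(cc.total_chromosomes),
                "." if cc is None else str(cc.homozygotes),
            ]
            row.extend(r.genotypes.get(s, "missing") for s in samples)
            fh.write("\t".join(row) + "\n")


def _read_variants_vcf(path, sex: dict[str, str]) -> list[VariantRecord]:
    """Minimal VCF 4.2 subset via cyvcf2: CHROM POS ID REF ALT QUAL FILTER
    INFO FORMAT + GT.  Annotations come from INFO keys GENE, CSQ, CLASS,
    MQ, KNOWN.  Haploid GT entries become hemizygous calls.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:  # malformed header
        raise FormatError(f"{path}: not parseable as VCF ({e})") from e
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF without sample/GT columns")

    records = []
    for rec in vcf:
        chrom = rec.CHROM.removeprefix("chr")
        gts = {}
        for s, entry in zip(samples, rec.genotypes):
            alleles = entry[:-1]  # trailing element is the phasing flag
            if len(alleles) == 1:
                a = alleles[0]
                gts[s] = (
                    "missing" if a < 0 else ("hemi_alt" if a == 1 else "hemi_ref")
                )
            elif any(a < 0 for a in alleles):
                gts[s] = "missing"
            else:
                n_alt = sum(a == 1 for a in alleles)
                gts[s] = ("hom_ref", "het", "hom_alt")[n_alt]
        ref = rec.REF
        alt = rec.ALT[0] if rec.ALT else "."
        info = rec.INFO
        mq = info.get("MQ")
        records.append(
            VariantRecord(
                chromosome=chrom,
                position_bp=int(rec.POS),
                ref_allele=ref,
                alt_allele=alt,
                gene=info.get("GENE") or ".",
                consequence=info.get("CSQ") or "noncoding",
                variant_class=info.get("CLASS")
                or ("snp" if len(ref) == 1 and len(alt) == 1 else "indel"),
                mapping_quality=float(mq) if mq is not None else None,
                known_variant=str(info.get("KNOWN", "0")) == "1",
                genotypes=gts,
            )
        )
    return records


def read_catalog(path) -> set[tuple[str, int, str, str]]:
    """Common-variant catalog: sites-only VCF or 4-column TSV (chrom pos ref alt)."""
    sites: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 5 and not f[2].isdigit():  # VCF-shaped: CHROM POS ID REF ALT
                chrom, pos, ref, alt = f[0], f[1], f[3], f[4]
            elif len(f) >= 4:
                chrom, pos, ref, alt = f[0], f[1], f[2], f[3]
            else:
                raise FormatError("catalog rows need >=4 columns")
            sites.add((chrom.removeprefix("chr"), int(pos), ref, alt))
    return sites


# ---------------------------------------------------------------------------
# ROH BED / TSV output


def write_roh_bed(segments, path) -> None:
    """BED (0-based half-open) with name=sample, plus cM columns 7-8."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\t"
                f"{s.n_markers}\t.\t{s.start_cM:.4f}\t{s.end_cM:.4f}\n"
            )


def read_roh_bed(path):
    """Read segments written by :func:`write_roh_bed`.

    Marker indices and het counts are not representable in BED and come back
    as -1/0; bp and cM coordinates, sample and marker count round-trip.
    """
    from .roh import ROHSegment

    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise FormatError("ROH BED rows need 8 columns")
            out.append(
                ROHSegment(
                    sample_id=f[3],
                    chromosome=f[0],
                    first_marker_index=-1,
                    last_marker_index=-1,
                    start_cM=float(f[6]),
                    end_cM=float(f[7]),
                    start_bp=int(f[1]) + 1,
                    end_bp=int(f[2]),
                    n_markers=int(f[4]),
                    n_het=0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# validation merge

VALIDATION_TSV_COLUMNS = [
    "chromosome", "position_bp", "ref_allele", "alt_allele",
    "sample_id", "assay_status", "run_status", "genotype_call",
]


def read_validation_table(path) -> ValidationTable:
    """Validation assays as TSV: one row per (variant, sample); "." for
    undefined run_status/genotype_call."""
    table = ValidationTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in VALIDATION_TSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"validation TSV missing columns: {missing}")
        col = {c: header.index(c) for c in VALIDATION_TSV_COLUMNS}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            key = (
                f[col["chromosome"]].removeprefix("chr"),
                int(f[col["position_bp"]]),
                f[col["ref_allele"]],
                f[col["alt_allele"]],
            )
            run = f[col["run_status"]]
            call = f[col["genotype_call"]]
            table.add(
                key,
                f[col["sample_id"]],
                ValidationEntry(
                    assay_status=f[col["assay_status"]],
                    run_status=None if run == "." else run,
                    genotype_call=None if call == "." else call,
                ),
            )
    return table


def write_validation_table(table: ValidationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VALIDATION_TSV_COLUMNS) + "\n")
        for (key, sample), e in table.items():
            chrom, pos, ref, alt = key
            fh.write(
                "\t".join(
                    [chrom, str(pos), ref, alt, sample, e.assay_status,
                     e.run_status or ".", e.genotype_call or "."]
                )
                + "\n"
            )


def apply_validation(variants: list[VariantRecord], table: ValidationTable,
                     proband: str) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Overlay orthogonal genotyping calls onto exome genotypes.

    Wherever a validation call exists for (variant, sample) the exome call is
    replaced.  A variant stays in the candidate stream only when a successful
    proband assay confirms the homozygous (or hemizygous) alternate call:
    contradicting calls are flagged ``not_validated``, assays that could not
    be designed or failed to run are flagged ``not_assayed``, and both groups
    are removed.  Variants with no table entry at all are kept untouched.
    Discordant validation calls in other family members replace the exome
    call but are only logged, never grounds for removal.  Returns
    (validated survivors, removed).
    """
    known_keys = {v.key for v in variants}
    for (key, _s), _e in table.items():
        if key not in known_keys:
            warnings.warn(f"validation call for unknown variant {key}", stacklevel=2)

    kept: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for v in variants:
        exome_proband = v.genotypes.get(proband, "missing")
        out = v
        for s in list(v.genotypes):
            entry = table.get(v.key, s)
            if entry is None or entry.genotype_call is None:
                continue
            if s != proband and entry.genotype_call != v.genotypes[s]:
                log.info(
                    "validation call for %s at %s differs from exome (%s vs %s)",
                    s, v.key, entry.genotype_call, v.genotypes[s],
                )
            out = out.with_genotype(s, entry.genotype_call)

        proband_entry = table.get(v.key, proband)
        if proband_entry is None:
            kept.append(out)
            continue
        if proband_entry.genotype_call is None:  # design failure or failed run
            out.annotations["not_assayed"] = True
            removed.append(out)
        elif exome_proband in ("hom_alt", "hemi_alt") and \
                proband_entry.genotype_call not in ("hom_alt", "hemi_alt"):
            out.annotations["not_validated"] = True
            removed.append(out)
        else:
            kept.append(out)
    return kept, removed
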