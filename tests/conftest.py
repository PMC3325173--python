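import numpy as np
import pytest

from rscan.core import (
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
    VariantRecord,
)


def make_map(n_markers, spacing_cM=0.5, chrom="1", start_cM=0.0):
    cm = start_cM + spacing_cM * np.arange(n_markers)
    return GeneticMap(
        marker_ids=np.array([f"{chrom}_{i}" for i in range(n_markers)], dtype=object),
        chromosomes=np.array([chrom] * n_markers, dtype=object),
        position_bp=(cm * 1_000_000).astype(np.int64) + 1,
        position_cM=cm,
    )


def make_matrix(calls_by_sample, spacing_cM=0.5, chrom="1", sex=None):
    """calls_by_sample: dict sample -> list of int calls (-1/0/1/2)."""
    samples = list(calls_by_sample)
    n = len(next(iter(calls_by_sample.values())))
    return GenotypeMatrix(
        sample_ids=samples,
        map=make_map(n, spacing_cM, chrom),
        calls=np.array([calls_by_sample[s] for s in samples], dtype=np.int8),
        sex=sex or {},
    )


def make_variant(chrom="1", pos=1000, ref="A", alt="T", gene="GENE1",
                 consequence="coding_nonsynonymous", variant_class="snp",
                 mq=50.0, known=False, genotypes=None, annotations=None,
                 control_counts=None):
    return VariantRecord(
        chromosome=chrom,
        position_bp=pos,
        ref_allele=ref,
        alt_allele=alt,
        gene=gene,
        consequence=consequence,
        variant_class=variant_class,
        mapping_quality=mq,
        known_variant=known,
        genotypes=genotypes or {},
        annotations=annotations or {},
        control_counts=control_counts,
    )


def trio_pedigree(n_affected=1, n_unaffected=1, affected_sex="male",
                  mz_twins=False):
    members = [
        Individual("F", None, None, "male", "unaffected"),
        Individual("M", None, None, "female", "unaffected"),
    ]
    aff = []
    for i in range(n_affected):
        iid = f"P{i + 1}"
        members.append(Individual(iid, "F", "M", affected_sex, "affected"))
        aff.append(iid)
    for i in range(n_unaffected):
        members.append(Individual(f"S{i + 1}", "F", "M", "female", "unaffected"))
    groups = [frozenset(aff)] if (mz_twins and len(aff) > 1) else []
    return Pedigree(family_id="FAM", members=members, mz_twin_groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
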