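"""Pairwise relatedness from genome-wide genotypes.

Identity-by-state (IBS) counting with the heterozygote-aware refinement:
IBS0 counts markers where the two samples are opposite homozygotes, IBS2*
counts markers where both are heterozygous.  Two derived statistics
summarize a pair:

    IBS2*_ratio        = IBS2* / (IBS2* + IBS0)
    percent informative = (IBS0 + IBS2*) / (IBS0 + IBS1 + IBS2)

For an unrelated pair the expected IBS2*_ratio is 2/3 regardless of the
allele-frequency spectrum (per marker, P(het,het) = 4p²q² and P(opposite
homozygotes) = 2p²q²); for a parent-offspring pair IBS0 is impossible and
the ratio is 1.

Genome-wide identity-by-descent proportions Z0/Z1/Z2 (and PI_HAT = Z1/2 +
Z2) are estimated by the classical method of moments: observed IBS counts
are equated with their expectations given per-marker allele frequencies,
solved sequentially for Z0, Z1, Z2, then truncated to the probability
simplex.  The X chromosome is excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import HET, HOM_ALT, HOM_REF, GenotypeMatrix, Pedigree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseRelatedness:
    sample_a: str
    sample_b: str
    ibs0: int
    ibs1: int
    ibs2: int
    ibs2_star: int
    ibs2_star_ratio: Optional[float]
    pct_informative: float
    z0: float
    z1: float
    z2: float
    pi_hat: float


def _autosomal(matrix: GenotypeMatrix) -> np.ndarray:
    return matrix.map.chromosomes != "X"


def count_ibs(matrix: GenotypeMatrix, a: str, b: str) -> tuple[int, int, int, int]:
    """(IBS0, IBS1, IBS2, IBS2*) over jointly non-missing autosomal markers."""
    if a == b:
        raise ValueError("cannot compare a sample with itself")
    keep = _autosomal(matrix)
    ga = matrix.row(a)[keep]
    gb = matrix.row(b)[keep]
    ok = (ga >= 0) & (gb >= 0)
    ga, gb = ga[ok], gb[ok]
    diff = np.abs(ga - gb)
    ibs0 = int(np.sum(diff == 2))
    ibs1 = int(np.sum(diff == 1))
    ibs2 = int(np.sum(diff == 0))
    ibs2_star = int(np.sum((ga == HET) & (gb == HET)))
    return ibs0, ibs1, ibs2, ibs2_star


def ibs2_star_ratio(counts: tuple[int, int, int, int]) -> Optional[float]:
    ibs0, _, _, ibs2_star = counts
    denom = ibs2_star + ibs0
    if denom == 0:
        log.warning("IBS2*_ratio undefined: IBS2* + IBS0 = 0")
        return None
    return ibs2_star / denom


def pct_informative(counts: tuple[int, int, int, int]) -> float:
    ibs0, ibs1, ibs2, ibs2_star = counts
    denom = ibs0 + ibs1 + ibs2
    if denom == 0:
        raise ValueError("no jointly genotyped markers")
    return (ibs0 + ibs2_star) / denom


def founder_allele_freqs(matrix: GenotypeMatrix, pedigrees: list[Pedigree]
                         ) -> np.ndarray:
    """Per-marker alt-allele frequency estimated from pedigree founders only.

    Using founders avoids inflating frequencies with the correlated genotypes
    of their descendants.  Markers with no genotyped founder get NaN.
    """
    founder_ids = [
        m.individual_id
        for p in pedigrees
        for m in p.founders()
        if m.individual_id in matrix.sample_ids
    ]
    if not founder_ids:
        raise ValueError("no founders present in the genotype matrix")
    rows = np.stack([matrix.row(s) for s in founder_ids]).astype(np.float64)
    rows[rows < 0] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(rows, axis=0) / 2.0


def estimate_ibd(matrix: GenotypeMatrix, a: str, b: str,
                 allele_freqs: Optional[np.ndarray] = None,
                 pedigrees: Optional[list[Pedigree]] = None,
                 min_maf: float = 0.01) -> tuple[float, float, float, float]:
    """Method-of-moments (Z0, Z1, Z2, PI_HAT) for one autosomal sample pair.

    ``allele_freqs`` is the per-marker alt frequency over the full map; when
    omitted it is estimated from pedigree founders.  Markers with minor
    allele frequency below ``min_maf`` are excluded (their conditional IBS
    probabilities are numerically unstable).
    """
    if allele_freqs is None:
        if pedigrees is None:
            raise ValueError("allele_freqs or pedigrees required")
        allele_freqs = founder_allele_freqs(matrix, pedigrees)
    allele_freqs = np.asarray(allele_freqs, dtype=np.float64)

    keep = _autosomal(matrix)
    p = allele_freqs[keep]
    ga = matrix.row(a)[keep]
    gb = matrix.row(b)[keep]
    maf = np.minimum(p, 1 - p)
    ok = (ga >= 0) & (gb >= 0) & np.isfinite(p) & (maf >= min_maf)
    if not ok.any():
        raise ValueError("no informative polymorphic markers for IBD estimation")
    ga, gb, p = ga[ok], gb[ok], p[ok]
    q = 1 - p

    diff = np.abs(ga - gb)
    n_ibs0 = float(np.sum(diff == 2))
    n_ibs1 = float(np.sum(diff == 1))
    n_ibs2 = float(np.sum(diff == 0))
    n = len(p)

    # expectations per marker conditional on sharing 0 or 1 allele IBD
    e0_ibs0 = float(np.sum(2 * p**2 * q**2))
    e0_ibs1 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e0_ibs2 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibs1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e1_ibs2 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    z0 = n_ibs0 / e0_ibs0 if e0_ibs0 > 0 else 0.0
    z1 = (n_ibs1 - z0 * e0_ibs1) / e1_ibs1 if e1_ibs1 > 0 else 0.0
    z2 = (n_ibs2 - z0 * e0_ibs2 - z1 * e1_ibs2) / n

    z = np.clip([z0, z1, z2], 0.0, None)
    total = z.sum()
    if total == 0:
        raise ValueError("degenerate IBD moment system")
    z = z / total
    z0, z1, z2 = (float(v) for v in z)
    return z0, z1, z2, z1 / 2 + z2


def pairwise_relatedness(matrix: GenotypeMatrix, a: str, b: str,
                         allele_freqs: Optional[np.ndarray] = None,
                         pedigrees: Optional[list[Pedigree]] = None
                         ) -> PairwiseRelatedness:
    """Full relatedness record for one pair."""
    counts = count_ibs(matrix, a, b)
    z0, z1, z2, pi_hat = estimate_ibd(
        matrix, a, b, allele_freqs=allele_freqs, pedigrees=pedigrees
    )
    return PairwiseRelatedness(
        sample_a=a,
        sample_b=b,
        ibs0=counts[0],
        ibs1=counts[1],
        ibs2=counts[2],
        ibs2_star=counts[3],
        ibs2_star_ratio=ibs2_star_ratio(counts),
        pct_informative=pct_informative(counts),
        z0=z0,
        z1=z1,
        z2=z2,
        pi_hat=pi_hat,
    )
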