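"""Runs-of-homozygosity detection with explicit heterozygote tolerance.

A run is a maximal marker interval that (i) begins and ends on a homozygous
call, (ii) never contains more than ``max_consecutive_het`` heterozygous
calls in a row, and (iii) contains at most ``max_het_per_window`` het calls
in every window of ``window_size`` consecutive markers lying fully inside
the run.  Missing calls are neutral: they neither break a run nor count as
heterozygous in either tolerance rule, but they do occupy window positions;
a run cannot begin or end on a missing call.  Runs shorter than
``window_size`` markers are subject only to the consecutive-het rule.

Detected runs are containment-maximal: no reported run lies inside another
marker interval that also satisfies the rules.  Reported segments are then
filtered by a strict genetic-length threshold (``length_cM >
min_length_cM``) and a marker-count floor.

The detector is linear-time: every way the rules can fail is a local
"violation span" (three hets with no intervening homozygote, or an
overloaded 10-marker window), a valid interval is exactly one containing no
violation span, and the maximal reach from every start follows from a
suffix-minimum over span ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HET, HOM_ALT, HOM_REF, GeneticMap, GenotypeMatrix


@dataclass(frozen=True)
class ROHParams:
    max_consecutive_het: int = 2
    window_size: int = 10
    max_het_per_window: int = 3
    min_length_cM: float = 5.0
    min_markers: int = 25

    def __post_init__(self) -> None:
        if self.max_het_per_window > self.window_size:
            raise ValueError("max_het_per_window cannot exceed window_size")
        if self.min_length_cM < 0:
            raise ValueError("min_length_cM must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    first_marker_index: int  # global marker index, inclusive
    last_marker_index: int
    start_cM: float
    end_cM: float
    start_bp: int
    end_bp: int
    n_markers: int
    n_het: int

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


@dataclass(frozen=True)
class HomozygosityProfile:
    sample_id: str
    percent_genome_in_roh: float
    n_segments: int
    mean_segment_cM: float
    total_map_cM: float


def _violation_limits(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per start index, the largest end index any valid interval may reach.

    A violation span (a, b) forbids every interval [i, j] with i <= a and
    j >= b; the reach from i is min(b) - 1 over spans starting at or after i.
    """
    n = len(calls)
    limit = np.full(n + 1, n - 1, dtype=np.int64)

    is_het = calls == HET
    is_hom = (calls == HOM_REF) | (calls == HOM_ALT)

    # consecutive-het spans: (k+1) hets with no homozygote in between
    k = params.max_consecutive_het
    chain: list[int] = []  # het positions since the last homozygous call
    for pos in range(n):
        if is_hom[pos]:
            chain.clear()
        elif is_het[pos]:
            chain.append(pos)
            if len(chain) > k:
                a, b = chain[-(k + 1)], pos
                limit[a] = min(limit[a], b - 1)

    # window spans: any full window of window_size markers with too many hets
    w = params.window_size
    if n >= w:
        counts = np.convolve(is_het.astype(np.int64), np.ones(w, dtype=np.int64), "valid")
        for a in np.nonzero(counts > params.max_het_per_window)[0]:
            limit[a] = min(limit[a], a + w - 2)  # span end is a+w-1

    return np.minimum.accumulate(limit[::-1])[::-1]


def _maximal_runs(calls: np.ndarray, params: ROHParams) -> list[tuple[int, int]]:
    """Containment-maximal valid intervals on one chromosome (local indices)."""
    n = len(calls)
    if n == 0:
        return []
    is_hom = (calls == HOM_REF) | (calls == HOM_ALT)
    hom_idx = np.nonzero(is_hom)[0]
    if len(hom_idx) == 0:
        return []

    # prev_hom[t]: largest homozygous index <= t, or -1
    prev_hom = np.full(n, -1, dtype=np.int64)
    prev_hom[hom_idx] = hom_idx
    prev_hom = np.maximum.accumulate(prev_hom)

    reach_limit = _violation_limits(calls, params)

    out: list[tuple[int, int]] = []
    last_end = -1
    for i in hom_idx:
        j = prev_hom[min(reach_limit[i], n - 1)]
        if j < i:
            continue
        if j > last_end:  # first (leftmost) start attaining this reach
            out.append((int(i), int(j)))
            last_end = j
    return out


def detect_roh(matrix: GenotypeMatrix, sample: str, params: ROHParams = ROHParams()
               ) -> list[ROHSegment]:
    """All maximal ROH segments for one sample, ordered along the genome.

    The X chromosome is skipped for male samples (hemizygous calls would make
    the whole chromosome a trivial run).
    """
    row = matrix.row(sample)
    gmap = matrix.map
    male = matrix.sex.get(sample) == "male"
    segments: list[ROHSegment] = []
    for chrom, sl in gmap.chromosome_slices().items():
        if chrom == "X" and male:
            continue
        calls = row[sl]
        cm = gmap.position_cM[sl]
        bp = gmap.position_bp[sl]
        for i, j in _maximal_runs(calls, params):
            length = float(cm[j] - cm[i])
            n_markers = j - i + 1
            if length <= params.min_length_cM or n_markers < params.min_markers:
                continue
            segments.append(
                ROHSegment(
                    sample_id=sample,
                    chromosome=chrom,
                    first_marker_index=sl.start + i,
                    last_marker_index=sl.start + j,
                    start_cM=float(cm[i]),
                    end_cM=float(cm[j]),
                    start_bp=int(bp[i]),
                    end_bp=int(bp[j]),
                    n_markers=n_markers,
                    n_het=int(np.sum(calls[i : j + 1] == HET)),
                )
            )
    return segments


def summarize_homozygosity(segments: list[ROHSegment], gmap: GeneticMap,
                           sample_id: str | None = None) -> HomozygosityProfile:
    """Genome-level summary: percent of the map in ROH, count, mean size."""
    if len(gmap) == 0:
        raise ValueError("empty genetic map")
    if sample_id is None:
        ids = {s.sample_id for s in segments}
        if len(ids) > 1:
            raise ValueError("segments from more than one sample")
        sample_id = ids.pop() if ids else ""
    total = gmap.total_cM()
    if total <= 0:
        raise ValueError("genetic map has zero total length")
    lengths = [s.length_cM for s in segments]
    return HomozygosityProfile(
        sample_id=sample_id,
        percent_genome_in_roh=100.0 * sum(lengths) / total,
        n_segments=len(segments),
        mean_segment_cM=float(np.mean(lengths)) if lengths else 0.0,
        total_map_cM=total,
    )


def shared_roh(matrix: GenotypeMatrix, affected: list[str], unaffected: list[str],
               params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Intervals homozygous for the same haplotype in every affected sample
    and not covered by any unaffected sibling's ROH.

    For two or more affected samples the interval must be covered by an ROH
    of each, and at every marker the non-missing affected calls must all be
    the same homozygous allele.  With a single affected sample its own ROHs
    are returned (minus any fully covered by an unaffected ROH): the
    same-haplotype condition is vacuous there and tolerated het calls inside
    the run do not split it.
    """
    if not affected:
        raise ValueError("at least one affected sample required")

    aff_segs = {s: detect_roh(matrix, s, params) for s in affected}
    unaff_segs = [seg for s in unaffected for seg in detect_roh(matrix, s, params)]

    def covered_by_unaffected(chrom: str, lo: int, hi: int) -> bool:
        return any(
            u.chromosome == chrom
            and u.first_marker_index <= lo
            and u.last_marker_index >= hi
            for u in unaff_segs
        )

    if len(affected) == 1:
        return [
            seg
            for seg in aff_segs[affected[0]]
            if not covered_by_unaffected(
                seg.chromosome, seg.first_marker_index, seg.last_marker_index
            )
        ]

    gmap = matrix.map
    n = len(gmap)
    covered = np.ones(n, dtype=bool)
    for s in affected:
        mask = np.zeros(n, dtype=bool)
        for seg in aff_segs[s]:
            mask[seg.first_marker_index : seg.last_marker_index + 1] = True
        covered &= mask

    rows = np.stack([matrix.row(s) for s in affected])
    nonmissing = rows >= 0
    hom = (rows == HOM_REF) | (rows == HOM_ALT)
    all_hom = np.all(hom | ~nonmissing, axis=0)
    # identical allele among the non-missing homozygous calls
    lo_call = np.where(nonmissing, rows, np.int8(3)).min(axis=0)
    hi_call = np.where(nonmissing, rows, np.int8(-2)).max(axis=0)
    same = (lo_call == hi_call) | (hi_call == -2)  # all missing counts as same
    good = covered & all_hom & same

    out: list[ROHSegment] = []
    cm = gmap.position_cM
    bp = gmap.position_bp
    for chrom, sl in gmap.chromosome_slices().items():
        g = good[sl]
        if not g.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], g.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2] - 1):
            lo, hi = sl.start + int(a), sl.start + int(b)
            if hi - lo + 1 < params.min_markers:
                continue
            if cm[hi] - cm[lo] <= params.min_length_cM:
                continue
            if covered_by_unaffected(chrom, lo, hi):
                continue
            out.append(
                ROHSegment(
                    sample_id="+".join(affected),
                    chromosome=chrom,
                    first_marker_index=lo,
                    last_marker_index=hi,
                    start_cM=float(cm[lo]),
                    end_cM=float(cm[hi]),
                    start_bp=int(bp[lo]),
                    end_bp=int(bp[hi]),
                    n_markers=hi - lo + 1,
                    n_het=0,
                )
            )
    return out
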