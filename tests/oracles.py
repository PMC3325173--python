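"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle restates the operation's definition directly (exhaustive
enumeration, full-sequence translation, exact integer arithmetic) and shares
no code with the implementation it checks.
"""

from math import comb

import numpy as np

from Bio.Seq import Seq

from rscan.variant_filter import TranscriptModel


# ---------------------------------------------------------------------------
# ROH: exhaustive maximal-interval enumeration


def roh_oracle(calls, cm, params):
    """All containment-maximal intervals satisfying the het-tolerance rules,
    then the length/marker-count thresholds, by testing every (i, j)."""
    n = len(calls)

    def valid(i, j):
        if calls[i] not in (0, 2) or calls[j] not in (0, 2):
            return False
        run = 0
        for t in range(i, j + 1):
            if calls[t] == 1:
                run += 1
                if run > params.max_consecutive_het:
                    return False
            elif calls[t] in (0, 2):
                run = 0
        w = params.window_size
        for a in range(i, j - w + 2):
            if sum(1 for t in range(a, a + w) if calls[t] == 1) > params.max_het_per_window:
                return False
        return True

    vals = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in vals
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in vals)
    ]
    return [
        (i, j)
        for (i, j) in maximal
        if cm[j] - cm[i] > params.min_length_cM and j - i + 1 >= params.min_markers
    ]


# ---------------------------------------------------------------------------
# Fisher: exact hypergeometric tail with integer arithmetic


def fisher_oracle(a, b, c, d):
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    hi = min(r1, c1)
    num = sum(comb(r1, x) * comb(n - r1, c1 - x) for x in range(a, hi + 1))
    return num / comb(n, c1)


# ---------------------------------------------------------------------------
# consequence classification: full-CDS translation before/after the edit


def random_transcript(rng, gene="G"):
    n_exons = int(rng.integers(1, 4))
    pos = int(rng.integers(100, 200))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(12, 40))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(10, 30))
    strand = "+" if rng.random() < 0.5 else "-"
    tx_start, tx_end = exons[0][0], exons[-1][1]
    seq = "".join(rng.choice(list("ACGT"), size=tx_end - tx_start + 1))
    # align the CDS to a multiple of 3 exonic bases
    exonic = [p for s, e in exons for p in range(s, e + 1)]
    lo = int(rng.integers(0, max(1, len(exonic) // 4)))
    hi = len(exonic) - 1 - int(rng.integers(0, max(1, len(exonic) // 4)))
    while (hi - lo + 1) % 3 != 0:
        hi -= 1
    cds_start, cds_end = exonic[lo], exonic[hi]
    return TranscriptModel(
        gene=gene, chromosome="1", strand=strand, exons=exons,
        cds_start=cds_start, cds_end=cds_end, sequence=seq,
    )


def translation_oracle(variant, model, splice_window=2):
    """Classify by rebuilding and translating the whole CDS."""
    pos = variant.position_bp
    if variant.chromosome != model.chromosome or not (
        model.tx_start <= pos <= model.tx_end
    ):
        return "noncoding"
    for i, (s, e) in enumerate(model.exons):
        if i > 0 and s - splice_window <= pos < s:
            return "splice_site"
        if i < len(model.exons) - 1 and e < pos <= e + splice_window:
            return "splice_site"
    base = {
        p: model.sequence[p - model.tx_start]
        for s, e in model.exons
        for p in range(s, e + 1)
    }
    cds_pos = sorted(p for p in base if model.cds_start <= p <= model.cds_end)
    cds_set = set(cds_pos)
    if variant.variant_class == "indel":
        if any(p in cds_set for p in range(pos, pos + len(variant.ref_allele))):
            shift = len(variant.alt_allele) - len(variant.ref_allele)
            return "frameshift" if shift % 3 else "coding_nonsynonymous"
        return "noncoding"
    if pos not in cds_set:
        return "noncoding"
    before_plus = "".join(base[p] for p in cds_pos)
    after_plus = "".join(base[p] if p != pos else variant.alt_allele for p in cds_pos)
    if model.strand == "-":
        before_plus = str(Seq(before_plus).reverse_complement())
        after_plus = str(Seq(after_plus).reverse_complement())
    prot_before = str(Seq(before_plus).translate())
    prot_after = str(Seq(after_plus).translate())
    return "coding_synonymous" if prot_before == prot_after else "coding_nonsynonymous"


def random_cds_snv(rng, model, make_variant):
    cds_pos = model.cds_positions()
    pos = int(rng.choice(cds_pos))
    ref = model.base_at(pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return make_variant(chrom="1", pos=pos, ref=ref, alt=alt, gene=model.gene)
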