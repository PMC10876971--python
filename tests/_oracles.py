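"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates — thresholds, base pairs, overlaps — and stays
deliberately naive and separate from the package's segment-arithmetic code.
"""

import numpy as np

from focalamp.genome_io import ArmTable, CopyNumberSegment, SampleProfile


def ap_oracle(labels, scores) -> float:
    """Step-wise average precision by explicit threshold enumeration."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def auroc_oracle(labels, scores) -> float:
    """Mann-Whitney concordance by explicit pair enumeration (ties = 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def _per_bp_arrays(profile: SampleProfile, length_by_chrom: dict[str, int]):
    """Dense per-base-pair total/minor arrays (position p stored at p-1;
    -1 marks bases covered by no segment)."""
    totals = {c: np.full(n, -1, dtype=int) for c, n in length_by_chrom.items()}
    minors = {c: np.full(n, -1, dtype=int) for c, n in length_by_chrom.items()}
    for seg in profile.segments:
        totals[seg.chrom][seg.start - 1 : seg.end] = seg.total_cn
        if seg.minor_cn is not None:
            minors[seg.chrom][seg.start - 1 : seg.end] = seg.minor_cn
    return totals, minors


def ploh_oracle(profile: SampleProfile, length_by_chrom) -> float:
    totals, minors = _per_bp_arrays(profile, length_by_chrom)
    num = den = 0
    for chrom in length_by_chrom:
        t, m = totals[chrom], minors[chrom]
        known = (t >= 0) & (m >= 0)
        den += int(known.sum())
        num += int((known & (m == 0) & (t >= 1)).sum())
    return num / den


def cna_burden_oracle(profile: SampleProfile, length_by_chrom, base: int) -> float:
    totals, _ = _per_bp_arrays(profile, length_by_chrom)
    num = den = 0
    for chrom in length_by_chrom:
        t = totals[chrom]
        covered = t >= 0
        den += int(covered.sum())
        num += int((covered & (t != base)).sum())
    return num / den


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def ascore_oracle(profile: SampleProfile, arms: ArmTable, base: int) -> int:
    lengths = {c: arms.chrom_length(c) for c in arms.chromosomes()}
    totals, _ = _per_bp_arrays(profile, lengths)
    score = 0
    for arm in arms.included_autosomal_arms():
        chrom, start, end = arms.arms[arm]
        t = totals[chrom][start - 1 : end]
        t = t[t >= 0]
        if t.size == 0:
            continue
        if _round_half_away(float(t.mean())) != base:
            score += 1
    return score


def collapse_oracle(profile: SampleProfile, genes):
    """Per-gene max-overlap assignment by exhaustive per-pair overlap
    counting; tie toward higher total copy number."""
    out = {}
    for gene in genes:
        best = None
        for seg in profile.segments:
            if seg.chrom != gene.chrom:
                continue
            ov = len(
                set(range(gene.start, gene.end + 1))
                & set(range(seg.start, seg.end + 1))
            )
            if ov == 0:
                continue
            if best is None or (ov, seg.total_cn) > (best[0], best[1]):
                best = (ov, seg.total_cn, seg.minor_cn)
        out[gene.gene_id] = (None, None) if best is None else (best[1], best[2])
    return out


def random_small_profile(rng, with_minor=True, max_segments=20):
    """Random valid profile on a 2-chromosome mini-genome (<= 1 Mb arms)."""
    lengths = {"1": 1_000_000, "2": 600_000}
    segments = []
    for chrom, length in lengths.items():
        n_seg = int(rng.integers(1, max_segments // 2 + 1))
        cuts = np.sort(rng.choice(np.arange(2, length), size=2 * n_seg, replace=False))
        for i in range(n_seg):
            start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
            total = int(rng.integers(0, 9))
            minor = int(rng.integers(0, total + 1)) if with_minor else None
            if with_minor and rng.random() < 0.1:
                minor = None  # occasional missing minor allele
            segments.append(CopyNumberSegment(chrom, start, end, total, minor))
    ploidy = float(rng.uniform(1.5, 4.5))
    return (
        SampleProfile("R", segments, purity=float(rng.uniform(0.2, 1.0)), ploidy=ploidy),
        lengths,
    )


def mini_arm_table(lengths=None) -> ArmTable:
    lengths = lengths or {"1": 1_000_000, "2": 600_000}
    arms = {}
    for chrom, length in lengths.items():
        mid = length // 2
        arms[f"{chrom}p"] = (chrom, 1, mid)
        arms[f"{chrom}q"] = (chrom, mid + 1, length)
    return ArmTable(arms=arms, excluded=set(), build="mini")
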