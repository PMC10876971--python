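"""Gene-level collapsing of copy number and the 11 predictive features.

The feature set per (sample, gene) row:

=============  ==============================================================
total_cn       total copy number of the gene (max-overlap segment)
minor_cn       minor-allele copy number of the gene (may be missing)
purity         tumor purity
ploidy         tumor ploidy
pLOH           fraction of the autosomal genome in LOH (minor_cn = 0)
AScore         number of autosomal arms whose rounded copy number deviates
               from the rounded sample ploidy
cna_burden     fraction of the autosomal genome whose total copy number
               deviates from the rounded sample ploidy
freq_*         four per-gene amplicon-class frequency priors
               (Circular / BFB / HR / Linear)
=============  ==============================================================

Sex chromosomes contribute to gene-level features but are excluded from the
genome-wide summaries (pLOH, AScore, cna_burden) to avoid gender-driven
artifacts.  All rounding is half away from zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_io import (
    AmpliconPriorTable,
    ArmTable,
    GeneAnnotation,
    SampleProfile,
    load_arm_table,
)

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "total_cn",
    "minor_cn",
    "purity",
    "ploidy",
    "pLOH",
    "AScore",
    "cna_burden",
    "freq_Circular",
    "freq_BFB",
    "freq_HR",
    "freq_Linear",
]

ID_COLUMNS = ["sample_id", "gene_id"]


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def collapse_to_gene_cn(
    profile: SampleProfile, genes: list[GeneAnnotation]
) -> dict[str, tuple[int | None, int | None]]:
    """Assign each gene the (total_cn, minor_cn) of the overlapping segment
    with the largest overlap length; ties break toward higher total_cn.

    Genes overlapping no segment map to ``(None, None)``.
    """
    by_chrom: dict[str, list] = {}
    for seg in profile.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    out: dict[str, tuple[int | None, int | None]] = {}
    for gene in genes:
        best: tuple[int, int] | None = None  # (overlap, total_cn)
        best_seg = None
        for seg in by_chrom.get(gene.chrom, []):
            ov = min(gene.end, seg.end) - max(gene.start, seg.start) + 1
            if ov <= 0:
                continue
            key = (ov, seg.total_cn)
            if best is None or key > best:
                best, best_seg = key, seg
        if best_seg is None:
            out[gene.gene_id] = (None, None)
        else:
            out[gene.gene_id] = (best_seg.total_cn, best_seg.minor_cn)
    return out


def compute_ploh(profile: SampleProfile) -> float:
    """Autosomal genome fraction in LOH: segments with minor_cn = 0 and
    total_cn >= 1, over all autosomal segments with known minor_cn."""
    segs = [s for s in profile.autosomal_segments() if s.minor_cn is not None]
    if not segs:
        raise ValueError(
            f"{profile.sample_id}: pLOH unavailable for tumor-only input "
            "(no autosomal segment has a minor-allele copy number)"
        )
    total = sum(s.length for s in segs)
    loh = sum(s.length for s in segs if s.minor_cn == 0 and s.total_cn >= 1)
    return loh / total


def compute_aneuploidy_score(
    profile: SampleProfile, arms: ArmTable | None = None
) -> int:
    """Count autosomal arms whose length-weighted mean copy number, rounded
    half away from zero, deviates from the rounded sample ploidy.

    Arms flagged excluded (acrocentric p-arms) and arms with zero covered
    length are skipped.
    """
    if arms is None:
        arms = load_arm_table()
    base = round_half_away(profile.ploidy)
    segs = profile.autosomal_segments()
    score = 0
    for arm_name in arms.included_autosomal_arms():
        chrom, a_start, a_end = arms.arms[arm_name]
        w_sum = 0
        cn_sum = 0.0
        for seg in segs:
            if seg.chrom != chrom:
                continue
            ov = min(seg.end, a_end) - max(seg.start, a_start) + 1
            if ov > 0:
                w_sum += ov
                cn_sum += ov * seg.total_cn
        if w_sum == 0:
            log.debug("arm %s has zero covered length; skipped", arm_name)
            continue
        if round_half_away(cn_sum / w_sum) != base:
            score += 1
    return score


def compute_cna_burden(profile: SampleProfile) -> float:
    """Autosomal genome fraction whose total copy number deviates from the
    rounded sample ploidy."""
    segs = profile.autosomal_segments()
    if not segs:
        return 0.0
    base = round_half_away(profile.ploidy)
    total = sum(s.length for s in segs)
    altered = sum(s.length for s in segs if s.total_cn != base)
    return altered / total


def sample_summary_features(
    profile: SampleProfile, arms: ArmTable | None = None
) -> dict[str, float]:
    """purity, ploidy, pLOH, AScore and cna_burden for one sample.

    pLOH is NaN when no autosomal minor-allele copy number is available
    (tumor-only input); the classifier routes missing values natively.
    """
    try:
        ploh: float = compute_ploh(profile)
    except ValueError:
        ploh = float("nan")
    return {
        "purity": profile.purity,
        "ploidy": profile.ploidy,
        "pLOH": ploh,
        "AScore": float(compute_aneuploidy_score(profile, arms)),
        "cna_burden": compute_cna_burden(profile),
    }


def build_feature_matrix(
    profiles: list[SampleProfile],
    genes: list[GeneAnnotation],
    priors: AmpliconPriorTable,
    arms: ArmTable | None = None,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """One row per (sample, gene) with identifier columns followed by the 11
    features.  Missing gene copy numbers stay missing (NaN); absent genes in
    the prior table get all-zero priors."""
    if not profiles:
        raise ValueError("empty profile list")
    if arms is None:
        arms = load_arm_table()
    scope = [g for g in genes if restrict_to is None or g.gene_id in restrict_to]

    rows = []
    for profile in profiles:
        summary = sample_summary_features(profile, arms)
        gene_cn = collapse_to_gene_cn(profile, scope)
        for gene in scope:
            total_cn, minor_cn = gene_cn[gene.gene_id]
            fC, fB, fH, fL = priors.lookup(gene.gene_id)
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "gene_id": gene.gene_id,
                    "total_cn": np.nan if total_cn is None else float(total_cn),
                    "minor_cn": np.nan if minor_cn is None else float(minor_cn),
                    **summary,
                    "freq_Circular": fC,
                    "freq_BFB": fB,
                    "freq_HR": fH,
                    "freq_Linear": fL,
                }
            )
    return pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_COLUMNS)
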