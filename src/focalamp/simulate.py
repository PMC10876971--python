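"""Synthetic tumor cohorts with planted focal amplifications.

The generator emulates the statistical structure the cargo-gene classifier
assumes: a mostly-diploid (or triploid/tetraploid) baseline with arm-level
gains and losses, LOH tracts, purity and ploidy variation, and planted
focal amplicons of two kinds — circular (ecDNA, copy number 8-100) and
noncircular (chromosomal HSR/BFB-like, copy number 5-12).  The two copy
number ranges deliberately overlap so that copy number alone is an
informative but imperfect predictor, mirroring the observed gap between a
copy-number-only baseline and the full model.  A small set of hotspot genes
attracts most circular events, which makes the per-gene amplicon-frequency
priors informative, the way recurrent oncogene cargo does in real tumor
catalogs.

Expression is coupled to copy number with an ecDNA-specific boost:
``TPM = a*CN + b*is_cargo + cancer-type offset + d*purity + noise``,
truncated at zero.

Ground truth (per-gene cargo labels and per-sample classes) is recorded for
every planted event, so the whole pipeline can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_engineering import collapse_to_gene_cn
from .focal_typing import AmpParams
from .genome_io import (
    AmpliconPriorTable,
    ArmTable,
    CopyNumberSegment,
    GeneAnnotation,
    SampleProfile,
    load_arm_table,
    write_gene_bed,
    write_priors,
)

NONCIRCULAR_SUBTYPES = ("BFB", "HR", "Linear")


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Defaults define the package's reference study conditions: 200 samples x
    1000 genes with a gene-level cargo rate in the few-per-thousand regime.
    """

    n_samples: int = 200
    n_genes: int = 1000
    gene_length: int = 100_000
    rate_circular_sample: float = 0.3
    rate_noncircular_sample: float = 0.25
    second_event_prob: float = 0.5  # events per positive sample: 1 or 2
    genes_per_event: tuple[int, int] = (2, 10)  # inclusive range
    circular_cn: tuple[int, int] = (8, 100)  # inclusive range
    noncircular_cn: tuple[int, int] = (5, 12)
    arm_gain_rate: float = 0.05
    arm_loss_rate: float = 0.05
    loh_rate: float = 0.1  # per chromosome, one tract
    loh_max_length: int = 30_000_000
    purity_range: tuple[float, float] = (0.2, 1.0)
    ploidy_choices: tuple[int, ...] = (2, 3, 4)
    ploidy_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    ploidy_jitter: float = 0.05
    hotspot_fraction: float = 0.05
    hotspot_weight: float = 0.9  # prob. a circular event anchors on a hotspot
    expr_a: float = 5.0  # TPM per copy
    expr_b: float = 50.0  # ecDNA-specific TPM boost
    expr_d: float = 10.0  # purity coefficient
    expr_noise_sd: float = 10.0
    cancer_types: tuple[str, ...] = ("GI", "CNS", "LUNG")
    cancer_type_offsets: tuple[float, ...] = (0.0, 20.0, 40.0)
    amp_params: AmpParams = field(default_factory=AmpParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.rate_circular_sample,
            self.rate_noncircular_sample,
            self.second_event_prob,
            self.arm_gain_rate,
            self.arm_loss_rate,
            self.loh_rate,
            self.hotspot_fraction,
            self.hotspot_weight,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.n_samples < 0 or self.n_genes < 1:
            raise ValueError("invalid cohort dimensions")
        if len(self.cancer_types) != len(self.cancer_type_offsets):
            raise ValueError("cancer_types and cancer_type_offsets must align")


@dataclass
class GenomeTemplate:
    """Deterministic gene catalog over the autosomes of an arm table."""

    arms: ArmTable
    genes: list[GeneAnnotation]
    hotspot_genes: set[str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {
            c: self.arms.chrom_length(c)
            for c in self.arms.chromosomes()
            if c in {str(i) for i in range(1, 23)}
        }


def build_template(config: SimulationConfig, arms: ArmTable | None = None) -> GenomeTemplate:
    """Place ``n_genes`` evenly across the autosomes and pick hotspot genes.

    Placement is an even grid (deterministic); the hotspot subset is drawn
    from the config seed so the whole template is a pure function of the
    config.
    """
    if arms is None:
        arms = load_arm_table()
    lengths = {
        c: arms.chrom_length(c)
        for c in arms.chromosomes()
        if c in {str(i) for i in range(1, 23)}
    }
    if not lengths:
        raise ValueError("arm table contains no autosomes")
    total = sum(lengths.values())
    step = total / config.n_genes
    genes: list[GeneAnnotation] = []
    offsets: list[tuple[str, int, int]] = []  # (chrom, cum_start, cum_end)
    cum = 0
    for c in sorted(lengths, key=int):
        offsets.append((c, cum, cum + lengths[c]))
        cum += lengths[c]
    for i in range(config.n_genes):
        pos = int(i * step + step / 2)
        for chrom, lo, hi in offsets:
            if lo <= pos < hi:
                start = max(1, pos - lo)
                end = min(start + config.gene_length - 1, lengths[chrom])
                genes.append(GeneAnnotation(f"G{i:04d}", chrom, start, end))
                break
    rng = np.random.default_rng([config.seed, 915])
    n_hot = max(1, int(round(config.hotspot_fraction * len(genes))))
    hot_idx = rng.choice(len(genes), size=n_hot, replace=False)
    hotspots = {genes[i].gene_id for i in hot_idx}
    return GenomeTemplate(arms=arms, genes=genes, hotspot_genes=hotspots)


# ---------------------------------------------------------------------------
# segment painting


def _paint(
    segments: list[CopyNumberSegment],
    start: int,
    end: int,
    total: int | None = None,
    minor: int | None | str = "keep",
    force_loh: bool = False,
) -> list[CopyNumberSegment]:
    """Overlay an interval onto a sorted, non-overlapping segment list.

    With ``total`` set, the overlapped region is replaced by one segment at
    (total, minor).  With ``force_loh``, the overlapped parts keep their
    total copy number but drop minor_cn to 0 (where total >= 1).
    """
    out: list[CopyNumberSegment] = []
    painted: list[CopyNumberSegment] = []
    for seg in segments:
        if seg.end < start or seg.start > end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(
                CopyNumberSegment(seg.chrom, seg.start, start - 1, seg.total_cn, seg.minor_cn)
            )
        if seg.end > end:
            out.append(
                CopyNumberSegment(seg.chrom, end + 1, seg.end, seg.total_cn, seg.minor_cn)
            )
        if force_loh:
            o_start, o_end = max(seg.start, start), min(seg.end, end)
            new_minor = 0 if seg.total_cn >= 1 else seg.minor_cn
            painted.append(
                CopyNumberSegment(seg.chrom, o_start, o_end, seg.total_cn, new_minor)
            )
    if total is not None:
        chrom = segments[0].chrom if segments else ""
        painted = [
            CopyNumberSegment(chrom, start, end, total, None if minor == "keep" else minor)
        ]
    out.extend(painted)
    return sorted(out, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# per-sample simulation


def _focal_cn(draw_range: tuple[int, int], ploidy: float, params: AmpParams, rng) -> int:
    """Draw an amplicon copy number, floored so the planted event always
    satisfies the focal-amplification predicate at this sample's ploidy."""
    thr = int(math.floor(max(params.cn_min, params.ratio_min * ploidy))) + 1
    lo, hi = draw_range
    return max(int(rng.integers(lo, hi + 1)), thr)


def simulate_profile(
    config: SimulationConfig,
    sample_index: int,
    template: GenomeTemplate | None = None,
) -> tuple[SampleProfile, pd.DataFrame, str]:
    """Simulate one tumor: returns (profile, per-gene truth frame, class).

    The truth frame has gene_id, is_cargo, planted_class
    (circular / BFB / HR / Linear / none).  Deterministic for a given
    (config seed, sample index).
    """
    if template is None:
        template = build_template(config)
    rng = np.random.default_rng([config.seed, 1, sample_index])

    base_ploidy = int(
        rng.choice(np.array(config.ploidy_choices), p=np.array(config.ploidy_probs))
    )
    ploidy = max(1.0, base_ploidy + float(rng.normal(0.0, config.ploidy_jitter)))
    purity = float(rng.uniform(*config.purity_range))
    if purity <= 0:
        purity = 0.01

    base_minor = base_ploidy // 2
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for arm_name in sorted(template.arms.arms):
        chrom, a_start, a_end = template.arms.arms[arm_name]
        if chrom not in template.chrom_lengths:
            continue
        total = base_ploidy
        if rng.random() < config.arm_gain_rate:
            total += 1
        elif rng.random() < config.arm_loss_rate and total > 1:
            total -= 1
        minor = min(base_minor, total)
        by_chrom.setdefault(chrom, []).append(
            CopyNumberSegment(chrom, a_start, a_end, total, minor)
        )

    for chrom in sorted(by_chrom, key=int):
        if rng.random() < config.loh_rate:
            length = template.chrom_lengths[chrom]
            tract_len = int(rng.integers(1_000_000, config.loh_max_length))
            tract_start = int(rng.integers(1, max(2, length - tract_len)))
            by_chrom[chrom] = _paint(
                by_chrom[chrom], tract_start, min(tract_start + tract_len, length),
                force_loh=True,
            )

    genes = template.genes
    gene_class = {g.gene_id: "none" for g in genes}
    used_gene_idx: set[int] = set()
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    hotspot_list = sorted(template.hotspot_genes)

    def plant_events(kind: str) -> bool:
        """Plant 1-2 focal events of the given kind; True if any planted."""
        planted = False
        n_events = 1 + int(rng.random() < config.second_event_prob)
        for _ in range(n_events):
            if kind == "circular" and rng.random() < config.hotspot_weight:
                anchor_id = hotspot_list[int(rng.integers(len(hotspot_list)))]
                anchor = gene_index[anchor_id]
            else:
                anchor = int(rng.integers(len(genes)))
            k = int(rng.integers(config.genes_per_event[0], config.genes_per_event[1] + 1))
            chrom = genes[anchor].chrom
            members = [
                i
                for i in range(anchor, min(anchor + k, len(genes)))
                if genes[i].chrom == chrom
            ]
            if not members or any(i in used_gene_idx for i in members):
                continue  # avoid stacking events on top of each other
            used_gene_idx.update(members)
            span_start = max(1, genes[members[0]].start - 10_000)
            span_end = min(
                genes[members[-1]].end + 10_000, template.chrom_lengths[chrom]
            )
            if kind == "circular":
                cn = _focal_cn(config.circular_cn, ploidy, config.amp_params, rng)
                klass = "circular"
            else:
                cn = _focal_cn(config.noncircular_cn, ploidy, config.amp_params, rng)
                klass = NONCIRCULAR_SUBTYPES[int(rng.integers(3))]
            minor = int(rng.integers(0, 2))
            by_chrom[chrom] = _paint(
                by_chrom[chrom], span_start, span_end, total=cn, minor=minor
            )
            for i in members:
                gene_class[genes[i].gene_id] = klass
            planted = True
        return planted

    has_circular = rng.random() < config.rate_circular_sample and plant_events("circular")
    has_noncircular = (
        rng.random() < config.rate_noncircular_sample and plant_events("noncircular")
    )

    segments = [s for chrom in sorted(by_chrom, key=int) for s in by_chrom[chrom]]
    profile = SampleProfile(
        sample_id=f"S{sample_index:04d}",
        segments=segments,
        purity=purity,
        ploidy=ploidy,
        gender="XX" if rng.random() < 0.5 else "XY",
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_cargo": [gene_class[g.gene_id] == "circular" for g in genes],
            "planted_class": [gene_class[g.gene_id] for g in genes],
        }
    )
    if has_circular:
        sample_class = "circular"
    elif has_noncircular:
        sample_class = "noncircular"
    else:
        sample_class = "nofocal"
    return profile, truth, sample_class


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    template: GenomeTemplate
    profiles: list[SampleProfile]
    truth: pd.DataFrame  # sample_id, gene_id, is_cargo, planted_class
    sample_classes: dict[str, str]
    sample_meta: pd.DataFrame  # sample_id, cancer_type, purity, ploidy
    expression: pd.DataFrame  # sample_id, gene_id, TPM, CN, circular, ...
    priors: AmpliconPriorTable

    @property
    def genes(self) -> list[GeneAnnotation]:
        return self.template.genes

    def gene_labels(self) -> pd.Series:
        """Binary cargo labels aligned to (sample_id, gene_id) sort order."""
        return self.truth.set_index(["sample_id", "gene_id"])["is_cargo"].astype(int)


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Simulate a full cohort with truth labels, coupled expression and
    catalog-derived amplicon-frequency priors."""
    if config is None:
        config = SimulationConfig()
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    template = build_template(config)
    rng = np.random.default_rng([config.seed, 2])

    profiles, truth_frames, classes = [], [], {}
    for i in range(config.n_samples):
        profile, truth, klass = simulate_profile(config, i, template)
        truth.insert(0, "sample_id", profile.sample_id)
        profiles.append(profile)
        truth_frames.append(truth)
        classes[profile.sample_id] = klass
    truth = pd.concat(truth_frames, ignore_index=True)

    # amplicon-class frequency priors from the planted catalog itself
    n = config.n_samples
    counts = (
        truth[truth["planted_class"] != "none"]
        .groupby(["gene_id", "planted_class"])
        .size()
        .unstack(fill_value=0)
    )
    mapping = {}
    for gene_id, row in counts.iterrows():
        mapping[str(gene_id)] = (
            row.get("circular", 0) / n,
            row.get("BFB", 0) / n,
            row.get("HR", 0) / n,
            row.get("Linear", 0) / n,
        )
    priors = AmpliconPriorTable(mapping)

    type_idx = rng.integers(len(config.cancer_types), size=config.n_samples)
    sample_meta = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "cancer_type": [config.cancer_types[i] for i in type_idx],
            "purity": [p.purity for p in profiles],
            "ploidy": [p.ploidy for p in profiles],
            "truth_class": [classes[p.sample_id] for p in profiles],
        }
    )

    # CN-coupled expression with an ecDNA-specific boost
    offsets = dict(zip(config.cancer_types, config.cancer_type_offsets))
    expr_rows = []
    cargo_lookup = truth.set_index(["sample_id", "gene_id"])["is_cargo"]
    for profile, ctype in zip(profiles, sample_meta["cancer_type"]):
        gene_cn = collapse_to_gene_cn(profile, template.genes)
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(template.genes))
        for j, gene in enumerate(template.genes):
            cn = gene_cn[gene.gene_id][0]
            cn_val = float(cn) if cn is not None else 0.0
            cargo = bool(cargo_lookup[(profile.sample_id, gene.gene_id)])
            tpm = (
                config.expr_a * cn_val
                + config.expr_b * cargo
                + offsets[ctype]
                + config.expr_d * profile.purity
                + noise[j]
            )
            expr_rows.append(
                {
                    "sample_id": profile.sample_id,
                    "gene_id": gene.gene_id,
                    "TPM": max(0.0, tpm),
                    "CN": cn_val,
                    "circular": int(cargo),
                    "cancer_type": ctype,
                    "purity": profile.purity,
                }
            )
    expression = pd.DataFrame(expr_rows)

    return SimulatedCohort(
        config=config,
        template=template,
        profiles=profiles,
        truth=truth,
        sample_classes=classes,
        sample_meta=sample_meta,
        expression=expression,
        priors=priors,
    )


def simulate_expression_study(
    n_samples: int = 500,
    n_signal_genes: int = 5,
    n_null_genes: int = 20,
    b: float = 50.0,
    noise_sd: float = 10.0,
    circular_fraction: float = 0.1,
    a: float = 5.0,
    d: float = 10.0,
    cancer_types: tuple[str, ...] = ("GI", "CNS", "LUNG"),
    cancer_type_offsets: tuple[float, ...] = (50.0, 70.0, 90.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Expression table drawn directly from the regression-model data-
    generating process, for parameter-recovery and FDR-control studies.

    Signal genes carry the ecDNA boost ``b``; null genes have b = 0 with the
    same copy-number and covariate structure.  Returns the long-format frame
    :func:`focalamp.cohort_stats.ecdna_oncogene_regression` consumes.
    """
    rng = np.random.default_rng([seed, 77])
    ctypes = [cancer_types[i] for i in rng.integers(len(cancer_types), size=n_samples)]
    offsets = dict(zip(cancer_types, cancer_type_offsets))
    purity = rng.uniform(0.2, 1.0, size=n_samples)
    rows = []
    for g in range(n_signal_genes + n_null_genes):
        signal = g < n_signal_genes
        gene_id = f"{'SIG' if signal else 'NULL'}{g:03d}"
        circ = rng.random(n_samples) < circular_fraction
        # non-circular CN overlaps the circular range (chromosomal focal
        # amplification exists too) so the two covariates are separable
        cn = np.where(
            circ,
            rng.integers(8, 41, size=n_samples),
            rng.integers(1, 16, size=n_samples),
        ).astype(float)
        noise = rng.normal(0.0, noise_sd, size=n_samples)
        tpm = (
            a * cn
            + (b if signal else 0.0) * circ
            + np.array([offsets[t] for t in ctypes])
            + d * purity
            + noise
        )
        for i in range(n_samples):
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "gene_id": gene_id,
                    "TPM": max(0.0, float(tpm[i])),
                    "CN": cn[i],
                    "circular": int(circ[i]),
                    "cancer_type": ctypes[i],
                    "purity": float(purity[i]),
                }
            )
    return pd.DataFrame(rows)


def export_fixtures(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as the plain-text fixture set the readers consume:
    segments.tsv, genes.bed, priors.tsv, expression.tsv, truth.tsv,
    samples.tsv.  Deterministic bytes for a fixed seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("segments", "segments.tsv"),
        ("genes", "genes.bed"),
        ("priors", "priors.tsv"),
        ("expression", "expression.tsv"),
        ("truth", "truth.tsv"),
        ("samples", "samples.tsv"),
    ]}

    seg_rows = []
    for p in cohort.profiles:
        for s in p.segments:
            seg_rows.append(
                {
                    "sample": p.sample_id,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "total_cn": s.total_cn,
                    "minor_cn": "" if s.minor_cn is None else s.minor_cn,
                    "purity": p.purity,
                    "ploidy": p.ploidy,
                    "gender": p.gender,
                }
            )
    pd.DataFrame(seg_rows).to_csv(paths["segments"], sep="\t", index=False)
    write_gene_bed(cohort.genes, paths["genes"])
    write_priors(cohort.priors, paths["priors"])
    cohort.expression[["sample_id", "gene_id", "TPM"]].to_csv(
        paths["expression"], sep="\t", index=False
    )
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.sample_meta.to_csv(paths["samples"], sep="\t", index=False)
    return paths
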