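"""Three-class focal-amplification typing.

A gene (and by precedence its tumor) is called:

* ``circular``    — focally amplified AND cargo probability >= p_cut
                    (resides on extrachromosomal DNA);
* ``noncircular`` — focally amplified only (chromosomal amplification,
                    e.g. HSR/BFB);
* ``nofocal``     — no focal amplification detected.

The focal-amplification predicate is ``total_cn >= max(cn_min,
ratio_min * ploidy)`` with defaults cn_min=5, ratio_min=2.25 — the
near-diploid CN>4.5 amplicon-seeding convention, scaled by ploidy.  A high
probability without focal amplification is vetoed to ``nofocal``, keeping
the classes mutually exclusive and anchored to observable amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CytobandTable, GeneAnnotation

log = logging.getLogger(__name__)

CLASSES = ("circular", "noncircular", "nofocal")
_PRECEDENCE = {"circular": 0, "noncircular": 1, "nofocal": 2}

DEFAULT_CN_MIN = 5.0
DEFAULT_RATIO_MIN = 2.25


@dataclass(frozen=True)
class AmpParams:
    cn_min: float = DEFAULT_CN_MIN
    ratio_min: float = DEFAULT_RATIO_MIN


@dataclass(frozen=True)
class GeneCall:
    sample_id: str
    gene_id: str
    probability: float
    total_cn: int | None
    ploidy: float
    klass: str


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    klass: str
    cargo_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "cargo_genes", tuple(self.cargo_genes))
        if (self.klass == "circular") != bool(self.cargo_genes):
            raise ValueError(
                f"{self.sample_id}: circular calls must carry cargo genes "
                "(and only circular calls may)"
            )


@dataclass(frozen=True)
class CytobandCall:
    sample_id: str
    cytoband: str
    klass: str
    supporting_genes: tuple[str, ...] = ()


def is_focally_amplified(
    total_cn: float | None, ploidy: float, params: AmpParams | None = None
) -> bool:
    """True iff total_cn >= max(cn_min, ratio_min * ploidy)."""
    if params is None:
        params = AmpParams()
    if total_cn is None or (isinstance(total_cn, float) and np.isnan(total_cn)):
        log.debug("missing total_cn treated as not focally amplified")
        return False
    return total_cn >= max(params.cn_min, params.ratio_min * ploidy)


def call_genes(
    probabilities,
    features: pd.DataFrame,
    p_cut: float = 0.5,
    amp_params: AmpParams | None = None,
) -> list[GeneCall]:
    """Type each (sample, gene) row given its cargo probability and copy
    number.  ``features`` needs sample_id, gene_id, total_cn, ploidy."""
    if not (0.0 < p_cut < 1.0):
        raise ValueError("p_cut must lie strictly inside (0, 1)")
    if amp_params is None:
        amp_params = AmpParams()
    probabilities = np.asarray(probabilities, dtype=float)
    if len(probabilities) != len(features):
        raise ValueError("probabilities and features are not aligned")
    calls = []
    for prob, (_, row) in zip(probabilities, features.iterrows()):
        cn = row["total_cn"]
        cn_val = None if pd.isna(cn) else float(cn)
        amplified = is_focally_amplified(cn_val, float(row["ploidy"]), amp_params)
        if amplified and prob >= p_cut:
            klass = "circular"
        elif amplified:
            klass = "noncircular"
        else:
            if prob >= p_cut:
                log.debug(
                    "vetoed: %s/%s prob %.3f without focal amplification",
                    row["sample_id"], row["gene_id"], prob,
                )
            klass = "nofocal"
        calls.append(
            GeneCall(
                sample_id=str(row["sample_id"]),
                gene_id=str(row["gene_id"]),
                probability=float(prob),
                total_cn=None if cn_val is None else int(cn_val),
                ploidy=float(row["ploidy"]),
                klass=klass,
            )
        )
    return calls


def call_sample(gene_calls: list[GeneCall]) -> SampleCall:
    """Collapse one sample's gene calls by precedence
    circular > noncircular > nofocal; circular genes become the cargo."""
    if not gene_calls:
        log.warning("empty gene-call list; sample typed nofocal")
        return SampleCall(sample_id="", klass="nofocal")
    sids = {c.sample_id for c in gene_calls}
    if len(sids) != 1:
        raise ValueError(f"gene calls span multiple samples: {sorted(sids)}")
    sid = gene_calls[0].sample_id
    cargo = tuple(c.gene_id for c in gene_calls if c.klass == "circular")
    if cargo:
        return SampleCall(sample_id=sid, klass="circular", cargo_genes=cargo)
    if any(c.klass == "noncircular" for c in gene_calls):
        return SampleCall(sample_id=sid, klass="noncircular")
    return SampleCall(sample_id=sid, klass="nofocal")


def call_cohort(gene_calls: list[GeneCall]) -> list[SampleCall]:
    by_sample: dict[str, list[GeneCall]] = {}
    for gc in gene_calls:
        by_sample.setdefault(gc.sample_id, []).append(gc)
    return [call_sample(v) for _, v in sorted(by_sample.items())]


def aggregate_to_cytoband(
    gene_calls: list[GeneCall],
    genes: list[GeneAnnotation],
    cytobands: CytobandTable,
) -> list[CytobandCall]:
    """Per (sample, cytoband) call: max-precedence class among member genes.

    Genes resolving to no cytoband are skipped.  Bands with no calls are
    absent from the output.
    """
    coords = {g.gene_id: g for g in genes}
    grouped: dict[tuple[str, str], list[GeneCall]] = {}
    for gc in gene_calls:
        ann = coords.get(gc.gene_id)
        if ann is None:
            log.debug("gene %s has no annotation; skipped", gc.gene_id)
            continue
        band = cytobands.band_of(ann.chrom, ann.start, ann.end)
        if band is None:
            log.debug("gene %s outside any cytoband; skipped", gc.gene_id)
            continue
        grouped.setdefault((gc.sample_id, band), []).append(gc)
    out = []
    for (sid, band), calls in sorted(grouped.items()):
        klass = min((c.klass for c in calls), key=_PRECEDENCE.__getitem__)
        out.append(
            CytobandCall(
                sample_id=sid,
                cytoband=band,
                klass=klass,
                supporting_genes=tuple(c.gene_id for c in calls if c.klass == klass),
            )
        )
    return out
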