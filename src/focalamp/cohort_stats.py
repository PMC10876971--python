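"""Downstream cohort statistics for focal-amplification calls.

Covers the association between extrachromosomal amplification and oncogene
expression (per-gene multivariable OLS with BH-FDR), fold-change-versus-CN
model comparison, mutual-exclusivity odds ratios, 1-Mb windowed genome-wide
distributions, Circle-Seq record filtering, and cohort summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome_io import CircleMapRecord

log = logging.getLogger(__name__)


@dataclass
class OncogeneAssocResult:
    gene_id: str
    coef_cn: float  # a
    coef_circular: float  # b
    coef_purity: float  # d
    intercept: float  # e
    cancer_type_coefs: dict[str, float]  # c_k contrasts
    p_circular: float  # NaN when the contrast is inestimable
    fdr_circular: float
    is_ecdna_associated: bool


def ecdna_oncogene_regression(data: pd.DataFrame) -> list[OncogeneAssocResult]:
    """Per-gene OLS of ``TPM ~ CN + Circular + CancerType + TumorPurity``.

    ``data`` is long-format with columns sample_id, gene_id, TPM, CN,
    circular (0/1), cancer_type, purity.  The two-sided p-value of the
    circular coefficient is BH-adjusted across all testable genes; a gene is
    ecDNA-associated iff that FDR is below 0.05.  Genes whose circular
    indicator has a single level (or too few samples) get missing p and are
    excluded from the FDR ranking.
    """
    need = {"sample_id", "gene_id", "TPM", "CN", "circular", "cancer_type", "purity"}
    if not need.issubset(data.columns):
        raise ValueError(f"regression input needs columns {sorted(need)}")
    results: list[OncogeneAssocResult] = []
    testable_idx: list[int] = []
    for gene, sub in data.groupby("gene_id", sort=True):
        sub = sub.dropna(subset=["TPM", "CN", "circular", "purity"])
        n_params = 3 + max(sub["cancer_type"].nunique() - 1, 0) + 1
        estimable = sub["circular"].nunique() == 2 and len(sub) > n_params
        if not estimable:
            results.append(
                OncogeneAssocResult(
                    gene_id=str(gene),
                    coef_cn=float("nan"),
                    coef_circular=float("nan"),
                    coef_purity=float("nan"),
                    intercept=float("nan"),
                    cancer_type_coefs={},
                    p_circular=float("nan"),
                    fdr_circular=float("nan"),
                    is_ecdna_associated=False,
                )
            )
            continue
        sub = sub.assign(circular=sub["circular"].astype(int))
        if sub["cancer_type"].nunique() > 1:
            formula = "TPM ~ CN + circular + C(cancer_type) + purity"
        else:
            formula = "TPM ~ CN + circular + purity"
        fit = smf.ols(formula, data=sub).fit()
        ct_coefs = {
            name: float(val)
            for name, val in fit.params.items()
            if name.startswith("C(cancer_type)")
        }
        results.append(
            OncogeneAssocResult(
                gene_id=str(gene),
                coef_cn=float(fit.params["CN"]),
                coef_circular=float(fit.params["circular"]),
                coef_purity=float(fit.params["purity"]),
                intercept=float(fit.params["Intercept"]),
                cancer_type_coefs=ct_coefs,
                p_circular=float(fit.pvalues["circular"]),
                fdr_circular=float("nan"),
                is_ecdna_associated=False,
            )
        )
        testable_idx.append(len(results) - 1)
    if not testable_idx:
        raise ValueError("no gene is testable (every circular contrast degenerate)")
    pvals = [results[i].p_circular for i in testable_idx]
    adj = benjamini_hochberg(pvals)
    for i, q in zip(testable_idx, adj):
        results[i].fdr_circular = float(q)
        results[i].is_ecdna_associated = bool(q < 0.05)
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_uq(
    expression: pd.DataFrame, amplified: dict[str, set[str]]
) -> pd.DataFrame:
    """Fold change in (upper-quartile-normalized) TPM for amplified samples.

    For gene g amplified in sample s:
    ``fc = (TPM_{s,g} + 1) / mean over non-amplified s' of (TPM_{s',g} + 1)``.
    Genes with no non-amplified reference sample are skipped.
    Returns a frame with gene_id, sample_id, fold_change.
    """
    rows = []
    for gene, sub in expression.groupby("gene_id", sort=True):
        amp = amplified.get(str(gene), set())
        if not amp:
            continue
        ref = sub[~sub["sample_id"].isin(amp)]
        if ref.empty:
            log.warning("gene %s has no non-amplified reference sample; skipped", gene)
            continue
        denom = float((ref["TPM"] + 1.0).mean())
        for _, row in sub[sub["sample_id"].isin(amp)].iterrows():
            rows.append(
                {
                    "gene_id": str(gene),
                    "sample_id": str(row["sample_id"]),
                    "fold_change": (float(row["TPM"]) + 1.0) / denom,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "fold_change"])


@dataclass
class FoldChangeFit:
    slopes: dict[str, float]  # per-class slope m in fc = m*CN + b
    intercepts: dict[str, float]
    f_statistic: float
    p_value: float


def compare_fc_models(df: pd.DataFrame) -> FoldChangeFit:
    """Fit ``fold_change = m * CN + b`` per amplification class and test the
    class effect by comparing the pooled model against the class-specific
    model with a nested ANOVA F-test.

    ``df`` needs columns fold_change, CN, klass; >= 3 points per class.
    """
    classes = sorted(df["klass"].unique())
    if len(classes) < 2:
        raise ValueError("need at least two amplification classes")
    counts = df["klass"].value_counts()
    if (counts < 3).any():
        raise ValueError("need >= 3 points per class")
    slopes, intercepts = {}, {}
    for klass, sub in df.groupby("klass"):
        fit = smf.ols("fold_change ~ CN", data=sub).fit()
        slopes[str(klass)] = float(fit.params["CN"])
        intercepts[str(klass)] = float(fit.params["Intercept"])
    pooled = smf.ols("fold_change ~ CN", data=df).fit()
    full = smf.ols("fold_change ~ CN * C(klass)", data=df).fit()
    anova = sm.stats.anova_lm(pooled, full)
    return FoldChangeFit(
        slopes=slopes,
        intercepts=intercepts,
        f_statistic=float(anova["F"].iloc[1]),
        p_value=float(anova["Pr(>F)"].iloc[1]),
    )


def odds_ratio(
    table, estimator: str = "cross_product"
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 table
    ``((a, b), (c, d))`` (exposed/unexposed x event/non-event).

    ``cross_product`` is (a*d)/(b*c); ``fisher_cmle`` is the conditional
    maximum-likelihood estimate underlying the Fisher test.
    """
    t = np.asarray(table, dtype=int).reshape(2, 2)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    p = float(sps.fisher_exact(t)[1])
    if estimator == "cross_product":
        if min(a, b, c, d) == 0:
            raise ValueError(
                "zero cell: the cross-product odds ratio is undefined; "
                "use estimator='fisher_cmle'"
            )
        return (a * d) / (b * c), p
    if estimator == "fisher_cmle":
        res = sps.contingency.odds_ratio(t, kind="conditional")
        return float(res.statistic), p
    raise ValueError(f"unknown estimator {estimator!r}")


def mutual_exclusivity(
    flag_a, flag_b, estimator: str = "cross_product"
) -> tuple[np.ndarray, float, float]:
    """2x2 co-occurrence table, odds ratio and Fisher p for two per-sample
    boolean flags; OR < 1 indicates mutual exclusivity."""
    a = np.asarray(flag_a, dtype=bool)
    b = np.asarray(flag_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must align")
    if a.all() or (~a).all() or b.all() or (~b).all():
        raise ValueError("degenerate margin: a flag vector is constant")
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    try:
        or_, p = odds_ratio(table, estimator=estimator)
    except ValueError:
        # zero cell (perfect exclusivity): fall back to the conditional MLE
        or_, p = odds_ratio(table, estimator="fisher_cmle")
    return table, or_, p


def windowed_frequency(
    entries: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_size: int = 1_000_000,
) -> pd.DataFrame:
    """Count entries per fixed genomic window (default 1 Mb, tiled from
    position 1), per amplification class; an entry is counted in every
    window it overlaps.

    ``entries`` needs chrom, start, end, klass columns (1-based inclusive).
    Returns the full tiling (all-zero windows included).
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    frames = []
    for chrom, length in chrom_lengths.items():
        n_windows = int(np.ceil(length / window_size))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_start": [i * window_size + 1 for i in range(n_windows)],
                    "window_end": [
                        min((i + 1) * window_size, length) for i in range(n_windows)
                    ],
                }
            )
        )
    tiling = pd.concat(frames, ignore_index=True)
    tiling["circular_count"] = 0
    tiling["noncircular_count"] = 0

    for _, row in entries.iterrows():
        chrom = str(row["chrom"])
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        start, end = int(row["start"]), int(row["end"])
        if end > chrom_lengths[chrom] or start < 1:
            raise ValueError(
                f"entry {chrom}:{start}-{end} outside chromosome bounds"
            )
        first = (start - 1) // window_size
        last = (end - 1) // window_size
        col = f"{row['klass']}_count"
        if col not in tiling.columns:
            continue
        mask = (
            (tiling["chrom"] == chrom)
            & (tiling["window_start"] >= first * window_size + 1)
            & (tiling["window_start"] <= last * window_size + 1)
        )
        tiling.loc[mask, col] += 1
    return tiling


def filter_circle_map(records: list[CircleMapRecord]) -> list[CircleMapRecord]:
    """Keep records passing the stringent circular-DNA criteria:
    CircleScore > 50, discordant reads > 1, split reads >= 4, mean coverage
    > 4, coverage continuity < 0.1 and region length > 10 kb."""
    return [
        r
        for r in records
        if r.circle_score > 50
        and r.discordant_reads > 1
        and r.split_reads >= 4
        and r.mean_coverage > 4
        and r.coverage_continuity < 0.1
        and r.length > 10_000
    ]


def _round_half_away(x: float, digits: int = 1) -> float:
    factor = 10.0**digits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def cohort_summary(sample_calls) -> dict[str, dict[str, float]]:
    """Per-class counts and percentages (1 decimal, half away from zero)."""
    if not sample_calls:
        raise ValueError("empty cohort")
    n = len(sample_calls)
    out: dict[str, dict[str, float]] = {}
    for klass in ("circular", "noncircular", "nofocal"):
        count = sum(1 for c in sample_calls if c.klass == klass)
        out[klass] = {
            "count": count,
            "percent": _round_half_away(100.0 * count / n, 1),
        }
    out["n"] = {"count": n, "percent": 100.0}
    return out
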