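"""Readers, writers and domain types for the tabular genomic formats.

Internal coordinate convention is 1-based inclusive (the allele-specific
copy-number caller convention); BED input/output is converted at the
boundary.  Chromosome names are normalized by stripping any ``chr`` prefix,
so ``chr8`` and ``8`` address the same chromosome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

AUTOSOMES = {str(i) for i in range(1, 23)}

__all__ = [
    "CopyNumberSegment",
    "SampleProfile",
    "GeneAnnotation",
    "AmpliconPriorTable",
    "CircleMapRecord",
    "ArmTable",
    "CytobandTable",
    "normalize_chrom",
    "read_segments",
    "read_gene_bed",
    "read_priors",
    "read_circle_map",
    "read_expression",
    "write_calls",
    "read_calls",
    "load_arm_table",
    "load_cytoband_table",
]


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix and canonicalize sex-chromosome case.

    Idempotent: ``normalize_chrom(normalize_chrom(x)) == normalize_chrom(x)``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"X", "Y", "MT", "M"}:
        s = s.upper()
    return s


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number segment (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int | None = None  # None = not available (tumor-only input)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValueError("minor_cn must be non-negative")
            if self.minor_cn > self.total_cn:
                raise ValueError(
                    f"segment {self.chrom}:{self.start}-{self.end}: "
                    f"minor_cn {self.minor_cn} > total_cn {self.total_cn}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleProfile:
    """One tumor's segment profile plus purity, ploidy and gender."""

    sample_id: str
    segments: list[CopyNumberSegment]
    purity: float = 1.0
    ploidy: float = 2.0
    gender: str = "unknown"  # {"XX", "XY", "unknown"}

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"{self.sample_id}: purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"{self.sample_id}: ploidy must be positive")
        self.segments = sorted(
            self.segments, key=lambda s: (_chrom_sort_key(s.chrom), s.start)
        )
        prev: CopyNumberSegment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on chromosome "
                    f"{seg.chrom} near {seg.start}"
                )
            prev = seg

    def autosomal_segments(self) -> list[CopyNumberSegment]:
        return [s for s in self.segments if s.chrom in AUTOSOMES]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


class AmpliconPriorTable:
    """Per-gene amplicon-class frequency priors.

    Lookup of an absent gene yields ``(0, 0, 0, 0)`` — genes never seen in
    the amplicon catalog carry no prior evidence for any class.
    """

    COLUMNS = ("freq_Circular", "freq_BFB", "freq_HR", "freq_Linear")

    def __init__(self, mapping: Mapping[str, tuple[float, float, float, float]]):
        for gene, vals in mapping.items():
            if len(vals) != 4:
                raise ValueError(f"prior for {gene}: need exactly 4 frequencies")
            for v in vals:
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"prior for {gene}: frequency {v} outside [0, 1]"
                    )
        self._map = {g: tuple(float(v) for v in vals) for g, vals in mapping.items()}

    def lookup(self, gene_id: str) -> tuple[float, float, float, float]:
        return self._map.get(gene_id, (0.0, 0.0, 0.0, 0.0))

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AmpliconPriorTable) and self._map == other._map

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, *v) for g, v in sorted(self._map.items())],
            columns=["gene_id", *self.COLUMNS],
        )


@dataclass(frozen=True)
class CircleMapRecord:
    """One Circle-Map Realign call (BED-like, half-open like BED)."""

    chrom: str
    start: int
    end: int
    discordant_reads: int
    split_reads: int
    circle_score: float
    mean_coverage: float
    coverage_sd: float
    coverage_continuity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CircleMapRecord: end must exceed start")
        if self.discordant_reads < 0 or self.split_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArmTable:
    """Chromosome arms (1-based inclusive) with an exclusion flag.

    Acrocentric p-arms are flagged excluded from the aneuploidy score.
    """

    arms: dict[str, tuple[str, int, int]]  # "8q" -> (chrom, start, end)
    excluded: set[str] = field(default_factory=set)
    build: str = "hg38"

    def included_autosomal_arms(self) -> list[str]:
        return [
            a
            for a, (chrom, _, _) in sorted(self.arms.items())
            if a not in self.excluded and chrom in AUTOSOMES
        ]

    def chrom_length(self, chrom: str) -> int:
        return max(e for c, _, e in self.arms.values() if c == chrom)

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _, _ in self.arms.values()}, key=_chrom_sort_key)


@dataclass
class CytobandTable:
    bands: dict[str, tuple[str, int, int]]  # "8q24" -> (chrom, start, end)
    build: str = "hg38"

    def band_of(self, chrom: str, start: int, end: int) -> str | None:
        """Band with the largest overlap with the query interval, or None."""
        chrom = normalize_chrom(chrom)
        best, best_ov = None, 0
        for name, (bc, bs, be) in self.bands.items():
            if bc != chrom:
                continue
            ov = min(end, be) - max(start, bs) + 1
            if ov > best_ov:
                best, best_ov = name, ov
        return best


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


_ASCAT_ALIASES = {
    "sample": {"sample", "sample_id", "id", "samplename"},
    "chrom": {"chrom", "chr", "chromosome"},
    "start": {"start", "startpos", "loc.start", "start_pos"},
    "end": {"end", "endpos", "loc.end", "end_pos"},
    "total_cn": {"total_cn", "ntot", "cn", "totalcn", "seg.cn"},
    "minor_cn": {"minor_cn", "nminor", "nb", "minorcn"},
    "purity": {"purity", "tumour_purity", "tumor_purity", "aberrantcellfraction"},
    "ploidy": {"ploidy", "tumour_ploidy", "tumor_ploidy"},
    "gender": {"gender", "sex"},
}


def _resolve_columns(df: pd.DataFrame, required: Iterable[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    out: dict[str, str] = {}
    for canon, aliases in _ASCAT_ALIASES.items():
        for a in aliases:
            if a in lower:
                out[canon] = lower[a]
                break
    missing = [c for c in required if c not in out]
    if missing:
        raise ValueError(f"segment file is missing required columns: {missing}")
    return out


def read_segments(
    path: str | Path,
    dialect: str = "ascat_tsv",
    sample_table: str | Path | None = None,
) -> list[SampleProfile]:
    """Read allele-specific (or total-only) segment profiles.

    ``ascat_tsv`` expects sample/chrom/start/end/total_cn/minor_cn columns
    (header-name aliases accepted); ``seg`` is the same without a minor-allele
    column.  Purity, ploidy and gender are taken from companion columns when
    present, else from the optional ``sample_table`` sidecar TSV
    (sample, purity, ploidy, gender), else default to 1.0 / 2.0 / unknown.
    """
    if dialect not in {"ascat_tsv", "seg"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    required = ["sample", "chrom", "start", "end", "total_cn"]
    if dialect == "ascat_tsv":
        required.append("minor_cn")
    cols = _resolve_columns(df, required)

    meta: dict[str, dict[str, object]] = {}
    if sample_table is not None:
        st = _read_tsv(sample_table)
        scols = _resolve_columns(st, ["sample"])
        for _, row in st.iterrows():
            entry: dict[str, object] = {}
            for key in ("purity", "ploidy", "gender"):
                if key in scols and pd.notna(row[scols[key]]):
                    entry[key] = row[scols[key]]
            meta[str(row[scols["sample"]])] = entry

    by_sample: dict[str, list[CopyNumberSegment]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        sid = str(row[cols["sample"]])
        try:
            chrom = normalize_chrom(row[cols["chrom"]])
            start = int(float(row[cols["start"]]))
            end = int(float(row[cols["end"]]))
            total = int(round(float(row[cols["total_cn"]])))
            minor: int | None = None
            if "minor_cn" in cols:
                raw = row[cols["minor_cn"]]
                if pd.notna(raw) and str(raw).strip().upper() not in {"", "NA", "NAN"}:
                    minor = int(round(float(raw)))
            seg = CopyNumberSegment(chrom, start, end, total, minor)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
        by_sample.setdefault(sid, []).append(seg)
        for key in ("purity", "ploidy", "gender"):
            if key in cols and pd.notna(row[cols[key]]):
                meta.setdefault(sid, {}).setdefault(key, row[cols[key]])

    profiles = []
    for sid, segs in by_sample.items():
        m = meta.get(sid, {})
        try:
            profiles.append(
                SampleProfile(
                    sample_id=sid,
                    segments=segs,
                    purity=float(m.get("purity", 1.0)),
                    ploidy=float(m.get("ploidy", 2.0)),
                    gender=str(m.get("gender", "unknown")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: sample {sid}: {exc}") from exc
    return profiles


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED3+name gene annotation; 0-based half-open converted to
    1-based inclusive (``start+1``, ``end``)."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {line_no}: BED3+name requires a name column"
                )
            chrom, bed_start, bed_end, name = parts[0], parts[1], parts[2], parts[3]
            strand = parts[5] if len(parts) > 5 else "."
            if name in seen:
                raise ValueError(f"{path}: line {line_no}: duplicate gene_id {name!r}")
            seen.add(name)
            try:
                genes.append(
                    GeneAnnotation(
                        gene_id=name,
                        chrom=normalize_chrom(chrom),
                        start=int(bed_start) + 1,
                        end=int(bed_end),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return genes


def write_gene_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_priors(path: str | Path) -> AmpliconPriorTable:
    """Read a five-column TSV of per-gene amplicon-class frequencies."""
    df = _read_tsv(path)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: prior table needs gene + four frequency columns")
    gene_col = df.columns[0]
    freq_cols = list(df.columns[1:5])
    mapping: dict[str, tuple[float, float, float, float]] = {}
    for idx, row in df.iterrows():
        vals = []
        for c in freq_cols:
            v = float(row[c])
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"{path}: line {idx + 2}: frequency {v} outside [0, 1]"
                )
            vals.append(v)
        mapping[str(row[gene_col])] = tuple(vals)  # type: ignore[arg-type]
    return AmpliconPriorTable(mapping)


def write_priors(priors: AmpliconPriorTable, path: str | Path) -> None:
    priors.to_frame().to_csv(path, sep="\t", index=False)


_CIRCLE_MAP_COLS = [
    "chrom",
    "start",
    "end",
    "discordant_reads",
    "split_reads",
    "circle_score",
    "mean_coverage",
    "coverage_sd",
    "coverage_continuity",
]


def read_circle_map(path: str | Path) -> list[CircleMapRecord]:
    """Read a Circle-Map Realign-style nine-column BED-like TSV."""
    records: list[CircleMapRecord] = []
    with open(path) as fh:
        header_skipped = False
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_skipped:
                header_skipped = True
                try:
                    float(parts[1])
                except (ValueError, IndexError):
                    continue  # header row
            if len(parts) < 9:
                raise ValueError(
                    f"{path}: line {line_no}: expected 9 columns, got {len(parts)}"
                )
            try:
                records.append(
                    CircleMapRecord(
                        chrom=normalize_chrom(parts[0]),
                        start=int(parts[1]),
                        end=int(parts[2]),
                        discordant_reads=int(parts[3]),
                        split_reads=int(parts[4]),
                        circle_score=float(parts[5]),
                        mean_coverage=float(parts[6]),
                        coverage_sd=float(parts[7]),
                        coverage_continuity=float(parts[8]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return records


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a long-format expression TSV (sample_id, gene_id, TPM)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"sample_id", "gene_id", "TPM"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expression table needs columns {sorted(need)}")
    if (df["TPM"] < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return df


# ---------------------------------------------------------------------------
# call output

CALL_COLUMNS = [
    "record_type",
    "sample_id",
    "gene_id",
    "klass",
    "probability",
    "total_cn",
    "ploidy",
    "cargo_genes",
]


def write_calls(
    sample_calls,
    gene_calls,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write sample- and gene-level calls as one TSV with ``#`` metadata
    header lines; round-trips through :func:`read_calls`."""
    rows = []
    for sc in sample_calls:
        rows.append(
            {
                "record_type": "sample",
                "sample_id": sc.sample_id,
                "gene_id": "",
                "klass": sc.klass,
                "probability": "",
                "total_cn": "",
                "ploidy": "",
                "cargo_genes": ",".join(sc.cargo_genes),
            }
        )
    for gc in gene_calls:
        rows.append(
            {
                "record_type": "gene",
                "sample_id": gc.sample_id,
                "gene_id": gc.gene_id,
                "klass": gc.klass,
                "probability": repr(float(gc.probability)),
                "total_cn": "" if gc.total_cn is None else str(gc.total_cn),
                "ploidy": repr(float(gc.ploidy)),
                "cargo_genes": "",
            }
        )
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in CALL_COLUMNS) + "\n")


def read_calls(path: str | Path):
    """Read back a calls TSV: returns (sample_calls, gene_calls, metadata)."""
    from .focal_typing import GeneCall, SampleCall  # deferred: avoid cycle

    metadata: dict[str, str] = {}
    sample_calls, gene_calls = [], []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    metadata[k] = v
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            if vals["record_type"] == "sample":
                sample_calls.append(
                    SampleCall(
                        sample_id=vals["sample_id"],
                        klass=vals["klass"],
                        cargo_genes=[g for g in vals["cargo_genes"].split(",") if g],
                    )
                )
            else:
                gene_calls.append(
                    GeneCall(
                        sample_id=vals["sample_id"],
                        gene_id=vals["gene_id"],
                        probability=float(vals["probability"]),
                        total_cn=int(vals["total_cn"]) if vals["total_cn"] else None,
                        ploidy=float(vals["ploidy"]),
                        klass=vals["klass"],
                    )
                )
    return sample_calls, gene_calls, metadata


# ---------------------------------------------------------------------------
# packaged resources


def _resource_path(name: str) -> Path:
    return Path(str(_ilres.files("focalamp").joinpath("resources", name)))


def load_arm_table(path: str | Path | None = None, build: str = "hg38") -> ArmTable:
    """Load the chromosome-arm table (packaged hg38 table by default)."""
    if path is None:
        path = _resource_path(f"arms_{build}.tsv")
    df = _read_tsv(path)
    arms: dict[str, tuple[str, int, int]] = {}
    excluded: set[str] = set()
    for _, row in df.iterrows():
        chrom = normalize_chrom(row["chrom"])
        name = f"{chrom}{row['arm']}"
        arms[name] = (chrom, int(row["start"]), int(row["end"]))
        if int(row["excluded"]):
            excluded.add(name)
    return ArmTable(arms=arms, excluded=excluded, build=build)


def load_cytoband_table(path: str | Path | None = None, build: str = "hg38") -> CytobandTable:
    """Load a cytoband table; the packaged default is a curated subset of
    oncogene-bearing hg38 bands."""
    if path is None:
        path = _resource_path("cytobands_hg38_curated.tsv")
    df = _read_tsv(path)
    bands = {
        str(row["cytoband"]): (
            normalize_chrom(row["chrom"]),
            int(row["start"]),
            int(row["end"]),
        )
        for _, row in df.iterrows()
    }
    return CytobandTable(bands=bands, build=build)
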