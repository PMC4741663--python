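"""Domain types and file I/O for the miRNA profiling pipeline.

Covers genomic locus strings in the array-annotation dialect
(``Chr21q21.1:17911409-17911489 [+]``), probe-by-sample expression
matrices (TSV), sample sheets (CSV), fragile-site catalogs (BED or
cytoband lists) and cross-study differential-expression record files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("mirprofiler")

#: The five tissue classes of the study design.
CLASS_LABELS = ("BRCA1-C", "BRCA2-C", "BRCA1-N", "BRCA2-N", "Healthy-N")

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_TRISTATE = {"pos", "neg", "missing"}

STRAND_UNKNOWN = "?"


class ParseError(ValueError):
    """Raised when an input file or token cannot be interpreted."""


# ---------------------------------------------------------------------------
# GenomicLocus
# ---------------------------------------------------------------------------

_LOCUS_RE = re.compile(
    r"^Chr([0-9XY]{1,2})\s*([pq]\d+(?:\.\d+)?)?\s*:\s*(\d+)\s*-\s*(\d+)"
    r"\s*\[\s*([+\-−?])\s*\]$"
)


@dataclass(frozen=True)
class GenomicLocus:
    """A 1-based, closed genomic interval with optional cytoband and strand."""

    chromosome: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN
    cytoband: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ParseError(f"unknown chromosome {self.chromosome!r}")
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"invalid interval {self.start}-{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", STRAND_UNKNOWN):
            raise ParseError(f"invalid strand {self.strand!r}")

    @property
    def band_label(self) -> str | None:
        """Chromosome+band label used for hotspot grouping, e.g. ``14q32.31``."""
        if self.cytoband is None:
            return None
        return f"{self.chromosome}{self.cytoband}"

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return self.chromosome == chromosome and self.start <= end and start <= self.end


def parse_locus(text: str) -> GenomicLocus:
    """Parse an annotation locus string such as ``Chr21q21.1:17911409-17911489 [+]``.

    Both the ASCII hyphen-minus and the Unicode minus sign are accepted as
    the reverse-strand glyph.
    """
    if not text or not text.strip():
        raise ParseError("empty locus string")
    s = text.strip()
    if not s.startswith("Chr"):
        raise ParseError(f"locus {text!r}: missing 'Chr' prefix")
    m = _LOCUS_RE.match(s)
    if m is None:
        raise ParseError(f"malformed locus string {text!r}")
    chrom, band, start, end, strand = m.groups()
    if strand == "−":
        strand = "-"
    if int(start) > int(end):
        raise ParseError(f"locus {text!r}: start {start} > end {end}")
    return GenomicLocus(
        chromosome=chrom,
        start=int(start),
        end=int(end),
        strand=strand,
        cytoband=band,
    )


def format_locus(locus: GenomicLocus) -> str:
    """Inverse of :func:`parse_locus`; always emits the ASCII strand glyph."""
    band = locus.cytoband or ""
    return f"Chr{locus.chromosome}{band}:{locus.start}-{locus.end} [{locus.strand}]"


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_NORMALIZED = "normalized"
_SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_NORMALIZED)


@dataclass
class ExpressionMatrix:
    """Probe x sample grid with a scale tag tracking the processing stage.

    ``data`` is a DataFrame indexed by probe id with sample-id columns.
    Raw matrices must be non-negative; every stage of the pipeline checks
    the tag so a matrix cannot be log-transformed twice or filtered before
    normalization.
    """

    data: pd.DataFrame
    scale_tag: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALES:
            raise ValueError(f"unknown scale tag {self.scale_tag!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate probe id(s): {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric cells")
        if np.isnan(values).any():
            raise ParseError("expression matrix contains missing cells")
        if self.scale_tag == SCALE_RAW and (values < 0).any():
            raise ParseError("raw intensities must be >= 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, scale_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, scale_tag=scale_tag)


def read_expression_matrix(
    path: str | Path, sheet: "SampleSheet | None" = None, scale_tag: str = SCALE_RAW
) -> ExpressionMatrix:
    """Read a TSV matrix (probe rows, first column probe id, sample header)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric cell in expression matrix: {exc}") from exc
    em = ExpressionMatrix(data=df, scale_tag=scale_tag)
    if sheet is not None:
        missing = [s for s in em.sample_ids if s not in sheet.sample_ids]
        if missing:
            raise ParseError(f"{path}: samples absent from sample sheet: {missing}")
    return em


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    out = em.data.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample class assignments plus optional clinicopathologic covariates."""

    data: pd.DataFrame  # indexed by sample_id; at least a class_label column

    def __post_init__(self) -> None:
        if "class_label" not in self.data.columns:
            raise ParseError("sample sheet needs a class_label column")
        if self.data.index.duplicated().any():
            raise ParseError("duplicate sample id in sample sheet")
        bad = set(self.data["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise ParseError(f"unknown class label(s): {sorted(bad)}")
        for cov in ("ER", "PR", "HER2"):
            if cov in self.data.columns:
                vals = set(self.data[cov].dropna().astype(str)) - _TRISTATE
                if vals:
                    raise ParseError(f"covariate {cov}: invalid value(s) {sorted(vals)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def class_labels(self) -> pd.Series:
        return self.data["class_label"]

    def samples_in_class(self, label: str) -> list[str]:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        return list(self.data.index[self.data["class_label"] == label])

    def class_sizes(self) -> dict[str, int]:
        return {c: len(self.samples_in_class(c)) for c in CLASS_LABELS}

    def covariate_groups(self, covariate: str, levels: Sequence[str]) -> dict[str, list[str]]:
        if covariate not in self.data.columns:
            raise ValueError(f"covariate {covariate!r} not in sample sheet")
        col = self.data[covariate].astype(str)
        return {lv: list(self.data.index[col == lv]) for lv in levels}


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleSheet(data=df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Fragile sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragileSite:
    chromosome: str
    name: str
    cytoband: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ParseError(f"fragile site {self.name}: unknown chromosome")
        if self.cytoband is None:
            if self.start is None or self.end is None:
                raise ParseError(f"fragile site {self.name}: needs a band or an interval")
            if not (1 <= self.start <= self.end):
                raise ParseError(f"fragile site {self.name}: malformed interval")

    def matches(self, locus: GenomicLocus) -> bool:
        if locus.chromosome != self.chromosome:
            return False
        if self.cytoband is not None:
            if locus.cytoband is None:
                return False
            a, b = self.cytoband, locus.cytoband
            # a band and its sub-bands overlap (q23 covers q23.2 and vice versa)
            return a == b or a.startswith(b + ".") or b.startswith(a + ".")
        assert self.start is not None and self.end is not None
        return locus.start <= self.end and self.start <= locus.end


@dataclass
class FragileSiteCatalog:
    entries: list[FragileSite] = field(default_factory=list)

    def contains(self, locus: GenomicLocus | None) -> bool:
        if locus is None:
            return False
        return any(site.matches(locus) for site in self.entries)


def _norm_chrom(token: str) -> str:
    t = token.strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t not in CHROMOSOMES:
        raise ParseError(f"unknown chromosome token {token!r}")
    return t


def read_fragile_sites(path: str | Path) -> FragileSiteCatalog:
    """Read a fragile-site catalog.

    Two dialects are auto-detected per line: 3+-column BED
    (``chrom<TAB>start<TAB>end[<TAB>name]``, 0-based half-open, converted
    to 1-based closed) and cytoband lists (``chrom<TAB>band[<TAB>name]``).
    """
    entries: list[FragileSite] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = re.split(r"\s+", line.strip())
        if len(cols) < 2:
            raise ParseError(f"{path}:{i}: expected >= 2 columns")
        chrom = _norm_chrom(cols[0])
        if cols[1].isdigit():
            if len(cols) < 3 or not cols[2].isdigit():
                raise ParseError(f"{path}:{i}: BED line needs numeric start and end")
            start0, end0 = int(cols[1]), int(cols[2])
            if end0 <= start0:
                raise ParseError(f"{path}:{i}: empty or inverted BED interval")
            name = cols[3] if len(cols) > 3 else f"site{i}"
            entries.append(
                FragileSite(chromosome=chrom, name=name, start=start0 + 1, end=end0)
            )
        else:
            band = cols[1]
            if not re.fullmatch(r"[pq]\d+(\.\d+)?", band):
                raise ParseError(f"{path}:{i}: malformed cytoband {band!r}")
            name = cols[2] if len(cols) > 2 else f"site{i}"
            entries.append(FragileSite(chromosome=chrom, name=name, cytoband=band))
    return FragileSiteCatalog(entries=entries)


def write_fragile_sites_bed(catalog: FragileSiteCatalog, path: str | Path) -> None:
    """Write interval entries as 3+1-column BED; band entries as cytoband lines."""
    lines = []
    for site in catalog.entries:
        if site.cytoband is not None:
            lines.append(f"{site.chromosome}\t{site.cytoband}\t{site.name}")
        else:
            lines.append(f"{site.chromosome}\t{site.start - 1}\t{site.end}\t{site.name}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Probe annotation (probe -> locus or unknown)
# ---------------------------------------------------------------------------

UNKNOWN_LOCUS_TOKEN = "unknown"


def read_annotation(path: str | Path) -> dict[str, GenomicLocus | None]:
    """Read a 2-column TSV of probe id and locus string (or ``unknown``)."""
    ann: dict[str, GenomicLocus | None] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "locus"} <= set(df.columns):
        raise ParseError(f"{path}: annotation needs probe_id and locus columns")
    for probe, text in zip(df["probe_id"], df["locus"]):
        if probe in ann:
            raise ParseError(f"{path}: duplicate probe {probe!r} in annotation")
        if pd.isna(text) or text.strip() == UNKNOWN_LOCUS_TOKEN:
            ann[str(probe)] = None
        else:
            ann[str(probe)] = parse_locus(text)
    return ann


def write_annotation(ann: Mapping[str, GenomicLocus | None], path: str | Path) -> None:
    rows = [
        (probe, UNKNOWN_LOCUS_TOKEN if locus is None else format_locus(locus))
        for probe, locus in ann.items()
    ]
    pd.DataFrame(rows, columns=["probe_id", "locus"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Study records (cross-study consensus input)
# ---------------------------------------------------------------------------

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class Finding:
    mirna_id: str
    direction: str
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ParseError(f"unknown direction token {self.direction!r}")
        if self.fold_change is not None and self.fold_change < 1.0:
            raise ParseError(
                f"{self.mirna_id}: fold change {self.fold_change} violates the "
                "magnitude convention (must be >= 1)"
            )


@dataclass
class StudyRecord:
    """One published study: its weighting sample count and its DE findings."""

    study_name: str
    n_samples: int
    findings: list[Finding] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ParseError(f"study {self.study_name}: non-positive sample count")
        seen = set()
        for f in self.findings:
            key = (f.mirna_id, f.direction)
            if key in seen:
                raise ParseError(
                    f"study {self.study_name}: duplicate finding {key}"
                )
            seen.add(key)


def read_study_records(path: str | Path) -> list[StudyRecord]:
    """Read study findings from CSV: study,n_samples,mirna,direction[,fold_change].

    A row with an empty mirna field declares a study with no findings.
    """
    df = pd.read_csv(path, dtype={"study": str, "mirna": str, "direction": str})
    needed = {"study", "n_samples", "mirna", "direction"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: study file needs columns {sorted(needed)}")
    records: dict[str, StudyRecord] = {}
    for _, row in df.iterrows():
        study = row["study"]
        n = int(row["n_samples"])
        if study not in records:
            records[study] = StudyRecord(study_name=study, n_samples=n, findings=[])
        elif records[study].n_samples != n:
            raise ParseError(f"{path}: inconsistent n_samples for study {study!r}")
        if pd.isna(row["mirna"]) or str(row["mirna"]).strip() == "":
            continue
        fc = None
        if "fold_change" in df.columns and not pd.isna(row["fold_change"]):
            fc = float(row["fold_change"])
        records[study].findings.append(
            Finding(mirna_id=str(row["mirna"]), direction=str(row["direction"]), fold_change=fc)
        )
    # re-validate duplicate findings per study
    return [StudyRecord(r.study_name, r.n_samples, r.findings) for r in records.values()]


def write_study_records(records: Iterable[StudyRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if not rec.findings:
            rows.append((rec.study_name, rec.n_samples, "", "", ""))
        for f in rec.findings:
            rows.append(
                (rec.study_name, rec.n_samples, f.mirna_id, f.direction,
                 "" if f.fold_change is None else f.fold_change)
            )
    pd.DataFrame(rows, columns=["study", "n_samples", "mirna", "direction", "fold_change"]).to_csv(
        path, index=False
    )


def load_literature_studies() -> list[StudyRecord]:
    """Load the bundled six-study breast-cancer literature compilation.

    Encodes the published study memberships and per-study sample totals
    used for sample-weighted consensus ranking. Fold changes are present
    only where individually attributable to a study.
    """
    here = Path(__file__).parent / "data" / "literature_studies.csv"
    return read_study_records(here)
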