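"""Chromosomal distribution of differentially expressed miRNAs.

Per-chromosome counts (probes without a known locus are tallied separately
and excluded), a Monte-Carlo Freeman–Halton exact test comparing two axes'
distributions, cytoband hotspot detection (>= 4 deregulated miRNAs at one
locus) and fragile-site overlap fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import random_table

from .core_io import CHROMOSOMES, FragileSiteCatalog, GenomicLocus
from .diffexpr import DERecord

log = logging.getLogger("mirprofiler")

#: coordinate-bin width used when a locus has no cytoband label
FALLBACK_BIN_BP = 1_000_000


@dataclass
class ChromosomeDistribution:
    axis_id: str
    counts: dict[str, int]
    n_unlocalized: int = 0

    def __post_init__(self) -> None:
        for c in CHROMOSOMES:
            self.counts.setdefault(c, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative chromosome count")

    @property
    def n_localized(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CHROMOSOMES], dtype=int)


def count_per_chromosome(
    de_records: Sequence[DERecord],
    annotation: Mapping[str, GenomicLocus | None],
    axis_id: str | None = None,
) -> ChromosomeDistribution:
    """Tally called DE probes per chromosome; unknown loci go to ``n_unlocalized``."""
    counts: dict[str, int] = {c: 0 for c in CHROMOSOMES}
    n_unloc = 0
    called = [r for r in de_records if r.called]
    for rec in called:
        locus = annotation.get(rec.probe_id)
        if locus is None:
            n_unloc += 1
        else:
            counts[locus.chromosome] += 1
    label = axis_id or (called[0].comparison_id if called else "empty")
    return ChromosomeDistribution(axis_id=label, counts=counts, n_unlocalized=n_unloc)


# ---------------------------------------------------------------------------
# Monte-Carlo Freeman–Halton exact test on the 2 x K chromosome table
# ---------------------------------------------------------------------------


@dataclass
class ExactTestResult:
    chi2: float  # Pearson chi-square of the observed table (descriptive)
    p_value: float  # Monte-Carlo Freeman–Halton p
    n_mc: int
    n_columns: int

    statistic_definition: str = (
        "Pearson chi-square of the observed 2xK table; the p-value is the "
        "fixed-margin (Freeman-Halton) exact probability estimated by "
        "Monte-Carlo sampling of tables with the observed margins"
    )


def _table_log_prob(tables: np.ndarray) -> np.ndarray:
    """Fixed-margin log-probability of 2xK tables up to a margin constant."""
    return -gammaln(tables + 1.0).sum(axis=(-2, -1))


def _chi2_statistic(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def exact_table_test(
    table: np.ndarray, n_mc: int = 100_000, seed: int | np.random.Generator | None = None
) -> ExactTestResult:
    """Freeman–Halton-style exact test of a 2 x K contingency table.

    The p-value is the probability, under fixed margins, of a table at most
    as probable as the observed one, estimated from ``n_mc`` Patefield
    samples. The add-one estimator ``(1 + hits) / (1 + n_mc)`` is used so
    the reported p is never exactly zero.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x K table")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.size == 0 or table.sum() == 0:
        raise ValueError("empty contingency table")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    if (row_m == 0).any():
        raise ValueError("a row margin is zero; nothing to compare")
    logp_obs = _table_log_prob(table[np.newaxis])[0]
    sampler = random_table(row_m, col_m)
    hits = 0
    chunk = 20_000
    remaining = n_mc
    while remaining > 0:
        m = min(chunk, remaining)
        samples = sampler.rvs(m, random_state=rng)
        logp = _table_log_prob(samples)
        hits += int(np.sum(logp <= logp_obs + 1e-9))
        remaining -= m
    p = (1 + hits) / (1 + n_mc)
    return ExactTestResult(
        chi2=_chi2_statistic(table), p_value=float(p), n_mc=n_mc, n_columns=table.shape[1]
    )


def compare_distributions(
    dist_a: ChromosomeDistribution,
    dist_b: ChromosomeDistribution,
    n_mc: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> ExactTestResult:
    """Compare two axes' per-chromosome counts with the 2 x K exact test.

    Chromosomes with zero counts in both axes are dropped from the table.
    """
    table = np.vstack([dist_a.as_vector(), dist_b.as_vector()])
    return exact_table_test(table, n_mc=n_mc, seed=seed)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


@dataclass
class Hotspot:
    locus_label: str  # chromosome+cytoband, or a coordinate-bin label
    axis_id: str
    members: list[str]
    directions: dict[str, str] = field(default_factory=dict)
    shared_between_axes: bool = False

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def direction_consistent(self) -> bool:
        return len(set(self.directions.values())) == 1

    @property
    def direction(self) -> str | None:
        dirs = set(self.directions.values())
        return dirs.pop() if len(dirs) == 1 else None

    def to_dict(self) -> dict:
        return {
            "locus": self.locus_label,
            "axis": self.axis_id,
            "n": self.n,
            "members": sorted(self.members),
            "direction_consistent": self.direction_consistent,
            "direction": self.direction,
            "shared_between_axes": self.shared_between_axes,
        }


def _group_label(locus: GenomicLocus) -> str:
    if locus.cytoband is not None:
        return locus.band_label  # e.g. 14q32.31
    bin_idx = (locus.start - 1) // FALLBACK_BIN_BP
    return f"{locus.chromosome}:bin{bin_idx}"


def detect_hotspots(
    axes: Mapping[str, Sequence[DERecord]],
    annotation: Mapping[str, GenomicLocus | None],
    min_count: int = 4,
) -> list[Hotspot]:
    """Find loci carrying >= ``min_count`` called DE miRNAs, per axis.

    Loci are cytoband labels; probes without a band fall back to 1-Mb
    coordinate bins. A hotspot locus found in more than one axis is
    flagged ``shared_between_axes`` on every axis's entry. Output order is
    deterministic (axis, then locus label).
    """
    per_axis: dict[str, dict[str, dict[str, str]]] = {}
    for axis_id, records in axes.items():
        groups: dict[str, dict[str, str]] = {}
        for rec in records:
            if not rec.called:
                continue
            locus = annotation.get(rec.probe_id)
            if locus is None:
                continue
            groups.setdefault(_group_label(locus), {})[rec.probe_id] = rec.direction
        per_axis[axis_id] = {
            label: members for label, members in groups.items() if len(members) >= min_count
        }
    locus_axes: dict[str, set[str]] = {}
    for axis_id, spots in per_axis.items():
        for label in spots:
            locus_axes.setdefault(label, set()).add(axis_id)
    hotspots = [
        Hotspot(
            locus_label=label,
            axis_id=axis_id,
            members=sorted(members),
            directions=members,
            shared_between_axes=len(locus_axes[label]) > 1,
        )
        for axis_id in sorted(per_axis)
        for label, members in sorted(per_axis[axis_id].items())
    ]
    return hotspots


# ---------------------------------------------------------------------------
# Fragile-site overlap
# ---------------------------------------------------------------------------


def fragile_overlap(
    de_records: Sequence[DERecord],
    annotation: Mapping[str, GenomicLocus | None],
    catalog: FragileSiteCatalog,
) -> float | None:
    """Fraction of localized called DE probes whose locus hits a fragile site.

    Returns ``None`` (not applicable) when no called probe has a known locus.
    """
    localized = [
        annotation.get(r.probe_id)
        for r in de_records
        if r.called and annotation.get(r.probe_id) is not None
    ]
    if not localized:
        log.warning("fragile_overlap: no localized DE probes; overlap undefined")
        return None
    n_hit = sum(1 for locus in localized if catalog.contains(locus))
    return n_hit / len(localized)
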