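"""Cross-study vote-counting consensus of differentially expressed miRNAs.

Findings from independent profiling studies are aggregated per
(miRNA, direction): the number of direction-concordant studies, the sum of
their sample counts, and the mean of the fold-change magnitudes they
supplied. Ranking follows the vote-counting protocol: concordant-study
count first, then total samples, then average fold change. No pooled
effect-size model is fitted — the aggregation is deliberately rank-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import DIRECTIONS, StudyRecord
from .diffexpr import ComparisonSet

log = logging.getLogger("mirprofiler")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Report-style rounding: halves away from zero (2.005 -> 2.01)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ConsensusEntry:
    mirna_id: str
    direction: str
    supporting_studies: list[str]
    total_samples: int
    fold_changes: list[float] = field(default_factory=list)

    @property
    def n_studies(self) -> int:
        return len(self.supporting_studies)

    @property
    def avg_fc(self) -> float | None:
        if not self.fold_changes:
            return None
        return sum(self.fold_changes) / len(self.fold_changes)

    @property
    def fc_range(self) -> tuple[float, float] | None:
        if len(self.fold_changes) < 2:
            return None
        return (min(self.fold_changes), max(self.fold_changes))

    @property
    def single_value_flag(self) -> bool:
        return len(self.fold_changes) == 1


def build_consensus(
    records: Sequence[StudyRecord],
) -> tuple[list[ConsensusEntry], list[str]]:
    """Aggregate study findings into per-(miRNA, direction) consensus entries.

    A miRNA reported in opposite directions by different studies yields two
    entries (one per direction) and is listed in the returned conflict
    report; it is never silently dropped. Average fold change covers only
    the studies that supplied one.
    """
    if not records:
        raise ValueError("build_consensus needs at least one study record")
    by_key: dict[tuple[str, str], ConsensusEntry] = {}
    for rec in sorted(records, key=lambda r: r.study_name):
        for f in rec.findings:
            key = (f.mirna_id, f.direction)
            entry = by_key.get(key)
            if entry is None:
                entry = ConsensusEntry(
                    mirna_id=f.mirna_id,
                    direction=f.direction,
                    supporting_studies=[],
                    total_samples=0,
                )
                by_key[key] = entry
            entry.supporting_studies.append(rec.study_name)
            entry.total_samples += rec.n_samples
            if f.fold_change is not None:
                entry.fold_changes.append(f.fold_change)
    conflicts = sorted(
        {m for m, d in by_key if d == "up"} & {m for m, d in by_key if d == "down"}
    )
    if conflicts:
        log.warning("direction-conflicted miRNA(s) across studies: %s", conflicts)
    entries = [by_key[k] for k in sorted(by_key)]
    return entries, conflicts


def rank_consensus(
    entries: Sequence[ConsensusEntry], min_studies: int = 2
) -> dict[str, list[ConsensusEntry]]:
    """Vote-counting rank per direction.

    Entries with fewer than ``min_studies`` concordant studies are dropped;
    the rest sort by (n_studies desc, total_samples desc, avg_fc desc,
    miRNA id asc). Entries without any fold change sort after any entry
    with one at the same study/sample counts.
    """
    ranked: dict[str, list[ConsensusEntry]] = {}
    for direction in DIRECTIONS:
        pool = [
            e for e in entries if e.direction == direction and e.n_studies >= min_studies
        ]
        pool.sort(
            key=lambda e: (
                -e.n_studies,
                -e.total_samples,
                -(e.avg_fc if e.avg_fc is not None else float("-inf")),
                e.mirna_id,
            )
        )
        ranked[direction] = pool
    return ranked


@dataclass
class OverlapStat:
    direction: str
    n_consistent: int  # distinct miRNAs reported concordantly by >= min_studies
    n_total_distinct: int  # distinct miRNAs reported in this direction at all
    min_studies: int = 2

    @property
    def fraction(self) -> float:
        if self.n_total_distinct == 0:
            return 0.0
        return self.n_consistent / self.n_total_distinct

    @property
    def percent(self) -> float:
        return round(100.0 * self.fraction, 1)


def overlap_stats(
    records: Sequence[StudyRecord], min_studies: int = 2
) -> dict[str, OverlapStat]:
    """How much do studies agree? Per direction: multi-study vs all distinct."""
    entries, _ = build_consensus(records)
    stats = {}
    for direction in DIRECTIONS:
        pool = [e for e in entries if e.direction == direction]
        stats[direction] = OverlapStat(
            direction=direction,
            n_consistent=sum(1 for e in pool if e.n_studies >= min_studies),
            n_total_distinct=len(pool),
            min_studies=min_studies,
        )
    return stats


CONCORDANT = "concordant"
DISCORDANT = "discordant"
ABSENT = "absent"


def crosscheck_internal(
    entries: Sequence[ConsensusEntry],
    internal: ComparisonSet | Mapping[str, str],
) -> pd.DataFrame:
    """Annotate consensus entries against this pipeline's own DE calls.

    ``internal`` is a ComparisonSet (or a miRNA -> direction mapping). Each
    entry is marked concordant (same direction), discordant (opposite), or
    absent (no internal call).
    """
    if isinstance(internal, ComparisonSet):
        calls = {p: "up" for p in internal.up} | {p: "down" for p in internal.down}
    else:
        calls = dict(internal)
    rows = []
    for e in entries:
        internal_dir = calls.get(e.mirna_id)
        if internal_dir is None:
            status = ABSENT
        elif internal_dir == e.direction:
            status = CONCORDANT
        else:
            status = DISCORDANT
        rows.append((e.mirna_id, e.direction, e.n_studies, internal_dir or "", status))
    return pd.DataFrame(
        rows, columns=["mirna_id", "direction", "n_studies", "internal_direction", "status"]
    )


def consensus_table(ranked: Mapping[str, Sequence[ConsensusEntry]]) -> pd.DataFrame:
    """Flatten ranked entries into the report table shape."""
    rows = []
    for direction in DIRECTIONS:
        for e in ranked.get(direction, []):
            rng = e.fc_range
            rows.append(
                {
                    "mirna_id": e.mirna_id,
                    "direction": direction,
                    "n_studies": e.n_studies,
                    "studies": ", ".join(e.supporting_studies),
                    "total_samples": e.total_samples,
                    "avg_fc": None if e.avg_fc is None else round_half_up(e.avg_fc),
                    "fc_range": "" if rng is None else f"{rng[0]:g}-{rng[1]:g}",
                    "single_value_fc": e.single_value_flag,
                }
            )
    return pd.DataFrame(rows)
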