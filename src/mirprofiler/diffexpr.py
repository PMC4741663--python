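"""Class-comparison engine.

Per-probe Welch tests (unpaired t for two groups, Welch's heteroscedastic
F for three or more), Benjamini–Hochberg FDR over the tested probe family,
signed fold changes from normalized log2 group means, thresholded DE calls
(FC magnitude AND FDR), deterministic top-k ranking, and the two-axis
intersection used to separate shared from axis-specific deregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, SampleSheet

log = logging.getLogger("mirprofiler")

UP = "up"
DOWN = "down"


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p-value. Two constant, equal groups are degenerate and
    return ``(0, nan, 1)`` by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            log.warning("welch_t: both groups constant and equal; p=1 by convention")
            return 0.0, float("nan"), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float("nan"), 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA for k >= 3 groups.

    Returns ``(F, df1, df2, p)``. Identical constant groups return
    ``(0, k-1, inf, 1)``. Two groups are routed to :func:`welch_t` by error.
    """
    k = len(groups)
    if k < 3:
        raise ValueError("welch_anova needs >= 3 groups; use welch_t for two")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("welch_anova needs at least 2 values per group")
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    if np.all(v == 0.0):
        if np.all(m == m[0]):
            return 0.0, float(k - 1), float("inf"), 1.0
        return float("inf"), float(k - 1), float("inf"), 0.0
    if np.any(v == 0.0):
        raise ValueError("welch_anova: a group has zero variance")
    w = n / v
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a_term = ((w * (m - m_w) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    f_stat = a_term / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * lam)
    p = float(scipy.stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, float(df2), p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Records and comparison sets
# ---------------------------------------------------------------------------


@dataclass
class DERecord:
    """One probe's statistics for one class (or covariate) comparison."""

    probe_id: str
    comparison_id: str
    mean_group1: float
    mean_group2: float
    log2fc: float  # group1 - group2 on the normalized log2 scale
    p_value: float
    fdr_q: float
    called: bool = False

    @property
    def fc_magnitude(self) -> float:
        return float(2.0 ** abs(self.log2fc))

    @property
    def direction(self) -> str:
        return UP if self.log2fc > 0 else DOWN


@dataclass
class ComparisonSet:
    """The up/down DE call lists for one comparison."""

    comparison_id: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("a probe cannot be both up- and down-regulated")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def called(self) -> set[str]:
        return set(self.up) | set(self.down)

    def direction_of(self, probe_id: str) -> str | None:
        if probe_id in self.up:
            return UP
        if probe_id in self.down:
            return DOWN
        return None

    def to_dict(self) -> dict:
        return {
            "comparison_id": self.comparison_id,
            "n_total": self.n_total,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "up": sorted(self.up),
            "down": sorted(self.down),
        }


def _compare_groups(
    matrix: ExpressionMatrix,
    cols1: list[str],
    cols2: list[str],
    comparison_id: str,
    fc_thresh: float,
    q_thresh: float,
) -> tuple[list[DERecord], ComparisonSet]:
    """Vectorized per-probe Welch t over two sample groups, then BH and calls."""
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError(f"{comparison_id}: each group needs >= 2 samples")
    a = matrix.data[cols1].to_numpy(dtype=float)
    b = matrix.data[cols2].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # degenerate probes: both groups constant -> nan p; equal means get p=1
    degenerate = np.isnan(p)
    if degenerate.any():
        log.warning(
            "%s: %d zero-variance probe(s); p set to 1 where means are equal",
            comparison_id,
            int(degenerate.sum()),
        )
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    q = bh_fdr(p)
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    log2fc = m1 - m2
    fc_mag = 2.0 ** np.abs(log2fc)
    called = (fc_mag >= fc_thresh) & (q < q_thresh)

    records = [
        DERecord(
            probe_id=probe,
            comparison_id=comparison_id,
            mean_group1=float(m1[i]),
            mean_group2=float(m2[i]),
            log2fc=float(log2fc[i]),
            p_value=float(p[i]),
            fdr_q=float(q[i]),
            called=bool(called[i]),
        )
        for i, probe in enumerate(matrix.probe_ids)
    ]
    up = [r.probe_id for r in records if r.called and r.direction == UP]
    down = [r.probe_id for r in records if r.called and r.direction == DOWN]
    return records, ComparisonSet(comparison_id=comparison_id, up=up, down=down)


def run_comparison(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    class1: str,
    class2: str,
    fc_thresh: float = 1.5,
    q_thresh: float = 0.05,
) -> tuple[list[DERecord], ComparisonSet]:
    """Welch-test every probe between two classes; call DE at FC & FDR thresholds.

    BH adjustment is applied over exactly the probes present in ``matrix``
    (i.e. the presence-filtered set when run inside the pipeline).
    A probe is called iff ``fc_magnitude >= fc_thresh`` and ``q < q_thresh``.
    """
    cols1 = [s for s in sheet.samples_in_class(class1) if s in matrix.sample_ids]
    cols2 = [s for s in sheet.samples_in_class(class2) if s in matrix.sample_ids]
    comparison_id = f"{class1}:{class2}"
    return _compare_groups(matrix, cols1, cols2, comparison_id, fc_thresh, q_thresh)


def run_covariate_comparison(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    covariate: str,
    levels: tuple[str, str],
    fc_thresh: float = 1.5,
    q_thresh: float = 0.05,
) -> tuple[list[DERecord], ComparisonSet]:
    """Same engine as :func:`run_comparison`, grouping by a binary covariate."""
    groups = sheet.covariate_groups(covariate, levels)
    for level, samples in groups.items():
        in_matrix = [s for s in samples if s in matrix.sample_ids]
        if len(in_matrix) < 2:
            raise ValueError(f"covariate {covariate}={level}: fewer than 2 samples")
        groups[level] = in_matrix
    comparison_id = f"{covariate}:{levels[0]}-vs-{levels[1]}"
    return _compare_groups(
        matrix, groups[levels[0]], groups[levels[1]], comparison_id, fc_thresh, q_thresh
    )


def rank_top(records: Sequence[DERecord], k: int = 10) -> dict[str, list[DERecord]]:
    """Top-k called records per direction, ranked by FDR then fold change.

    Sort key: ``fdr_q`` ascending, then ``fc_magnitude`` descending, then
    ``probe_id`` ascending as a deterministic final tie-break.
    """
    ranked: dict[str, list[DERecord]] = {}
    for direction in (UP, DOWN):
        pool = [r for r in records if r.called and r.direction == direction]
        pool.sort(key=lambda r: (r.fdr_q, -r.fc_magnitude, r.probe_id))
        ranked[direction] = pool[:k]
    return ranked


@dataclass
class AxisIntersection:
    """Partition of two comparison sets into shared and axis-specific calls."""

    shared: ComparisonSet
    only_a: ComparisonSet
    only_b: ComparisonSet
    direction_conflicts: list[str] = field(default_factory=list)


def intersect_axes(set_a: ComparisonSet, set_b: ComparisonSet) -> AxisIntersection:
    """Shared = called in both axes with the same direction.

    Probes called in both but in opposite directions are excluded from
    ``shared`` and reported in ``direction_conflicts``; probes called in
    exactly one axis land in that axis's specific set.
    """
    called_a, called_b = set_a.called, set_b.called
    both = called_a & called_b
    shared_up = sorted(p for p in both if p in set_a.up and p in set_b.up)
    shared_down = sorted(p for p in both if p in set_a.down and p in set_b.down)
    conflicts = sorted(both - set(shared_up) - set(shared_down))
    if conflicts:
        log.warning("direction conflict between axes for: %s", conflicts)
    only_a = called_a - called_b
    only_b = called_b - called_a
    label = f"{set_a.comparison_id}&{set_b.comparison_id}"
    return AxisIntersection(
        shared=ComparisonSet(f"shared[{label}]", up=shared_up, down=shared_down),
        only_a=ComparisonSet(
            f"only[{set_a.comparison_id}]",
            up=sorted(p for p in set_a.up if p in only_a),
            down=sorted(p for p in set_a.down if p in only_a),
        ),
        only_b=ComparisonSet(
            f"only[{set_b.comparison_id}]",
            up=sorted(p for p in set_b.up if p in only_b),
            down=sorted(p for p in set_b.down if p in only_b),
        ),
        direction_conflicts=conflicts,
    )
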