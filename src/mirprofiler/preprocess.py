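"""GeneSpring-style array preprocessing.

Three stages, applied in this fixed order:

1. intensity floor at a threshold (default 1) followed by log2 transform,
2. per-sample percentile-shift normalization (default: subtract each
   sample's 75th percentile of log2 intensities),
3. presence filter keeping probes whose normalized value lies at or above
   the per-sample 50th percentile in *every* sample of at least one class.

Percentiles use linear interpolation (the type-7 convention shared by
numpy's default and common spreadsheet software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    CLASS_LABELS,
    SCALE_LOG2,
    SCALE_NORMALIZED,
    SCALE_RAW,
    ExpressionMatrix,
    SampleSheet,
)


@dataclass
class FilterReport:
    """Outcome of the presence filter: kept/dropped partition per probe."""

    kept: list[str]
    dropped: list[str]
    qualifying_classes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.dropped):
            raise ValueError("kept and dropped probe sets overlap")

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_dict(self) -> dict:
        return {
            "n_kept": self.n_kept,
            "n_dropped": len(self.dropped),
            "kept": self.kept,
            "dropped": self.dropped,
            "qualifying_classes": self.qualifying_classes,
        }


def floor_and_log(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Floor raw intensities at ``threshold`` and log2-transform.

    Guards against double transformation: the input must carry the raw tag.
    """
    if matrix.scale_tag != SCALE_RAW:
        raise ValueError(
            f"floor_and_log expects a raw matrix, got scale {matrix.scale_tag!r}"
        )
    if threshold <= 0:
        raise ValueError("floor threshold must be positive")
    logged = np.log2(np.maximum(matrix.values, threshold))
    out = matrix.data.copy()
    out.loc[:, :] = logged
    return matrix.with_data(out, SCALE_LOG2)


def percentile_shift(matrix: ExpressionMatrix, pct: float = 75.0) -> ExpressionMatrix:
    """Subtract each sample's ``pct``-th percentile (across probes) from that sample."""
    if matrix.scale_tag != SCALE_LOG2:
        raise ValueError(
            f"percentile_shift expects a log2 matrix, got scale {matrix.scale_tag!r}"
        )
    if not (0.0 < pct < 100.0):
        raise ValueError(f"percentile must lie in (0, 100), got {pct}")
    values = matrix.values
    shifts = np.percentile(values, pct, axis=0)  # one per sample column
    out = matrix.data.copy()
    out.loc[:, :] = values - shifts[np.newaxis, :]
    return matrix.with_data(out, SCALE_NORMALIZED)


def presence_filter(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    band: tuple[float, float] = (50.0, 100.0),
) -> FilterReport:
    """Keep probes expressed in the upper percentile band in all samples of some class.

    A probe qualifies through a class when, for every sample of that class,
    its normalized value is at or above that sample's ``band[0]``-th
    percentile (computed across probes). The upper bound of the default
    (50, 100) band is vacuous; it is validated but imposes no constraint
    beyond each sample's maximum when set below 100.
    """
    if matrix.scale_tag != SCALE_NORMALIZED:
        raise ValueError(
            f"presence_filter expects a normalized matrix, got {matrix.scale_tag!r}"
        )
    lo, hi = band
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError(f"invalid percentile band {band}")
    matrix_samples = set(matrix.sample_ids)
    present = {
        c: [s for s in sheet.samples_in_class(c) if s in matrix_samples]
        for c in CLASS_LABELS
    }
    classes = [c for c in CLASS_LABELS if present[c]]
    if not classes:
        raise ValueError("no class has any sample in the matrix")

    values = matrix.values
    sample_index = {s: j for j, s in enumerate(matrix.sample_ids)}
    lo_cut = np.percentile(values, lo, axis=0)
    hi_cut = np.percentile(values, hi, axis=0)
    in_band = (values >= lo_cut[np.newaxis, :]) & (values <= hi_cut[np.newaxis, :])

    kept: list[str] = []
    dropped: list[str] = []
    qualifying: dict[str, list[str]] = {}
    probe_ids = matrix.probe_ids
    class_cols = {c: [sample_index[s] for s in present[c]] for c in classes}
    for i, probe in enumerate(probe_ids):
        quals = [c for c in classes if in_band[i, class_cols[c]].all()]
        if quals:
            kept.append(probe)
            qualifying[probe] = quals
        else:
            dropped.append(probe)
    return FilterReport(kept=kept, dropped=dropped, qualifying_classes=qualifying)


def apply_filter(matrix: ExpressionMatrix, report: FilterReport) -> ExpressionMatrix:
    """Subset a matrix to the probes a :class:`FilterReport` kept."""
    return matrix.with_data(matrix.data.loc[report.kept], matrix.scale_tag)
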