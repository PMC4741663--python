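"""Relative quantification of qPCR data by the comparative-Ct (ddCt) method.

Replicate Ct values are averaged on the cycle scale, normalized to a
reference miRNA (dCt), harmonized across two instrument cohorts via
samples measured in both, referenced to a baseline tissue class (ddCt,
RQ = 2^-ddCt, assuming amplification efficiency 2.0), and compared across
classes with the tie-corrected Kruskal–Wallis test on the normalized Ct
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import ParseError, SampleSheet

log = logging.getLogger("mirprofiler")

DEFAULT_REFERENCE = "miR-125a-5p"

CT_COLUMNS = ["sample_id", "cohort", "mirna_id", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format replicate Ct measurements.

    Columns: sample_id, cohort (1 or 2), mirna_id, replicate, ct (cycles).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ParseError(f"Ct table missing column(s): {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if np.isnan(ct).any() or np.any(ct <= 0) or np.any(ct > 45):
            raise ParseError("Ct values must lie in (0, 45]")
        if not set(self.data["cohort"].unique()) <= {1, 2}:
            raise ParseError("cohort labels must be 1 or 2")

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.data["mirna_id"].unique())


def read_ct_table(path) -> CtTable:
    df = pd.read_csv(path)
    df["cohort"] = df["cohort"].astype(int)
    return CtTable(data=df)


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, index=False)


@dataclass
class DeltaCtMatrix:
    """Per (sample, cohort, target): dCt = mean Ct(target) - mean Ct(reference)."""

    data: pd.DataFrame  # columns: sample_id, cohort, mirna_id, delta_ct
    reference: str


def delta_ct(table: CtTable, reference: str = DEFAULT_REFERENCE) -> DeltaCtMatrix:
    """Reference-normalize: replicate means first, then target minus reference.

    Samples lacking the reference miRNA in a cohort are excluded with a
    warning. The reference's own dCt is identically zero and is retained
    as an internal control row.
    """
    df = table.data
    if reference not in set(df["mirna_id"]):
        raise ValueError(f"reference miRNA {reference!r} absent from Ct table")
    means = (
        df.groupby(["sample_id", "cohort", "mirna_id"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "mean_ct"})
    )
    ref = means[means["mirna_id"] == reference][["sample_id", "cohort", "mean_ct"]]
    ref = ref.rename(columns={"mean_ct": "ref_ct"})
    merged = means.merge(ref, on=["sample_id", "cohort"], how="left")
    lacking = merged[merged["ref_ct"].isna()]
    if not lacking.empty:
        bad = sorted(set(zip(lacking["sample_id"], lacking["cohort"])))
        log.warning("delta_ct: excluding %d sample/cohort pair(s) lacking reference: %s",
                    len(bad), bad)
        merged = merged.dropna(subset=["ref_ct"])
    merged["delta_ct"] = merged["mean_ct"] - merged["ref_ct"]
    out = merged[["sample_id", "cohort", "mirna_id", "delta_ct"]].reset_index(drop=True)
    return DeltaCtMatrix(data=out, reference=reference)


def harmonize_cohorts(
    dct: DeltaCtMatrix, shared_sample_ids: list[str] | None = None
) -> tuple[DeltaCtMatrix, dict[str, float]]:
    """Shift cohort-1 dCt values onto the cohort-2 scale via shared samples.

    For each target, offset = mean over shared samples of
    (dCt_cohort1 - dCt_cohort2); cohort-1 values are shifted by -offset and
    cohort 2 is left unchanged. Returns the harmonized matrix and the
    per-target offsets. Raises if no sample was measured in both cohorts.
    """
    df = dct.data
    c1 = df[df["cohort"] == 1]
    c2 = df[df["cohort"] == 2]
    if shared_sample_ids is None:
        shared_sample_ids = sorted(set(c1["sample_id"]) & set(c2["sample_id"]))
    if not shared_sample_ids:
        raise ValueError("no shared samples between cohorts; harmonization impossible")
    offsets: dict[str, float] = {}
    out = df.copy()
    for target in sorted(df["mirna_id"].unique()):
        a = c1[(c1["mirna_id"] == target) & (c1["sample_id"].isin(shared_sample_ids))]
        b = c2[(c2["mirna_id"] == target) & (c2["sample_id"].isin(shared_sample_ids))]
        pair = a.merge(b, on="sample_id", suffixes=("_1", "_2"))
        if pair.empty:
            log.warning("harmonize_cohorts: target %s has no shared measurement; "
                        "left unshifted", target)
            continue
        offset = float((pair["delta_ct_1"] - pair["delta_ct_2"]).mean())
        offsets[target] = offset
        mask = (out["cohort"] == 1) & (out["mirna_id"] == target)
        out.loc[mask, "delta_ct"] -= offset
    return DeltaCtMatrix(data=out, reference=dct.reference), offsets


def relative_quant(
    dct: DeltaCtMatrix, sheet: SampleSheet, baseline_class: str = "Healthy-N"
) -> pd.DataFrame:
    """ddCt relative to the baseline class mean; RQ = 2^-ddCt.

    Returns a DataFrame with columns sample_id, cohort, mirna_id,
    delta_ct, ddct, rq.
    """
    base_samples = set(sheet.samples_in_class(baseline_class))
    df = dct.data.copy()
    if not base_samples & set(df["sample_id"]):
        raise ValueError(f"baseline class {baseline_class!r} has no measured samples")
    base = df[df["sample_id"].isin(base_samples)]
    base_mean = base.groupby("mirna_id")["delta_ct"].mean().rename("baseline_dct")
    df = df.merge(base_mean, on="mirna_id", how="left")
    df["ddct"] = df["delta_ct"] - df["baseline_dct"]
    df["rq"] = 2.0 ** (-df["ddct"])
    return df[["sample_id", "cohort", "mirna_id", "delta_ct", "ddct", "rq"]]


@dataclass
class KruskalResult:
    mirna_id: str
    h_statistic: float
    df: int
    p_value: float
    significant: bool
    degenerate: bool = False


def kruskal_wallis_by_class(
    dct: DeltaCtMatrix,
    sheet: SampleSheet,
    target: str,
    alpha: float = 0.01,
) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis test of a target's dCt across classes.

    Significance is declared at ``p <= alpha`` (default 0.01, the stricter
    level used because several classes are compared at once). Groups with
    no measurements are dropped; fewer than two non-empty classes is an
    error. A fully tied input is flagged degenerate with H=0, p=1.
    """
    df = dct.data
    sub = df[df["mirna_id"] == target]
    if sub.empty:
        raise ValueError(f"target {target!r} absent from dCt matrix")
    labels = sheet.class_labels
    groups = []
    for cls in sorted(labels.unique()):
        samples = set(labels.index[labels == cls])
        vals = sub[sub["sample_id"].isin(samples)]["delta_ct"].to_numpy()
        if vals.size:
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 classes with measurements")
    k = len(groups)
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            h, p = scipy.stats.kruskal(*groups)
    except ValueError:
        h, p = float("nan"), float("nan")
    if not np.isfinite(h):  # all values identical: total ties, H undefined
        log.warning("kruskal_wallis: all values identical for %s; degenerate", target)
        return KruskalResult(target, 0.0, k - 1, 1.0, False, degenerate=True)
    return KruskalResult(
        mirna_id=target,
        h_statistic=float(h),
        df=k - 1,
        p_value=float(p),
        significant=bool(p <= alpha),
    )
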