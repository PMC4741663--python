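"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the 5-class FFPE breast-tissue study design: a
probe-by-sample log2-scale intensity matrix (class sizes default to
17/9/5/5/10 for BRCA1-C / BRCA2-C / BRCA1-N / BRCA2-N / Healthy-N),
planted per-class fold-change effects on chosen probe sets, locus
annotations containing planted cytoband hotspots and fragile sites,
replicate qPCR Ct tables consistent with planted expression effects, and
multi-study differential-expression lists with controllable direction
concordance.

Raw intensity model: ``2 ** (baseline + class_effect + N(0, noise_sd))``
with per-probe baselines drawn from a Normal(6, 2) truncated at 0 — a
realistic log2 dynamic range whose lower tail exercises the floor-at-1
preprocessing rule. Noise is probe-independent Gaussian in log2 space;
no correlation structure, dye effects or spatial artifacts are emulated.

One global seed feeds per-artifact RNG streams (numpy ``SeedSequence``
spawning) so adding an artifact never perturbs the others; a fixed seed
yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CHROMOSOMES,
    CLASS_LABELS,
    ExpressionMatrix,
    Finding,
    FragileSite,
    FragileSiteCatalog,
    GenomicLocus,
    SampleSheet,
    StudyRecord,
    write_annotation,
    write_expression_matrix,
    write_fragile_sites_bed,
    write_sample_sheet,
    write_study_records,
)
from .qpcr import CtTable, write_ct_table

DEFAULT_CLASS_SIZES = {
    "BRCA1-C": 17,
    "BRCA2-C": 9,
    "BRCA1-N": 5,
    "BRCA2-N": 5,
    "Healthy-N": 10,
}

#: validation-cohort class sizes (15/15/10/10/10)
VALIDATION_CLASS_SIZES = {
    "BRCA1-C": 15,
    "BRCA2-C": 15,
    "BRCA1-N": 10,
    "BRCA2-N": 10,
    "Healthy-N": 10,
}

#: per-study sample totals of the six-study literature compilation
LITERATURE_STUDY_SIZES = {
    "Chen": 24,
    "Iorio": 110,
    "Ouyang": 6,
    "Tahiri": 58,
    "Tanic": 36,
    "Yan": 8,
}

AXIS1 = "BRCA1-C:BRCA1-N"
AXIS2 = "BRCA2-C:BRCA2-N"

# RNG stream indices (fixed so adding artifacts never perturbs earlier ones)
_STREAM_MATRIX = 0
_STREAM_ANNOTATION = 1
_STREAM_QPCR = 2
_STREAM_STUDIES = 3


def _stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffect:
    """A log2 shift applied to a probe set in the given classes."""

    probes: list[str]
    classes: tuple[str, ...]
    log2_effect: float

    def __post_init__(self) -> None:
        if self.log2_effect == 0.0:
            raise ValueError("planted log2 effect must be nonzero")
        unknown = set(self.classes) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class(es) in planted effect: {sorted(unknown)}")


@dataclass
class PlannedHotspot:
    chromosome: str
    cytoband: str
    probes: list[str]
    direction: str
    scope: str = "axis1"  # axis1 | axis2 | shared

    @property
    def locus_label(self) -> str:
        return f"{self.chromosome}{self.cytoband}"


@dataclass
class SimulationConfig:
    n_probes: int = 862
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    hotspot_plan: list[PlannedHotspot] = field(default_factory=list)
    unlocalized_probes: list[str] = field(default_factory=list)
    fragile_probes: list[str] = field(default_factory=list)
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        for cls, n in self.class_sizes.items():
            if cls not in CLASS_LABELS:
                raise ValueError(f"unknown class {cls!r}")
            if n < 2:
                raise ValueError(f"class {cls} needs >= 2 samples, got {n}")
        n_hot = sum(len(h.probes) for h in self.hotspot_plan)
        if n_hot > self.n_probes:
            raise ValueError(
                f"hotspot plan requests {n_hot} probes but only {self.n_probes} exist"
            )

    @property
    def probe_ids(self) -> list[str]:
        width = len(str(self.n_probes))
        return [f"probe{i:0{width}d}" for i in range(1, self.n_probes + 1)]


@dataclass
class GroundTruth:
    """Planted per-probe effects plus hotspot/fragile/locus bookkeeping."""

    effects: dict[str, dict[str, float]]  # probe -> class -> log2 effect
    hotspot_loci: list[dict] = field(default_factory=list)
    fragile_members: list[str] = field(default_factory=list)
    unlocalized: list[str] = field(default_factory=list)

    def de_set(self, class1: str, class2: str) -> dict[str, str]:
        """Probes truly differing between two classes, with direction (group1 vs group2)."""
        out: dict[str, str] = {}
        for probe, eff in self.effects.items():
            delta = eff.get(class1, 0.0) - eff.get(class2, 0.0)
            if delta != 0.0:
                out[probe] = "up" if delta > 0 else "down"
        return out

    def de_axis(self, axis: str) -> dict[str, str]:
        c, n = axis.split(":")
        return self.de_set(c, n)

    @property
    def n_de_probes(self) -> int:
        return len([p for p, e in self.effects.items() if any(v != 0 for v in e.values())])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": self.effects,
            "hotspot_loci": self.hotspot_loci,
            "fragile_members": self.fragile_members,
            "unlocalized": self.unlocalized,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            effects=payload["effects"],
            hotspot_loci=payload["hotspot_loci"],
            fragile_members=payload["fragile_members"],
            unlocalized=payload["unlocalized"],
        )


class Dataset(NamedTuple):
    matrix: ExpressionMatrix
    sheet: SampleSheet
    annotation: dict[str, GenomicLocus | None]
    fragile_catalog: FragileSiteCatalog
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Expression dataset
# ---------------------------------------------------------------------------

_CLASS_PREFIX = {
    "BRCA1-C": "b1c",
    "BRCA2-C": "b2c",
    "BRCA1-N": "b1n",
    "BRCA2-N": "b2n",
    "Healthy-N": "hn",
}


def _sample_ids(class_sizes: dict[str, int]) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for cls in CLASS_LABELS:
        for i in range(1, class_sizes.get(cls, 0) + 1):
            ids.append(f"{_CLASS_PREFIX[cls]}{i:02d}")
            labels.append(cls)
    return ids, labels


def _default_locus(i: int) -> GenomicLocus:
    """A unique, deterministic locus per probe index (no accidental hotspots)."""
    chrom = CHROMOSOMES[i % 23]  # autosomes + X
    band_major = 11 + (i // 23) % 30
    band_minor = 1 + i // (23 * 30)
    start = 1_000_000 + 10_000 * i
    return GenomicLocus(
        chromosome=chrom,
        start=start,
        end=start + 80,
        strand="+" if i % 2 == 0 else "-",
        cytoband=f"q{band_major}.{band_minor}",
    )


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate the raw expression matrix, sample sheet, annotation and truth."""
    probes = config.probe_ids
    probe_index = {p: i for i, p in enumerate(probes)}
    sample_ids, labels = _sample_ids(config.class_sizes)
    n_samples = len(sample_ids)

    rng = _stream(config.seed, _STREAM_MATRIX)
    baseline = np.clip(
        rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes), 0, None
    )
    # planted DE probes sit on expressed baselines (the study only ever calls
    # probes that pass its presence filter, i.e. expressed ones)
    de_probe_idx = sorted(
        {probe_index[p] for pe in config.planted_effects for p in pe.probes if p in probe_index}
    )
    if de_probe_idx:
        floor_level = config.baseline_mean + 1.5
        baseline[de_probe_idx] = np.maximum(baseline[de_probe_idx], floor_level)
    effect = np.zeros((config.n_probes, n_samples))
    effects_truth: dict[str, dict[str, float]] = {p: {} for p in probes}
    col_of_class = {
        cls: [j for j, lab in enumerate(labels) if lab == cls] for cls in CLASS_LABELS
    }
    for pe in config.planted_effects:
        for probe in pe.probes:
            if probe not in probe_index:
                raise ValueError(f"planted effect references unknown probe {probe!r}")
            i = probe_index[probe]
            for cls in pe.classes:
                effect[i, col_of_class[cls]] += pe.log2_effect
                effects_truth[probe][cls] = (
                    effects_truth[probe].get(cls, 0.0) + pe.log2_effect
                )
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n_samples))
    raw = 2.0 ** (baseline[:, np.newaxis] + effect + noise)

    matrix = ExpressionMatrix(
        data=pd.DataFrame(raw, index=probes, columns=sample_ids), scale_tag="raw"
    )
    sheet = SampleSheet(
        data=pd.DataFrame({"class_label": labels}, index=pd.Index(sample_ids, name="sample_id"))
    )

    # annotation: planned hotspot probes share the planned band; everything
    # else gets a unique band; unlocalized probes get no locus at all
    annotation: dict[str, GenomicLocus | None] = {}
    hotspot_band: dict[str, PlannedHotspot] = {}
    for plan in config.hotspot_plan:
        for probe in plan.probes:
            if probe in hotspot_band:
                raise ValueError(f"probe {probe} planned into two hotspots")
            hotspot_band[probe] = plan
    unloc = set(config.unlocalized_probes)
    overlap = unloc & set(hotspot_band)
    if overlap:
        raise ValueError(f"probes both unlocalized and in hotspots: {sorted(overlap)}")
    for i, probe in enumerate(probes):
        if probe in unloc:
            annotation[probe] = None
        elif probe in hotspot_band:
            plan = hotspot_band[probe]
            offset = plan.probes.index(probe)
            start = 500_000 + 2_000 * offset
            annotation[probe] = GenomicLocus(
                chromosome=plan.chromosome,
                start=start,
                end=start + 80,
                strand="+",
                cytoband=plan.cytoband,
            )
        else:
            annotation[probe] = _default_locus(i)

    catalog = FragileSiteCatalog(
        entries=[
            FragileSite(
                chromosome=annotation[p].chromosome,
                cytoband=annotation[p].cytoband,
                name=f"FRA-{p}",
            )
            for p in config.fragile_probes
            if annotation.get(p) is not None
        ]
    )

    truth = GroundTruth(
        effects=effects_truth,
        hotspot_loci=[
            {
                "locus": plan.locus_label,
                "scope": plan.scope,
                "direction": plan.direction,
                "members": list(plan.probes),
            }
            for plan in config.hotspot_plan
        ],
        fragile_members=list(config.fragile_probes),
        unlocalized=sorted(unloc),
    )
    return Dataset(matrix, sheet, annotation, catalog, truth)


def planted_axis_design(
    n_probes: int = 862,
    n_axis1: int = 145,
    n_axis2: int = 96,
    n_shared: int = 53,
    n_up: tuple[int, int, int] = (41, 8, 2),  # axis1 total, axis2 total, shared
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_unlocalized: tuple[int, int] = (44, 20),
    fragile_fraction: float = 0.208,
    class_sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """The planted two-axis design emulating the observed study footprint.

    Defaults plant 145 probes deregulated along the BRCA1 axis and 96 along
    the BRCA2 axis with 53 shared (same direction in both), up/down splits
    of 41/104 and 8/88, effect magnitude ``effect`` in log2 units on the
    carcinoma class of each axis, 44 and 20 axis-specific probes with
    unknown loci, shared down-regulated hotspots at 5q32 / 14q32.2 /
    14q32.31 / 21q21.1, a BRCA1-specific up-regulated hotspot at 7q32.2,
    and a fragile-site catalog covering ~20.8% of the localized BRCA1-axis
    DE probes.
    """
    n_a1_specific = n_axis1 - n_shared
    n_a2_specific = n_axis2 - n_shared
    up1, up2, up_sh = n_up
    up1_specific = up1 - up_sh
    up2_specific = up2 - up_sh
    if min(n_a1_specific, n_a2_specific, up1_specific, up2_specific, up_sh) < 0:
        raise ValueError("inconsistent axis/shared/up counts")
    if n_axis1 + n_axis2 - n_shared > n_probes:
        raise ValueError("design plants more DE probes than n_probes")

    cfg = SimulationConfig(
        n_probes=n_probes,
        class_sizes=dict(class_sizes or DEFAULT_CLASS_SIZES),
        noise_sd=noise_sd,
        seed=seed,
    )
    probes = cfg.probe_ids
    shared = probes[:n_shared]
    a1 = probes[n_shared : n_shared + n_a1_specific]
    a2 = probes[n_shared + n_a1_specific : n_shared + n_a1_specific + n_a2_specific]
    shared_up, shared_down = shared[:up_sh], shared[up_sh:]
    a1_up, a1_down = a1[:up1_specific], a1[up1_specific:]
    a2_up, a2_down = a2[:up2_specific], a2[up2_specific:]

    effects = []
    for group, classes, sign in (
        (shared_up, ("BRCA1-C", "BRCA2-C"), +1),
        (shared_down, ("BRCA1-C", "BRCA2-C"), -1),
        (a1_up, ("BRCA1-C",), +1),
        (a1_down, ("BRCA1-C",), -1),
        (a2_up, ("BRCA2-C",), +1),
        (a2_down, ("BRCA2-C",), -1),
    ):
        if group:
            effects.append(PlantedEffect(list(group), classes, sign * effect))
    cfg.planted_effects = effects

    hotspot_specs = [
        ("5", "q32", 4, "down", "shared"),
        ("14", "q32.2", 4, "down", "shared"),
        ("14", "q32.31", 5, "down", "shared"),
        ("21", "q21.1", 4, "down", "shared"),
        ("7", "q32.2", 4, "up", "axis1"),
    ]
    pools = {
        ("shared", "down"): list(shared_down),
        ("shared", "up"): list(shared_up),
        ("axis1", "down"): list(a1_down),
        ("axis1", "up"): list(a1_up),
        ("axis2", "down"): list(a2_down),
        ("axis2", "up"): list(a2_up),
    }
    plan = []
    for chrom, band, n, direction, scope in hotspot_specs:
        pool = pools[(scope, direction)]
        if len(pool) < n:
            continue  # design too small for this hotspot; skip it
        members, pools[(scope, direction)] = pool[:n], pool[n:]
        plan.append(PlannedHotspot(chrom, band, members, direction, scope))
    cfg.hotspot_plan = plan

    in_hotspot = {p for h in plan for p in h.probes}
    a1_free = [p for p in a1 if p not in in_hotspot]
    a2_free = [p for p in a2 if p not in in_hotspot]
    if n_unlocalized[0] > len(a1_free) or n_unlocalized[1] > len(a2_free):
        raise ValueError("not enough axis-specific probes to mark unlocalized")
    cfg.unlocalized_probes = a1_free[: n_unlocalized[0]] + a2_free[: n_unlocalized[1]]

    # fragile catalog covers the requested fraction of localized axis-1 DE
    # probes; hotspot members are excluded from selection because a catalog
    # entry at a hotspot band would sweep in every co-located probe
    axis1_all = shared + a1
    localized_a1 = [p for p in axis1_all if p not in set(cfg.unlocalized_probes)]
    n_fragile = int(round(fragile_fraction * len(localized_a1)))
    candidates = [p for p in localized_a1 if p not in in_hotspot]
    if n_fragile > len(candidates):
        raise ValueError("fragile fraction too high for the non-hotspot probe pool")
    rng = _stream(seed, _STREAM_ANNOTATION)
    cfg.fragile_probes = sorted(
        rng.choice(np.array(candidates), size=n_fragile, replace=False).tolist()
    )
    return cfg


def null_config(
    n_probes: int = 862,
    class_sizes: dict[str, int] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """Global-null design: no planted effects at the default class sizes."""
    return SimulationConfig(
        n_probes=n_probes,
        class_sizes=dict(class_sizes or DEFAULT_CLASS_SIZES),
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class QpcrSimConfig:
    """Two-cohort replicate Ct simulation.

    ``targets`` maps each target miRNA to per-class log2 expression levels
    relative to the baseline class (omitted classes sit at 0). The planted
    ``cohort_offset`` (cycles) is added to cohort-1 measurements of target
    assays only — it emulates assay-chemistry differences between the two
    instruments and therefore survives reference normalization, which is
    exactly what the shared-replicate harmonization must remove.
    """

    targets: dict[str, dict[str, float]]
    reference: str = "miR-125a-5p"
    class_sizes_cohort1: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    class_sizes_cohort2: dict[str, int] = field(
        default_factory=lambda: dict(VALIDATION_CLASS_SIZES)
    )
    n_shared: int = 5
    cohort_offset: float = 1.5
    tech_sd: float = 0.1
    ref_ct: float = 20.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference in self.targets:
            raise ValueError("reference miRNA cannot also be a target")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        for mirna, levels in self.targets.items():
            unknown = set(levels) - set(CLASS_LABELS)
            if unknown:
                raise ValueError(f"{mirna}: unknown class(es) {sorted(unknown)}")


def generate_qpcr(config: QpcrSimConfig) -> tuple[CtTable, SampleSheet]:
    """Simulate replicate Ct measurements for two instrument cohorts.

    Ct(target) = ref_ct - log2(relative expression) + cohort offset (cohort
    1 only) + N(0, tech_sd) per replicate; the reference assay omits both
    the expression term and the offset. The first ``n_shared`` cohort-1
    samples are re-measured in cohort 2 under the same sample id.
    """
    rng = _stream(config.seed, _STREAM_QPCR)
    rows = []
    sheet_rows: dict[str, str] = {}

    def emit(sample: str, cls: str, cohort: int, apply_offset: bool) -> None:
        sheet_rows[sample] = cls
        mirnas = [config.reference] + sorted(config.targets)
        for mirna in mirnas:
            expr = 0.0 if mirna == config.reference else config.targets[mirna].get(cls, 0.0)
            offset = (
                config.cohort_offset
                if (apply_offset and mirna != config.reference)
                else 0.0
            )
            for rep in range(1, config.n_replicates + 1):
                ct = config.ref_ct - expr + offset + rng.normal(0.0, config.tech_sd)
                rows.append((sample, cohort, mirna, rep, float(np.clip(ct, 1e-6, 45.0))))

    cohort1_samples: list[tuple[str, str]] = []
    for cls in CLASS_LABELS:
        for i in range(1, config.class_sizes_cohort1.get(cls, 0) + 1):
            sid = f"q1_{_CLASS_PREFIX[cls]}{i:02d}"
            cohort1_samples.append((sid, cls))
            emit(sid, cls, cohort=1, apply_offset=True)
    for cls in CLASS_LABELS:
        for i in range(1, config.class_sizes_cohort2.get(cls, 0) + 1):
            emit(f"q2_{_CLASS_PREFIX[cls]}{i:02d}", cls, cohort=2, apply_offset=False)
    # shared replicate samples: re-measured on the cohort-2 instrument
    for sid, cls in cohort1_samples[: config.n_shared]:
        emit(sid, cls, cohort=2, apply_offset=False)

    table = CtTable(
        data=pd.DataFrame(rows, columns=["sample_id", "cohort", "mirna_id", "replicate", "ct"])
    )
    sheet = SampleSheet(
        data=pd.DataFrame(
            {"class_label": list(sheet_rows.values())},
            index=pd.Index(list(sheet_rows.keys()), name="sample_id"),
        )
    )
    return table, sheet


# ---------------------------------------------------------------------------
# Multi-study DE lists
# ---------------------------------------------------------------------------


@dataclass
class StudySimConfig:
    """Random multi-study report simulation with controllable concordance."""

    study_sizes: dict[str, int] = field(default_factory=lambda: dict(LITERATURE_STUDY_SIZES))
    n_mirnas: int = 100
    p_report: float = 0.4
    p_flip: float = 0.0
    fc_log2_mean: float = 1.0
    fc_log2_sd: float = 0.5
    seed: int = 0


def generate_study_lists(
    config: StudySimConfig,
) -> tuple[list[StudyRecord], dict[str, str]]:
    """Each study reports each miRNA with ``p_report``; direction flips with ``p_flip``."""
    rng = _stream(config.seed, _STREAM_STUDIES)
    mirnas = [f"miR-s{i:03d}" for i in range(1, config.n_mirnas + 1)]
    truth = {m: ("up" if rng.random() < 0.5 else "down") for m in mirnas}
    records = []
    for study in sorted(config.study_sizes):
        findings = []
        for m in mirnas:
            if rng.random() >= config.p_report:
                continue
            direction = truth[m]
            if rng.random() < config.p_flip:
                direction = "down" if direction == "up" else "up"
            fc = float(
                round(max(1.0, 2.0 ** abs(rng.normal(config.fc_log2_mean, config.fc_log2_sd))), 2)
            )
            findings.append(Finding(mirna_id=m, direction=direction, fold_change=fc))
        records.append(
            StudyRecord(study_name=study, n_samples=config.study_sizes[study], findings=findings)
        )
    return records, truth


def planted_overlap_design(
    n_up: int = 92,
    n_up_multi: int = 15,
    n_down: int = 101,
    n_down_multi: int = 15,
    study_sizes: dict[str, int] | None = None,
) -> list[StudyRecord]:
    """Deterministic study lists with a planted multi-study overlap structure.

    Plants ``n_up`` distinct up-regulated miRNAs of which ``n_up_multi`` are
    reported concordantly by exactly two studies (likewise for down), the
    remainder by exactly one study each.
    """
    sizes = dict(study_sizes or LITERATURE_STUDY_SIZES)
    names = sorted(sizes)
    if len(names) < 2:
        raise ValueError("need at least two studies")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    findings: dict[str, list[Finding]] = {s: [] for s in names}

    def plant(direction: str, n_total: int, n_multi: int) -> None:
        if n_multi > n_total:
            raise ValueError("n_multi exceeds n_total")
        for i in range(n_multi):
            m = f"miR-{direction}{i:03d}"
            for study in pairs[i % len(pairs)]:
                findings[study].append(Finding(m, direction))
        for i in range(n_total - n_multi):
            m = f"miR-{direction}single{i:03d}"
            findings[names[i % len(names)]].append(Finding(m, direction))

    plant("up", n_up, n_up_multi)
    plant("down", n_down, n_down_multi)
    return [StudyRecord(s, sizes[s], findings[s]) for s in names]


# ---------------------------------------------------------------------------
# Writing a dataset to disk
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: Dataset,
    out_dir: str | Path,
    ct_table: CtTable | None = None,
    study_records: Sequence[StudyRecord] | None = None,
) -> dict[str, Path]:
    """Write every artifact in the file dialects the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "samples": out / "samples.csv",
        "annotation": out / "annotation.tsv",
        "fragile": out / "fragile_sites.bed",
        "truth": out / "truth.json",
    }
    write_expression_matrix(dataset.matrix, paths["matrix"])
    write_sample_sheet(dataset.sheet, paths["samples"])
    write_annotation(dataset.annotation, paths["annotation"])
    write_fragile_sites_bed(dataset.fragile_catalog, paths["fragile"])
    dataset.truth.to_json(paths["truth"])
    if ct_table is not None:
        paths["ct"] = out / "ct.csv"
        write_ct_table(ct_table, paths["ct"])
    if study_records is not None:
        paths["studies"] = out / "studies.csv"
        write_study_records(study_records, paths["studies"])
    return paths
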