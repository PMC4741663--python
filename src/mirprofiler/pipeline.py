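"""End-to-end orchestration of the profiling workflow.

One config drives preprocess -> differential expression over the standard
eight class comparisons -> two-axis intersection -> chromosomal analysis ->
SOM clustering -> qPCR statistics -> cross-study consensus, writing every
stage's outputs plus a reproducibility manifest (config hash, seeds,
library versions). All randomness flows from named seeds in the config;
reruns with the same config produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .chromosomal import (
    compare_distributions,
    count_per_chromosome,
    detect_hotspots,
    fragile_overlap,
)
from .consensus import (
    build_consensus,
    consensus_table,
    crosscheck_internal,
    overlap_stats,
    rank_consensus,
)
from .core_io import (
    read_annotation,
    read_expression_matrix,
    read_fragile_sites,
    read_sample_sheet,
    read_study_records,
    write_expression_matrix,
)
from .diffexpr import ComparisonSet, intersect_axes, rank_top, run_comparison
from .preprocess import apply_filter, floor_and_log, percentile_shift, presence_filter
from .qpcr import delta_ct, harmonize_cohorts, kruskal_wallis_by_class, read_ct_table, relative_quant
from .som import order_and_export, train_som

log = logging.getLogger("mirprofiler")

#: the standard comparison roster: each carcinoma class against healthy and
#: matched normal tissue, the normals against healthy, and the cross-axis pairs
DEFAULT_COMPARISONS = (
    "BRCA1-C:Healthy-N",
    "BRCA1-C:BRCA1-N",
    "BRCA1-N:Healthy-N",
    "BRCA2-C:Healthy-N",
    "BRCA2-C:BRCA2-N",
    "BRCA2-N:Healthy-N",
    "BRCA1-C:BRCA2-C",
    "BRCA1-N:BRCA2-N",
)

AXIS1 = "BRCA1-C:BRCA1-N"
AXIS2 = "BRCA2-C:BRCA2-N"


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    matrix: str
    samples: str
    out_dir: str
    annotation: str | None = None
    fragile: str | None = None
    ct: str | None = None
    qpcr_samples: str | None = None
    studies: str | None = None

    floor: float = 1.0
    pct: float = 75.0
    band: tuple[float, float] = (50.0, 100.0)
    fc: float = 1.5
    q: float = 0.05
    top_k: int = 10
    min_hotspot: int = 4
    alpha_qpcr: float = 0.01
    qpcr_reference: str = "miR-125a-5p"
    qpcr_baseline: str = "Healthy-N"
    min_studies: int = 2
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS

    probes_grid: tuple[int, int] = (6, 6)
    samples_grid: tuple[int, int] = (3, 3)
    probes_iterations: int = 100_000
    samples_iterations: int = 20_000
    som_learning_rate: float = 0.02
    mc_iterations: int = 100_000

    seed_som: int = 1
    seed_fisher: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("band", "comparisons", "probes_grid", "samples_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("band", "comparisons", "probes_grid", "samples_grid"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "comparison": [r.comparison_id for r in records],
            "mean_group1": [r.mean_group1 for r in records],
            "mean_group2": [r.mean_group2 for r in records],
            "log2fc": [r.log2fc for r in records],
            "fc_magnitude": [r.fc_magnitude for r in records],
            "direction": [r.direction for r in records],
            "p_value": [r.p_value for r in records],
            "fdr_q": [r.fdr_q for r in records],
            "called": [r.called for r in records],
        }
    )


def _safe_name(comparison: str) -> str:
    return comparison.replace(":", "_vs_")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns the map of written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        sheet = read_sample_sheet(config.samples)
        matrix = read_expression_matrix(config.matrix, sheet)

        stage = "preprocess"
        normalized = percentile_shift(floor_and_log(matrix, config.floor), config.pct)
        report = presence_filter(normalized, sheet, config.band)
        filtered = apply_filter(normalized, report)
        outputs["normalized"] = out / "normalized_matrix.tsv"
        write_expression_matrix(filtered, outputs["normalized"])
        outputs["filter_report"] = out / "filter_report.json"
        _write_json(report.to_dict(), outputs["filter_report"])

        stage = "differential-expression"
        all_records: dict[str, list] = {}
        sets: dict[str, ComparisonSet] = {}
        summary_rows = []
        for comp in config.comparisons:
            c1, c2 = comp.split(":")
            records, cset = run_comparison(filtered, sheet, c1, c2, config.fc, config.q)
            all_records[comp] = records
            sets[comp] = cset
            path = out / f"de_{_safe_name(comp)}.csv"
            _records_frame(records).to_csv(path, index=False)
            outputs[f"de_{comp}"] = path
            summary_rows.append((c1, c2, cset.n_total, cset.n_up, cset.n_down))
        summary = pd.DataFrame(
            summary_rows, columns=["class", "class_compared_to", "total", "up", "down"]
        )
        outputs["summary"] = out / "comparison_summary.csv"
        summary.to_csv(outputs["summary"], index=False)

        stage = "axis-intersection"
        inter = None
        if AXIS1 in sets and AXIS2 in sets:
            inter = intersect_axes(sets[AXIS1], sets[AXIS2])
            outputs["intersection"] = out / "axis_intersection.json"
            _write_json(
                {
                    "shared": inter.shared.to_dict(),
                    "only_axis1": inter.only_a.to_dict(),
                    "only_axis2": inter.only_b.to_dict(),
                    "direction_conflicts": inter.direction_conflicts,
                },
                outputs["intersection"],
            )
            partitions = {
                "shared": inter.shared.called,
                "axis1_specific": inter.only_a.called,
                "axis2_specific": inter.only_b.called,
            }
            rank_source = {
                "shared": AXIS1,
                "axis1_specific": AXIS1,
                "axis2_specific": AXIS2,
            }
            for name, probes in partitions.items():
                recs = [r for r in all_records[rank_source[name]] if r.probe_id in probes]
                ranked = rank_top(recs, config.top_k)
                frame = _records_frame(ranked["up"] + ranked["down"])
                path = out / f"top{config.top_k}_{name}.csv"
                frame.to_csv(path, index=False)
                outputs[f"top_{name}"] = path

        stage = "chromosomal"
        annotation = None
        if config.annotation:
            annotation = read_annotation(config.annotation)
            dist1 = count_per_chromosome(all_records.get(AXIS1, []), annotation, "axis1")
            dist2 = count_per_chromosome(all_records.get(AXIS2, []), annotation, "axis2")
            dist_frame = pd.DataFrame(
                {"axis1": pd.Series(dist1.counts), "axis2": pd.Series(dist2.counts)}
            )
            dist_frame.index.name = "chromosome"
            outputs["chromosome_distribution"] = out / "chromosome_distribution.csv"
            dist_frame.to_csv(outputs["chromosome_distribution"])
            if dist1.n_localized and dist2.n_localized:
                fisher = compare_distributions(
                    dist1, dist2, n_mc=config.mc_iterations, seed=config.seed_fisher
                )
                outputs["fisher"] = out / "distribution_test.json"
                _write_json(
                    {
                        "chi2": fisher.chi2,
                        "p_value": fisher.p_value,
                        "n_mc": fisher.n_mc,
                        "statistic_definition": fisher.statistic_definition,
                        "n_unlocalized_axis1": dist1.n_unlocalized,
                        "n_unlocalized_axis2": dist2.n_unlocalized,
                    },
                    outputs["fisher"],
                )
            hotspots = detect_hotspots(
                {"axis1": all_records.get(AXIS1, []), "axis2": all_records.get(AXIS2, [])},
                annotation,
                config.min_hotspot,
            )
            outputs["hotspots"] = out / "hotspots.json"
            _write_json([h.to_dict() for h in hotspots], outputs["hotspots"])
            if config.fragile and Path(config.fragile).exists():
                catalog = read_fragile_sites(config.fragile)
                overlap = {
                    axis: fragile_overlap(all_records.get(comp, []), annotation, catalog)
                    for axis, comp in (("axis1", AXIS1), ("axis2", AXIS2))
                }
                outputs["fragile_overlap"] = out / "fragile_overlap.json"
                _write_json(overlap, outputs["fragile_overlap"])
            else:
                if config.fragile:
                    log.warning(
                        "fragile-site file %s missing; overlap stage skipped", config.fragile
                    )
        else:
            log.warning("no probe annotation supplied; chromosomal stage skipped")

        stage = "som-clustering"
        som_probes = train_som(
            filtered,
            axis="probes",
            grid=config.probes_grid,
            iterations=config.probes_iterations,
            lr0=config.som_learning_rate,
            seed=config.seed_som,
        )
        som_samples = train_som(
            filtered,
            axis="samples",
            grid=config.samples_grid,
            iterations=config.samples_iterations,
            lr0=config.som_learning_rate,
            seed=config.seed_som,
        )
        outputs["heatmap"] = out / "heatmap.cdt"
        order_and_export(som_probes, som_samples, filtered, path=outputs["heatmap"])
        outputs["som_assignments"] = out / "som_assignments.json"
        _write_json(
            {"probes": som_probes.assignment, "samples": som_samples.assignment},
            outputs["som_assignments"],
        )

        stage = "qpcr"
        if config.ct:
            ct = read_ct_table(config.ct)
            qsheet = (
                read_sample_sheet(config.qpcr_samples) if config.qpcr_samples else sheet
            )
            dct = delta_ct(ct, config.qpcr_reference)
            offsets: dict[str, float] = {}
            if set(dct.data["cohort"].unique()) == {1, 2}:
                dct, offsets = harmonize_cohorts(dct)
            outputs["delta_ct"] = out / "delta_ct.csv"
            dct.data.to_csv(outputs["delta_ct"], index=False)
            outputs["harmonization"] = out / "harmonization_offsets.json"
            _write_json(offsets, outputs["harmonization"])
            rq = relative_quant(dct, qsheet, config.qpcr_baseline)
            outputs["rq"] = out / "relative_quantities.csv"
            rq.to_csv(outputs["rq"], index=False)
            targets = [m for m in ct.mirnas if m != config.qpcr_reference]
            stats = [
                kruskal_wallis_by_class(dct, qsheet, t, config.alpha_qpcr) for t in targets
            ]
            stats_frame = pd.DataFrame(
                {
                    "mirna_id": [s.mirna_id for s in stats],
                    "kruskal_wallis_H": [s.h_statistic for s in stats],
                    "df": [s.df for s in stats],
                    "p_value": [s.p_value for s in stats],
                    "significant": [s.significant for s in stats],
                }
            )
            outputs["qpcr_stats"] = out / "qpcr_stats.csv"
            stats_frame.to_csv(outputs["qpcr_stats"], index=False)

        stage = "consensus"
        if config.studies:
            records = read_study_records(config.studies)
            entries, conflicts = build_consensus(records)
            ranked = rank_consensus(entries, config.min_studies)
            outputs["consensus"] = out / "consensus.csv"
            consensus_table(ranked).to_csv(outputs["consensus"], index=False)
            stats = overlap_stats(records, config.min_studies)
            outputs["consensus_overlap"] = out / "consensus_overlap.json"
            _write_json(
                {
                    d: {
                        "n_consistent": s.n_consistent,
                        "n_total_distinct": s.n_total_distinct,
                        "percent": s.percent,
                    }
                    for d, s in stats.items()
                },
                outputs["consensus_overlap"],
            )
            _write_json(conflicts, out / "consensus_conflicts.json")
            outputs["consensus_conflicts"] = out / "consensus_conflicts.json"
            if inter is not None:
                internal = {p: "up" for p in sets[AXIS1].up + sets[AXIS2].up}
                internal |= {p: "down" for p in sets[AXIS1].down + sets[AXIS2].down}
                outputs["crosscheck"] = out / "consensus_crosscheck.csv"
                crosscheck_internal(entries, internal).to_csv(
                    outputs["crosscheck"], index=False
                )

        stage = "manifest"
        manifest = {
            "mirprofiler_version": __version__,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "pandas_version": pd.__version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seeds": {"som": config.seed_som, "fisher": config.seed_fisher},
            "outputs": sorted(str(p.name) for p in outputs.values()),
        }
        outputs["manifest"] = out / "manifest.json"
        _write_json(manifest, outputs["manifest"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outputs


# ---------------------------------------------------------------------------
# Demo dataset
# ---------------------------------------------------------------------------


def make_demo(seed: int = 0, out_dir: str | Path = "demo") -> tuple[PipelineConfig, dict]:
    """Build a small planted dataset plus a config that runs end-to-end fast.

    500 probes with 72/48/26 planted axis effects, hotspots, fragile sites,
    a two-cohort Ct table and planted multi-study lists. Returns the config
    (also written as config.yaml) and the ground-truth expectations dict.
    """
    from .core_io import write_sample_sheet
    from .synthetic import (
        QpcrSimConfig,
        generate_dataset,
        generate_qpcr,
        planted_axis_design,
        planted_overlap_design,
        write_dataset,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = planted_axis_design(
        n_probes=500,
        n_axis1=72,
        n_axis2=48,
        n_shared=26,
        n_up=(20, 6, 2),
        effect=2.0,
        noise_sd=0.5,
        n_unlocalized=(10, 5),
        fragile_fraction=0.2,
        seed=seed,
    )
    dataset = generate_dataset(cfg)
    qcfg = QpcrSimConfig(
        targets={
            "miR-99a": {"BRCA1-C": -2.0, "BRCA2-C": -2.0},
            "miR-21": {"BRCA1-C": 1.5},
            "let-7b": {"BRCA2-C": -1.5},
        },
        seed=seed,
    )
    ct, qsheet = generate_qpcr(qcfg)
    studies = planted_overlap_design(n_up=30, n_up_multi=8, n_down=30, n_down_multi=8)
    paths = write_dataset(dataset, out, ct_table=ct, study_records=studies)
    qsheet_path = out / "qpcr_samples.csv"
    write_sample_sheet(qsheet, qsheet_path)

    pipeline_config = PipelineConfig(
        matrix=str(paths["matrix"]),
        samples=str(paths["samples"]),
        annotation=str(paths["annotation"]),
        fragile=str(paths["fragile"]),
        ct=str(paths["ct"]),
        qpcr_samples=str(qsheet_path),
        studies=str(paths["studies"]),
        out_dir=str(out / "results"),
        probes_grid=(4, 4),
        samples_grid=(2, 2),
        probes_iterations=4000,
        samples_iterations=1000,
        mc_iterations=20_000,
        seed_som=seed + 1,
        seed_fisher=seed + 1,
    )
    pipeline_config.to_yaml(out / "config.yaml")
    expectations = {
        "n_axis1_de": 72,
        "n_axis2_de": 48,
        "n_shared_de": 26,
        "axis1_truth": dataset.truth.de_axis(AXIS1),
        "axis2_truth": dataset.truth.de_axis(AXIS2),
        "hotspots": dataset.truth.hotspot_loci,
        "unlocalized": dataset.truth.unlocalized,
    }
    (out / "expected_results.json").write_text(
        json.dumps(expectations, indent=1, sort_keys=True)
    )
    return pipeline_config, expectations
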