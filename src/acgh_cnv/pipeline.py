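"""Config-driven end-to-end pipeline.

Stages: simulate (or load) profiles -> normalize -> calibrate on self-self
arrays -> call segments -> collate unique CNVs -> merge CNVRs -> catalog
statistics -> fixation classification -> sample clustering.  Every stage
writes a TSV/BED/JSON artifact plus a run log carrying the seed and the
calibrated threshold, sufficient to re-run exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as aio
from .calling import calibrate_threshold, call_segments, collate_calls
from .normalize import normalize_cohort
from .population import LineCatalog, classify_regions, cluster_samples, occurrence_matrix
from .regions import catalog_stats, merge_to_cnvrs
from .scenario import default_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Options of a full synthetic-cohort run."""

    out_dir: str
    seed: int = 0
    genome_scale: float = 0.05
    spacing_bp: int = 4000
    jitter_fraction: float = 0.2
    noise_sd: float = 0.10
    n_self_self: int = 5
    dye_bias_amplitude: float = 0.05
    span: float = 0.3
    sex_center: bool = False
    grid: list[float] = field(default_factory=lambda: [round(2.0 + 0.5 * i, 1) for i in range(9)])
    min_probes: int = 2
    max_gap_probes: int = 1
    target_false_calls_per_array: float = 1.0
    strict_specific: bool = True
    cluster_distance: str = "jaccard"
    cluster_linkage: str = "average"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    out_dir: Path
    calibration: object
    cnvs: list
    regions: list
    stats: object
    classifications: list
    cluster: object
    truth: list


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the default synthetic scenario end to end, writing artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    probe_map, profiles, truth, self_self = _stage("simulate")(default_cohort)(
        seed=config.seed,
        genome_scale=config.genome_scale,
        spacing_bp=config.spacing_bp,
        jitter_fraction=config.jitter_fraction,
        noise_sd=config.noise_sd,
        n_self_self=config.n_self_self,
        dye_bias_amplitude=config.dye_bias_amplitude,
    )
    aio.write_profiles(out / "profiles_raw.tsv", probe_map, profiles)
    aio.write_line_map(out / "samples.tsv", profiles)
    aio.write_truth(out / "truth_cnvs.tsv", truth)

    normalized = _stage("normalize")(normalize_cohort)(
        profiles, probe_map, span=config.span, per_chromosome_center=config.sex_center
    )
    self_self_norm = _stage("normalize")(normalize_cohort)(
        self_self, probe_map, span=config.span, per_chromosome_center=config.sex_center
    )
    aio.write_profiles(out / "profiles_normalized.tsv", probe_map, normalized)

    calibration = _stage("calibrate")(calibrate_threshold)(
        self_self_norm,
        probe_map,
        grid=config.grid,
        min_probes=config.min_probes,
        max_gap_probes=config.max_gap_probes,
        target_false_calls_per_array=config.target_false_calls_per_array,
    )
    calls = []
    for p in normalized:
        calls.extend(_stage("call")(call_segments)(p, probe_map, calibration))
    aio.write_calls_bed(out / "calls.bed", calls)

    sample_to_line = {p.sample_id: p.line_id for p in profiles}
    line_catalog = LineCatalog(sample_to_line)
    cnvs = _stage("collate")(collate_calls)(calls, sample_to_line)
    aio.write_cnv_table(out / "unique_cnvs.tsv", cnvs, line_catalog.lines)

    regions = _stage("merge")(merge_to_cnvrs)(cnvs)
    aio.write_cnvr_table(out / "cnvrs.tsv", regions, line_catalog.lines)
    aio.write_cnvr_bed(out / "cnvrs.bed", regions)

    calls_per_sample = {p.sample_id: 0 for p in profiles}
    for c in calls:
        calls_per_sample[c.sample_id] += 1
    stats = _stage("stats")(catalog_stats)(
        cnvs,
        regions,
        genome_length_bp=probe_map.genome.total_length,
        calls_per_sample=calls_per_sample,
        sample_to_line=sample_to_line,
    )
    aio.write_stats(out / "stats.json", stats)

    matrix = _stage("classify")(occurrence_matrix)(regions, cnvs, line_catalog)
    classifications = _stage("classify")(classify_regions)(
        matrix, line_catalog, strict_specific=config.strict_specific
    )
    aio.write_classifications(out / "classifications.tsv", classifications)

    cluster = _stage("cluster")(cluster_samples)(
        matrix, distance=config.cluster_distance, linkage=config.cluster_linkage
    )
    (out / "dendrogram.nwk").write_text(cluster.to_newick() + "\n")

    log = {
        "version": __version__,
        "seed": config.seed,
        "n_probes": probe_map.n_probes,
        "n_samples": len(profiles),
        "threshold_multiple": calibration.threshold_multiple,
        "mean_self_self_calls": calibration.mean_self_self_calls,
        "calibration_warning": calibration.warning,
        "min_probes": config.min_probes,
        "max_gap_probes": config.max_gap_probes,
        "span": config.span,
        "n_calls": len(calls),
        "n_unique_cnvs": len(cnvs),
        "n_cnvrs": len(regions),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        out_dir=out,
        calibration=calibration,
        cnvs=cnvs,
        regions=regions,
        stats=stats,
        classifications=classifications,
        cluster=cluster,
        truth=truth,
    )
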