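"""End-to-end orchestration: inputs -> traces -> features -> classes ->
subpopulation profiles -> condition tests -> figures.

The pipeline mirrors the study design: the control condition is
clustered with k-means (k = 4), the clusters are named by activity
boundaries, boundaries re-derived from the control data classify every
condition, and repeated 90-cell subsamples give the per-condition
percentage profiles compared with Kruskal-Wallis. Every stage logs the
parameters it actually used, and the run manifest registers every file
written, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
import traceback
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from . import io as fio
from .population import (
    CLASS_ORDER,
    ActivityClass,
    ClassBoundaries,
    classify_table,
    cluster_features,
    compare_conditions,
    derive_boundaries,
    name_clusters,
    subsample_profiles,
)
from .segmentation import extract_traces, segment_movie_pca
from .synthetic import preset, simulate_population
from .traces import DetectionParams, process_traces

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records which."""


@dataclass
class PipelineConfig:
    """Everything a run needs.

    ``conditions`` maps a condition name to its input: a dict with one of
    ``traces`` (CSV path), ``movie`` (TIFF path) or ``synthetic`` (preset
    name, with optional ``n_cells``). ``control_condition`` names the
    condition whose cells are clustered and whose boundaries classify the
    rest.
    """

    conditions: Mapping[str, Mapping]
    outdir: str
    control_condition: str = "control"
    frame_interval: float = 10.0
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    k: int = 4
    n_restarts: int = 50
    fraction: float = 0.6
    sample_size: int | None = 90
    n_repeats: int = 5
    segmentation_components: int | None = None
    min_area: int = 20
    max_area: int = 2000
    make_figures: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = fio.read_yaml(path)
        det = raw.pop("detection", {})
        return cls(detection=DetectionParams(**det), **raw)


@dataclass
class RunManifest:
    """Record of one run: config snapshot, seeds, counts, files, status."""

    config: dict
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)
    files: list = field(default_factory=list)
    status: str = "ok"
    failed_stage: str | None = None
    error: str | None = None
    tests: dict = field(default_factory=dict)

    def register(self, path) -> str:
        self.files.append(str(path))
        return str(path)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "status": self.status,
            "failed_stage": self.failed_stage,
            "error": self.error,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "tests": self.tests,
            "files": self.files,
        }


def _load_condition(name: str, spec: Mapping, cfg: PipelineConfig, manifest: RunManifest,
                    outdir: Path):
    if "traces" in spec:
        return fio.read_traces(spec["traces"], condition_label=name)
    if "movie" in spec:
        movie = fio.load_movie(spec["movie"], frame_interval=cfg.frame_interval)
        mask = segment_movie_pca(
            movie, n_components=cfg.segmentation_components,
            min_area=cfg.min_area, max_area=cfg.max_area,
        )
        fio.write_mask(outdir / f"mask_{name}.tif", mask,
                       roi_csv=outdir / f"rois_{name}.csv")
        manifest.register(outdir / f"mask_{name}.tif")
        manifest.register(outdir / f"rois_{name}.csv")
        ts = extract_traces(movie, mask)
        ts.condition_label = name
        return ts
    if "synthetic" in spec:
        n_cells = int(spec.get("n_cells", 160))
        cond_seed = (cfg.seed + zlib.crc32(name.encode())) % (2**31)
        sim = simulate_population(
            preset(spec["synthetic"], n_cells=n_cells, seed=cond_seed)
        )
        ts = sim.traces
        ts.condition_label = name
        return ts
    raise PipelineError(f"condition {name!r} specifies no input")


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage; returns the manifest (written even on failure)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest = RunManifest(config={
        "conditions": {k: dict(v) for k, v in cfg.conditions.items()},
        "control_condition": cfg.control_condition,
        "frame_interval": cfg.frame_interval,
        "seed": cfg.seed,
        "detection": vars(cfg.detection).copy(),
        "k": cfg.k, "n_restarts": cfg.n_restarts,
        "fraction": cfg.fraction, "sample_size": cfg.sample_size,
        "n_repeats": cfg.n_repeats,
    })
    stage = "setup"
    try:
        if cfg.control_condition not in cfg.conditions:
            raise PipelineError(
                f"control condition {cfg.control_condition!r} not among conditions"
            )
        stage = "load"
        trace_sets = {
            name: _load_condition(name, spec, cfg, manifest, outdir)
            for name, spec in cfg.conditions.items()
        }
        stage = "process"
        processed = {}
        for name, ts in trace_sets.items():
            pr = process_traces(ts, cfg.detection)
            processed[name] = pr
            manifest.stage_counts[f"cells_{name}"] = ts.n_cells
            fio.write_features(outdir / f"features_{name}.csv", pr.features)
            manifest.register(outdir / f"features_{name}.csv")
            fio.write_spikes(outdir / f"spikes_{name}.csv", pr.spike_trains,
                             ts.frame_interval)
            manifest.register(outdir / f"spikes_{name}.csv")

        stage = "cluster"
        control = processed[cfg.control_condition]
        model = cluster_features(control.features, k=cfg.k, seed=cfg.seed,
                                 n_restarts=cfg.n_restarts)
        naming = name_clusters(model)
        stage = "boundaries"
        boundaries = derive_boundaries(model, naming, features=control.features)
        fio.write_boundaries(outdir / "boundaries.json", boundaries)
        manifest.register(outdir / "boundaries.json")

        stage = "classify"
        cluster_rows = control.features.copy()
        cluster_rows["cluster"] = model.assignments
        cluster_rows["class"] = [naming[c].value for c in model.assignments]
        fio.write_features(outdir / "clusters_control.csv", cluster_rows)
        manifest.register(outdir / "clusters_control.csv")
        features_by_condition = {}
        for name, pr in processed.items():
            feats = pr.features.copy()
            feats["class"] = [c.value for c in classify_table(feats, boundaries)]
            features_by_condition[name] = feats
            fio.write_features(outdir / f"classified_{name}.csv", feats)
            manifest.register(outdir / f"classified_{name}.csv")

        stage = "profiles"
        profiles_by_condition = {}
        for name, pr in processed.items():
            size = cfg.sample_size
            if size is not None and size > len(pr.features):
                size = len(pr.features)
            profiles = subsample_profiles(
                pr.features, boundaries, fraction=cfg.fraction, sample_size=size,
                n_repeats=cfg.n_repeats, seed=cfg.seed, condition_label=name,
            )
            profiles_by_condition[name] = profiles
            fio.write_profiles(outdir / f"profiles_{name}.csv", profiles)
            manifest.register(outdir / f"profiles_{name}.csv")

        stage = "condition_tests"
        if len(profiles_by_condition) >= 2:
            tests = {}
            for cls in CLASS_ORDER:
                h, p = compare_conditions(profiles_by_condition, cls)
                tests[cls.value] = {"H": h, "p": p, "significant": p < 0.05}
            manifest.tests = tests
            fio.write_json(outdir / "condition_tests.json", tests)
            manifest.register(outdir / "condition_tests.json")

        if cfg.make_figures:
            stage = "figures"
            from .figures import render_figures

            results = {
                "frame_interval": cfg.frame_interval,
                "spike_trains_by_condition": {n: p.spike_trains for n, p in processed.items()},
                "dff_by_condition": {n: p.normalized.dff for n, p in processed.items()},
                "features_by_condition": features_by_condition,
                "profiles_by_condition": profiles_by_condition,
                "box_samples": {
                    "spike_count": {n: f["spike_count"].to_numpy()
                                    for n, f in features_by_condition.items()},
                    "ca_max": {n: f["ca_max"].to_numpy()
                               for n, f in features_by_condition.items()},
                },
            }
            for f in render_figures(results, outdir):
                manifest.register(f)
    except Exception as exc:  # record the failing stage, then re-raise
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed at stage %s\n%s", stage, traceback.format_exc())
        fio.write_json(outdir / "manifest.json", manifest.to_dict())
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest.register(outdir / "manifest.json")
    fio.write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest
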