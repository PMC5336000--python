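"""End-to-end orchestration: simulate -> fuse -> evaluate -> rank.

A :class:`RunConfig` fully determines a run; re-executing a saved config
with the same seed reproduces every numeric output bit-identically.  The
run directory holds fused rasters (TIFF), quality reports (JSON), block
quality maps, a Borda rank table (CSV) and a manifest listing every file
written.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .raster import (MultispectralImage, PanchromaticImage, load_ms, load_pan,
                     upsample_ms, save_ms, save_pan)
from .fusion import fuse, ALGORITHMS, FusedImage, DEFAULT_WINDOW_BY_ARCHETYPE
from .metrics import evaluate, quality_map, DEFAULT_H_OVER_L
from .ranking import IndexTable, aggregate, rank_report, DEFAULT_GROUPINGS
from .synthetic import SceneConfig, paint_truth_scene, degrade_to_pair

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("pansharp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    # scene source: either paths ...
    ms_path: str | None = None
    pan_path: str | None = None
    # ... or a synthetic scene
    scene: dict | None = None
    ratio: int = 4
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    algorithm_params: dict[str, dict] = field(default_factory=dict)
    subsets: list[str] = field(default_factory=lambda: ["all", "in_pan", "out_pan"])
    compare_at: str = "pan"
    fc_block: int = 8
    qmap_block: int = 64
    pan_adjust: str = "matched"
    h_over_l: float = DEFAULT_H_OVER_L
    groupings: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GROUPINGS.items()})
    tie_policy: str = "high"
    out_dir: str = "pansharp_run"
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_scene(config: RunConfig) -> tuple[MultispectralImage, PanchromaticImage]:
    if config.scene is not None:
        sc = dict(config.scene)
        sc.setdefault("seed", config.seed)
        scene_cfg = SceneConfig(**sc)
        truth = paint_truth_scene(scene_cfg)
        return degrade_to_pair(truth, scene_cfg)
    if config.ms_path is None or config.pan_path is None:
        raise PipelineError("load", "config needs either scene or ms_path+pan_path")
    ms = load_ms(config.ms_path)
    pan = load_pan(config.pan_path, ratio=config.ratio)
    return ms, pan


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow and return the manifest (also written to
    ``manifest.json`` in the run directory)."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": asdict(config), "files": [], "stages": {},
                      "complete": False}

    def _write(name: str, writer) -> str:
        path = os.path.join(config.out_dir, name)
        writer(path)
        manifest["files"].append(name)
        return path

    def _stage(name: str):
        manifest["stages"][name] = round(time.time() - t0, 3)
        log.info("stage %s done at %.2fs", name, time.time() - t0)

    try:
        ms, pan = _load_scene(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-labelled with the stage
        raise PipelineError("load", str(exc)) from exc
    _write("ms.tif", lambda p: save_ms(p, ms))
    _write("pan.tif", lambda p: save_pan(p, pan))
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    manifest["files"].append("config.yaml")
    _stage("load")

    try:
        ms_up = upsample_ms(ms, pan.ratio)
    except Exception as exc:
        raise PipelineError("upsample", str(exc)) from exc
    _stage("upsample")

    fused_products: dict[str, FusedImage] = {}
    for alg in config.algorithms:
        params = dict(config.algorithm_params.get(alg, {}))
        try:
            fused_products[alg] = fuse(alg, ms_up, pan, **params)
        except Exception as exc:
            raise PipelineError("fuse", f"algorithm {alg!r}: {exc}") from exc
        _write(f"fused_{alg}.tif",
               lambda p, a=alg: save_ms(p, fused_products[a].as_ms()))
    _stage("fuse")

    all_reports: dict[str, dict] = {}
    for alg, fused in fused_products.items():
        try:
            reports = evaluate(ms, pan, fused, subsets=list(config.subsets),
                               h_over_l=config.h_over_l, fc_block=config.fc_block,
                               pan_adjust=config.pan_adjust,
                               compare_at=config.compare_at)
        except Exception as exc:
            raise PipelineError("evaluate", f"algorithm {alg!r}: {exc}") from exc
        all_reports[alg] = reports
        for subset, rep in reports.items():
            _write(f"report_{alg}_{subset}.json", rep.to_json)
    _stage("evaluate")

    try:
        table = IndexTable.from_reports(
            {alg: reps["all"] if "all" in reps else next(iter(reps.values()))
             for alg, reps in all_reports.items()})
        result = aggregate(table, groupings=config.groupings,
                           tie_policy=config.tie_policy)
        ranks = rank_report(result)
    except Exception as exc:
        raise PipelineError("rank", str(exc)) from exc

    rows = []
    for alg in table.items:
        row = {"algorithm": alg, **table.values[alg]}
        for gname in result.scores:
            row[f"borda_{gname}"] = result.scores[gname][alg]
        rows.append(row)
    rank_df = pd.DataFrame(rows).sort_values("borda_global", ascending=False)
    _write("ranks.csv", lambda p: rank_df.to_csv(p, index=False))
    manifest["borda"] = result.scores
    manifest["rank_order"] = ranks
    _stage("rank")

    # block quality maps for the globally best algorithm
    best = ranks["global"][0][0] if "global" in ranks else table.items[0]
    manifest["best_algorithm"] = best
    try:
        qm_ref = upsample_ms(ms, pan.ratio)
        block = min(config.qmap_block, max(8, min(qm_ref.pixels.shape[:2])))
        qm = quality_map(qm_ref, fused_products[best], block=block)
        _write(f"qmap_{best}.json", lambda p: _dump_qmap(p, qm))
    except Exception as exc:
        raise PipelineError("quality_map", str(exc)) from exc
    _stage("quality_map")

    manifest["complete"] = True
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["files"].append("manifest.json")
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _dump_qmap(path, qm) -> None:
    with open(path, "w") as fh:
        json.dump({"block_size": qm.block_size,
                   "values": np.round(qm.values, 6).tolist()}, fh)
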