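"""End-to-end orchestration: semantic maps in, pick target out.

Phase 1 (semantic segmentation) is a pluggable input — any segmenter's label
map, or ground-truth labels — so the pipeline here covers instance clustering
(phase 2) and obstacle perception + target selection (phase 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .instance_clustering import (
    ClusteringConfig,
    adaptive_kmeans,
    extract_fruit_pixels,
    instances_from_state,
)
from .obstacle_perception import PerceptionConfig, assess_pickability
from .scene_io import DepthMap, RgbImage, SemanticMap
from .selection_eval import PickTarget, select_target

logger = logging.getLogger("fruitpick")


@dataclass
class PipelineConfig:
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    perception: PerceptionConfig = field(default_factory=PerceptionConfig)
    selection_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        # one top-level seed drives every stage unless overridden explicitly
        self.clustering.seed = self.clustering.seed or self.seed
        self.perception.seed = self.perception.seed or self.seed

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "clustering": {
                "alpha": self.clustering.alpha,
                "k0": self.clustering.k0,
                "merge_dist": self.clustering.merge_dist,
                "downsample_factor": self.clustering.downsample_factor,
                "max_iter": self.clustering.max_iter,
                "depth_scale": self.clustering.depth_scale,
                "seed": self.clustering.seed,
            },
            "perception": {
                "connectivity": self.perception.connectivity,
                "min_area": self.perception.min_area,
                "n_samples": self.perception.n_samples,
                "min_class_pixels": self.perception.min_class_pixels,
                "blocking_classes": sorted(self.perception.blocking_classes),
                "seed": self.perception.seed,
            },
            "selection_weights": list(self.selection_weights),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        clu = data.get("clustering", {})
        per = dict(data.get("perception", {}))
        if "blocking_classes" in per:
            per["blocking_classes"] = frozenset(per["blocking_classes"])
        return cls(
            clustering=ClusteringConfig(**clu),
            perception=PerceptionConfig(**per),
            selection_weights=tuple(data.get("selection_weights", (0.5, 0.5))),
            seed=int(data.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    instances: list
    reports: list
    target: Optional[PickTarget]


def run_pipeline(
    sem: SemanticMap,
    depth: DepthMap,
    rgb: RgbImage,
    cfg: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """extract → adaptive K-means → instances → pickability → selection."""
    if cfg is None:
        cfg = PipelineConfig()
    if not (sem.shape == depth.shape == rgb.shape):
        raise ValueError(
            f"misaligned inputs: labels {sem.shape}, depth {depth.shape}, "
            f"rgb {rgb.shape}"
        )
    samples = extract_fruit_pixels(sem, depth, cfg.clustering)
    logger.info("extracted %d working-resolution fruit samples", len(samples))
    if len(samples) == 0:
        return PipelineResult(instances=[], reports=[], target=None)
    state = adaptive_kmeans(samples, cfg.clustering)
    logger.info("adaptive K-means settled at K=%d (loss %.1f)", state.K, state.loss)
    instances = instances_from_state(state, sem, depth, cfg.clustering)
    reports = [
        assess_pickability(inst, sem, rgb, cfg.perception) for inst in instances
    ]
    for rep in reports:
        logger.info(
            "instance %d: regions=%d occluded=%s classes=%s pickable=%s",
            rep.instance_id,
            rep.n_regions,
            rep.occluded,
            sorted(rep.obstacle_classes),
            rep.pickable,
        )
    target = select_target(reports, instances, depth, cfg.selection_weights)
    if target is None:
        logger.info("no pickable target in this scene")
    else:
        logger.info(
            "target: instance %d center=(%.1f, %.1f) r=%.1f depth=%.0f mm score=%.3f",
            target.instance_id,
            target.center[0],
            target.center[1],
            target.radius,
            target.mean_depth,
            target.score,
        )
    return PipelineResult(instances=instances, reports=reports, target=target)
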