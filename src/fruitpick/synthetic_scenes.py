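"""Deterministic synthetic tomato scenes with exact ground truth.

A scene is a pixel-aligned triplet (RGB, depth in mm, semantic labels) plus
ground truth for every fruit and obstacle.  Mature fruits are disks at
distinct depths; occluders (full-height stems, thin near-horizontal wires,
short oblique branch/petiole segments, green leaf bands) are painted over
their fruit so the visible mature mask genuinely splits, which is the
condition the blind-spot perception stage keys on.  Leaves follow the
empirical annotation policy by default: green in RGB but labeled background,
so the Otsu excess-green fallback is actually exercised; a `leaf`-labeled
variant is available for synthetic-style ground truth.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .scene_io import (
    ClassPalette,
    DepthMap,
    RgbImage,
    SemanticMap,
    write_depth_png,
    write_label_png,
    write_rgb_png,
)

OCCLUDER_CHOICES = ("none", "stem", "wire", "branch_petiole", "leaf")

BG_RGB = (45, 35, 25)
MATURE_RGB = (205, 40, 35)
STEM_RGB = (70, 95, 60)
WIRE_RGB = (180, 180, 185)
BRANCH_RGB = (95, 70, 40)
LEAF_RGB = (60, 170, 60)


@dataclass
class SceneSpec:
    """Study conditions of the generator (ranges are inclusive)."""

    size: tuple[int, int] = (600, 800)
    n_fruits: tuple[int, int] = (1, 5)
    fruit_radius: tuple[int, int] = (24, 48)
    fruit_depth: tuple[int, int] = (400, 1200)  # mm
    min_separation: float = 150.0  # px between fruit centers
    depth_gap: float = 100.0  # mm between fruit depth bands
    n_stems: tuple[int, int] = (0, 2)  # background clutter, non-occluding
    n_wires: tuple[int, int] = (0, 2)
    n_branches: tuple[int, int] = (0, 2)
    n_leaf_blobs: tuple[int, int] = (0, 3)
    stem_width: tuple[int, int] = (2, 6)
    wire_width: tuple[int, int] = (1, 2)
    branch_width: tuple[int, int] = (2, 5)
    leaf_band_width: tuple[int, int] = (10, 16)
    occlusion_plan: Optional[tuple[str, ...]] = None  # per fruit; None = random
    depth_noise_sigma: float = 5.0  # mm
    background_depth: int = 0  # mm; 0 = invalid (beyond reliable stereo range)
    clutter_depth: int = 1500  # mm, for background stems/wires/leaf blobs
    occluder_standoff: int = 150  # mm closer than the occluded fruit
    edge_dropout_px: int = 2  # invalid-depth band at depth discontinuities
    protect_margin: int = 20  # px dilation shielding other fruits
    leaf_label_mode: str = "background"  # or "leaf"
    max_retries: int = 50

    def __post_init__(self) -> None:
        for lo, hi in (
            self.n_fruits,
            self.fruit_radius,
            self.fruit_depth,
            self.stem_width,
            self.wire_width,
            self.branch_width,
        ):
            if hi < lo:
                raise ValueError("ranges must be non-empty (lo <= hi)")
        if self.leaf_label_mode not in ("background", "leaf"):
            raise ValueError("leaf_label_mode must be 'background' or 'leaf'")

    @property
    def palette(self) -> ClassPalette:
        if self.leaf_label_mode == "leaf":
            return ClassPalette.with_leaf()
        return ClassPalette.default()


@dataclass
class FruitGroundTruth:
    center: tuple[float, float]
    radius: float
    depth: float  # mm, noise-free band value
    occluder: str  # one of OCCLUDER_CHOICES
    pickable: bool
    full_mask: np.ndarray = field(repr=False)
    visible_mask: np.ndarray = field(repr=False)


@dataclass
class ObstacleGroundTruth:
    class_name: str
    pixels: np.ndarray = field(repr=False)  # (N, 2) final visible pixels


@dataclass
class SceneGroundTruth:
    fruits: list[FruitGroundTruth]
    obstacles: list[ObstacleGroundTruth]


class _Canvas:
    """Label/RGB/depth arrays plus an owner map for exact ground truth."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        h, w = spec.size
        self.labels = np.zeros((h, w), dtype=np.uint8)
        self.rgb = np.empty((h, w, 3), dtype=np.uint8)
        self.rgb[:] = BG_RGB
        if spec.background_depth > 0:
            noise = rng.normal(0.0, spec.depth_noise_sigma, (h, w))
            self.depth = np.clip(
                np.rint(spec.background_depth + noise), 1, 65535
            ).astype(np.uint16)
        else:  # depth dropout: far background returns no measurement
            self.depth = np.zeros((h, w), dtype=np.uint16)
        self.owner = np.full((h, w), -1, dtype=np.int32)
        self.rr, self.cc = np.mgrid[0:h, 0:w]
        self.sigma = spec.depth_noise_sigma

    def paint(self, mask, class_id, color, depth_mm, owner_idx, rng):
        self.labels[mask] = class_id
        self.rgb[mask] = color
        if depth_mm is not None:
            n = int(mask.sum())
            vals = depth_mm + rng.normal(0.0, self.sigma, n)
            self.depth[mask] = np.clip(np.rint(vals), 1, 65535).astype(np.uint16)
        self.owner[mask] = owner_idx


def _disk(canvas: _Canvas, center, radius) -> np.ndarray:
    return (canvas.rr - center[0]) ** 2 + (canvas.cc - center[1]) ** 2 <= radius**2


def _band(canvas: _Canvas, point, angle, width, length=None) -> np.ndarray:
    """Thick line (optionally finite segment) through `point` at `angle`."""
    dy, dx = np.sin(angle), np.cos(angle)
    pr = canvas.rr - point[0]
    pc = canvas.cc - point[1]
    dist = np.abs(pr * dx - pc * dy)  # perpendicular distance to the line
    mask = dist <= width / 2.0
    if length is not None:
        proj = pr * dy + pc * dx
        mask &= np.abs(proj) <= length / 2.0
    return mask


def _place_fruits(spec: SceneSpec, rng, n: int):
    h, w = spec.size
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n):
        radius = float(rng.integers(spec.fruit_radius[0], spec.fruit_radius[1] + 1))
        for _try in range(300):
            margin = radius + 5
            r = float(rng.uniform(margin, h - margin))
            c = float(rng.uniform(margin, w - margin))
            if all(
                np.hypot(r - r2, c - c2) >= spec.min_separation
                for r2, c2 in centers
            ):
                centers.append((r, c))
                radii.append(radius)
                break
        else:
            return None
    return centers, radii


def _sample_depths(spec: SceneSpec, rng, n: int):
    lo, hi = spec.fruit_depth
    depths: list[float] = []
    for _ in range(n):
        for _try in range(300):
            d = float(rng.uniform(lo, hi))
            if all(abs(d - d2) >= spec.depth_gap for d2 in depths):
                depths.append(d)
                break
        else:
            return None
    return depths


def _occluder_mask(canvas, spec, rng, kind, center, radius):
    h, w = spec.size
    if kind == "stem":
        width = int(rng.integers(spec.stem_width[0], spec.stem_width[1] + 1))
        col = center[1] + rng.uniform(-radius / 3, radius / 3)
        return np.abs(canvas.cc - col) <= width / 2.0
    if kind == "wire":
        width = int(rng.integers(spec.wire_width[0], spec.wire_width[1] + 1))
        row = center[0] + rng.uniform(-radius / 3, radius / 3)
        slope = rng.uniform(-0.03, 0.03)
        mid = (canvas.cc - center[1]) * slope + row
        return np.abs(canvas.rr - mid) <= width / 2.0
    if kind == "branch_petiole":
        width = int(rng.integers(spec.branch_width[0], spec.branch_width[1] + 1))
        angle = np.deg2rad(rng.uniform(25, 65)) * rng.choice([-1.0, 1.0])
        return _band(canvas, center, angle, width, length=2 * (radius + 30))
    if kind == "leaf":
        width = int(rng.integers(spec.leaf_band_width[0], spec.leaf_band_width[1] + 1))
        angle = np.deg2rad(rng.uniform(0, 180))
        return _band(canvas, center, angle, width, length=2 * (radius + 30))
    raise ValueError(f"unknown occluder kind {kind!r}")


def _attempt_scene(spec: SceneSpec, rng: np.random.Generator):
    palette = spec.palette
    n = int(rng.integers(spec.n_fruits[0], spec.n_fruits[1] + 1))
    if spec.occlusion_plan is not None:
        if len(spec.occlusion_plan) < n:
            n = len(spec.occlusion_plan)
        plan = tuple(spec.occlusion_plan[:n])
    else:
        plan = tuple(str(rng.choice(OCCLUDER_CHOICES)) for _ in range(n))
    for kind in plan:
        if kind not in OCCLUDER_CHOICES:
            raise ValueError(f"unknown occluder in plan: {kind!r}")

    placed = _place_fruits(spec, rng, n)
    if placed is None:
        return None
    centers, radii = placed
    depths = _sample_depths(spec, rng, n)
    if depths is None:
        return None

    canvas = _Canvas(spec, rng)
    mature_id = palette.id_of("mature_fruit")
    leaf_id = (
        palette.id_of("leaf") if spec.leaf_label_mode == "leaf" else palette.id_of("background")
    )
    obstacles: list[tuple[str, int]] = []  # (class, owner idx); fruits own 0..n-1
    next_owner = n

    # background clutter, drawn first so fruits paint over it
    clutter_depth = spec.clutter_depth
    h, w = spec.size
    for _ in range(int(rng.integers(spec.n_stems[0], spec.n_stems[1] + 1))):
        width = int(rng.integers(spec.stem_width[0], spec.stem_width[1] + 1))
        col = rng.uniform(0, w)
        mask = np.abs(canvas.cc - col) <= width / 2.0
        canvas.paint(mask, palette.id_of("stem"), STEM_RGB, clutter_depth, next_owner, rng)
        obstacles.append(("stem", next_owner))
        next_owner += 1
    for _ in range(int(rng.integers(spec.n_wires[0], spec.n_wires[1] + 1))):
        width = int(rng.integers(spec.wire_width[0], spec.wire_width[1] + 1))
        row = rng.uniform(0, h)
        slope = rng.uniform(-0.03, 0.03)
        mask = np.abs(canvas.rr - (row + slope * canvas.cc)) <= width / 2.0
        canvas.paint(mask, palette.id_of("wire"), WIRE_RGB, clutter_depth, next_owner, rng)
        obstacles.append(("wire", next_owner))
        next_owner += 1
    for _ in range(int(rng.integers(spec.n_branches[0], spec.n_branches[1] + 1))):
        width = int(rng.integers(spec.branch_width[0], spec.branch_width[1] + 1))
        pt = (rng.uniform(0, h), rng.uniform(0, w))
        angle = np.deg2rad(rng.uniform(0, 180))
        mask = _band(canvas, pt, angle, width, length=rng.uniform(80, 160))
        canvas.paint(
            mask, palette.id_of("branch_petiole"), BRANCH_RGB, clutter_depth, next_owner, rng
        )
        obstacles.append(("branch_petiole", next_owner))
        next_owner += 1
    for _ in range(int(rng.integers(spec.n_leaf_blobs[0], spec.n_leaf_blobs[1] + 1))):
        ctr = (rng.uniform(0, h), rng.uniform(0, w))
        a, b = rng.uniform(25, 60), rng.uniform(25, 60)
        theta = rng.uniform(0, np.pi)
        pr = canvas.rr - ctr[0]
        pc = canvas.cc - ctr[1]
        u = pr * np.cos(theta) + pc * np.sin(theta)
        v = -pr * np.sin(theta) + pc * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        canvas.paint(mask, leaf_id, LEAF_RGB, clutter_depth, next_owner, rng)
        obstacles.append(("leaf", next_owner))
        next_owner += 1

    # fruits
    fruit_disks = []
    for i in range(n):
        disk = _disk(canvas, centers[i], radii[i])
        fruit_disks.append(disk)
        jitter = rng.integers(-15, 16, size=3)
        color = tuple(int(np.clip(v + j, 0, 255)) for v, j in zip(MATURE_RGB, jitter))
        canvas.paint(disk, mature_id, color, depths[i], i, rng)

    # planned occluders, shielded away from every other fruit
    occluder_class = {
        "stem": ("stem", STEM_RGB),
        "wire": ("wire", WIRE_RGB),
        "branch_petiole": ("branch_petiole", BRANCH_RGB),
        "leaf": (None, LEAF_RGB),  # labeled per leaf_label_mode
    }
    for i in range(n):
        kind = plan[i]
        if kind == "none":
            continue
        geom = _occluder_mask(canvas, spec, rng, kind, centers[i], radii[i])
        for j in range(n):
            if j == i:
                continue
            shield = _disk(canvas, centers[j], radii[j] + spec.protect_margin)
            geom &= ~shield
        cname, color = occluder_class[kind]
        cid = leaf_id if kind == "leaf" else palette.id_of(cname)
        depth_mm = max(depths[i] - spec.occluder_standoff, 50.0)
        canvas.paint(geom, cid, color, depth_mm, next_owner, rng)
        obstacles.append((kind, next_owner))
        next_owner += 1

    # occlusion-shadow dropout: stereo depth is unreliable at object borders,
    # so invalidate depth in a small band around every ownership boundary
    if spec.edge_dropout_px > 0:
        from scipy.ndimage import maximum_filter, minimum_filter

        size = 2 * spec.edge_dropout_px + 1
        edges = maximum_filter(canvas.owner, size=size) != minimum_filter(
            canvas.owner, size=size
        )
        canvas.depth[edges] = 0

    # ground truth + split verification
    from .obstacle_perception import connected_regions

    fruits: list[FruitGroundTruth] = []
    for i in range(n):
        visible = canvas.owner == i
        if plan[i] != "none":
            regions = connected_regions(visible, connectivity=8, min_area=20)
            if len(regions) < 2:
                return None  # occluder failed to split: retry the scene
        else:
            if not visible.any():
                return None
        fruits.append(
            FruitGroundTruth(
                center=centers[i],
                radius=radii[i],
                depth=depths[i],
                occluder=plan[i],
                pickable=plan[i] in ("none", "leaf"),
                full_mask=fruit_disks[i],
                visible_mask=visible,
            )
        )
    obstacle_gt = [
        ObstacleGroundTruth(class_name=cname, pixels=np.argwhere(canvas.owner == idx))
        for cname, idx in obstacles
    ]
    return (
        RgbImage(canvas.rgb),
        DepthMap(canvas.depth),
        SemanticMap(canvas.labels),
        SceneGroundTruth(fruits=fruits, obstacles=obstacle_gt),
    )


def generate_scene(spec: SceneSpec, seed: int):
    """Deterministic (RgbImage, DepthMap, SemanticMap, SceneGroundTruth).

    Placement or splitting failures retry with a fresh sub-stream, up to
    spec.max_retries, then raise.
    """
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng([seed, attempt])
        result = _attempt_scene(spec, rng)
        if result is not None:
            return result
    raise RuntimeError(
        f"could not generate a valid scene for seed {seed} "
        f"after {spec.max_retries} attempts"
    )


def fixture_scene():
    """The canonical two-fruit demo scene: one clear fruit, one stem-split.

    Only the clear fruit is pickable, so the pipeline should select it.
    """
    spec = SceneSpec(
        n_fruits=(2, 2),
        fruit_radius=(40, 48),
        occlusion_plan=("none", "stem"),
        min_separation=250.0,
        n_stems=(1, 1),
        n_wires=(1, 1),
        n_branches=(0, 0),
        n_leaf_blobs=(1, 1),
    )
    return generate_scene(spec, seed=7)


def generate_feature_tensor(
    C: int, H: int, W: int, n_lines: int = 0, seed: int = 0
) -> np.ndarray:
    """Low-amplitude noise plus full-length high-amplitude axis-aligned lines.

    Emulates a feature map over a scene with slender structures: strong shape
    priors (whole rows/columns light up) over weak appearance noise.
    """
    rng = np.random.default_rng(seed)
    F = rng.normal(0.0, 0.1, (C, H, W))
    for _ in range(n_lines):
        if rng.random() < 0.5:
            F[:, int(rng.integers(H)), :] += 3.0
        else:
            F[:, :, int(rng.integers(W))] += 3.0
    return F


def batch_generate(spec: SceneSpec, n: int, seed: int, out_dir: str | Path) -> dict:
    """Write n scene triplets plus a JSON manifest of their ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    palette = spec.palette
    entries = []
    for i in range(n):
        rgb, depth, sem, gt = generate_scene(spec, seed + i)
        stem = f"scene_{i:04d}"
        write_rgb_png(rgb, out / f"{stem}_rgb.png")
        write_depth_png(depth, out / f"{stem}_depth.png")
        write_label_png(sem, palette, out / f"{stem}_labels.png")
        entries.append(
            {
                "id": stem,
                "seed": seed + i,
                "files": {
                    "rgb": f"{stem}_rgb.png",
                    "depth": f"{stem}_depth.png",
                    "labels": f"{stem}_labels.png",
                },
                "fruits": [
                    {
                        "center": [f.center[0], f.center[1]],
                        "radius": f.radius,
                        "depth_mm": f.depth,
                        "occluder": f.occluder,
                        "pickable": f.pickable,
                    }
                    for f in gt.fruits
                ],
            }
        )
    manifest = {"n_scenes": n, "seed": seed, "scenes": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
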