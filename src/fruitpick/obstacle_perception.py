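"""Blind-spot obstacle perception and pickability judgment.

A fruit instance that is a single connected region is unobstructed.  When an
occluder splits it, the occluder must lie between the visible parts, so for
every pair of disconnected regions we span "blind spot" quadrilaterals between
two random points of each region and look up the semantic classes inside.
Stems, wires and branches/petioles offer strong mechanical resistance, so any
of them in a blind spot vetoes picking; leaves do not.  Blind spots containing
only background are resolved by an Otsu threshold on the excess-green index
ExG = 2g - r - b of the scene's background pixels: mostly-green spots are
leaves (pickable), the rest stay unknown (pickable, conservatively reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional

import numpy as np
from skimage.measure import label as cc_label

from .scene_io import RgbImage, SemanticMap, polygon_mask

BLOCKING_CLASSES = frozenset({"stem", "wire", "branch_petiole"})

# semantic classes looked up inside a blind spot (everything but background/cut)
LOOKUP_CLASSES = (
    "mature_fruit",
    "immature_fruit",
    "peduncle",
    "stem",
    "branch_petiole",
    "wire",
    "leaf",
)


@dataclass
class InstanceMask:
    instance_id: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConnectedRegion:
    region_id: int
    pixels: np.ndarray  # (N, 2) int, row-major scan order
    area: int

    @property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


@dataclass
class BlindSpot:
    vertices: np.ndarray  # (4, 2) float (row, col), angularly ordered
    region_pair: tuple[int, int]
    pixels: np.ndarray  # (M, 2) int: rasterized quad minus instance pixels
    detected_classes: set = field(default_factory=set)


@dataclass
class OcclusionReport:
    instance_id: int
    n_regions: int
    blind_spots: list
    obstacle_classes: set
    occluded: bool
    pickable: bool


@dataclass
class PerceptionConfig:
    connectivity: int = 8
    min_area: int = 20
    n_samples: int = 10
    min_class_pixels: int = 3
    blocking_classes: FrozenSet[str] = BLOCKING_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def connected_regions(
    mask: np.ndarray, connectivity: int = 8, min_area: int = 20
) -> list[ConnectedRegion]:
    """Maximal connected components, small ones discarded as noise.

    Region ids follow raster scan order of each component's first pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    lab = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    regions = []
    rid = 0
    for comp in range(1, lab.max() + 1):
        pixels = np.argwhere(lab == comp)
        if len(pixels) < min_area:
            continue
        regions.append(ConnectedRegion(region_id=rid, pixels=pixels, area=len(pixels)))
        rid += 1
    return regions


def rasterize_quad(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Pixel centers inside or on the quadrilateral (even-odd rule), clipped."""
    return np.argwhere(polygon_mask(vertices, shape))


def _quad_support(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Quad fill plus its Bresenham outline.

    A near-degenerate quad (four nearly collinear points) can be thinner than
    a pixel along most of its length, so the even-odd fill alone may keep only
    pixels near the corners; the outline guarantees the support stays
    connected between the two sampled regions.
    """
    from skimage.draw import line as sk_line

    mask = polygon_mask(vertices, shape)
    v = np.rint(vertices).astype(int)
    for i in range(len(v)):
        rr, cc = sk_line(v[i][0], v[i][1], v[(i + 1) % len(v)][0], v[(i + 1) % len(v)][1])
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def _order_by_angle(points: np.ndarray) -> np.ndarray:
    """Order 4 points by angle around their centroid -> a simple polygon."""
    ctr = points.mean(axis=0)
    ang = np.arctan2(points[:, 0] - ctr[0], points[:, 1] - ctr[1])
    return points[np.argsort(ang, kind="stable")]


def _poly_area(pts: np.ndarray) -> float:
    x = pts[:, 1]
    y = pts[:, 0]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sample_blind_spots(
    region_a: ConnectedRegion,
    region_b: ConnectedRegion,
    n_samples: int,
    seed,
    shape: tuple[int, int],
    exclude_mask: Optional[np.ndarray] = None,
    max_redraws: int = 20,
) -> list[BlindSpot]:
    """Seeded random quadrilaterals spanning two disconnected regions.

    Each draw takes two points from each region (a single-pixel region repeats
    its point and the quad degenerates to a triangle), orders the four by
    angle around their centroid so the polygon is simple, and redraws a
    bounded number of times if the polygon is degenerate (near-zero area).
    Quads are drawn sequentially from one RNG stream, so the first m spots for
    n_samples = m are a prefix of those for any larger n_samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spots: list[BlindSpot] = []
    for _ in range(n_samples):
        verts = None
        for _try in range(max_redraws):
            pa = region_a.pixels[rng.choice(len(region_a.pixels), 2, replace=len(region_a.pixels) < 2)]
            pb = region_b.pixels[rng.choice(len(region_b.pixels), 2, replace=len(region_b.pixels) < 2)]
            cand = _order_by_angle(np.vstack([pa, pb]).astype(float))
            if _poly_area(cand) > 0.5:
                verts = cand
                break
            verts = cand  # keep last degenerate draw as fallback
        support = _quad_support(verts, shape)
        if exclude_mask is not None:
            support &= ~exclude_mask
        pix = np.argwhere(support)
        spots.append(
            BlindSpot(
                vertices=verts,
                region_pair=(region_a.region_id, region_b.region_id),
                pixels=pix,
            )
        )
    return spots


def otsu_threshold(values) -> float:
    """Between-class-variance-maximizing threshold over the value histogram.

    Values <= threshold fall in the low class.  Ties take the smallest
    maximizer; constant input has no split and raises.
    """
    v = np.asarray(values, dtype=float).ravel()
    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("cannot threshold constant values")
    w = counts / counts.sum()
    mu = uniq
    cum_w = np.cumsum(w)[:-1]  # P(low) for threshold = uniq[i], i < len-1
    cum_mu = np.cumsum(w * mu)[:-1]
    total_mu = (w * mu).sum()
    mu0 = cum_mu / cum_w
    mu1 = (total_mu - cum_mu) / (1 - cum_w)
    sigma_b = cum_w * (1 - cum_w) * (mu0 - mu1) ** 2
    return float(uniq[int(np.argmax(sigma_b))])


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """ExG = 2g - r - b vegetation index (int arithmetic, range [-510, 510])."""
    px = np.asarray(rgb, dtype=np.int32)
    return 2 * px[..., 1] - px[..., 0] - px[..., 2]


def classify_blind_spot(
    spot: BlindSpot,
    sem: SemanticMap,
    rgb: RgbImage,
    instance: InstanceMask,
    palette_names: tuple[str, ...],
    min_class_pixels: int = 3,
    background_id: int = 0,
) -> set[str]:
    """Semantic-class lookup inside the blind spot, with the Otsu leaf fallback.

    Pixels of the instance itself are ignored.  Any non-background class
    covering >= min_class_pixels of the spot is reported.  If only background
    remains, the Otsu/ExG vegetation test over the scene's background pixels
    decides between {leaf} and {unknown}.
    """
    pix = spot.pixels
    if len(pix):
        keep = ~instance.mask[pix[:, 0], pix[:, 1]]
        pix = pix[keep]
    if len(pix) == 0:
        spot.detected_classes = {"unknown"}
        return spot.detected_classes
    labels = sem.labels[pix[:, 0], pix[:, 1]]
    found: set[str] = set()
    for name in LOOKUP_CLASSES:
        if name not in palette_names:
            continue
        cid = palette_names.index(name)
        if int((labels == cid).sum()) >= min_class_pixels:
            found.add(name)
    if found:
        spot.detected_classes = found
        return found
    # only background (or sub-threshold noise) in the spot: leaf vs unknown
    bg_spot = pix[labels == background_id]
    if len(bg_spot) == 0:
        spot.detected_classes = {"unknown"}
        return spot.detected_classes
    bg_mask = sem.labels == background_id
    exg_all = excess_green(rgb.pixels)[bg_mask]
    try:
        thr = otsu_threshold(exg_all)
    except ValueError:  # constant-color background, nothing green to find
        spot.detected_classes = {"unknown"}
        return spot.detected_classes
    exg_spot = excess_green(rgb.pixels[bg_spot[:, 0], bg_spot[:, 1]])
    if (exg_spot > thr).mean() > 0.5:
        spot.detected_classes = {"leaf"}
    else:
        spot.detected_classes = {"unknown"}
    return spot.detected_classes


def assess_pickability(
    instance: InstanceMask,
    sem: SemanticMap,
    rgb: RgbImage,
    cfg: Optional[PerceptionConfig] = None,
    palette_names: tuple[str, ...] = None,
) -> OcclusionReport:
    """Full per-instance occlusion analysis and pickability verdict.

    One connected region means no occlusion; otherwise blind spots are sampled
    for every region pair and their detected classes unioned.  The verdict is
    not-pickable iff the union contains a blocking class (stems, wires,
    branches/petioles by default); leaf- or unknown-only occlusion is
    harmless for mechanical picking.
    """
    if cfg is None:
        cfg = PerceptionConfig()
    if palette_names is None:
        from .scene_io import EMPIRICAL_CLASSES

        palette_names = EMPIRICAL_CLASSES
    if instance.area == 0:
        raise ValueError("empty instance mask")
    if instance.mask.shape != sem.shape or sem.shape != rgb.shape:
        raise ValueError("instance, semantic map and RGB image must be aligned")
    regions = connected_regions(instance.mask, cfg.connectivity, cfg.min_area)
    if len(regions) <= 1:
        return OcclusionReport(
            instance_id=instance.instance_id,
            n_regions=len(regions),
            blind_spots=[],
            obstacle_classes=set(),
            occluded=False,
            pickable=True,
        )
    spots: list[BlindSpot] = []
    classes: set[str] = set()
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            # per-pair stream independent of n_samples, so unions are monotone
            rng = np.random.default_rng(
                [cfg.seed, instance.instance_id, regions[i].region_id, regions[j].region_id]
            )
            pair_spots = sample_blind_spots(
                regions[i],
                regions[j],
                cfg.n_samples,
                rng,
                sem.shape,
                exclude_mask=instance.mask,
            )
            for spot in pair_spots:
                classes |= classify_blind_spot(
                    spot, sem, rgb, instance, tuple(palette_names), cfg.min_class_pixels
                )
            spots.extend(pair_spots)
    pickable = not (classes & cfg.blocking_classes)
    return OcclusionReport(
        instance_id=instance.instance_id,
        n_regions=len(regions),
        blind_spots=spots,
        obstacle_classes=classes,
        occluded=True,
        pickable=pickable,
    )
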