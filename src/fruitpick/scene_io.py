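"""Scene artifact I/O: label / depth / RGB PNGs and polygon annotations.

All maps share one coordinate convention: 0-based ``(row, col)`` with row 0 at
the top of the image.  Semantic labels are small integers indexing a
:class:`ClassPalette`; depth is stored as 16-bit unsigned millimetres with 0 as
the invalid-depth sentinel (commodity depth-camera convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

# The eight empirical classes of the tomato-scene ontology, in palette order.
EMPIRICAL_CLASSES = (
    "background",
    "mature_fruit",
    "immature_fruit",
    "peduncle",
    "stem",
    "branch_petiole",
    "wire",
    "cut",
)

DEFAULT_COLORS = {
    "background": (0, 0, 0),
    "mature_fruit": (255, 0, 0),
    "immature_fruit": (0, 255, 0),
    "peduncle": (255, 255, 0),
    "stem": (0, 0, 128),
    "branch_petiole": (128, 0, 128),
    "wire": (0, 255, 255),
    "cut": (128, 128, 128),
    # synthetic-label-only class; empirical annotations fold leaves into
    # background, synthetic ground truth may label them explicitly
    "leaf": (0, 128, 0),
}

DEPTH_INVALID = 0


@dataclass(frozen=True)
class ClassPalette:
    """Ordered mapping class-name -> color; class id = position in `entries`."""

    entries: tuple[tuple[str, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        colors = [tuple(c) for _, c in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("palette class names must be unique")
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be unique")
        missing = set(EMPIRICAL_CLASSES) - set(names)
        if missing:
            raise ValueError(f"palette missing required classes: {sorted(missing)}")
        extra = set(names) - set(EMPIRICAL_CLASSES) - {"leaf"}
        if extra:
            raise ValueError(f"unknown palette classes: {sorted(extra)}")

    @classmethod
    def default(cls) -> "ClassPalette":
        return cls(tuple((n, DEFAULT_COLORS[n]) for n in EMPIRICAL_CLASSES))

    @classmethod
    def with_leaf(cls) -> "ClassPalette":
        names = EMPIRICAL_CLASSES + ("leaf",)
        return cls(tuple((n, DEFAULT_COLORS[n]) for n in names))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def colors(self) -> tuple[tuple[int, int, int], ...]:
        return tuple(tuple(c) for _, c in self.entries)

    def id_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in palette") from None

    def color_of(self, name: str) -> tuple[int, int, int]:
        return self.colors[self.id_of(name)]

    def __len__(self) -> int:
        return len(self.entries)

    def to_yaml(self, path: str | Path) -> None:
        data = {"classes": [{"name": n, "color": list(c)} for n, c in self.entries]}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassPalette":
        data = yaml.safe_load(Path(path).read_text())
        return cls(tuple((e["name"], tuple(e["color"])) for e in data["classes"]))


@dataclass
class SemanticMap:
    """H×W grid of class ids (uint8), pixel-aligned with its depth map."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class DepthMap:
    """H×W grid of depths in millimetres; 0 marks missing depth."""

    depth: np.ndarray
    invalid_value: int = DEPTH_INVALID

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2-D array")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")
        self.depth = self.depth.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    @property
    def valid(self) -> np.ndarray:
        return self.depth != self.invalid_value


@dataclass
class RgbImage:
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


# ---------------------------------------------------------------------------
# PNG round-trips


def write_label_png(sem: SemanticMap, palette: ClassPalette, path: str | Path) -> None:
    """Write an indexed-color PNG; exact inverse of :func:`read_label_png`."""
    if sem.labels.max(initial=0) >= len(palette):
        bad = int(sem.labels.max())
        raise ValueError(f"label id {bad} has no palette color ({len(palette)} classes)")
    img = Image.fromarray(sem.labels, mode="P")
    flat = [v for color in palette.colors for v in color]
    img.putpalette(flat)
    img.save(path, format="PNG")


def read_label_png(path: str | Path, palette: ClassPalette) -> SemanticMap:
    """Map every pixel color back to its palette class id.

    A color absent from the palette raises, naming the color and the first
    pixel location where it occurs.
    """
    img = Image.open(path)
    rgb = np.asarray(img.convert("RGB"))
    h, w = rgb.shape[:2]
    colors = np.array(palette.colors, dtype=np.uint8)  # (K,3)
    # match each pixel against each palette color
    eq = (rgb[:, :, None, :] == colors[None, None, :, :]).all(axis=3)  # (H,W,K)
    known = eq.any(axis=2)
    if not known.all():
        r, c = np.argwhere(~known)[0]
        raise ValueError(
            f"color {tuple(int(v) for v in rgb[r, c])} at pixel (row={r}, col={c}) "
            "is not in the palette"
        )
    labels = eq.argmax(axis=2).astype(np.uint8)
    return SemanticMap(labels)


def write_depth_png(d: DepthMap, path: str | Path) -> None:
    Image.fromarray(d.depth.astype(np.uint16)).save(path, format="PNG")


def read_depth_png(path: str | Path) -> DepthMap:
    img = Image.open(path)
    if img.mode not in ("I;16", "I;16B", "I"):
        raise ValueError(
            f"depth PNG must be 16-bit single-channel, got mode {img.mode!r}"
        )
    arr = np.asarray(img, dtype=np.int64)
    if arr.max(initial=0) > np.iinfo(np.uint16).max or arr.min(initial=0) < 0:
        raise ValueError("depth PNG values exceed the 16-bit range")
    return DepthMap(arr.astype(np.uint16))


def write_rgb_png(img: RgbImage, path: str | Path) -> None:
    Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")


def read_rgb_png(path: str | Path) -> RgbImage:
    return RgbImage(np.asarray(Image.open(path).convert("RGB")))


# ---------------------------------------------------------------------------
# Polygon rasterization (pixel-center even-odd rule, boundary inclusive)


def polygon_mask(
    vertices: Sequence[tuple[float, float]],
    shape: tuple[int, int],
    eps: float = 1e-9,
) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside or on the polygon.

    Vertices are ``(row, col)``; pixel centers sit at integer coordinates.
    Interior membership uses the even-odd (ray-crossing) rule; points exactly
    on an edge are always included.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    h, w = shape
    r0 = max(int(np.floor(v[:, 0].min())), 0)
    r1 = min(int(np.ceil(v[:, 0].max())), h - 1)
    c0 = max(int(np.floor(v[:, 1].min())), 0)
    c1 = min(int(np.ceil(v[:, 1].max())), w - 1)
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    py = rr.ravel().astype(float)
    px = cc.ravel().astype(float)
    inside = np.zeros(py.shape, dtype=bool)
    boundary = np.zeros(py.shape, dtype=bool)
    n = len(v)
    for i in range(n):
        y1, x1 = v[i]
        y2, x2 = v[(i + 1) % n]
        # exact-boundary test: zero cross product and within segment bbox
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        seg_eps = eps * max(1.0, abs(x1), abs(x2), abs(y1), abs(y2))
        on = (
            (np.abs(cross) <= seg_eps)
            & (px >= min(x1, x2) - seg_eps)
            & (px <= max(x1, x2) + seg_eps)
            & (py >= min(y1, y2) - seg_eps)
            & (py <= max(y1, y2) + seg_eps)
        )
        boundary |= on
        if y1 != y2:
            # half-open rule avoids double-counting vertices on the scan ray
            straddles = (y1 > py) != (y2 > py)
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= straddles & (px < x_at)
    mask[rr.ravel(), cc.ravel()] = inside | boundary
    return mask


def rasterize_polygons(
    annotations: Sequence[tuple[str, Sequence[tuple[float, float]]]],
    size: tuple[int, int],
    palette: ClassPalette,
) -> SemanticMap:
    """Paint polygons back-to-front: later annotations overwrite earlier ones.

    Annotation order is the authoring order of the ground truth (objects are
    annotated from the back of the scene to the front), so the last-listed
    polygon wins on overlap.
    """
    labels = np.full(size, palette.id_of("background"), dtype=np.uint8)
    for name, verts in annotations:
        cid = palette.id_of(name)
        labels[polygon_mask(verts, size)] = cid
    return SemanticMap(labels)


def read_labelme_json(
    path: str | Path, size: tuple[int, int], palette: ClassPalette
) -> SemanticMap:
    """Rasterize a Labelme-style annotation file (`shapes` with [x, y] points)."""
    data = json.loads(Path(path).read_text())
    annotations = []
    for shape in data["shapes"]:
        pts = [(float(y), float(x)) for x, y in shape["points"]]
        annotations.append((shape["label"], pts))
    return rasterize_polygons(annotations, size, palette)


# ---------------------------------------------------------------------------
# Downsampling


def downsample(obj: SemanticMap | DepthMap, factor: int):
    """Reduce resolution by an integer factor.

    Labels keep the top-left pixel of each block (nearest-neighbour); depth
    takes the median over valid (non-zero) pixels of each block, with the
    invalid sentinel where a block has no valid depth.  Edge blocks may be
    partial; they are padded with invalid pixels, which the valid-median
    ignores, so output dims are always ``ceil(H/f) × ceil(W/f)``.
    """
    if factor <= 0 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if isinstance(obj, SemanticMap):
        return SemanticMap(obj.labels[::factor, ::factor].copy())
    if isinstance(obj, DepthMap):
        d = obj.depth.astype(float)
        d[~obj.valid] = np.nan
        h, w = d.shape
        hc = -(-h // factor)
        wc = -(-w // factor)
        padded = np.full((hc * factor, wc * factor), np.nan)
        padded[:h, :w] = d
        blocks = padded.reshape(hc, factor, wc, factor).transpose(0, 2, 1, 3)
        blocks = blocks.reshape(hc, wc, factor * factor)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                med = np.nanmedian(blocks, axis=2)
        med = np.where(np.isnan(med), obj.invalid_value, np.rint(med))
        return DepthMap(med.astype(np.uint16))
    raise TypeError(f"cannot downsample object of type {type(obj).__name__}")
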