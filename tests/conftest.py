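"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (scalar loops, brute-force
enumeration, BFS flood fill) and share no code with the package paths they
check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import fruitpick as fp


@pytest.fixture(scope="session")
def palette():
    return fp.ClassPalette.default()


@pytest.fixture(scope="session")
def leaf_palette():
    return fp.ClassPalette.with_leaf()


@pytest.fixture(scope="session")
def demo_scene():
    """The packaged two-fruit demo scene (one clear, one stem-split)."""
    return fp.fixture_scene()


# ---------------------------------------------------------------------------
# Oracle: scalar-loop SFM (direct transliteration of the defining equations)


def sfm_scalar_oracle(F: np.ndarray) -> np.ndarray:
    """Pure-Python per-element evaluation of the SFM with averaging fusion."""
    C, H, W = F.shape
    mask_h = []
    for h in range(H):
        total = 0.0
        for c in range(C):
            row_mean = sum(F[c, h, w] for w in range(W)) / W
            total += row_mean
        mask_h.append(max(0.0, total / C))
    mask_v = []
    for w in range(W):
        total = 0.0
        for c in range(C):
            col_mean = sum(F[c, h, w] for h in range(H)) / H
            total += col_mean
        mask_v.append(max(0.0, total / C))
    out = np.zeros_like(F, dtype=float)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                f_o = F[c, h, w]
                f_h = f_o * mask_h[h]
                f_v = f_o * mask_v[w]
                out[c, h, w] = (f_o + f_h + f_v) / 3.0
    return out


# ---------------------------------------------------------------------------
# Oracle: BFS flood fill for connected components


def flood_fill_regions(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """Connected components as sets of (row, col), by BFS."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    regions = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    comp.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                regions.append(comp)
    return regions


# ---------------------------------------------------------------------------
# Oracle: brute-force minimum enclosing circle over 2- and 3-point candidates


def brute_force_circle(points: np.ndarray, eps: float = 1e-7):
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    best = None
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            candidates.append((c, np.linalg.norm(pts[i] - c)))
            for k in range(j + 1, n):
                ay, ax = pts[i]
                by, bx = pts[j]
                cy, cx = pts[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
                ctr = np.array([uy, ux])
                candidates.append((ctr, np.linalg.norm(pts[i] - ctr)))
    for ctr, r in candidates:
        if np.all(np.linalg.norm(pts - ctr, axis=1) <= r + eps):
            if best is None or r < best[1]:
                best = (ctr, r)
    return best


# ---------------------------------------------------------------------------
# Oracle: point-in-polygon via shapely (independent geometry kernel)


def polygon_mask_oracle(vertices, shape) -> np.ndarray:
    from shapely.geometry import Point, Polygon

    poly = Polygon([(x, y) for y, x in vertices])
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = poly.covers(Point(c, r))
    return mask
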