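"""Adaptive K-means fruit-instance clustering over joint (position, depth).

Mature-fruit pixels that belong to one physical fruit sit close together in
the image and share similar depth even when an occluder splits the mask, so
clustering in the joint space separates adjacent fruits that touch in 2-D.
The loss being minimized is

    L = sum_j sum_{i in S_j}  ||p(X_i) - p(Z_j)||^2 + alpha * (d(X_i) - d(Z_j))^2

with p in working-resolution pixels and d in working depth units.  The cluster
count adapts to the scene: start from an upper bound K0, cluster, merge
centers closer than `merge_dist` in the combined metric, and re-cluster at the
reduced K until the count stabilizes.

Samples are plain ``(n, 3)`` float arrays with columns ``(row, col, depth)``;
the mm→working-unit depth scaling (``depth_scale``, default 0.1 i.e.
centimetres) is applied once during sample extraction so position and depth
are commensurate under the default ``alpha = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scene_io import DepthMap, SemanticMap, downsample


@dataclass
class ClusteringConfig:
    alpha: float = 1.0
    k0: int = 8
    merge_dist: float = 12.0
    downsample_factor: int = 4
    max_iter: int = 100
    depth_scale: float = 0.1
    min_cluster_size: int = 20  # working-res samples; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.merge_dist <= 0:
            raise ValueError("merge_dist must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class ClusterState:
    """Result of one clustering round: K centers and a full assignment."""

    K: int
    centers: np.ndarray  # (K, 3): row, col, depth (working units)
    assignment: np.ndarray  # (n,) cluster index per sample
    loss: float
    history: Optional[list[float]] = field(default=None, repr=False)


def _as_samples(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("samples must be an (n, 3) array of (row, col, depth)")
    return arr


def _sq_dist(samples: np.ndarray, centers: np.ndarray, alpha: float) -> np.ndarray:
    """(n, K) squared combined distances under the clustering metric."""
    dpos = samples[:, None, :2] - centers[None, :, :2]
    dd = samples[:, None, 2] - centers[None, :, 2]
    return (dpos**2).sum(axis=2) + alpha * dd**2


def clustering_loss(samples, centers, assignment, alpha: float) -> float:
    """Evaluate the joint position+depth loss for a given partition."""
    samples = _as_samples(samples)
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    assignment = np.asarray(assignment, dtype=int)
    diff = samples - centers[assignment]
    return float((diff[:, :2] ** 2).sum() + alpha * (diff[:, 2] ** 2).sum())


def extract_fruit_pixels(
    sem: SemanticMap, depth: DepthMap, cfg: ClusteringConfig, mature_id: int = 1
) -> np.ndarray:
    """Working-resolution mature-fruit samples with valid depth.

    Both maps are downsampled by ``cfg.downsample_factor``; mature pixels
    whose downsampled depth is the invalid sentinel are dropped.  Depth is
    scaled to working units here, once.
    """
    if sem.shape != depth.shape:
        raise ValueError("semantic and depth maps must be aligned")
    ds_sem = downsample(sem, cfg.downsample_factor)
    ds_depth = downsample(depth, cfg.downsample_factor)
    mask = (ds_sem.labels == mature_id) & ds_depth.valid
    rows, cols = np.nonzero(mask)
    d = ds_depth.depth[rows, cols].astype(float) * cfg.depth_scale
    return np.column_stack([rows.astype(float), cols.astype(float), d])


def _update_centers(samples: np.ndarray, assignment: np.ndarray, k: int) -> np.ndarray:
    centers = np.zeros((k, 3))
    for j in range(k):
        members = samples[assignment == j]
        centers[j] = members.mean(axis=0)
    return centers


def _dsq_weighted_init(
    samples: np.ndarray, k: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded init from the samples, spread by D²-weighted sampling.

    The first center is uniform; each further center is drawn without
    replacement with probability proportional to the squared combined
    distance to the nearest chosen center, so every well-separated fruit
    blob attracts a center with high probability.
    """
    n = len(samples)
    idx = [int(rng.integers(n))]
    d2 = _sq_dist(samples, samples[idx], alpha).ravel()
    for _ in range(1, k):
        probs = d2.copy()
        probs[idx] = 0.0
        total = probs.sum()
        if total <= 0:  # all remaining samples coincide with a center
            remaining = np.setdiff1d(np.arange(n), idx)
            idx.append(int(remaining[0]))
        else:
            idx.append(int(rng.choice(n, p=probs / total)))
        d2 = np.minimum(d2, _sq_dist(samples, samples[idx[-1:]], alpha).ravel())
    return samples[idx].copy()


def run_kmeans(
    samples,
    k: int,
    alpha: float = 1.0,
    seed: int = 0,
    max_iter: int = 100,
    track_history: bool = False,
    init_centers=None,
) -> ClusterState:
    """Seeded Lloyd iteration under the combined metric.

    Centers initialize by seeded sampling of k distinct fruit pixels
    (D²-weighted so separated blobs each attract a center), or from
    `init_centers` when given; assignment ties go to the lowest cluster
    index; an emptied cluster is re-seeded at the sample farthest from its
    previous center.  Stops when the assignment stops changing (or at
    max_iter); the loss is non-increasing across iterations.
    """
    samples = _as_samples(samples)
    n = len(samples)
    if k > n:
        raise ValueError(f"K={k} exceeds the number of samples n={n}")
    if k < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).reshape(k, 3).copy()
    else:
        centers = _dsq_weighted_init(samples, k, alpha, rng)
    assignment = np.full(n, -1, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = _sq_dist(samples, centers, alpha)
        new_assignment = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        # repair empty clusters: re-seed at the sample farthest from the
        # empty center and pin that sample to it (bounded, deterministic)
        for _repair in range(2 * k):
            empty = [j for j in range(k) if not np.any(new_assignment == j)]
            if not empty:
                break
            j = empty[0]
            far = int(d2[:, j].argmax())
            centers[j] = samples[far]
            d2 = _sq_dist(samples, centers, alpha)
            new_assignment = d2.argmin(axis=1)
            new_assignment[far] = j
        if track_history:
            history.append(clustering_loss(samples, centers, new_assignment, alpha))
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        centers = _update_centers(samples, assignment, k)
        if track_history:
            history.append(clustering_loss(samples, centers, assignment, alpha))
    loss = clustering_loss(samples, centers, assignment, alpha)
    return ClusterState(
        K=k,
        centers=centers,
        assignment=assignment,
        loss=loss,
        history=history if track_history else None,
    )


def merge_close_centers(
    state: ClusterState, samples, merge_dist: float, alpha: float
) -> ClusterState:
    """Iteratively merge the closest center pair while it is under merge_dist.

    Distance is the combined metric sqrt(||dpos||^2 + alpha*dd^2); the
    smallest-distance pair merges first, ties resolved by the lowest index
    pair; the merged center is the mean of the united members.
    """
    samples = _as_samples(samples)
    centers = state.centers.copy()
    assignment = state.assignment.copy()
    k = state.K
    while k > 1:
        d2 = _sq_dist(centers, centers, alpha)
        iu = np.triu_indices(k, 1)
        pair_d = np.sqrt(d2[iu])
        best = pair_d.argmin()  # lowest flat index wins ties -> lowest (i, j)
        if pair_d[best] >= merge_dist:
            break
        i, j = iu[0][best], iu[1][best]
        assignment[assignment == j] = i
        assignment[assignment > j] -= 1
        k -= 1
        centers = _update_centers(samples, assignment, k)
    loss = clustering_loss(samples, centers, assignment, alpha)
    return ClusterState(K=k, centers=centers, assignment=assignment, loss=loss)


def _dissolve_small_clusters(
    state: ClusterState, samples: np.ndarray, min_size: int, alpha: float
) -> ClusterState:
    """Absorb clusters far smaller than any plausible fruit footprint.

    Mixed fruit/occluder depth pixels at object borders can leave a handful
    of samples whose depth is tens of working units off; they hold a center
    of their own yet are an order of magnitude below the ~50-sample footprint
    of the smallest fruit.  Smallest cluster first, its members move to the
    nearest remaining center and all centers are re-estimated.
    """
    centers = state.centers.copy()
    assignment = state.assignment.copy()
    k = state.K
    while k > 1:
        sizes = np.bincount(assignment, minlength=k)
        j = int(sizes.argmin())
        if sizes[j] >= min_size:
            break
        others = np.delete(np.arange(k), j)
        members = np.nonzero(assignment == j)[0]
        d2 = _sq_dist(samples[members], centers[others], alpha)
        assignment[members] = others[d2.argmin(axis=1)]
        assignment[assignment > j] -= 1
        k -= 1
        centers = _update_centers(samples, assignment, k)
    loss = clustering_loss(samples, centers, assignment, alpha)
    return ClusterState(K=k, centers=centers, assignment=assignment, loss=loss)


def adaptive_kmeans(samples, cfg: ClusteringConfig) -> ClusterState:
    """Cluster, merge close centers, and re-cluster until K stabilizes.

    K starts at min(cfg.k0, n) and can only shrink, so the loop terminates in
    at most k0 rounds.  After stabilization, dust clusters (below
    cfg.min_cluster_size samples, depth artifacts at object borders) are
    dissolved into their nearest neighbours.
    """
    samples = _as_samples(samples)
    n = len(samples)
    if n == 0:
        raise ValueError("no samples to cluster")
    k = min(cfg.k0, n)
    for round_idx in range(cfg.k0 + 1):
        state = run_kmeans(
            samples, k, cfg.alpha, seed=cfg.seed + round_idx, max_iter=cfg.max_iter
        )
        merged = merge_close_centers(state, samples, cfg.merge_dist, cfg.alpha)
        if merged.K == k:
            break
        k = merged.K
    if cfg.min_cluster_size > 0:
        merged = _dissolve_small_clusters(
            merged, samples, cfg.min_cluster_size, cfg.alpha
        )
    return merged


def instances_from_state(
    state: ClusterState,
    sem_full: SemanticMap,
    depth_full: DepthMap,
    cfg: ClusteringConfig,
    mature_id: int = 1,
):
    """Assign every full-resolution mature pixel to its nearest cluster center.

    Working-resolution center positions are rescaled by the downsample factor;
    pixels with valid depth use the full combined metric, pixels without use
    the position term only.  Returns one binary InstanceMask per non-empty
    cluster; together the masks partition the mature-fruit mask.
    """
    from .obstacle_perception import InstanceMask

    f = cfg.downsample_factor
    rows, cols = np.nonzero(sem_full.labels == mature_id)
    if len(rows) == 0:
        return []
    centers_pos = state.centers[:, :2] * f
    centers_d = state.centers[:, 2]
    pts = np.column_stack([rows, cols]).astype(float)
    d2 = ((pts[:, None, :] - centers_pos[None, :, :]) ** 2).sum(axis=2)
    depth_vals = depth_full.depth[rows, cols].astype(float) * cfg.depth_scale
    valid = depth_full.valid[rows, cols]
    dd = depth_vals[:, None] - centers_d[None, :]
    d2 = d2 + cfg.alpha * np.where(valid[:, None], dd**2, 0.0)
    assign = d2.argmin(axis=1)
    instances = []
    next_id = 0
    for j in range(state.K):
        sel = assign == j
        if not sel.any():
            continue
        mask = np.zeros(sem_full.shape, dtype=bool)
        mask[rows[sel], cols[sel]] = True
        instances.append(InstanceMask(instance_id=next_id, mask=mask))
        next_id += 1
    return instances
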