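"""JSON-friendly encodings of pipeline artifacts.

Pixel sets are stored as row runs ``[row, col_start, col_end]`` (inclusive),
which keeps instance files compact and diff-able.  Round-trips preserve
row-major pixel order, so CLI stage outputs match in-memory results exactly.
"""

from __future__ import annotations

import numpy as np

from .obstacle_perception import BlindSpot, InstanceMask, OcclusionReport
from .selection_eval import PickTarget


def coords_to_runs(coords: np.ndarray) -> list[list[int]]:
    """Row-major (N,2) pixel coordinates -> inclusive [row, c0, c1] runs."""
    if len(coords) == 0:
        return []
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    runs = []
    r0, c0 = int(coords[0][0]), int(coords[0][1])
    prev = c0
    for r, c in coords[1:]:
        r, c = int(r), int(c)
        if r == r0 and c == prev + 1:
            prev = c
            continue
        runs.append([r0, c0, prev])
        r0, c0, prev = r, c, c
    runs.append([r0, c0, prev])
    return runs


def runs_to_coords(runs) -> np.ndarray:
    if not runs:
        return np.empty((0, 2), dtype=int)
    parts = [
        np.column_stack([np.full(c1 - c0 + 1, r), np.arange(c0, c1 + 1)])
        for r, c0, c1 in runs
    ]
    return np.vstack(parts)


def mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    return coords_to_runs(np.argwhere(mask))


def runs_to_mask(runs, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    coords = runs_to_coords(runs)
    if len(coords):
        mask[coords[:, 0], coords[:, 1]] = True
    return mask


def instances_to_json(instances, depth=None) -> dict:
    out = []
    for inst in instances:
        pix = inst.pixels
        entry = {
            "id": inst.instance_id,
            "center": [float(v) for v in pix.mean(axis=0)],
            "area": inst.area,
            "runs": mask_to_runs(inst.mask),
        }
        if depth is not None:
            d = depth.depth[pix[:, 0], pix[:, 1]]
            d = d[d != depth.invalid_value]
            entry["mean_depth"] = float(d.mean()) if len(d) else None
        out.append(entry)
    return {"instances": out}


def instances_from_json(data: dict, shape) -> list[InstanceMask]:
    return [
        InstanceMask(instance_id=e["id"], mask=runs_to_mask(e["runs"], shape))
        for e in data["instances"]
    ]


def reports_to_json(reports) -> dict:
    out = []
    for rep in reports:
        out.append(
            {
                "instance_id": rep.instance_id,
                "n_regions": rep.n_regions,
                "occluded": rep.occluded,
                "pickable": rep.pickable,
                "obstacle_classes": sorted(rep.obstacle_classes),
                "blind_spots": [
                    {
                        "region_pair": list(s.region_pair),
                        "vertices": np.asarray(s.vertices).tolist(),
                        "detected_classes": sorted(s.detected_classes),
                        "pixel_runs": coords_to_runs(s.pixels),
                    }
                    for s in rep.blind_spots
                ],
            }
        )
    return {"reports": out}


def reports_from_json(data: dict) -> list[OcclusionReport]:
    reports = []
    for e in data["reports"]:
        spots = [
            BlindSpot(
                vertices=np.asarray(s["vertices"], dtype=float),
                region_pair=tuple(s["region_pair"]),
                pixels=runs_to_coords(s["pixel_runs"]),
                detected_classes=set(s["detected_classes"]),
            )
            for s in e["blind_spots"]
        ]
        reports.append(
            OcclusionReport(
                instance_id=e["instance_id"],
                n_regions=e["n_regions"],
                blind_spots=spots,
                obstacle_classes=set(e["obstacle_classes"]),
                occluded=e["occluded"],
                pickable=e["pickable"],
            )
        )
    return reports


def target_to_json(target) -> dict | None:
    if target is None:
        return None
    return {
        "instance_id": target.instance_id,
        "center": [float(target.center[0]), float(target.center[1])],
        "radius": float(target.radius),
        "mean_depth": float(target.mean_depth),
        "score": float(target.score),
    }


def target_from_json(data) -> PickTarget | None:
    if data is None:
        return None
    return PickTarget(
        instance_id=data["instance_id"],
        center=tuple(data["center"]),
        radius=data["radius"],
        mean_depth=data["mean_depth"],
        score=data["score"],
    )
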