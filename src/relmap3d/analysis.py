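"""Quantitative analytics on relevance maps.

Region-mask aggregation (e.g. total hippocampus relevance), connected-cluster
extraction with threshold and minimum-size filters, per-slice positive and
negative relevance profiles, atlas lookups, and the occlusion sensitivity scan
(sliding a 20-voxel = 30 mm cube of simulated 50% gray-matter loss across the
volume and recording the model's disease probability and total relevance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .lrp import LRPConfig, compute_relevance_map
from .network import TrainedNetwork, predict

AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class Cluster:
    voxels: np.ndarray       # (n, 3) coordinates
    size_voxels: int
    volume_ml: float
    peak_relevance: float
    peak_coordinate: tuple


@dataclass
class ClusterSet:
    clusters: list
    threshold_used: float
    min_size_used: int
    connectivity: int
    size_histogram: list = field(default_factory=list)  # sizes before min-size filter

    def __len__(self) -> int:
        return len(self.clusters)

    def to_table(self, atlas=None) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            row = {
                "cluster_id": i,
                "size_voxels": c.size_voxels,
                "volume_ml": c.volume_ml,
                "peak": c.peak_relevance,
                "peak_x": c.peak_coordinate[0],
                "peak_y": c.peak_coordinate[1],
                "peak_z": c.peak_coordinate[2],
            }
            if atlas is not None:
                row["region"] = atlas.lookup(c.peak_coordinate)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class OcclusionResult:
    probability_grid: np.ndarray      # target-class probability per cube position
    total_relevance_grid: np.ndarray | None
    cube_edge_voxels: int
    cube_edge_mm: float
    attenuation: float
    stride: int
    centers: tuple                    # per-axis arrays of cube-center voxel indices
    baseline_probability: float


def _map_values(relevance_map) -> np.ndarray:
    return np.asarray(getattr(relevance_map, "values", relevance_map), float)


def region_relevance_sum(relevance_map, mask: np.ndarray) -> float:
    """Sum of relevance over the masked voxels (e.g. hippocampus relevance)."""
    values = _map_values(relevance_map)
    mask = np.asarray(mask, bool)
    if mask.shape != values.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {values.shape}")
    return float(values[mask].sum())


def region_volume_ml(volume, mask: np.ndarray, voxel_size_mm: float | None = None) -> float:
    """Gray-matter volume in ml: sum of masked density x voxel volume.

    On modulated maps the voxel intensity is proportional to local tissue
    volume, so the masked density total times the voxel volume (1.5^3 mm^3 by
    default) estimates the region's volume.
    """
    values = _map_values(volume)
    mask = np.asarray(mask, bool)
    if mask.shape != values.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {values.shape}")
    if voxel_size_mm is None:
        voxel_size_mm = getattr(volume, "voxel_size_mm", 1.5)
    return float(values[mask].sum() * voxel_size_mm**3 / 1000.0)


def extract_clusters(
    relevance_map,
    threshold: float,
    min_size: int = 1,
    connectivity: int = 6,
    voxel_size_mm: float | None = None,
) -> ClusterSet:
    """Connected components of the supra-threshold voxel set (>= threshold).

    ``connectivity`` is 6 (face adjacency, default) or 26. Components smaller
    than ``min_size`` are discarded but still counted in the size histogram.
    """
    values = _map_values(relevance_map)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if voxel_size_mm is None:
        voxel_size_mm = getattr(relevance_map, "voxel_size_mm", 1.5)
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(values >= threshold, structure=structure)
    clusters, sizes = [], []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        size = len(coords)
        sizes.append(size)
        if size < min_size:
            continue
        vals = values[tuple(coords.T)]
        peak_idx = int(vals.argmax())
        clusters.append(
            Cluster(
                voxels=coords,
                size_voxels=size,
                volume_ml=size * voxel_size_mm**3 / 1000.0,
                peak_relevance=float(vals[peak_idx]),
                peak_coordinate=tuple(int(c) for c in coords[peak_idx]),
            )
        )
    clusters.sort(key=lambda c: c.size_voxels, reverse=True)
    return ClusterSet(
        clusters=clusters,
        threshold_used=float(threshold),
        min_size_used=int(min_size),
        connectivity=connectivity,
        size_histogram=sorted(sizes, reverse=True),
    )


def slice_relevance_profile(relevance_map, axis) -> pd.DataFrame:
    """Per-slice positive and negative relevance sums along a named axis.

    Backend of the viewer's slice-navigation guide plots. ``axis`` is
    'sagittal', 'coronal' or 'axial' (or 0/1/2).
    """
    values = _map_values(relevance_map)
    if isinstance(axis, str):
        if axis not in AXIS_NAMES:
            raise ValueError(f"axis must be one of {sorted(AXIS_NAMES)}, got {axis!r}")
        axis = AXIS_NAMES[axis]
    other = tuple(i for i in range(3) if i != axis)
    pos = np.clip(values, 0, None).sum(axis=other)
    neg = np.clip(values, None, 0).sum(axis=other)
    return pd.DataFrame(
        {"slice": np.arange(values.shape[axis]), "positive_sum": pos, "negative_sum": neg}
    )


def atlas_lookup(coordinate, atlas) -> str:
    """Region name at a grid coordinate ('background' outside any region)."""
    return atlas.lookup(coordinate)


def occlusion_scan(
    network: TrainedNetwork,
    volume,
    cube_edge: int = 20,
    attenuation: float = 0.5,
    stride: int = 4,
    target_class: int = 1,
    compute_relevance: bool = True,
    lrp_config: LRPConfig | None = None,
    preprocess=None,
) -> OcclusionResult:
    """Slide an intensity-attenuating cube across the volume.

    At each cube position on the stride lattice (cubes fully inside the grid)
    the voxels inside the cube are multiplied by (1 - attenuation), the
    occluded volume is classified, and -- optionally -- a full relevance map is
    computed and its total recorded.

    ``preprocess`` (optional) maps the occluded volume to the network input.
    For a model trained on covariate residuals, atrophy is simulated on the
    gray-matter map itself, so pass the volume in raw intensity units and a
    preprocess that subtracts the subject's predicted intensities: attenuating
    a near-zero residual directly would not emulate tissue loss.
    """
    values = np.asarray(getattr(volume, "values", volume), float)
    voxel_size = getattr(volume, "voxel_size_mm", 1.5)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if any(cube_edge > s for s in values.shape):
        raise ValueError(f"cube edge {cube_edge} exceeds grid {values.shape}")
    starts = [np.arange(0, s - cube_edge + 1, stride) for s in values.shape]
    centers = tuple(s + cube_edge // 2 for s in starts)

    if preprocess is None:
        preprocess = lambda v: v  # noqa: E731 - identity input mapping
    probs0, _ = predict(network, preprocess(values.copy()))
    prob_grid = np.zeros(tuple(len(s) for s in starts))
    rel_grid = np.zeros_like(prob_grid) if compute_relevance else None
    for i, sx in enumerate(starts[0]):
        for j, sy in enumerate(starts[1]):
            for k, sz in enumerate(starts[2]):
                occluded = values.copy()
                occluded[
                    sx : sx + cube_edge, sy : sy + cube_edge, sz : sz + cube_edge
                ] *= 1.0 - attenuation
                occluded = preprocess(occluded)
                probs, _ = predict(network, occluded)
                prob_grid[i, j, k] = probs[target_class]
                if compute_relevance:
                    rmap = compute_relevance_map(
                        network, occluded, target_class, lrp_config
                    )
                    rel_grid[i, j, k] = float(rmap.values.sum())
    return OcclusionResult(
        probability_grid=prob_grid,
        total_relevance_grid=rel_grid,
        cube_edge_voxels=int(cube_edge),
        cube_edge_mm=float(cube_edge * voxel_size),
        attenuation=float(attenuation),
        stride=int(stride),
        centers=centers,
        baseline_probability=float(probs0[target_class]),
    )


def normalize_map(relevance_map, cohort_maps, percentile: float = 99.5) -> np.ndarray:
    """Scale a map by the cohort's high-percentile absolute relevance.

    Display thresholds (e.g. 0.2) are defined on maps normalized this way.
    """
    ref = np.percentile(np.abs(np.stack([_map_values(m) for m in cohort_maps])), percentile)
    values = _map_values(relevance_map)
    return values / ref if ref > 0 else values.copy()


def group_mean_map(maps) -> np.ndarray:
    """Voxelwise mean relevance over a group of maps."""
    return np.stack([_map_values(m) for m in maps]).mean(axis=0)
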