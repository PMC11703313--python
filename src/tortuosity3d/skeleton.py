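"""Centerline extraction: binarize, thin, find endpoints, order the path.

A labelled artery segmentation is reduced to an ordered list of 3D points
tracing its medial axis:

1. isolate the target label as a binary mask;
2. thin the mask to a one-voxel-wide line (3D medial-axis thinning);
3. detect endpoints by counting 26-neighbors (exactly one foreground
   neighbor marks a terminal voxel);
4. traverse the skeleton's 26-adjacency graph from one endpoint to the
   other, yielding voxel indices and their world-mm coordinates.

Vessels with side branches are handled by taking the longest
endpoint-to-endpoint path and dropping spurs, with a warning recorded; closed
loops and multi-component masks are errors (they indicate a bad segmentation
that needs upstream correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import (
    DegenerateStructureError,
    DisconnectionError,
    EmptyStructureError,
    LoopTopologyError,
    MultiComponentError,
)
from .volume import LabelVolume

__all__ = [
    "SkeletonMask",
    "CenterlinePath",
    "binarize",
    "skeletonize3d",
    "find_endpoints",
    "order_path",
    "extract_centerline",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SkeletonMask:
    """One-voxel-wide skeleton with the affine of its source volume."""

    voxels: np.ndarray
    affine: np.ndarray

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass
class CenterlinePath:
    """Ordered centerline in voxel indices and world millimetres."""

    points_vox: np.ndarray  # (N, 3) int
    points_mm: np.ndarray   # (N, 3) float
    warnings: list = field(default_factory=list)
    n_endpoints: int = 2    # endpoints detected on the source skeleton

    @property
    def n_points(self) -> int:
        return len(self.points_vox)


def binarize(volume: LabelVolume, label: int) -> LabelVolume:
    """Isolate one label as a binary mask, preserving the affine."""
    mask = volume.voxels == label
    if not mask.any():
        raise EmptyStructureError(f"label {label} not present in volume")
    return LabelVolume(voxels=mask.astype(np.uint8), affine=volume.affine)


def skeletonize3d(mask: LabelVolume, keep_largest: bool = False) -> SkeletonMask:
    """Thin a binary mask to its medial line.

    Delegates to scikit-image's 3D thinning, which preserves topology while
    reducing the foreground to a single-voxel-wide line.

    Parameters
    ----------
    keep_largest : bool
        If the foreground has several 26-connected components, keep only the
        largest instead of raising (a warning is logged).
    """
    fg = mask.voxels > 0
    if not fg.any():
        raise EmptyStructureError("mask is empty, nothing to skeletonize")
    labeled, n_comp = ndimage.label(fg, structure=_STRUCT26)
    if n_comp > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        if not keep_largest:
            raise MultiComponentError(
                f"mask has {n_comp} 26-connected components "
                f"(sizes {sorted(sizes, reverse=True)}); expected 1",
                component_sizes=sorted(sizes, reverse=True),
            )
        keep = int(np.argmax(sizes)) + 1
        log.warning(
            "keeping largest of %d components (%d of %d voxels)",
            n_comp, sizes.max(), fg.sum(),
        )
        fg = labeled == keep
    skel = _skimage_skeletonize(fg)
    return SkeletonMask(voxels=skel.astype(bool), affine=mask.affine)


def _neighbor_counts(voxels: np.ndarray) -> np.ndarray:
    """Number of foreground 26-neighbors of every voxel (center excluded)."""
    counts = ndimage.convolve(
        voxels.astype(np.uint8), _STRUCT26.astype(np.uint8), mode="constant"
    )
    return counts - voxels.astype(np.uint8)


def find_endpoints(skeleton: SkeletonMask) -> list[tuple[int, int, int]]:
    """Terminal voxels: foreground with exactly one foreground 26-neighbor.

    Returned in lexicographic voxel-index order (deterministic).
    """
    fg = skeleton.voxels
    n_fg = int(np.count_nonzero(fg))
    if n_fg == 0:
        raise EmptyStructureError("skeleton is empty")
    if n_fg == 1:
        raise DegenerateStructureError("skeleton is a single isolated voxel")
    counts = _neighbor_counts(fg)
    ends = np.argwhere(fg & (counts == 1))
    if len(ends) == 0:
        raise LoopTopologyError(
            "skeleton has no endpoints (closed loop); open curve expected"
        )
    # np.argwhere is already lexicographic, make it explicit for safety
    ends = ends[np.lexsort((ends[:, 2], ends[:, 1], ends[:, 0]))]
    return [tuple(int(v) for v in e) for e in ends]


def _skeleton_graph(skeleton: SkeletonMask) -> nx.Graph:
    """26-adjacency graph over skeleton voxels, Euclidean-mm edge weights."""
    idx = np.argwhere(skeleton.voxels)
    voxset = {tuple(v): i for i, v in enumerate(map(tuple, idx))}
    lin = skeleton.affine[:3, :3]
    g = nx.Graph()
    g.add_nodes_from(voxset)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # half of the 26 offsets, avoids dupes
    ]
    for v in voxset:
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxset:
                dist = float(np.linalg.norm(lin @ np.asarray(off, dtype=float)))
                g.add_edge(v, w, weight=dist)
    return g


def order_path(
    skeleton: SkeletonMask,
    start: tuple[int, int, int],
    end: tuple[int, int, int],
) -> CenterlinePath:
    """Walk the skeleton from ``start`` to ``end``.

    For a clean 2-endpoint skeleton this is the unique traversal; with
    spurious branches it is the Euclidean-weighted shortest path, so side
    branches are dropped (a warning is recorded on the returned path).
    """
    g = _skeleton_graph(skeleton)
    start, end = tuple(start), tuple(end)
    try:
        vox_path = nx.shortest_path(g, start, end, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise DisconnectionError(
            f"no path between {start} and {end} on the skeleton"
        ) from exc
    warnings = []
    if len(vox_path) < g.number_of_nodes():
        warnings.append("spur_dropped")
        log.warning(
            "path uses %d of %d skeleton voxels; side branches dropped",
            len(vox_path), g.number_of_nodes(),
        )
    points_vox = np.asarray(vox_path, dtype=int)
    lin, trans = skeleton.affine[:3, :3], skeleton.affine[:3, 3]
    points_mm = points_vox.astype(float) @ lin.T + trans
    return CenterlinePath(points_vox=points_vox, points_mm=points_mm,
                          warnings=warnings)


def extract_centerline(
    volume: LabelVolume, label: int, keep_largest: bool = False
) -> CenterlinePath:
    """Full centerline extraction for one label: binarize through order_path.

    With more than two endpoints the pair with the maximal path length is
    used and a warning recorded; the start is the lexicographically smaller
    endpoint (metrics are reversal-invariant, so the choice is cosmetic).
    """
    mask = binarize(volume, label)
    skel = skeletonize3d(mask, keep_largest=keep_largest)
    endpoints = find_endpoints(skel)
    warnings = []
    if len(endpoints) == 2:
        a, b = endpoints
    else:
        warnings.append(f"multiple_endpoints:{len(endpoints)}")
        log.warning("%d endpoints found; using maximal-length pair",
                    len(endpoints))
        g = _skeleton_graph(skel)
        best, best_len = None, -1.0
        for i, u in enumerate(endpoints):
            dists = nx.single_source_dijkstra_path_length(g, u, weight="weight")
            for v in endpoints[i + 1:]:
                d = dists.get(v)
                if d is not None and d > best_len:
                    best, best_len = (u, v), d
        if best is None:
            raise DisconnectionError("no endpoint pair is connected")
        a, b = best
    start, end = (a, b) if a <= b else (b, a)
    path = order_path(skel, start, end)
    path.warnings = warnings + path.warnings
    path.n_endpoints = len(endpoints)
    return path
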