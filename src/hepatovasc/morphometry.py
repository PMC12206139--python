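"""Skeleton-graph morphometry of the sinusoid network.

The binary sinusoid mask is thinned to a one-voxel centerline (3D thinning),
decomposed into a graph of nodes (centerline voxels of degree != 2:
endpoints and junctions) and branches (maximal degree-2 chains), and
summarized by:

* length        — total skeleton voxel count x mean in-plane spacing (um)
* volume        — foreground voxel count x voxel volume (um^3)
* radius        — cylinder model, r = sqrt(volume / (pi * length)) (um)
* tortuosity    — straightness index: per-branch Euclidean end-to-end
                  distance / path length, length-weighted mean; in (0, 1],
                  1 for a straight segment
* density       — D = V_S / (V - V_L): sinusoid volume over the non-vessel
                  tissue volume
* vessel counts — 26-connected vessel components, normalized across datasets

plus the pre/post-separation relative-change statistic used to compare
paired per-mouse measurements: |a - b| / max(a, b), averaged across mice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

from .volumes import BinaryVolume

__all__ = [
    "skeletonize",
    "SkeletonGraph",
    "Branch",
    "build_graph",
    "SinusoidMorphometry",
    "sinusoid_metrics",
    "sinusoid_density",
    "vessel_count_ratio",
    "StageComparison",
    "relative_change_table",
]

_NEIGHBOR_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def skeletonize(mask: BinaryVolume) -> BinaryVolume:
    """Topology-preserving 3D thinning to a one-voxel-wide centerline."""
    if not mask.data.any():
        return BinaryVolume(data=np.zeros(mask.shape, bool), spacing=mask.spacing,
                            role=mask.role)
    skel = _skimage_skeletonize(mask.data)
    return BinaryVolume(data=skel.astype(bool), spacing=mask.spacing, role=mask.role)


@dataclass(frozen=True)
class Branch:
    """A maximal degree-2 chain between two skeleton nodes.

    ``path`` is the ordered (z, y, x) voxel sequence including both end
    nodes; ``length_um`` sums inter-voxel center distances along it;
    ``chord_um`` is the straight-line end-to-end distance (0 for a cycle).
    """

    index: int
    path: np.ndarray
    length_um: float
    chord_um: float
    end_degrees: tuple[int, int]
    component: int = 0

    @property
    def straightness(self) -> float:
        """Euclidean chord over path length; the tortuosity index in (0, 1]."""
        return self.chord_um / self.length_um if self.length_um > 0 else 1.0

    @property
    def is_terminal(self) -> bool:
        return min(self.end_degrees) <= 1


@dataclass(frozen=True)
class SkeletonGraph:
    """Voxel-resolution centerline graph of a skeletonized mask."""

    nodes: dict[tuple[int, int, int], int]  # node voxel -> degree
    branches: list[Branch]
    spacing: tuple[float, float, float]
    n_skeleton_voxels: int
    n_components: int

    @property
    def endpoints(self) -> list[tuple[int, int, int]]:
        return [c for c, d in self.nodes.items() if d <= 1]

    @property
    def junctions(self) -> list[tuple[int, int, int]]:
        return [c for c, d in self.nodes.items() if d >= 3]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for coord, deg in self.nodes.items():
            g.add_node(coord, degree=deg)
        for b in self.branches:
            u = tuple(b.path[0])
            v = tuple(b.path[-1])
            g.add_edge(u, v, key=b.index, length_um=b.length_um, branch=b)
        return g


def _physical_length(path: np.ndarray, spacing: Sequence[float]) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(path.astype(np.float64), axis=0) * np.asarray(spacing)
    return float(np.sqrt((steps ** 2).sum(axis=1)).sum())


def build_graph(skeleton: BinaryVolume, spacing: Sequence[float] | None = None) -> SkeletonGraph:
    """Decompose a skeleton into nodes and branches.

    Nodes are skeleton voxels whose 26-neighbourhood degree differs from 2
    (endpoints: degree <= 1, junctions: degree >= 3).  Branches are maximal
    chains of degree-2 voxels between nodes; a pure cycle with no node gets
    an arbitrary voxel promoted to node so every skeleton voxel is covered.
    """
    spacing = tuple(spacing) if spacing is not None else skeleton.spacing
    data = skeleton.data
    coords = {tuple(c) for c in np.argwhere(data)}
    if not coords:
        return SkeletonGraph(nodes={}, branches=[], spacing=spacing,
                             n_skeleton_voxels=0, n_components=0)

    def neighbors(c: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        out = []
        for dz, dy, dx in _NEIGHBOR_OFFSETS:
            n = (c[0] + dz, c[1] + dy, c[2] + dx)
            if n in coords:
                out.append(n)
        return out

    adj = {c: neighbors(c) for c in coords}
    degree = {c: len(ns) for c, ns in adj.items()}
    nodes = {c: d for c, d in degree.items() if d != 2}

    branches: list[Branch] = []
    used_chain: set[tuple[int, int, int]] = set()
    used_direct: set[frozenset] = set()

    def trace(start: tuple[int, int, int], first: tuple[int, int, int]) -> list:
        """Walk a degree-2 chain from node `start` through `first`."""
        path = [start, first]
        prev, cur = start, first
        while cur not in nodes:
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:  # defensive: broken chain
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    def add_branch(path: list) -> None:
        arr = np.asarray(path, dtype=np.int64)
        chord = float(
            np.sqrt(
                (((arr[-1] - arr[0]).astype(np.float64) * np.asarray(spacing)) ** 2).sum()
            )
        )
        branches.append(
            Branch(
                index=len(branches),
                path=arr,
                length_um=_physical_length(arr, spacing),
                chord_um=chord,
                end_degrees=(degree[path[0]], degree[path[-1]]),
            )
        )

    for node in nodes:
        for nb in adj[node]:
            if nb in nodes:
                key = frozenset((node, nb))
                if key not in used_direct:
                    used_direct.add(key)
                    add_branch([node, nb])
            elif nb not in used_chain:
                path = trace(node, nb)
                used_chain.update(p for p in path if p not in nodes)
                add_branch(path)

    # pure cycles: degree-2 voxels not reached from any node
    for c in coords:
        if c in nodes or c in used_chain:
            continue
        nodes[c] = degree[c]
        path = trace(c, adj[c][0])
        used_chain.update(p for p in path if p not in nodes)
        add_branch(path)

    labels, n_comp = ndi.label(data, structure=ndi.generate_binary_structure(3, 3))
    branches = [
        Branch(
            index=b.index,
            path=b.path,
            length_um=b.length_um,
            chord_um=b.chord_um,
            end_degrees=b.end_degrees,
            component=int(labels[tuple(b.path[0])]),
        )
        for b in branches
    ]
    return SkeletonGraph(
        nodes=nodes,
        branches=branches,
        spacing=spacing,
        n_skeleton_voxels=len(coords),
        n_components=n_comp,
    )


@dataclass(frozen=True)
class SinusoidMorphometry:
    """Headline structural metrics of one sinusoid mask."""

    length_um: float
    volume_um3: float
    radius_um: float  # NaN when length is zero
    tortuosity: float

    def as_dict(self) -> dict:
        return {
            "length_um": self.length_um,
            "volume_um3": self.volume_um3,
            "radius_um": self.radius_um,
            "tortuosity": self.tortuosity,
        }


def sinusoid_metrics(mask: BinaryVolume, graph: SkeletonGraph) -> SinusoidMorphometry:
    """Length, volume, cylinder-model radius and tortuosity of a mask.

    Length counts skeleton voxels at the mean in-plane pitch; volume counts
    foreground voxels; the radius assumes the whole network is a cylinder of
    that volume and length; tortuosity is the length-weighted mean branch
    straightness (chord / path length).
    """
    dz, dy, dx = mask.spacing
    in_plane = (dy + dx) / 2.0
    length = graph.n_skeleton_voxels * in_plane
    volume = float(mask.data.sum()) * mask.voxel_volume_um3
    radius = float(np.sqrt(volume / (np.pi * length))) if length > 0 else float("nan")
    weights = np.array([b.length_um for b in graph.branches])
    if weights.sum() > 0:
        straightness = np.array([b.straightness for b in graph.branches])
        tortuosity = float((weights * straightness).sum() / weights.sum())
    else:
        tortuosity = 1.0 if graph.n_skeleton_voxels else 0.0
    return SinusoidMorphometry(
        length_um=length, volume_um3=volume, radius_um=radius, tortuosity=tortuosity
    )


def sinusoid_density(v_s: float, v_l: float, v: float) -> float:
    """D = V_S / (V - V_L): sinusoid volume per unit of non-vessel volume."""
    if v_s < 0 or v_l < 0:
        raise ValueError("volumes must be non-negative")
    if v <= v_l:
        return float("nan")
    return v_s / (v - v_l)


def vessel_count_ratio(counts: Sequence[float]) -> np.ndarray:
    """Normalize per-dataset vessel component counts by the maximum count."""
    arr = np.asarray(counts, dtype=np.float64)
    if arr.size == 0 or np.any(arr < 0):
        raise ValueError("counts must be non-negative and non-empty")
    peak = arr.max()
    if peak == 0:
        raise ValueError("all counts are zero; ratio undefined")
    return arr / peak


@dataclass(frozen=True)
class StageComparison:
    """Paired relative-change statistics across subjects.

    Per subject, change = |a - b| / max(a, b) x 100 %; the summary is the
    mean and the sample standard deviation across subjects.  ``direction``
    is +1 when b > a for the majority of subjects (an increase), -1 for a
    decrease, 0 on a tie.
    """

    changes_pct: np.ndarray
    mean_pct: float
    sd_pct: float
    direction: int

    @property
    def label(self) -> str:
        return {1: "increase", -1: "decrease", 0: "mixed"}[self.direction]


def relative_change_table(pairs: Sequence[tuple[float, float]]) -> StageComparison:
    """Relative change between paired measurements, larger value as denominator.

    This is the convention under which paired pre/post-separation metric
    tables reproduce their printed summary percentages; symmetric or
    smaller-denominator variants do not.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one subject pair")
    a = np.asarray([p[0] for p in pairs], dtype=np.float64)
    b = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("paired values must be positive")
    changes = np.abs(a - b) / np.maximum(a, b) * 100.0
    sd = float(changes.std(ddof=1)) if changes.size > 1 else 0.0
    direction = int(np.sign(np.sign(b - a).sum()))
    return StageComparison(
        changes_pct=changes, mean_pct=float(changes.mean()), sd_pct=sd, direction=direction
    )
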