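"""Branch typing and box-counting fractal dimension of the sinusoid skeleton.

Branches are classified globally over the 3D skeleton graph:

* dead_end — at least one end of the branch is a degree-1 endpoint: a
  terminal path, the signature of obstructed flow;
* crossing — a branch joining two junctions that shares a junction with at
  most one other junction-junction branch: an isolated connector;
* complex  — a junction-junction branch participating in a multi-segment
  trunk, i.e. sharing its junctions with two or more other
  junction-junction branches.

Each class's centerline voxels are then measured by box counting: the
number N(L) of occupied cubes on an origin-anchored partition of side L,
with the fractal dimension the least-squares slope of log N(L) against
log(1/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import Branch, SkeletonGraph

__all__ = [
    "BranchClass",
    "BranchClassification",
    "classify_branches",
    "branch_fractions",
    "FDResult",
    "box_count_fd",
    "fd_by_class",
    "DEFAULT_BOX_SIZES",
]

DEFAULT_BOX_SIZES = (1, 2, 4, 8, 16, 32)

CLASSES = ("dead_end", "crossing", "complex")


@dataclass(frozen=True)
class BranchClassification:
    """Per-branch labels plus per-class voxel sets and count fractions."""

    labels: list[str]  # parallel to graph.branches
    graph: SkeletonGraph

    def voxels_of(self, cls: str) -> np.ndarray:
        """(N, 3) voxel coordinates of all branches in one class."""
        paths = [b.path for b, lab in zip(self.graph.branches, self.labels) if lab == cls]
        if not paths:
            return np.empty((0, 3), dtype=np.int64)
        return np.unique(np.concatenate(paths, axis=0), axis=0)

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {c: self.labels.count(c) / n for c in CLASSES}


def classify_branches(graph: SkeletonGraph) -> BranchClassification:
    """Label every branch dead_end / crossing / complex (see module doc)."""
    jj = [b for b in graph.branches if min(b.end_degrees) >= 3]
    # how many junction-junction branches touch each junction voxel
    jj_count: dict[tuple, int] = {}
    for b in jj:
        for end in (tuple(b.path[0]), tuple(b.path[-1])):
            jj_count[end] = jj_count.get(end, 0) + 1
    labels = []
    for b in graph.branches:
        if min(b.end_degrees) < 3:
            labels.append("dead_end")
            continue
        u, v = tuple(b.path[0]), tuple(b.path[-1])
        others = (jj_count[u] - 1) + ((jj_count[v] - 1) if v != u else 0)
        labels.append("complex" if others >= 2 else "crossing")
    return BranchClassification(labels=labels, graph=graph)


def branch_fractions(classification: BranchClassification) -> dict[str, float]:
    """Count-based class proportions; they sum to 1."""
    if not classification.labels:
        raise ValueError("graph has no branches to classify")
    return classification.fractions


@dataclass(frozen=True)
class FDResult:
    """Box counts N(L) over sizes L and the fitted fractal dimension."""

    sizes: np.ndarray
    counts: np.ndarray
    fd: float
    r_squared: float


def _box_counts(coords: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    counts = []
    for L in sizes:
        boxes = coords // L
        counts.append(len(np.unique(boxes, axis=0)))
    return np.asarray(counts)


def box_count_fd(voxels: np.ndarray, sizes=DEFAULT_BOX_SIZES) -> FDResult:
    """Box-counting fractal dimension of a voxel set.

    ``voxels`` is a boolean volume or an (N, 3) integer coordinate array.
    Boxes are anchored at the grid origin.  The slope is fitted over sizes
    where 1 < N(L) < N(voxels) to stay clear of the saturation plateaus at
    both ends; a set that never leaves a single box has dimension 0.
    """
    if isinstance(voxels, np.ndarray) and voxels.ndim == 3:
        coords = np.argwhere(voxels)
    else:
        coords = np.asarray(voxels, dtype=np.int64)
    if coords.size == 0:
        raise ValueError("cannot measure the dimension of an empty set")
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if sizes.size < 2:
        raise ValueError("need at least 2 box sizes")
    counts = _box_counts(coords, sizes)
    n_vox = len(coords)

    informative = (counts > 1) & (counts < n_vox)
    use = informative if informative.sum() >= 2 else counts > 0
    if counts.max() == 1:
        return FDResult(sizes=sizes, counts=counts, fd=0.0, r_squared=1.0)
    x = np.log(1.0 / sizes[use])
    y = np.log(counts[use].astype(np.float64))
    if np.unique(x).size < 2:
        return FDResult(sizes=sizes, counts=counts, fd=0.0, r_squared=1.0)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FDResult(sizes=sizes, counts=counts, fd=float(slope), r_squared=r2)


def fd_by_class(
    classification: BranchClassification, sizes=DEFAULT_BOX_SIZES
) -> dict[str, FDResult | None]:
    """Box-counting FD per branch class; None for an empty class."""
    out: dict[str, FDResult | None] = {}
    for cls in CLASSES:
        coords = classification.voxels_of(cls)
        out[cls] = box_count_fd(coords, sizes) if len(coords) else None
    return out
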