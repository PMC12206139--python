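"""GLCM texture scoring for comparing imaging configurations.

Maximum-amplitude-projection images from different window materials or
mounts are ranked by second-order texture statistics of the gray-level
co-occurrence matrix P(i, j):

    contrast    = sum P(i,j) (i-j)^2          — local intensity variation
    entropy     = -sum P log2 P               — information content
    homogeneity = sum P / (1 + |i-j|)         — closeness to the diagonal

A sharper, information-rich image has high contrast and entropy and low
homogeneity, so the composite score rewards the first two and penalizes the
third, each min-max normalized over the compared set, with the final scores
normalized so the best image scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TextureFeatures", "glcm_features", "composite_score",
           "DEFAULT_LEVELS", "DEFAULT_OFFSETS"]

DEFAULT_LEVELS = 64
#: (dy, dx) displacements: right, down, down-right, down-left, all distance 1.
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    entropy: float
    homogeneity: float


def _quantize(image: np.ndarray, levels: int) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = ((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def cooccurrence_matrix(
    image: np.ndarray, levels: int = DEFAULT_LEVELS,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix averaged over offsets."""
    if np.ndim(image) != 2:
        raise ValueError("GLCM features are defined on 2D images")
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    q = _quantize(image, levels)
    h, w = q.shape
    P = np.zeros((levels, levels), dtype=np.float64)
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a = q[y0:y1, x0:x1].ravel()
        b = q[y0 + dy:y1 + dy, x0 + dx:x1 + dx].ravel()
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)  # symmetric
    total = P.sum()
    if total > 0:
        P /= total
    return P


def glcm_features(
    image: np.ndarray, levels: int = DEFAULT_LEVELS,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> TextureFeatures:
    """Contrast, entropy and homogeneity of a 2D image's GLCM.

    A constant image has a single occupied co-occurrence cell and yields the
    degenerate triple (0, 0, 1).
    """
    P = cooccurrence_matrix(image, levels=levels, offsets=offsets)
    i, j = np.indices(P.shape)
    contrast = float((P * (i - j) ** 2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    return TextureFeatures(contrast=contrast, entropy=entropy, homogeneity=homogeneity)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def composite_score(features: Sequence[TextureFeatures]) -> np.ndarray:
    """Composite quality scores in [0, 1]; the best image scores exactly 1.

    raw = norm(contrast) + norm(entropy) + (1 - norm(homogeneity)), each
    normalized over the compared set, then divided by the maximum raw score.
    A single image scores 1 by convention.
    """
    if len(features) == 0:
        raise ValueError("no features to score")
    if len(features) == 1:
        return np.array([1.0])
    contrast = _minmax(np.array([f.contrast for f in features]))
    entropy = _minmax(np.array([f.entropy for f in features]))
    homogeneity = _minmax(np.array([f.homogeneity for f in features]))
    raw = contrast + entropy + (1.0 - homogeneity)
    peak = raw.max()
    if peak <= 0:
        return np.ones_like(raw)
    return raw / peak
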