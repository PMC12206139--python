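"""Sinusoid recovery: mask subtraction, negative clipping, tubular filtering.

The sinusoid compartment is what remains of the enhanced volume once vessels
are taken out.  The vessel mask, scaled to the volume's intensity maximum, is
subtracted voxelwise — vessel voxels go non-positive, everything else keeps
its intensity — negatives are clipped to zero, and a multiscale Hessian
(Frangi-type) vesselness filter accentuates the thin bright tubes before the
final adaptive segmentation.  The resulting sinusoid mask is forced disjoint
from the vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import frangi

from .vessels import adaptive_threshold, robust_max as adaptive_robust_max
from .volumes import BinaryVolume, IntensityVolume, require_same_grid

__all__ = [
    "DifferenceVolume",
    "subtract_vessels",
    "clip_negative",
    "tubular_enhance",
    "segment_sinusoids",
    "DEFAULT_VESSELNESS_SCALES_UM",
]

#: Frangi scales spanning the sinusoid radius range (um).
DEFAULT_VESSELNESS_SCALES_UM = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class DifferenceVolume:
    """Signed voxelwise difference; negatives mark subtracted vessel voxels."""

    data: np.ndarray
    spacing: tuple[float, float, float]


def subtract_vessels(enhanced: IntensityVolume, vessels: BinaryVolume) -> DifferenceVolume:
    """enhanced - (vessel mask scaled to the volume's intensity maximum).

    Scaling the binary mask to the global intensity maximum guarantees every
    vessel voxel lands at or below zero while non-vessel voxels are
    untouched.
    """
    require_same_grid(enhanced, vessels)
    peak = float(enhanced.data.max())
    diff = enhanced.data.astype(np.float64) - peak * vessels.data
    return DifferenceVolume(data=diff, spacing=enhanced.spacing)


def clip_negative(diff: DifferenceVolume) -> IntensityVolume:
    """Zero out negatives, keeping only the positive (sinusoid) signal."""
    return IntensityVolume(
        data=np.maximum(diff.data, 0.0), spacing=diff.spacing, provenance="clip_negative"
    )


def tubular_enhance(
    volume: IntensityVolume,
    scales_um: Sequence[float] = DEFAULT_VESSELNESS_SCALES_UM,
) -> IntensityVolume:
    """Multiscale Hessian vesselness (Frangi), bright-tube polarity.

    Scales are physical (um) and converted to filter sigmas with the mean
    voxel pitch; the response is the per-voxel maximum over scales and is
    non-negative.
    """
    if any(s <= 0 for s in scales_um):
        raise ValueError("vesselness scales must be positive")
    mean_spacing = float(np.mean(volume.spacing))
    sigmas = [s / mean_spacing for s in scales_um]
    response = frangi(volume.data.astype(np.float64), sigmas=sigmas, black_ridges=False)
    response = np.maximum(response, 0.0)
    return volume.with_data(response, provenance=volume.provenance + "|frangi")


def segment_sinusoids(
    enhanced_tubular: IntensityVolume,
    vessels: BinaryVolume,
    window_um: float = 25.0,
    offset: float = 0.0,
    intensity: IntensityVolume | None = None,
    floor_fraction: float = 0.85,
    support_fraction: float = 1e-3,
) -> BinaryVolume:
    """Adaptive segmentation into the final sinusoid mask.

    With only the tubular response, the local-mean rule is applied to it
    directly.  When the pre-filter ``intensity`` volume is also supplied,
    the response instead gates candidate tube voxels (response above
    ``support_fraction`` of its maximum) and the decision is made on the
    intensity: above its local mean and above ``floor_fraction`` of its
    robust maximum.  The floor rejects the partial-volume halo around thin
    tubes, whose intensity sits well below the lumen plateau.  Vessel
    voxels are removed, so the compartment masks are disjoint by
    construction.
    """
    require_same_grid(enhanced_tubular, vessels)
    if intensity is None:
        data = adaptive_threshold(enhanced_tubular, window_um=window_um, offset=offset).data
    else:
        require_same_grid(intensity, vessels)
        data = adaptive_threshold(intensity, window_um=window_um, offset=offset).data
        if support_fraction > 0 and enhanced_tubular.data.max() > 0:
            data &= enhanced_tubular.data >= support_fraction * enhanced_tubular.data.max()
        if floor_fraction > 0:
            peak = adaptive_robust_max(intensity.data)
            if peak > 0:
                data &= intensity.data >= floor_fraction * peak
    data = data & ~vessels.data
    return BinaryVolume(data=data, spacing=enhanced_tubular.spacing, role="sinusoid")
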