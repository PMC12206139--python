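"""Depth-compensating enhancement by percentile analysis and histogram matching.

Photoacoustic amplitude falls off with depth (optical attenuation), so deep
slices of a Z stack have a compressed dynamic range.  The compensation used
here is purely statistical: the per-slice 1st and 99th percentile intensities
(I1, I99) are profiled along Z, the slice with the widest I99 - I1 range is
taken as the reference layer, and every other slice is histogram-matched to
it by monotone quantile mapping.  This stretches attenuated deep slices onto
the reference distribution without any physical attenuation model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import BinaryVolume, IntensityVolume, require_same_grid

__all__ = ["PercentileProfile", "percentile_profile", "match_to_reference", "snr_profile"]


@dataclass(frozen=True)
class PercentileProfile:
    """Per-slice intensity percentiles along Z.

    ``i1``/``i99`` are the 1st / 99th percentile of each slice, ``range_``
    their difference, and ``reference_index`` the Z index of the slice with
    the largest range (shallowest slice on ties).
    """

    i1: np.ndarray
    i99: np.ndarray
    reference_index: int

    @property
    def range_(self) -> np.ndarray:
        return self.i99 - self.i1


def percentile_profile(volume: IntensityVolume) -> PercentileProfile:
    """Profile per-slice (I1, I99) and pick the reference layer.

    Percentiles use linear interpolation between order statistics.  Ties in
    the range argmax resolve to the shallowest slice (np.argmax convention).
    """
    flat = volume.data.reshape(volume.shape[0], -1)
    i1, i99 = np.percentile(flat, [1, 99], axis=1)
    ref = int(np.argmax(i99 - i1))
    return PercentileProfile(i1=i1, i99=i99, reference_index=ref)


def _match_slice(source: np.ndarray, ref_values: np.ndarray, ref_quantiles: np.ndarray,
                 bins: int) -> np.ndarray:
    """Monotone quantile mapping of one slice onto the reference CDF."""
    src = source.ravel()
    lo, hi = float(src.min()), float(src.max())
    if hi <= lo:
        return source  # constant slice: nothing to match
    # empirical CDF of the source on `bins` levels over its own min-max range;
    # midpoint rule: a bin holding mass h at cumulative mass c sits at
    # quantile c - h/2, so e.g. a zero-inflated floor maps to the reference's
    # floor instead of halfway up its distribution
    hist, edges = np.histogram(src, bins=bins, range=(lo, hi))
    cum = np.cumsum(hist).astype(np.float64)
    quantiles = (cum - hist / 2.0) / cum[-1]
    mapped_levels = np.interp(quantiles, ref_quantiles, ref_values)
    idx = np.minimum(((src - lo) / (hi - lo) * bins).astype(np.intp), bins - 1)
    return mapped_levels[idx].reshape(source.shape)


def match_to_reference(volume: IntensityVolume, profile: PercentileProfile | None = None,
                       bins: int = 256) -> IntensityVolume:
    """Histogram-match every slice to the reference layer.

    Each non-reference slice's empirical distribution is mapped onto the
    reference slice's by CDF inversion at ``bins`` quantization levels; the
    map is monotone within each slice, so intensity order is preserved.  A
    degenerate reference (zero range) makes matching meaningless: the input
    is returned unchanged with a warning.
    """
    if profile is None:
        profile = percentile_profile(volume)
    ref = volume.data[profile.reference_index].ravel()
    if float(ref.max()) <= float(ref.min()):
        warnings.warn("reference slice has zero intensity range; volume left unchanged",
                      stacklevel=2)
        return volume
    ref_values = np.sort(ref).astype(np.float64)
    ref_quantiles = (np.arange(1, ref_values.size + 1)) / ref_values.size
    out = np.empty_like(volume.data, dtype=np.float64)
    for z in range(volume.shape[0]):
        out[z] = _match_slice(volume.data[z], ref_values, ref_quantiles, bins)
    out = np.maximum(out, 0.0)
    return volume.with_data(out, provenance=volume.provenance + "|histmatch")


def snr_profile(volume: IntensityVolume, foreground: BinaryVolume) -> np.ndarray:
    """Per-slice SNR in dB: 20*log10(mean foreground / std background).

    Slices with no foreground voxels yield NaN; a zero background standard
    deviation yields +inf.  The foreground mask is whatever segmentation the
    caller trusts (typically the combined vessel+sinusoid mask).
    """
    require_same_grid(volume, foreground)
    nz = volume.shape[0]
    snr = np.full(nz, np.nan)
    for z in range(nz):
        fg = foreground.data[z]
        if not fg.any():
            continue
        signal = float(volume.data[z][fg].mean())
        bg = volume.data[z][~fg]
        noise = float(bg.std()) if bg.size else 0.0
        if noise == 0.0:
            snr[z] = np.inf
        else:
            with np.errstate(divide="ignore"):
                snr[z] = 20.0 * np.log10(signal / noise) if signal > 0 else -np.inf
    return snr
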