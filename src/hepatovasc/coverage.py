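"""Sinusoidal coverage of vessels: how completely the mesh canopies each vessel.

For every 26-connected vessel instance V_i the deepest occupied slice Z_max
is found, the sinusoid mask is truncated to the layers strictly above it
(S'), and a vessel voxel counts as covered when the sinusoid mask contains
at least one voxel somewhere above it in the same (x, y) column.  The
coverage rate R_i is the covered fraction of the instance's voxels; vessels
with R_i > 0.5 are high-coverage (HC), the rest low-coverage (LC).

Because the separated vessel and sinusoid masks are disjoint in 3D, the
overlay is columnar (projective) rather than a literal voxel AND — coverage
asks whether sinusoids roof the vessel, not whether they touch it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .vessels import STRUCT_26
from .volumes import BinaryVolume, require_same_grid

__all__ = [
    "vessel_instances",
    "vessel_zmax",
    "sinusoid_upper_mask",
    "coverage_rate",
    "CoverageReport",
    "coverage_report",
    "classify_coverage",
]

HC_THRESHOLD = 0.5


def vessel_instances(vessels: BinaryVolume) -> tuple[np.ndarray, int]:
    """Label 26-connected vessel components; each label is one instance."""
    labels, n = ndi.label(vessels.data, structure=STRUCT_26)
    return labels, int(n)


def vessel_zmax(instance: np.ndarray) -> int:
    """Deepest slice index containing any voxel of the instance."""
    zs = np.flatnonzero(instance.any(axis=(1, 2)))
    if zs.size == 0:
        raise ValueError("empty vessel instance has no Z_max")
    return int(zs[-1])


def sinusoid_upper_mask(sinusoids: BinaryVolume, z_max: int) -> BinaryVolume:
    """S': sinusoid voxels strictly above the vessel's deepest layer.

    Slices z >= z_max are cleared, removing sinusoid signal at or below the
    vessel so only the canopy overhead is counted.
    """
    nz = sinusoids.shape[0]
    if not 0 <= z_max <= nz:
        raise ValueError(f"z_max {z_max} outside volume of {nz} slices")
    data = sinusoids.data.copy()
    data[z_max:] = False
    return BinaryVolume(data=data, spacing=sinusoids.spacing, role="sinusoid")


def coverage_rate(instance: np.ndarray, s_upper: BinaryVolume) -> float:
    """R_i: fraction of instance voxels with sinusoid signal above them.

    Implemented with a top-down cumulative-presence map: presence[z] is
    true in a column once any S' voxel occurred at z' < z; ANDing it with
    the instance slice by slice yields the covered voxels.
    """
    if instance.shape != s_upper.shape:
        raise ValueError("instance and sinusoid mask must share a grid")
    n_inst = int(instance.sum())
    if n_inst == 0:
        raise ValueError("empty vessel instance has no coverage rate")
    presence = np.zeros_like(s_upper.data)
    # exclusive cumulative OR along Z: anything strictly above
    np.logical_or.accumulate(s_upper.data[:-1], axis=0, out=presence[1:])
    covered = int((instance & presence).sum())
    return covered / n_inst


@dataclass(frozen=True)
class CoverageReport:
    """Per-vessel coverage table plus summary statistics."""

    table: pd.DataFrame  # columns: vessel, voxels, z_max, covered, rate, klass

    @property
    def mean_rate(self) -> float:
        return float(self.table["rate"].mean())

    @property
    def hc_fraction(self) -> float:
        return float((self.table["klass"] == "HC").mean())

    @property
    def lc_fraction(self) -> float:
        return float((self.table["klass"] == "LC").mean())

    def summary(self) -> dict:
        return {
            "n_vessels": int(len(self.table)),
            "mean_rate": self.mean_rate,
            "hc_fraction": self.hc_fraction,
            "lc_fraction": self.lc_fraction,
        }


def classify_coverage(rates, threshold: float = HC_THRESHOLD) -> list[str]:
    """HC iff R_i strictly exceeds the threshold; ties are LC."""
    return ["HC" if r > threshold else "LC" for r in rates]


def coverage_report(
    vessels: BinaryVolume, sinusoids: BinaryVolume, threshold: float = HC_THRESHOLD
) -> CoverageReport:
    """Full per-instance coverage analysis of a vessel/sinusoid mask pair."""
    require_same_grid(vessels, sinusoids)
    labels, n = vessel_instances(vessels)
    rows = []
    for i in range(1, n + 1):
        inst = labels == i
        z_max = vessel_zmax(inst)
        s_up = sinusoid_upper_mask(sinusoids, z_max)
        rate = coverage_rate(inst, s_up)
        rows.append(
            {
                "vessel": i,
                "voxels": int(inst.sum()),
                "z_max": z_max,
                "covered": int(round(rate * inst.sum())),
                "rate": rate,
            }
        )
    table = pd.DataFrame(rows, columns=["vessel", "voxels", "z_max", "covered", "rate"])
    table["klass"] = classify_coverage(table["rate"], threshold) if len(table) else []
    return CoverageReport(table=table)
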