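"""Volumetric containers and I/O.

The whole package works on 3D grids laid out ``(z, y, x)`` with per-axis
voxel spacing in micrometres.  Depth increases with the Z index: slice 0 is
the shallowest (closest to the objective), the last slice the deepest.  All
physical quantities (lengths, volumes, radii) are derived from the spacing;
raw voxel counts are never reported to the user.

Intensities are photoacoustic amplitudes in arbitrary units.  They are kept
exactly as stored on disk — any rescaling is the job of the enhancement
stage, not of I/O.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "IntensityVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "write_report",
    "read_report",
]

Spacing = tuple[float, float, float]

_SPACING_SIDECAR_SUFFIX = ".spacing.json"


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    dz, dy, dx = (float(s) for s in spacing)
    if not all(s > 0 and math.isfinite(s) for s in (dz, dy, dx)):
        raise ValueError(f"spacing must be positive and finite, got {(dz, dy, dx)}")
    return (dz, dy, dx)


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D grid of non-negative photoacoustic intensities.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; intensities >= 0 in arbitrary
        amplitude units.
    spacing
        Voxel pitch ``(dz, dy, dx)`` in micrometres.
    provenance
        Free-text tag describing where the volume came from.
    """

    data: np.ndarray
    spacing: Spacing
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if data.shape[0] < 2:
            raise ValueError("volume must have at least 2 Z slices")
        if data.size and float(np.nanmin(data)) < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "IntensityVolume":
        """Same grid, new intensities."""
        return replace(
            self, data=data, provenance=self.provenance if provenance is None else provenance
        )


MaskRole = Literal["vessel", "sinusoid", "other"]


@dataclass(frozen=True)
class BinaryVolume:
    """A boolean mask on the same grid as an :class:`IntensityVolume`."""

    data: np.ndarray
    spacing: Spacing
    role: MaskRole = "other"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if data.dtype != bool:
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_um3

    def same_grid(self, other: "BinaryVolume | IntensityVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_grid(a: BinaryVolume | IntensityVolume, b: BinaryVolume | IntensityVolume) -> None:
    if a.data.shape != b.data.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError(
            f"grid mismatch: {a.data.shape}@{a.spacing} vs {b.data.shape}@{b.spacing}"
        )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, spacing: Sequence[float] | None = None) -> IntensityVolume:
    """Read a multi-page grayscale TIFF stack as an :class:`IntensityVolume`.

    One page per Z slice, page 0 shallowest.  Values are cast to float64
    without rescaling.  ``spacing`` (dz, dy, dx in um) overrides any spacing
    recorded in the sidecar written by :func:`write_volume`; one of the two
    must be available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError(f"{path}: single-page TIFF; a volume needs at least 2 pages")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got array of ndim {data.ndim}")
    if spacing is None:
        sidecar = path.with_name(path.name + _SPACING_SIDECAR_SUFFIX)
        if not sidecar.exists():
            raise ValueError(f"{path}: no spacing given and no sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        spacing = meta["spacing_um"]
    return IntensityVolume(
        data=np.asarray(data, dtype=np.float64), spacing=tuple(spacing), provenance=str(path)
    )


def write_volume(volume: IntensityVolume | BinaryVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus a JSON spacing sidecar.

    Boolean masks are stored as uint8 0/255 pages; intensities as float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if data.dtype == bool:
        out = (data.astype(np.uint8)) * np.uint8(255)
    else:
        out = data.astype(np.float32)
    # photometric set explicitly: 3-slice stacks must not be read back as RGB
    tifffile.imwrite(path, out, photometric="minisblack")
    sidecar = path.with_name(path.name + _SPACING_SIDECAR_SUFFIX)
    sidecar.write_text(json.dumps({"spacing_um": list(volume.spacing)}))
    return path


def read_mask(path: str | Path, spacing: Sequence[float] | None = None,
              role: MaskRole = "other") -> BinaryVolume:
    """Read a mask written by :func:`write_volume` (any non-zero voxel is True)."""
    vol = read_volume(path, spacing)
    return BinaryVolume(data=vol.data > 0, spacing=vol.spacing, role=role)


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

def write_report(records: pd.DataFrame | Sequence[dict], path: str | Path) -> Path:
    """Write a metric table as CSV (default) or JSON, chosen by extension.

    Floats are written at full repr precision; NaN (e.g. an undefined density
    from a division guard) is serialized as an empty CSV field / JSON null so
    it round-trips as NaN.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False, float_format=None)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="records")
    return pd.read_csv(path)
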