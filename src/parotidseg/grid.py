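"""Volume containers: a 3D scalar grid plus its physical geometry.

Axis order is fixed to (z, y, x) throughout the package; ``spacing`` and
``origin`` are stated in the same order, in millimetres.  Direction cosines
other than identity are rejected at read time rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "VALID_LABELS"]

VALID_LABELS = frozenset({0, 1, 2})  # 0 background, 1 left parotid, 2 right parotid


def _check_geometry(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"every grid dimension must be >= 1, got {data.shape}")
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must be (z, y, x) triples")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing and origin in mm.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities.
    spacing : (sz, sy, sx)
        Voxel edge lengths in mm, strictly positive.
    origin : (oz, oy, ox)
        Physical position of voxel (0, 0, 0) in mm.
    units : {"HU", "normalized"}
        Intensity-unit tag.  ``normalized`` promises values in [0, 1].
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing, self.origin)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.units not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity units {self.units!r}")
        if self.units == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"units='normalized' requires values in [0, 1], got [{lo}, {hi}]"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        """Same geometry, new voxel values."""
        return replace(self, data=data, units=units or self.units)

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelVolume:
    """An integer label grid sharing geometry with its paired image.

    Labels are restricted to {0, 1, 2}: background, left parotid, right parotid.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing, self.origin)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label grid must hold integers")
            self.data = self.data.astype(np.int16)
        present = set(np.unique(self.data).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels must be a subset of {{0,1,2}}, got {sorted(present)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )
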