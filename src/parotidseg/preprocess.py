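"""Spatial resampling and HU windowing.

CT volumes from heterogeneous scanners are brought to a common spacing
(default 3.0 mm slices, 0.87 mm in-plane) and their Hounsfield intensities
clipped to a soft-tissue window of (-160, 240) HU, then mapped linearly onto
[0, 1].  Images are interpolated linearly, label masks with nearest
neighbours so no new labels can appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grid import ImageVolume, LabelVolume

__all__ = ["PreprocessConfig", "resample", "resample_labels", "normalize_hu", "preprocess_pair"]


@dataclass
class PreprocessConfig:
    target_spacing: Tuple[float, float, float] = (3.0, 0.87, 0.87)
    hu_window: Tuple[float, float] = (-160.0, 240.0)
    image_interp: str = "linear"
    mask_interp: str = "nearest"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"hu_window requires lo < hi, got {self.hu_window}")


def _output_shape(shape, spacing, target) -> Tuple[int, ...]:
    # round-half-up on the physical extent ratio, at least one voxel per axis
    return tuple(
        max(1, int(np.floor(n * s / t + 0.5)))
        for n, s, t in zip(shape, spacing, target)
    )


def _resample_array(data: np.ndarray, spacing, target, order: int) -> np.ndarray:
    out_shape = _output_shape(data.shape, spacing, target)
    grids = np.meshgrid(
        *[
            np.arange(n, dtype=np.float64) * t / s
            for n, t, s in zip(out_shape, target, spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        data.astype(np.float32 if order > 0 else data.dtype),
        np.stack([g.ravel() for g in grids]),
        order=order,
        mode="nearest",
    )
    return out.reshape(out_shape)


def resample(
    vol: ImageVolume,
    target_spacing: Tuple[float, float, float],
    interp: str = "linear",
) -> ImageVolume:
    """Resample an image onto ``target_spacing``, preserving physical extent.

    Output grid size per axis is round(n_in * s_in / s_target), minimum 1.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be strictly positive")
    order = {"linear": 1, "nearest": 0}[interp]
    data = _resample_array(vol.data, vol.spacing, target_spacing, order)
    if vol.units == "normalized":
        data = np.clip(data, 0.0, 1.0)
    return ImageVolume(
        data=data,
        spacing=tuple(float(t) for t in target_spacing),
        origin=vol.origin,
        units=vol.units,
    )


def resample_labels(
    labels: LabelVolume, target_spacing: Tuple[float, float, float]
) -> LabelVolume:
    """Nearest-neighbour label resampling; never invents labels."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be strictly positive")
    data = _resample_array(labels.data, labels.spacing, target_spacing, order=0)
    return LabelVolume(
        data=data.astype(labels.data.dtype),
        spacing=tuple(float(t) for t in target_spacing),
        origin=labels.origin,
    )


def normalize_hu(
    vol: ImageVolume, window: Tuple[float, float] = (-160.0, 240.0)
) -> ImageVolume:
    """Clip HU to ``window`` and map it linearly onto [0, 1]."""
    if vol.units != "HU":
        raise ValueError(f"normalize_hu expects units='HU', got {vol.units!r}")
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got {window}")
    data = (np.clip(vol.data.astype(np.float32), lo, hi) - lo) / (hi - lo)
    return vol.with_data(data, units="normalized")


def preprocess_pair(
    image: ImageVolume,
    mask: LabelVolume | None,
    cfg: PreprocessConfig | None = None,
) -> Tuple[ImageVolume, LabelVolume | None]:
    """Resample to the common spacing and normalize the HU window."""
    cfg = cfg or PreprocessConfig()
    image = resample(image, cfg.target_spacing, cfg.image_interp)
    image = normalize_hu(image, cfg.hu_window)
    if mask is not None:
        mask = resample_labels(mask, cfg.target_spacing)
        if mask.shape != image.shape:
            raise ValueError("image and mask disagree after resampling")
    return image, mask
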