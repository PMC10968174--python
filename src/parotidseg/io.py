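"""NIfTI reading and writing via nibabel.

On disk NIfTI stores arrays in (x, y, z) order with an affine; in memory the
package works in (z, y, x).  Only axis-aligned affines (identity direction
cosines up to the RAS/LPS sign convention) are accepted — anything else is an
error rather than a silent geometry bug.
"""

from __future__ import annotations

import os
from typing import Union

import nibabel as nib
import numpy as np

from .grid import ImageVolume, LabelVolume

__all__ = ["read_volume", "read_labels", "write_volume", "write_labels"]

_SUPPORTED = (".nii", ".nii.gz")


def _check_path(path: str) -> None:
    name = str(path)
    if not (name.endswith(".nii") or name.endswith(".nii.gz")):
        raise IOError(
            f"unsupported volume format for {path!r}: this build reads/writes NIfTI "
            f"({', '.join(_SUPPORTED)}) only"
        )


def _load(path: Union[str, os.PathLike]):
    _check_path(str(path))
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got ndim={data.ndim} in {path}")
    aff = img.affine
    # require an axis-aligned affine: off-diagonal 3x3 entries must vanish
    lin = aff[:3, :3]
    if not np.allclose(lin - np.diag(np.diag(lin)), 0.0, atol=1e-4):
        raise ValueError(
            f"{path}: non-axis-aligned direction cosines are not supported"
        )
    spacing_xyz = np.abs(np.diag(lin))
    if np.any(spacing_xyz <= 0):
        raise ValueError(f"{path}: degenerate affine (zero spacing)")
    origin_xyz = aff[:3, 3]
    # (x, y, z) -> (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return data, spacing, origin


def read_volume(path: Union[str, os.PathLike]) -> ImageVolume:
    """Read a 3D scalar image; intensities are tagged HU by default."""
    data, spacing, origin = _load(path)
    return ImageVolume(data=data.astype(np.float32), spacing=spacing, origin=origin, units="HU")


def read_labels(path: Union[str, os.PathLike]) -> LabelVolume:
    """Read an integer parotid mask (labels in {0, 1, 2})."""
    data, spacing, origin = _load(path)
    return LabelVolume(data=np.rint(data).astype(np.int16), spacing=spacing, origin=origin)


def _affine(vol) -> np.ndarray:
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def write_volume(vol: ImageVolume, path: Union[str, os.PathLike]) -> None:
    _check_path(str(path))
    data = np.transpose(np.asarray(vol.data), (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(vol)), str(path))


def write_labels(labels: LabelVolume, path: Union[str, os.PathLike]) -> None:
    _check_path(str(path))
    data = np.transpose(np.asarray(labels.data), (2, 1, 0)).astype(np.int16)
    nib.save(nib.Nifti1Image(data, _affine(labels)), str(path))
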