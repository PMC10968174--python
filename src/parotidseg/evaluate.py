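"""Full-volume inference and overlap/distance metrics on the united parotid mask.

Metrics follow the usual binary-mask definitions: DSC = 2TP/(2TP+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN), and HD95 the symmetric
95th-percentile surface distance in millimetres.  Surfaces are foreground
voxels with at least one background 6-neighbour; distances are Euclidean in
physical space.  Cases where either surface is empty carry an undefined HD95
and are excluded (and counted) in aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageVolume, LabelVolume
from .nn import AttentionUNet3D

__all__ = [
    "SegReport",
    "sliding_window_predict",
    "unite_parotids",
    "dsc",
    "hd95",
    "precision_recall",
    "evaluate_cases",
]


@dataclass
class SegReport:
    per_case: pd.DataFrame  # columns: case, dsc, hd95_mm, precision, recall
    dsc_mean: float
    dsc_std: float
    hd95_mean: float
    hd95_std: float
    precision_mean: float
    precision_std: float
    recall_mean: float
    recall_std: float
    hd95_undefined_count: int


def _gaussian_importance(window: Tuple[int, int, int]) -> np.ndarray:
    """Gaussian tile weighting (sigma = window/8), favouring tile centres."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in window], indexing="ij"
    )
    w = np.zeros(window)
    for g, n in zip(grids, window):
        w += (g / (n / 8.0)) ** 2
    return np.exp(-0.5 * w).astype(np.float32) + 1e-6


def sliding_window_predict(
    net: AttentionUNet3D,
    volume: ImageVolume,
    window: Optional[Tuple[int, int, int]] = None,
    overlap: float = 0.5,
) -> LabelVolume:
    """Tile the volume with overlapping windows, accumulate Gaussian-weighted
    class probabilities, and argmax (ties toward the lower label).

    Volumes smaller than the window on any axis are zero-padded, predicted,
    and cropped back.
    """
    window = tuple(window or net.spec.window)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    data = volume.data.astype(np.float32)
    orig_shape = data.shape
    pad = [max(0, w - n) for w, n in zip(window, orig_shape)]
    if any(pad):
        data = np.pad(data, [(0, p) for p in pad])
    shape = data.shape

    step = [max(1, int(round(w * (1.0 - overlap)))) for w in window]
    starts = []
    for n, w, s in zip(shape, window, step):
        pos = list(range(0, max(n - w, 0) + 1, s))
        if pos[-1] != n - w:
            pos.append(n - w)
        starts.append(sorted(set(pos)))

    num_classes = net.spec.num_classes
    acc = np.zeros((num_classes,) + shape, dtype=np.float32)
    weight = np.zeros(shape, dtype=np.float32)
    imp = _gaussian_importance(window)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (
                    slice(z0, z0 + window[0]),
                    slice(y0, y0 + window[1]),
                    slice(x0, x0 + window[2]),
                )
                tile = data[sl][None, None]
                probs = net.forward(tile, train=False, cache=False)[0]
                acc[(slice(None),) + sl] += probs * imp
                weight[sl] += imp
    acc /= weight[None]
    crop = tuple(slice(0, n) for n in orig_shape)
    # argmax with ties broken toward the lower label (numpy argmax does this)
    labels = np.argmax(acc[(slice(None),) + crop], axis=0).astype(np.int16)
    return LabelVolume(data=labels, spacing=volume.spacing, origin=volume.origin)


def unite_parotids(labels: LabelVolume) -> LabelVolume:
    """Merge left (1) and right (2) gland labels into one binary mask."""
    return labels.with_data((labels.data > 0).astype(np.int16))


def _as_bool(mask) -> np.ndarray:
    arr = mask.data if isinstance(mask, (LabelVolume, ImageVolume)) else np.asarray(mask)
    return arr > 0


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask geometry mismatch: {a.shape} vs {b.shape}")


def dsc(pred, gt) -> float:
    """Dice overlap; 1.0 when both masks are empty."""
    p, g = _as_bool(pred), _as_bool(gt)
    _check_same_shape(p, g)
    tp = np.count_nonzero(p & g)
    denom = 2 * tp + np.count_nonzero(p & ~g) + np.count_nonzero(~p & g)
    return 1.0 if denom == 0 else 2.0 * tp / denom


def precision_recall(pred, gt) -> Tuple[float, float]:
    """(precision, recall); empty denominators yield NaN."""
    p, g = _as_bool(pred), _as_bool(gt)
    _check_same_shape(p, g)
    tp = np.count_nonzero(p & g)
    fp = np.count_nonzero(p & ~g)
    fn = np.count_nonzero(~p & g)
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall


def _surface(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbour."""
    if not mask.any():
        return mask
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(pred, gt, spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile surface distance in mm.

    Directed distances run from every surface voxel of one mask to the
    nearest surface voxel of the other (Euclidean, spacing-aware); the
    reported value is the max of the two directed 95th percentiles (linear
    interpolation between order statistics).  NaN if either mask is empty.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    _check_same_shape(p, g)
    if not p.any() or not g.any():
        return float("nan")
    sp = _surface(p)
    sg = _surface(g)
    # EDT of the complement of each surface gives distance-to-that-surface maps
    d_to_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    d_to_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    d_pg = np.percentile(d_to_g[sp], 95)
    d_gp = np.percentile(d_to_p[sg], 95)
    return float(max(d_pg, d_gp))


def evaluate_cases(
    cases: Sequence[Tuple[LabelVolume, LabelVolume]],
    case_ids: Optional[Sequence[str]] = None,
) -> SegReport:
    """Per-case metrics on the united parotid masks plus mean/std aggregates.

    ``cases`` is a sequence of (prediction, ground truth) label volumes.
    Cases with an undefined HD95 are excluded from the HD aggregate and
    counted in ``hd95_undefined_count``.
    """
    if len(cases) == 0:
        raise ValueError("evaluate_cases needs at least one case")
    ids = list(case_ids) if case_ids is not None else [f"case{i}" for i in range(len(cases))]
    rows = []
    for cid, (pred, gt) in zip(ids, cases):
        if pred.shape != gt.shape:
            raise ValueError(f"{cid}: prediction/ground-truth geometry mismatch")
        pu, gu = unite_parotids(pred), unite_parotids(gt)
        prec, rec = precision_recall(pu.data, gu.data)
        rows.append(
            {
                "case": cid,
                "dsc": dsc(pu.data, gu.data),
                "hd95_mm": hd95(pu.data, gu.data, gt.spacing),
                "precision": prec,
                "recall": rec,
            }
        )
    df = pd.DataFrame(rows)
    hd_valid = df["hd95_mm"].dropna()

    def _agg(series):
        vals = series.dropna()
        if len(vals) == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    dsc_m, dsc_s = _agg(df["dsc"])
    hd_m, hd_s = _agg(df["hd95_mm"])
    p_m, p_s = _agg(df["precision"])
    r_m, r_s = _agg(df["recall"])
    return SegReport(
        per_case=df,
        dsc_mean=dsc_m,
        dsc_std=dsc_s,
        hd95_mean=hd_m,
        hd95_std=hd_s,
        precision_mean=p_m,
        precision_std=p_s,
        recall_mean=r_m,
        recall_std=r_s,
        hd95_undefined_count=int(len(df) - len(hd_valid)),
    )
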