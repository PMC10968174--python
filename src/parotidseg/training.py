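"""Patch sampling, the Dice + cross-entropy loss, fold construction and the
optimization loop.

Training follows the patch regime of the source workflow: 96-cube boxes are
drawn from each volume with centres inside the parotid mask with probability
0.8 and outside with probability 0.2, four boxes per volume forming one Adam
batch (learning rate 1e-4).  The loss is CE + (1 - soft Dice) with equal unit
weights.  Model selection keeps the checkpoint with the best united-mask
validation DSC.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import ImageVolume, LabelVolume
from .nn import Adam, AttentionUNet3D, softmax_channels

__all__ = [
    "PatchSpec",
    "LossConfig",
    "TrainConfig",
    "FoldPlan",
    "Checkpoint",
    "sample_patches",
    "one_hot",
    "dice_ce_loss",
    "dice_ce_loss_and_grad",
    "make_folds",
    "train",
]

_SMOOTH = 1e-5  # soft-Dice smoothing in numerator and denominator


@dataclass
class PatchSpec:
    size: Tuple[int, int, int] = (96, 96, 96)
    p_inside: float = 0.8
    p_outside: float = 0.2
    patches_per_volume: int = 4

    def __post_init__(self) -> None:
        if abs(self.p_inside + self.p_outside - 1.0) > 1e-9:
            raise ValueError("p_inside + p_outside must equal 1")
        if not 0.0 <= self.p_inside <= 1.0:
            raise ValueError("p_inside must lie in [0, 1]")
        if self.patches_per_volume < 1:
            raise ValueError("patches_per_volume must be >= 1")


@dataclass
class LossConfig:
    w_dice: float = 1.0
    w_ce: float = 1.0

    def __post_init__(self) -> None:
        if self.w_dice < 0 or self.w_ce < 0 or (self.w_dice == 0 and self.w_ce == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 600
    validation_every: int = 10
    seed: int = 0
    # cap on the global gradient norm; tames the rare catastrophic batch
    # (a background-only patch set can otherwise throw the Dice term)
    max_grad_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FoldPlan:
    k: int
    assignment: Dict[str, int]
    source_tags: Dict[str, str]

    def fold_members(self, fold: int) -> List[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


@dataclass
class Checkpoint:
    state: Dict[str, np.ndarray]
    val_dsc: float
    epoch: int


def sample_patches(
    image: ImageVolume,
    mask: LabelVolume,
    spec: Optional[PatchSpec] = None,
    rng_seed: int = 0,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Draw ``patches_per_volume`` (image, mask) boxes of ``spec.size``.

    A box drawn "inside" is centred on a foreground voxel, "outside" on a
    background voxel.  Boxes crossing the border are padded with 0.0 for the
    image (normalized air) and 0 for the mask.
    """
    spec = spec or PatchSpec()
    if image.shape != mask.shape:
        raise ValueError("image and mask must share geometry")
    rng = np.random.default_rng(rng_seed)
    fg = np.argwhere(mask.data > 0)
    bg = np.argwhere(mask.data == 0)
    if spec.p_inside > 0 and len(fg) == 0:
        raise ValueError("mask has no foreground voxels but p_inside > 0")
    if spec.p_outside > 0 and len(bg) == 0:
        raise ValueError("mask has no background voxels but p_outside > 0")

    size = np.array(spec.size)
    half = size // 2
    img = image.data.astype(np.float32)
    msk = mask.data
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.patches_per_volume):
        pool = fg if rng.random() < spec.p_inside else bg
        center = pool[rng.integers(len(pool))]
        lo = center - half
        hi = lo + size
        pad_lo = np.maximum(-lo, 0)
        pad_hi = np.maximum(hi - np.array(img.shape), 0)
        src = tuple(
            slice(max(l, 0), min(h, n)) for l, h, n in zip(lo, hi, img.shape)
        )
        ip = np.zeros(spec.size, dtype=np.float32)
        mp = np.zeros(spec.size, dtype=msk.dtype)
        dst = tuple(
            slice(pl, s - ph) for pl, ph, s in zip(pad_lo, pad_hi, spec.size)
        )
        ip[dst] = img[src]
        mp[dst] = msk[src]
        out.append((ip, mp))
    return out


def one_hot(labels: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """(... ) int labels -> (C, ...) float32 one-hot."""
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 0)


def _soft_dice_terms(probs: np.ndarray, target: np.ndarray):
    # sums over batch and voxels, per class
    axes = (0,) + tuple(range(2, probs.ndim))
    inter = (probs * target).sum(axis=axes)
    denom = probs.sum(axis=axes) + target.sum(axis=axes)
    return inter, denom


def dice_ce_loss(
    pred_probs: np.ndarray, target_onehot: np.ndarray, cfg: Optional[LossConfig] = None
) -> float:
    """L = w_ce * mean-voxel CE  +  w_dice * (1 - mean-class soft DSC).

    ``pred_probs`` and ``target_onehot`` are (C, ...) or (N, C, ...) arrays on
    the same grid; the soft DSC uses probabilities with smoothing 1e-5.
    """
    cfg = cfg or LossConfig()
    if pred_probs.shape != target_onehot.shape:
        raise ValueError(
            f"shape mismatch: {pred_probs.shape} vs {target_onehot.shape}"
        )
    p = pred_probs if pred_probs.ndim == 5 else pred_probs[None]
    y = target_onehot if target_onehot.ndim == 5 else target_onehot[None]
    n_vox = p.shape[0] * np.prod(p.shape[2:])
    ce = float(-(y * np.log(np.clip(p, 1e-12, None))).sum() / n_vox)
    inter, denom = _soft_dice_terms(p, y)
    dsc = (2.0 * inter + _SMOOTH) / (denom + _SMOOTH)
    return cfg.w_ce * ce + cfg.w_dice * float(1.0 - dsc.mean())


def dice_ce_loss_and_grad(
    logits: np.ndarray, target_onehot: np.ndarray, cfg: Optional[LossConfig] = None
) -> Tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the logits (pre-softmax activations)."""
    cfg = cfg or LossConfig()
    squeeze = logits.ndim == 4
    if squeeze:
        logits = logits[None]
        target_onehot = target_onehot[None]
    p = softmax_channels(logits)
    y = target_onehot.astype(p.dtype)
    loss = dice_ce_loss(p, y, cfg)

    n_vox = p.shape[0] * np.prod(p.shape[2:])
    g_logits = cfg.w_ce * (p - y) / n_vox

    inter, denom = _soft_dice_terms(p, y)
    num_classes = p.shape[1]
    # d(1 - mean_c dsc_c)/dp_c, then chain through softmax
    d_dsc_dp = (
        2.0 * y * (denom + _SMOOTH).reshape(1, -1, 1, 1, 1)
        - (2.0 * inter + _SMOOTH).reshape(1, -1, 1, 1, 1)
    ) / np.square(denom + _SMOOTH).reshape(1, -1, 1, 1, 1)
    g_p = -d_dsc_dp / num_classes  # dL_dice/dp
    dot = (g_p * p).sum(axis=1, keepdims=True)
    g_logits = g_logits + cfg.w_dice * p * (g_p - dot)
    g_logits = g_logits.astype(p.dtype)
    return loss, (g_logits[0] if squeeze else g_logits)


def make_folds(
    sample_ids: Sequence[str],
    source_tags: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Partition samples into k folds, per-source counts balanced to +-1.

    Sources are interleaved with a running fold offset so that total fold
    sizes also balance (48 + 42 samples -> five folds of 18).  Deterministic
    under ``seed`` and invariant to the input ordering.
    """
    if len(sample_ids) != len(source_tags):
        raise ValueError("sample_ids and source_tags must align")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample ids must be unique")
    tags = dict(zip(sample_ids, source_tags))
    by_source: Dict[str, List[str]] = {}
    for sid in sorted(sample_ids):
        by_source.setdefault(tags[sid], []).append(sid)
    for src, members in by_source.items():
        if k > len(members):
            raise ValueError(
                f"k={k} exceeds the {len(members)} samples of source {src!r}"
            )
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    offset = 0
    for src in sorted(by_source):
        members = list(by_source[src])
        rng.shuffle(members)
        for j, sid in enumerate(members):
            assignment[sid] = (offset + j) % k
        offset = (offset + len(members)) % k
    return FoldPlan(k=k, assignment=assignment, source_tags=tags)


def train(
    train_set: Sequence[Tuple[ImageVolume, LabelVolume]],
    val_set: Sequence[Tuple[ImageVolume, LabelVolume]],
    net: AttentionUNet3D,
    cfg: Optional[TrainConfig] = None,
    loss_cfg: Optional[LossConfig] = None,
    patch_spec: Optional[PatchSpec] = None,
) -> Tuple[Checkpoint, pd.DataFrame]:
    """Optimize ``net`` and return the best-validation-DSC checkpoint.

    Each epoch resamples ``patch_spec.patches_per_volume`` boxes per training
    volume; the boxes of one volume form one Adam batch.  Every
    ``cfg.validation_every`` epochs the united-parotid DSC is measured on the
    validation volumes with full-volume sliding-window inference and the best
    state is retained.
    """
    from .evaluate import dsc, sliding_window_predict, unite_parotids

    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be nonempty")
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    patch_spec = patch_spec or PatchSpec(size=tuple(net.spec.window))
    if tuple(patch_spec.size) != tuple(net.spec.window):
        raise ValueError("patch size must equal the network window")

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    best = Checkpoint(state=copy.deepcopy(net.state_dict()), val_dsc=-1.0, epoch=0)

    def validate() -> float:
        scores = []
        for img, msk in val_set:
            pred = sliding_window_predict(net, img, window=net.spec.window)
            scores.append(dsc(unite_parotids(pred).data, unite_parotids(msk).data))
        return float(np.mean(scores))

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for vi in order:
            img, msk = train_set[vi]
            patches = sample_patches(
                img, msk, patch_spec, rng_seed=int(rng.integers(2**31 - 1))
            )
            x = np.stack([p[0][None] for p in patches])
            y = np.stack([one_hot(p[1], net.spec.num_classes) for p in patches])
            logits = net.forward_logits(x, train=True, cache=True)
            loss, g = dice_ce_loss_and_grad(logits, y, loss_cfg)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            net.backward(g)
            grads = net.gradients()
            if cfg.max_grad_norm:
                total = np.sqrt(sum(float(np.sum(v**2)) for v in grads.values()))
                if total > cfg.max_grad_norm:
                    scale = cfg.max_grad_norm / total
                    for v in grads.values():
                        v *= scale
            opt.step(net.parameters(), grads)
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dsc": np.nan}
        if epoch % cfg.validation_every == 0 or epoch == cfg.epochs:
            vd = validate()
            row["val_dsc"] = vd
            if vd > best.val_dsc:
                best = Checkpoint(
                    state=copy.deepcopy(net.state_dict()), val_dsc=vd, epoch=epoch
                )
        rows.append(row)

    net.load_state_dict(best.state)
    _recalibrate_bn(net, [img for img, _ in train_set])
    best.state = copy.deepcopy(net.state_dict())
    return best, pd.DataFrame(rows)


def _recalibrate_bn(net: AttentionUNet3D, volumes, passes: int = 3) -> None:
    """Re-estimate batch-norm running statistics on the inference tiling.

    Training batches are gland-centred patches; inference sees 50%-overlap
    sliding-window tiles, most of which are background.  Forwarding the tile
    distribution in training mode after checkpoint selection removes that
    normalization mismatch.
    """
    from .nn.ops import BatchNorm3d

    window = net.spec.window
    bns = [l for l in net._layers().values() if isinstance(l, BatchNorm3d)]
    saved = [b.momentum for b in bns]
    for b in bns:
        b.momentum = 0.05
    try:
        for _ in range(passes):
            for vol in volumes:
                data = vol.data.astype(np.float32)
                pad = [max(0, w - n) for w, n in zip(window, data.shape)]
                if any(pad):
                    data = np.pad(data, [(0, p) for p in pad])
                tiles = []
                for z0 in _tile_starts(data.shape[0], window[0]):
                    for y0 in _tile_starts(data.shape[1], window[1]):
                        for x0 in _tile_starts(data.shape[2], window[2]):
                            tiles.append(
                                data[z0 : z0 + window[0], y0 : y0 + window[1], x0 : x0 + window[2]]
                            )
                x = np.stack(tiles)[:, None]
                net.forward_logits(x, train=True, cache=False)
    finally:
        for b, m in zip(bns, saved):
            b.momentum = m


def _tile_starts(n: int, w: int):
    step = max(1, w // 2)
    pos = list(range(0, max(n - w, 0) + 1, step))
    if pos[-1] != n - w:
        pos.append(n - w)
    return sorted(set(pos))
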