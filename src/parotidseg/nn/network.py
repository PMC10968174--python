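"""The attention-gated 3D U-Net segmenter.

Encoder: five stages of two (conv3 -> batch-norm -> ReLU) blocks, max-pooled
by 2 between stages, filter counts 16/32/64/128 with a 256-filter bottleneck.
Decoder: transpose-convolution upsampling, an attention gate on every skip
connection, concatenation, one merge conv block per stage, and a final
1-kernel convolution to the 3 classes followed by a per-voxel softmax.

The attention gate projects the skip features x (pooled to the coarse grid)
and the gating signal g through 1-kernel convolutions, adds them, applies
ReLU, a second 1-kernel convolution and a sigmoid, then resamples the
resulting coefficients back to x's grid with trilinear interpolation and
multiplies them onto x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ops import (
    AvgPool2x,
    BatchNorm3d,
    Conv3d,
    ConvTranspose2x,
    Layer,
    MaxPool2x,
    ReLU,
    Sigmoid,
    UpsampleLinear2x,
    softmax_channels,
)

__all__ = ["NetworkSpec", "AttentionGate", "AttentionUNet3D", "build_network"]


@dataclass
class NetworkSpec:
    in_channels: int = 1
    num_classes: int = 3
    encoder_filters: Tuple[int, ...] = (16, 32, 64, 128)
    bottleneck_filters: int = 256
    window: Tuple[int, int, int] = (96, 96, 96)

    def __post_init__(self) -> None:
        depth = len(self.encoder_filters)
        if any(w % (2**depth) != 0 or w < 2**depth for w in self.window):
            raise ValueError(
                f"window {self.window} must be divisible by 2^{depth} for {depth} poolings"
            )
        for a, b in zip(self.encoder_filters, self.encoder_filters[1:]):
            if b != 2 * a:
                raise ValueError("encoder filter counts must double per stage")
        if self.bottleneck_filters != 2 * self.encoder_filters[-1]:
            raise ValueError("bottleneck must double the deepest encoder filters")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


class _ConvBlock:
    """conv3 -> batch-norm -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        self.conv = Conv3d(in_ch, out_ch, 3, rng)
        self.bn = BatchNorm3d(out_ch)
        self.act = ReLU()

    def layers(self) -> List[Layer]:
        return [self.conv, self.bn, self.act]

    def forward(self, x, train=False, cache=False):
        x = self.conv.forward(x, train, cache)
        x = self.bn.forward(x, train, cache)
        return self.act.forward(x, train, cache)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.act.backward(gy)))


class AttentionGate:
    """Multiplicative attention gate on a skip connection.

    x carries fine-grid skip features, g the gating signal from one level
    coarser.  Coefficients are computed on g's grid and trilinearly resampled
    to x's grid, so the output has exactly x's shape and lies in x * [0, 1].
    """

    def __init__(self, x_channels: int, g_channels: int, rng: np.random.Generator,
                 inter_channels: Optional[int] = None) -> None:
        self.x_channels, self.g_channels = x_channels, g_channels
        inter = inter_channels if inter_channels is not None else max(1, x_channels // 2)
        self.inter_channels = inter
        self.pool = AvgPool2x()
        self.theta = Conv3d(x_channels, inter, 1, rng)
        self.phi = Conv3d(g_channels, inter, 1, rng)
        self.act = ReLU()
        self.psi = Conv3d(inter, 1, 1, rng)
        self.sig = Sigmoid()
        self.up = UpsampleLinear2x()
        self._cache = None

    def layers(self) -> List[Layer]:
        return [self.pool, self.theta, self.phi, self.act, self.psi, self.sig, self.up]

    def forward(self, x: np.ndarray, g: np.ndarray, train=False, cache=False):
        if x.shape[1] != self.x_channels or g.shape[1] != self.g_channels:
            raise ValueError(
                f"attention gate configured for ({self.x_channels}, {self.g_channels}) "
                f"channels, got ({x.shape[1]}, {g.shape[1]})"
            )
        if tuple(2 * s for s in g.shape[2:]) != x.shape[2:]:
            raise ValueError(
                f"gating signal must sit one level coarser than x: {g.shape[2:]} vs {x.shape[2:]}"
            )
        xc = self.pool.forward(x, train, cache)
        a = self.theta.forward(xc, train, cache) + self.phi.forward(g, train, cache)
        a = self.act.forward(a, train, cache)
        a = self.sig.forward(self.psi.forward(a, train, cache), train, cache)
        alpha = self.up.forward(a, train, cache)  # (N, 1, D, H, W) in [0, 1]
        if cache:
            self._cache = (x, alpha)
        return x * alpha

    def backward(self, gy: np.ndarray):
        x, alpha = self._cache
        gx = gy * alpha
        galpha = (gy * x).sum(axis=1, keepdims=True).astype(np.float32)
        ga = self.sig.backward(self.up.backward(galpha))
        ga = self.act.backward(self.psi.backward(ga))
        gg = self.phi.backward(ga)
        gx += self.pool.backward(self.theta.backward(ga))
        return gx, gg

    def coefficients(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Expose the post-sigmoid, post-resampling attention coefficients."""
        self.forward(x, g, train=False, cache=True)
        _, alpha = self._cache
        self._cache = None
        return alpha


class AttentionUNet3D:
    """Encoder-bottleneck-decoder segmenter with gated skip connections."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.encoder_filters
        fb = spec.bottleneck_filters
        self.enc: List[Tuple[_ConvBlock, _ConvBlock]] = []
        in_ch = spec.in_channels
        for ch in f:
            self.enc.append((_ConvBlock(in_ch, ch, rng), _ConvBlock(ch, ch, rng)))
            in_ch = ch
        self.pools = [MaxPool2x() for _ in f]
        self.bottleneck = (_ConvBlock(f[-1], fb, rng), _ConvBlock(fb, fb, rng))
        # decoder from deep to shallow; deep_ch halves at every stage
        self.ups: List[ConvTranspose2x] = []
        self.gates: List[AttentionGate] = []
        self.merges: List[_ConvBlock] = []
        deep_ch = fb
        for ch in reversed(f):
            self.ups.append(ConvTranspose2x(deep_ch, ch, rng))
            self.gates.append(AttentionGate(ch, deep_ch, rng))
            self.merges.append(_ConvBlock(2 * ch, ch, rng))
            deep_ch = ch
        self.head = Conv3d(f[0], spec.num_classes, 1, rng)
        # bias the final layer toward the background-heavy class prior so
        # early training does not first collapse to all-background and then
        # have to dig itself out (standard imbalance initialization)
        priors = np.full(spec.num_classes, 0.05, dtype=np.float32)
        priors[0] = 1.0 - 0.05 * (spec.num_classes - 1)
        self.head.params["b"] = np.log(priors)
        self._acts = None

    # -- parameter bookkeeping -------------------------------------------------

    def _modules(self) -> Dict[str, object]:
        mods: Dict[str, object] = {}
        for i, (b1, b2) in enumerate(self.enc):
            mods[f"enc{i}a"], mods[f"enc{i}b"] = b1, b2
        mods["botta"], mods["bottb"] = self.bottleneck
        for i in range(len(self.ups)):
            mods[f"up{i}"] = self.ups[i]
            mods[f"gate{i}"] = self.gates[i]
            mods[f"merge{i}"] = self.merges[i]
        mods["head"] = self.head
        return mods

    def _layers(self) -> Dict[str, Layer]:
        out: Dict[str, Layer] = {}
        for name, mod in self._modules().items():
            if isinstance(mod, Layer):
                out[name] = mod
            elif isinstance(mod, _ConvBlock):
                out[f"{name}.conv"], out[f"{name}.bn"] = mod.conv, mod.bn
            elif isinstance(mod, AttentionGate):
                out[f"{name}.theta"] = mod.theta
                out[f"{name}.phi"] = mod.phi
                out[f"{name}.psi"] = mod.psi
        return out

    def parameters(self) -> Dict[str, np.ndarray]:
        return {
            f"{ln}/{pn}": arr
            for ln, layer in self._layers().items()
            for pn, arr in layer.params.items()
        }

    def gradients(self) -> Dict[str, np.ndarray]:
        return {
            f"{ln}/{pn}": arr
            for ln, layer in self._layers().items()
            for pn, arr in layer.grads.items()
        }

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = dict(self.parameters())
        for ln, layer in self._layers().items():
            if isinstance(layer, BatchNorm3d):
                state[f"{ln}/running_mean"] = layer.running_mean
                state[f"{ln}/running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        layers = self._layers()
        for key, arr in state.items():
            ln, pn = key.rsplit("/", 1)
            layer = layers[ln]
            if pn == "running_mean":
                layer.running_mean = np.array(arr, dtype=np.float32)
            elif pn == "running_var":
                layer.running_var = np.array(arr, dtype=np.float32)
            else:
                layer.params[pn] = np.array(arr, dtype=np.float32)

    # -- forward / backward ----------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channel(s)")
        if tuple(x.shape[2:]) != tuple(self.spec.window):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured window {self.spec.window}"
            )
        skips = []
        h = x.astype(np.float32)
        for i, (b1, b2) in enumerate(self.enc):
            h = b2.forward(b1.forward(h, train, cache), train, cache)
            skips.append(h)
            h = self.pools[i].forward(h, train, cache)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h, train, cache), train, cache)
        if cache:
            self._acts = []
        for i, skip in enumerate(reversed(skips)):
            up = self.ups[i].forward(h, train, cache)
            gated = self.gates[i].forward(skip, h, train, cache)
            h = self.merges[i].forward(
                np.concatenate([gated, up], axis=1), train, cache
            )
            if cache:
                self._acts.append(skip.shape[1])
        return self.head.forward(h, train, cache)

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        """Per-voxel class probabilities (N, num_classes, D, H, W)."""
        return softmax_channels(self.forward_logits(x, train, cache))

    def backward(self, glogits: np.ndarray) -> None:
        """Backprop from d(loss)/d(logits); gradients land in the layers."""
        gh = self.head.backward(glogits)
        g_skips = [None] * len(self.merges)
        for i in range(len(self.merges) - 1, -1, -1):
            gcat = self.merges[i].backward(gh)
            ch = self._acts[i]
            ggate = np.ascontiguousarray(gcat[:, :ch])
            gup = np.ascontiguousarray(gcat[:, ch:])
            gskip, gg_gate = self.gates[i].backward(ggate)
            gg_up = self.ups[i].backward(gup)
            g_skips[i] = gskip
            gh = gg_gate + gg_up  # gradient w.r.t. the stage's input feature map
        gh = self.bottleneck[0].backward(self.bottleneck[1].backward(gh))
        for i in range(len(self.enc) - 1, -1, -1):
            gh = self.pools[i].backward(gh)
            gh = gh + g_skips[len(self.enc) - 1 - i]
            b1, b2 = self.enc[i]
            gh = b1.backward(b2.backward(gh))

    # -- persistence -----------------------------------------------------------

    def save(self, path: str, extra: Optional[Dict] = None) -> None:
        meta = {
            "in_channels": self.spec.in_channels,
            "num_classes": self.spec.num_classes,
            "encoder_filters": list(self.spec.encoder_filters),
            "bottleneck_filters": self.spec.bottleneck_filters,
            "window": list(self.spec.window),
            "extra": extra or {},
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "AttentionUNet3D":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        spec = NetworkSpec(
            in_channels=meta["in_channels"],
            num_classes=meta["num_classes"],
            encoder_filters=tuple(meta["encoder_filters"]),
            bottleneck_filters=meta["bottleneck_filters"],
            window=tuple(meta["window"]),
        )
        net = cls(spec, seed=0)
        net.load_state_dict(state)
        return net


def build_network(spec: Optional[NetworkSpec] = None, seed: int = 0) -> AttentionUNet3D:
    """Construct the segmenter with reproducible seeded initialization."""
    return AttentionUNet3D(spec or NetworkSpec(), seed=seed)
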