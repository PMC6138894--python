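"""Multi-scale fully convolutional segmentation network.

The architecture follows a VGG-style encoder: five scales of 3x3
convolutions (widths 16/32/64/128/256, two or three convolutions per scale,
each followed by batch normalisation and ReLU), 2x2 max pooling between
scales.  Every scale's features are upsampled to full resolution in one shot
by a strided transposed convolution (scale 1 passes through unchanged), all
five are concatenated, and a three-layer 1x1 head ending in softmax emits
per-pixel probabilities over K classes.  Excluding transposed convolutions
the default network has 16 convolutional layers; the residual variant
replaces scales 3-5 with identity-skip residual blocks for a total of 33.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Layer,
    MaxPool2x2,
    ReLU,
    Softmax,
)

__all__ = [
    "NetworkSpec",
    "Network",
    "ResidualBlock",
    "build_fcn",
    "count_conv_layers",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_WIDTHS = (16, 32, 64, 128, 256)
DEFAULT_CONVS = (2, 2, 3, 3, 3)
DEFAULT_HEAD = (64, 64)
DEFAULT_RESIDUAL_BLOCKS = (4, 4, 5)  # scales 3..5; totals 33 conv layers


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the segmentation network."""

    n_classes: int
    widths: tuple[int, ...] = DEFAULT_WIDTHS
    convs_per_scale: tuple[int, ...] = DEFAULT_CONVS
    head_widths: tuple[int, ...] = DEFAULT_HEAD
    upsample_width: int = 16
    variant: str = "vgg"
    residual_blocks: tuple[int, ...] = DEFAULT_RESIDUAL_BLOCKS

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 label classes")
        if len(self.widths) != len(self.convs_per_scale):
            raise ValueError("widths and convs_per_scale must align")
        if self.variant not in ("vgg", "residual"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "residual" and len(self.residual_blocks) != max(
            0, len(self.widths) - 2
        ):
            raise ValueError("residual_blocks must cover scales 3..S")

    @property
    def n_scales(self) -> int:
        return len(self.widths)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "widths": list(self.widths),
            "convs_per_scale": list(self.convs_per_scale),
            "head_widths": list(self.head_widths),
            "upsample_width": self.upsample_width,
            "variant": self.variant,
            "residual_blocks": list(self.residual_blocks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            n_classes=int(d["n_classes"]),
            widths=tuple(d["widths"]),
            convs_per_scale=tuple(d["convs_per_scale"]),
            head_widths=tuple(d["head_widths"]),
            upsample_width=int(d["upsample_width"]),
            variant=d["variant"],
            residual_blocks=tuple(d.get("residual_blocks", DEFAULT_RESIDUAL_BLOCKS)),
        )

    @classmethod
    def reduced(cls, n_classes: int, widths=(4, 8, 16), convs=(2, 2, 2),
                head=(16,), upsample_width: int = 8) -> "NetworkSpec":
        """A small configuration for desk-scale experiments and tests."""
        return cls(n_classes, tuple(widths), tuple(convs), tuple(head),
                   upsample_width)


def _conv_bn_relu(c_in: int, c_out: int, kernel: int, rng) -> list[Layer]:
    return [Conv2D(c_in, c_out, kernel, rng), BatchNorm2D(c_out), ReLU()]


class ResidualBlock(Layer):
    """Two 3x3 convolutions with an identity skip (zero-padded on width change)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.branch = (
            _conv_bn_relu(c_in, c_out, 3, rng)
            + [Conv2D(c_out, c_out, 3, rng), BatchNorm2D(c_out)]
        )
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.branch:
            h = layer(h)
        if self.c_in != self.c_out:
            pad = self.c_out - self.c_in
            skip = np.pad(x, ((0, 0), (0, pad), (0, 0), (0, 0)))
        else:
            skip = x
        return self.relu(h + skip)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad)
        gb = g
        for layer in reversed(self.branch):
            gb = layer.backward(gb)
        gskip = g[:, : self.c_in] if self.c_in != self.c_out else g
        return gb + gskip

    def params(self):
        out = []
        for layer in self.branch:
            out.extend(layer.params())
        return out

    @property
    def training(self):  # propagate mode to inner layers
        return self.branch[1].training

    @training.setter
    def training(self, flag: bool) -> None:
        for layer in self.branch:
            layer.training = flag


class Network:
    """Realised network: multi-scale encoder, one-shot upsampling, 1x1 head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.scales: list[list[Layer]] = []
        self.pools: list[MaxPool2x2] = []
        c_prev = 1
        for s, (width, n_conv) in enumerate(zip(spec.widths, spec.convs_per_scale)):
            layers: list[Layer] = []
            if spec.variant == "residual" and s >= 2:
                n_blocks = spec.residual_blocks[s - 2]
                c = c_prev
                for _ in range(n_blocks):
                    layers.append(ResidualBlock(c, width, rng))
                    c = width
            else:
                c = c_prev
                for _ in range(n_conv):
                    layers.extend(_conv_bn_relu(c, width, 3, rng))
                    c = width
            self.scales.append(layers)
            if s > 0:
                self.pools.append(MaxPool2x2())
            c_prev = width
        # one-shot upsamplers; scale 1 joins the concatenation untouched
        self.upsamplers: list[ConvTranspose2D | None] = [None]
        for s in range(1, spec.n_scales):
            self.upsamplers.append(
                ConvTranspose2D(spec.widths[s], spec.upsample_width, 2**s, rng)
            )
        cat_width = spec.widths[0] + spec.upsample_width * (spec.n_scales - 1)
        self.head: list[Layer] = []
        c = cat_width
        for w in spec.head_widths:
            self.head.extend(_conv_bn_relu(c, w, 1, rng))
            c = w
        self.head.append(Conv2D(c, spec.n_classes, 1, rng))
        self.softmax = Softmax()
        self.scale_sides: list[int] = []

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self):
        for layers in self.scales:
            yield from layers
        yield from self.pools
        for up in self.upsamplers:
            if up is not None:
                yield up
        yield from self.head
        yield self.softmax

    def body_layers(self):
        """Layers shared between variants of the prediction head."""
        for layers in self.scales:
            yield from layers
        yield from self.pools
        for up in self.upsamplers:
            if up is not None:
                yield up

    def set_training(self, flag: bool) -> None:
        for layer in self._all_layers():
            layer.training = flag

    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    # -- forward / backward ------------------------------------------------

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-pixel class probabilities for a batch of 2D slices.

        ``batch`` is ``(B, H, W)`` or ``(B, H, W, 1)`` channels-last in [0, 1];
        output is ``(B, H, W, K)``.
        """
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim == 4 and x.shape[-1] == 1:
            x = x[..., 0]
        if x.ndim != 3:
            raise ValueError(f"expected (B, H, W) batch, got shape {batch.shape}")
        h, w = x.shape[1:]
        down = 2 ** (self.spec.n_scales - 1)
        if h % down or w % down:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by the downsampling factor {down}"
            )
        self.set_training(training)
        z = x[:, None, :, :]
        feats = []
        self.scale_sides = []
        for s, layers in enumerate(self.scales):
            if s > 0:
                z = self.pools[s - 1](z)
            for layer in layers:
                z = layer(z)
            self.scale_sides.append(z.shape[2])
            feats.append(z)
        ups = [
            feats[s] if self.upsamplers[s] is None else self.upsamplers[s](feats[s])
            for s in range(self.spec.n_scales)
        ]
        self._split = [u.shape[1] for u in ups]
        z = np.concatenate(ups, axis=1)
        for layer in self.head:
            z = layer(z)
        probs = self.softmax(z)
        return probs.transpose(0, 2, 3, 1)

    def backward_from_logit_grad(self, dlogits: np.ndarray) -> None:
        """Backpropagate from the gradient w.r.t. pre-softmax scores (B, H, W, K)."""
        g = np.ascontiguousarray(dlogits.transpose(0, 3, 1, 2), dtype=np.float32)
        for layer in reversed(self.head):
            g = layer.backward(g)
        # split concat gradient back into per-scale branches
        offsets = np.cumsum([0] + self._split)
        dfeats = []
        for s in range(self.spec.n_scales):
            gs = g[:, offsets[s] : offsets[s + 1]]
            if self.upsamplers[s] is not None:
                gs = self.upsamplers[s].backward(gs)
            dfeats.append(gs)
        gdown = None
        for s in range(self.spec.n_scales - 1, -1, -1):
            gs = dfeats[s] if gdown is None else dfeats[s] + gdown
            for layer in reversed(self.scales[s]):
                gs = layer.backward(gs)
            gdown = self.pools[s - 1].backward(gs) if s > 0 else None

    __call__ = forward


def build_fcn(n_classes: int, variant: str = "vgg", seed: int = 0,
              spec: NetworkSpec | None = None) -> Network:
    """Construct the segmentation network for ``n_classes`` output classes."""
    if spec is None:
        spec = NetworkSpec(n_classes, variant=variant)
    return Network(spec, seed=seed)


def count_conv_layers(net: Network) -> int:
    """Count convolutional layers of any kernel size, excluding transposed ones."""
    n = 0
    for layers in net.scales:
        for layer in layers:
            if isinstance(layer, Conv2D):
                n += 1
            elif isinstance(layer, ResidualBlock):
                n += sum(isinstance(l, Conv2D) for l in layer.branch)
    n += sum(isinstance(layer, Conv2D) for layer in net.head)
    return n


# ---------------------------------------------------------------------------
# Checkpoints: weights in .npz, spec in a sidecar YAML readable on its own.
# ---------------------------------------------------------------------------


def _state_arrays(net: Network) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    i = 0
    for layer in net._all_layers():
        for p, _ in layer.params():
            state[f"p{i:04d}"] = p
            i += 1
        if isinstance(layer, BatchNorm2D):
            state[f"p{i:04d}"] = layer.running_mean
            i += 1
            state[f"p{i:04d}"] = layer.running_var
            i += 1
        elif isinstance(layer, ResidualBlock):
            for sub in layer.branch:
                if isinstance(sub, BatchNorm2D):
                    state[f"p{i:04d}"] = sub.running_mean
                    i += 1
                    state[f"p{i:04d}"] = sub.running_var
                    i += 1
    return state


def _normalize_ckpt_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    return path


def save_checkpoint(net: Network, path: str | Path) -> None:
    path = _normalize_ckpt_path(path)
    np.savez(path, **_state_arrays(net))
    spec_path = path.with_name(path.name + ".spec.yaml")
    spec_path.write_text(yaml.safe_dump(net.spec.to_dict(), sort_keys=False))


def read_spec(path: str | Path) -> NetworkSpec:
    """Read the architecture description of a checkpoint without its weights."""
    path = _normalize_ckpt_path(path)
    spec_path = path.with_name(path.name + ".spec.yaml")
    return NetworkSpec.from_dict(yaml.safe_load(spec_path.read_text()))


def load_checkpoint(path: str | Path) -> Network:
    path = _normalize_ckpt_path(path)
    spec = read_spec(path)
    net = Network(spec)
    with np.load(path) as data:
        state = _state_arrays(net)
        if set(state) != set(data.files):
            raise ValueError("checkpoint does not match the network spec")
        for key, target in state.items():
            target[...] = data[key]
    return net
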