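"""Loss, on-the-fly augmentation, optimisation schedule and fine-tuning.

Training follows a fixed-length Adam schedule (learning rate 0.001, 50,000
iterations by default, mini-batches of 20 image slices) on slices sampled
uniformly with replacement.  Each mini-batch is augmented on the fly with
random translation, rotation, scaling and intensity variation before being
fed to the network.  The loss is the mean cross entropy between the
predicted probabilistic label map and the annotated label map, optionally
excluding named structures (used when fine-tuning to a reduced label
scheme).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import CineStack, LabelScheme, SegmentationMap, preprocess
from .network import Conv2D, Network, NetworkSpec, build_fcn
from .nn import Adam

__all__ = [
    "TrainConfig",
    "LossValue",
    "cross_entropy_loss",
    "augment_batch",
    "apply_affine_pair",
    "train",
    "fine_tune",
    "make_training_slices",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the optimisation schedule and augmentation ranges.

    All augmentation ranges are symmetric about the identity transform.
    """

    learning_rate: float = 0.001
    iterations: int = 50_000
    batch_size: int = 20
    translation_px: float = 15.0
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_scale: tuple[float, float] = (0.9, 1.1)
    intensity_offset: float = 0.05
    augment: bool = True
    seed: int = 0
    fine_tune_iterations: int = 10_000
    log_every: int = 0  # 0 disables progress printing

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.iterations < 0 or self.fine_tune_iterations < 0:
            raise ValueError("iteration counts must be >= 0")
        lo, hi = self.scale_range
        if not math.isclose(lo * hi, 1.0, rel_tol=0.05) and not (lo <= 1.0 <= hi):
            raise ValueError("scale_range must bracket 1.0")


@dataclass(frozen=True)
class LossValue:
    value: float
    n_pixels: int

    def __float__(self) -> float:
        return self.value


def _ignore_indices(ignore, scheme: LabelScheme | None) -> set[int]:
    if not ignore:
        return set()
    out = set()
    for item in ignore:
        if isinstance(item, (int, np.integer)):
            out.add(int(item))
        else:
            if scheme is None:
                raise ValueError("a LabelScheme is required to ignore structures by name")
            out.add(scheme.index(item))
    return out


def cross_entropy_loss(
    pred: np.ndarray,
    truth: np.ndarray | SegmentationMap,
    ignore=None,
    scheme: LabelScheme | None = None,
) -> LossValue:
    """Mean cross entropy -log p(true class) over contributing pixels.

    ``pred`` is a channels-last probability map ``(..., K)``; ``truth`` an
    integer label array of the matching spatial shape.  Pixels whose true
    structure is listed in ``ignore`` (names or indices) are excluded from
    the mean.  Probabilities are clipped below at 1e-12 before the log.
    """
    if isinstance(truth, SegmentationMap):
        scheme = scheme or truth.scheme
        truth = truth.labels
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape[:-1] != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape[:-1]} vs truth {truth.shape}")
    k = pred.shape[-1]
    if truth.size and (truth.min() < 0 or truth.max() >= k):
        raise ValueError("truth labels outside prediction classes")
    mask = np.ones(truth.shape, dtype=bool)
    for idx in _ignore_indices(ignore, scheme):
        mask &= truth != idx
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no pixels contribute to the loss")
    p_true = np.take_along_axis(pred, truth[..., None].astype(np.int64), axis=-1)[..., 0]
    ce = -np.log(np.clip(p_true[mask], _PROB_FLOOR, None))
    return LossValue(float(ce.mean()), n)


def _ce_logit_grad(probs: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gradient of the masked mean CE w.r.t. pre-softmax scores."""
    k = probs.shape[-1]
    onehot = np.eye(k, dtype=np.float32)[truth]
    g = (probs - onehot) * mask[..., None]
    return (g / max(int(mask.sum()), 1)).astype(np.float32)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def apply_affine_pair(
    image: np.ndarray,
    labels: np.ndarray,
    rotation_deg: float = 0.0,
    translation_px: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one rigid+scale transform to an image (bilinear) and its labels
    (nearest-neighbour), rotating about the image centre."""
    theta = math.radians(rotation_deg)
    c, s = math.cos(theta), math.sin(theta)
    matrix = np.array([[c, -s], [s, c]]) / scale
    centre = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    offset = centre - matrix @ (centre + np.asarray(translation_px, dtype=float))
    img = ndimage.affine_transform(image, matrix, offset=offset, order=1, mode="constant")
    lab = ndimage.affine_transform(labels, matrix, offset=offset, order=0, mode="constant")
    return img.astype(np.float32), lab.astype(labels.dtype)


def augment_batch(
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform each (image, label) slice pair of a mini-batch.

    The same spatial transform is applied to image and labels; the intensity
    transform touches the image only, re-clipped to [0, 1].
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    out_img = np.empty_like(images)
    out_lab = np.empty_like(labels)
    lo_s, hi_s = cfg.scale_range
    lo_i, hi_i = cfg.intensity_scale
    for b in range(images.shape[0]):
        rot = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        trans = rng.uniform(-cfg.translation_px, cfg.translation_px, size=2)
        scale = rng.uniform(lo_s, hi_s)
        img, lab = apply_affine_pair(images[b], labels[b], rot, tuple(trans), scale)
        gain = rng.uniform(lo_i, hi_i)
        bias = rng.uniform(-cfg.intensity_offset, cfg.intensity_offset)
        out_img[b] = np.clip(img * gain + bias, 0.0, 1.0)
        out_lab[b] = lab
    return out_img, out_lab


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------


def make_training_slices(
    cases,
    size: int = 192,
    frames: str = "edes",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract paired (image, label) 2D slices from phantom cases.

    ``frames`` selects ``"edes"`` (annotated ED/ES frames only, as manual
    analysis provides) or ``"all"``.
    """
    from .image_io import restore_geometry  # noqa: F401  (symmetry with preprocess)

    slices = []
    for case in cases:
        stack, truth = case.stack, case.truth
        batch, rec = preprocess(stack, size=size)
        n_frames = stack.n_frames
        if frames == "edes":
            frame_ids = sorted({case.ed_frame, case.es_frame})
        elif frames == "all":
            frame_ids = list(range(n_frames))
        else:
            raise ValueError(f"frames must be 'edes' or 'all', got {frames!r}")
        for s in range(stack.n_slices):
            for f in frame_ids:
                img = batch[s * n_frames + f]
                lab = _crop_labels(truth.labels[:, :, s, f], rec)
                slices.append((img, lab))
    return slices


def _crop_labels(lab2d: np.ndarray, rec) -> np.ndarray:
    """Forward crop/pad of a 2D label slice matching :func:`preprocess`."""
    rows, cols = rec.original_shape
    r_off, c_off = rec.crop_offset
    r_pad, c_pad = rec.pad_before
    h, w = min(rec.size, rows), min(rec.size, cols)
    out = np.zeros((rec.size, rec.size), dtype=lab2d.dtype)
    out[r_pad : r_pad + h, c_pad : c_pad + w] = lab2d[r_off : r_off + h, c_off : c_off + w]
    return out


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------


def train(
    net: Network,
    slices,
    cfg: TrainConfig | None = None,
    ignore=None,
    scheme: LabelScheme | None = None,
) -> tuple[Network, list[float]]:
    """Run the fixed-length Adam schedule on uniformly sampled mini-batches.

    ``slices`` is a sequence of (image2d, label2d) pairs.  Returns the
    trained network (modified in place) and the per-iteration loss history.
    """
    cfg = cfg or TrainConfig()
    pool = list(slices)
    if not pool:
        raise ValueError("training requires at least one annotated slice")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate)
    ignore_idx = _ignore_indices(ignore, scheme)
    history: list[float] = []
    k = net.spec.n_classes
    for it in range(cfg.iterations):
        picks = rng.integers(0, len(pool), size=cfg.batch_size)
        imgs = np.stack([pool[i][0] for i in picks])
        labs = np.stack([pool[i][1] for i in picks])
        if cfg.augment:
            imgs, labs = augment_batch(imgs, labs, cfg, rng)
        probs = net.forward(imgs, training=True)
        mask = np.ones(labs.shape, dtype=bool)
        for idx in ignore_idx:
            mask &= labs != idx
        if not mask.any():
            raise ValueError("mini-batch has no pixels contributing to the loss")
        # ignored pixels may carry out-of-range sentinels; gather safely
        safe = np.where(mask, labs, 0).astype(np.int64)
        p_true = np.take_along_axis(probs, safe[..., None], axis=-1)[..., 0]
        loss = float(-np.log(np.clip(p_true[mask], _PROB_FLOOR, None)).mean())
        if not math.isfinite(loss):
            raise FloatingPointError(
                f"loss became non-finite at iteration {it} (lr={cfg.learning_rate})"
            )
        net.backward_from_logit_grad(_ce_logit_grad(probs, safe, mask))
        opt.step()
        history.append(loss)
        if cfg.log_every and (it + 1) % cfg.log_every == 0:
            print(f"iter {it + 1}/{cfg.iterations}  loss {loss:.4f}")
    return net, history


def fine_tune(
    net: Network,
    slices,
    new_scheme: LabelScheme,
    cfg: TrainConfig | None = None,
    data_scheme: LabelScheme | None = None,
) -> Network:
    """Adapt a trained network to a (possibly reduced) label scheme.

    When the class count changes, the final prediction layer is rebuilt for
    the new scheme's K; all other parameters carry over.  ``slices`` carry
    labels under ``data_scheme`` (default: ``new_scheme``); pixels whose
    structure has no counterpart in ``new_scheme`` are excluded from the
    loss.  Training then runs for ``cfg.fine_tune_iterations`` steps.
    """
    cfg = cfg or TrainConfig()
    data_scheme = data_scheme or new_scheme
    k_new = new_scheme.n_classes
    if k_new != net.spec.n_classes:
        net = _rebuild_head(net, k_new)

    # translate data labels into the new scheme; unmapped structures -> ignore
    lut = np.zeros(data_scheme.n_classes, dtype=np.int64)
    ignored_values: set[int] = set()
    sentinel = k_new  # out-of-range marker, masked out below
    for idx, name in enumerate(data_scheme.structures):
        if name in new_scheme:
            lut[idx] = new_scheme.index(name)
        else:
            lut[idx] = sentinel
            ignored_values.add(sentinel)
    remapped = []
    for img, lab in slices:
        remapped.append((img, lut[lab]))

    ft_cfg = replace(cfg, iterations=cfg.fine_tune_iterations)
    if ft_cfg.iterations == 0:
        return net
    trained, _ = train(net, remapped, ft_cfg, ignore=ignored_values)
    return trained


def _rebuild_head(net: Network, k_new: int) -> Network:
    """Replace the final 1x1 prediction layer for a new class count."""
    old_final = net.head[-1]
    assert isinstance(old_final, Conv2D) and old_final.kernel == 1
    rng = np.random.default_rng(0)
    net.head[-1] = Conv2D(old_final.c_in, k_new, 1, rng)
    net.spec = replace(net.spec, n_classes=k_new)
    return net
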