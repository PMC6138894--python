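"""Full-stack segmentation: per-slice forward pass, argmax, geometry restore."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_io import (
    CineStack,
    LabelScheme,
    SegmentationMap,
    preprocess,
    restore_geometry,
    scheme_for_view,
)
from .network import Network

__all__ = ["segment_stack", "argmax_labels"]


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the trailing class axis; ties -> lowest index."""
    return np.argmax(probs, axis=-1)  # np.argmax already returns the first maximum


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def segment_stack(
    net: Network,
    stack: CineStack,
    frames: str = "all",
    scheme: LabelScheme | None = None,
    size: int = 192,
    batch_slices: int = 10,
    keep_largest_component: bool = False,
) -> SegmentationMap:
    """Segment a cine stack with a trained network.

    Every requested frame's slices are preprocessed, forwarded through the
    network, argmaxed per pixel and restored to the original geometry; frames
    not requested are filled with background.  ``frames`` is ``"all"`` or
    ``"edes"`` (first and middle frame of the cycle, the conventional ED/ES
    positions when ED is at acquisition start).
    """
    scheme = scheme or scheme_for_view(stack.view)
    if net.spec.n_classes != scheme.n_classes:
        raise ValueError(
            f"network predicts {net.spec.n_classes} classes but the "
            f"{scheme.view} scheme has {scheme.n_classes}"
        )
    rows, cols, n_slices, n_frames = stack.shape
    if frames == "all":
        frame_ids = list(range(n_frames))
    elif frames == "edes":
        frame_ids = sorted({0, n_frames // 2}) if n_frames > 1 else [0]
    else:
        raise ValueError(f"frames must be 'all' or 'edes', got {frames!r}")

    batch, rec = preprocess(stack, size=size)
    labels192 = np.zeros((size, size, n_slices, n_frames), dtype=np.uint8)
    jobs = [(s, f) for s in range(n_slices) for f in frame_ids]
    for start in range(0, len(jobs), batch_slices):
        chunk = jobs[start : start + batch_slices]
        x = np.stack([batch[s * n_frames + f] for s, f in chunk])
        probs = net.forward(x, training=False)
        lab = argmax_labels(probs).astype(np.uint8)
        for i, (s, f) in enumerate(chunk):
            labels192[:, :, s, f] = lab[i]

    if keep_largest_component:
        for f in frame_ids:
            for s in range(n_slices):
                sl = labels192[:, :, s, f]
                for k in range(1, scheme.n_classes):
                    m = sl == k
                    if m.any():
                        keep = _largest_component(m)
                        sl[m & ~keep] = 0

    restored = restore_geometry(labels192, rec)
    return SegmentationMap(restored, scheme, stack.spacing_mm, stack.frame_interval_ms)
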