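"""Segmentation agreement metrics: Dice, mean contour distance, Hausdorff.

Dice is the overlap ratio 2|A n B| / (|A| + |B|) between two voxel sets.
The contour metrics act on structure boundaries dA, dB extracted under
4-connectivity, with pixel centres mapped to physical mm coordinates:

* mean contour distance: the symmetric average
  1/(2|dA|) sum_{p in dA} d(p, dB) + 1/(2|dB|) sum_{q in dB} d(q, dA);
* Hausdorff distance: max(max_{p in dA} d(p, dB), max_{q in dB} d(q, dA)),

where d(p, d) is the minimal Euclidean distance from a point to a contour.
Cases with an empty structure are flagged undefined and excluded from
aggregates (never silently reported as 0 or 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import SegmentationMap

__all__ = [
    "Contour",
    "StructureMetrics",
    "CaseMetrics",
    "dice",
    "extract_contour",
    "mean_contour_distance",
    "hausdorff_distance",
    "evaluate_case",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class Contour:
    """Boundary points of one structure on one 2D slice, in mm coordinates."""

    points_mm: np.ndarray  # (n, 2)

    @property
    def is_empty(self) -> bool:
        return self.points_mm.shape[0] == 0

    def __len__(self) -> int:
        return self.points_mm.shape[0]


@dataclass
class StructureMetrics:
    dice: float | None
    mcd_mm: float | None
    hd_mm: float | None
    n_slices: int  # 2D slices contributing to the distance metrics


@dataclass
class CaseMetrics:
    """Per-structure agreement metrics for one case."""

    per_structure: dict[str, StructureMetrics]

    def __getitem__(self, structure: str) -> StructureMetrics:
        return self.per_structure[structure]


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    return mask.astype(bool) if mask.dtype != bool else mask


def dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """Overlap 2|A n B| / (|A| + |B|); None (undefined) when both are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def extract_contour(mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> Contour:
    """Boundary pixels of a 2D mask (pixels with a 4-neighbour outside),
    with centres scaled to mm.  Image-border pixels of the mask count as
    boundary."""
    mask = _as_bool(mask)
    if mask.ndim != 2:
        raise ValueError("extract_contour expects a 2D mask")
    if not mask.any():
        return Contour(np.empty((0, 2)))
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    boundary = mask & ~interior
    rows, cols = np.nonzero(boundary)
    pts = np.stack([rows * spacing[0], cols * spacing[1]], axis=1).astype(float)
    return Contour(pts)


def _directed_min_distances(src: Contour, dst: Contour) -> np.ndarray:
    """d(p, dst) for every point p of src, via a KD-tree."""
    tree = cKDTree(dst.points_mm)
    d, _ = tree.query(src.points_mm)
    return d


def mean_contour_distance(ca: Contour, cb: Contour) -> float | None:
    """Symmetric mean point-to-contour distance in mm; None if a contour is empty."""
    if ca.is_empty or cb.is_empty:
        return None
    d_ab = _directed_min_distances(ca, cb)
    d_ba = _directed_min_distances(cb, ca)
    return 0.5 * float(d_ab.mean()) + 0.5 * float(d_ba.mean())


def hausdorff_distance(ca: Contour, cb: Contour) -> float | None:
    """Maximum point-to-contour distance in mm; None if a contour is empty."""
    if ca.is_empty or cb.is_empty:
        return None
    d_ab = _directed_min_distances(ca, cb)
    d_ba = _directed_min_distances(cb, ca)
    return max(float(d_ab.max()), float(d_ba.max()))


def evaluate_case(
    auto: SegmentationMap,
    manual: SegmentationMap,
    frames: np.ndarray | None = None,
    dice_mode: str = "3d",
    distance_mode: str = "2d",
) -> CaseMetrics:
    """Per-structure Dice / MCD / HD between two segmentations of one case.

    Dice is computed on the voxel sets pooled over the manually annotated
    frames (``dice_mode="slice"`` averages per-slice values instead).  The
    distance metrics are evaluated in-plane per 2D slice where the structure
    is nonempty in both maps, then averaged (MCD) and maximised (HD) over
    slices; ``distance_mode="3d"`` treats the whole annotated grid as one
    3D point cloud using the slice separation for the third coordinate.
    """
    if auto.shape != manual.shape:
        raise ValueError(f"grid mismatch: {auto.shape} vs {manual.shape}")
    if auto.scheme != manual.scheme:
        raise ValueError("segmentations use different label schemes")
    if frames is None:
        frames = manual.annotated_frames()
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValueError("no annotated frames in common")
    spacing2d = auto.spacing_mm[:2]

    results: dict[str, StructureMetrics] = {}
    for structure in auto.scheme.foreground():
        a4 = auto.mask(structure)[:, :, :, frames]
        m4 = manual.mask(structure)[:, :, :, frames]
        dc = _pooled_dice(a4, m4, dice_mode)
        if distance_mode == "2d":
            mcds, hds = [], []
            for fi in range(frames.size):
                for s in range(auto.shape[2]):
                    ca = extract_contour(a4[:, :, s, fi], spacing2d)
                    cb = extract_contour(m4[:, :, s, fi], spacing2d)
                    m = mean_contour_distance(ca, cb)
                    if m is None:
                        continue
                    mcds.append(m)
                    hds.append(hausdorff_distance(ca, cb))
            n = len(mcds)
            mcd = float(np.mean(mcds)) if n else None
            hd = float(np.max(hds)) if n else None
        elif distance_mode == "3d":
            ca, cb = (_contour_3d(x4, auto.spacing_mm) for x4 in (a4, m4))
            mcd, hd, n = _distance_3d(ca, cb)
        else:
            raise ValueError(f"unknown distance_mode {distance_mode!r}")
        results[structure] = StructureMetrics(dc, mcd, hd, n)
    return CaseMetrics(results)


def _pooled_dice(a4: np.ndarray, m4: np.ndarray, mode: str) -> float | None:
    if mode == "3d":
        return dice(a4, m4)
    if mode == "slice":
        vals = []
        for fi in range(a4.shape[3]):
            for s in range(a4.shape[2]):
                d = dice(a4[:, :, s, fi], m4[:, :, s, fi])
                if d is not None:
                    vals.append(d)
        return float(np.mean(vals)) if vals else None
    raise ValueError(f"unknown dice_mode {mode!r}")


def _contour_3d(mask4: np.ndarray, spacing) -> np.ndarray:
    pts = []
    for fi in range(mask4.shape[3]):
        for s in range(mask4.shape[2]):
            c = extract_contour(mask4[:, :, s, fi], spacing[:2])
            if not c.is_empty:
                z = np.full((len(c), 1), s * spacing[2])
                pts.append(np.hstack([c.points_mm, z]))
    return np.vstack(pts) if pts else np.empty((0, 3))


def _distance_3d(pa: np.ndarray, pb: np.ndarray):
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        return None, None, 0
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa)[0]
    d_ba = ta.query(pb)[0]
    mcd = 0.5 * float(d_ab.mean()) + 0.5 * float(d_ba.mean())
    hd = max(float(d_ab.max()), float(d_ba.max()))
    return mcd, hd, 1
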