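"""Cine stack / segmentation containers, NIfTI I/O and model-input preprocessing.

The unit of analysis is a 4D cine stack indexed ``(row, col, slice, frame)``
with physical spacing in mm and an optional frame interval in ms.  Images are
prepared for the network by cropping/padding every 2D slice to a fixed square
window (192 x 192 by default) and min-max normalising intensities to [0, 1].
The geometric step is exactly invertible through a :class:`CropRecord`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "CineStack",
    "LabelScheme",
    "SegmentationMap",
    "CropRecord",
    "SHORT_AXIS_SCHEME",
    "LAX_2CH_SCHEME",
    "LAX_4CH_SCHEME",
    "scheme_for_view",
    "load_cine",
    "save_cine",
    "load_segmentation",
    "save_segmentation",
    "preprocess",
    "restore_geometry",
]

VIEWS = ("short_axis", "long_axis_2ch", "long_axis_4ch")

MODEL_INPUT_SIZE = 192


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a cine stack / label map."""


@dataclass(frozen=True)
class LabelScheme:
    """Ordered integer coding of anatomical structures for one view.

    Index 0 is always background; structure indices are contiguous.
    """

    view: str
    structures: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if not self.structures or self.structures[0] != "background":
            raise ValueError("index 0 must be 'background'")
        if len(set(self.structures)) != len(self.structures):
            raise ValueError("duplicate structure names")

    @property
    def n_classes(self) -> int:
        return len(self.structures)

    def index(self, structure: str) -> int:
        try:
            return self.structures.index(structure)
        except ValueError:
            raise KeyError(f"structure {structure!r} not in scheme") from None

    def __contains__(self, structure: str) -> bool:
        return structure in self.structures

    def foreground(self) -> tuple[str, ...]:
        return self.structures[1:]


SHORT_AXIS_SCHEME = LabelScheme(
    "short_axis", ("background", "lv_cavity", "lv_myocardium", "rv_cavity")
)
LAX_2CH_SCHEME = LabelScheme("long_axis_2ch", ("background", "la_cavity"))
LAX_4CH_SCHEME = LabelScheme("long_axis_4ch", ("background", "la_cavity", "ra_cavity"))

_VIEW_SCHEMES = {
    "short_axis": SHORT_AXIS_SCHEME,
    "long_axis_2ch": LAX_2CH_SCHEME,
    "long_axis_4ch": LAX_4CH_SCHEME,
    # CLI shorthands
    "sa": SHORT_AXIS_SCHEME,
    "2ch": LAX_2CH_SCHEME,
    "4ch": LAX_4CH_SCHEME,
}


def scheme_for_view(view: str) -> LabelScheme:
    try:
        return _VIEW_SCHEMES[view]
    except KeyError:
        raise ValueError(f"no label scheme for view {view!r}") from None


@dataclass
class CineStack:
    """4D intensity array (row, col, slice, frame) with physical metadata."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    frame_interval_ms: float | None = None
    view: str = "short_axis"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim == 2:
            vox = vox[:, :, None, None]
        elif vox.ndim == 3:
            vox = vox[:, :, :, None]
        elif vox.ndim != 4:
            raise ValueError(f"expected 2D-4D voxel array, got {vox.ndim}D")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel intensities must be finite")
        self.voxels = vox
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive components, got {sp}")
        self.spacing_mm = sp
        if self.frame_interval_ms is not None and self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.view.startswith("long_axis") and self.n_slices != 1:
            raise ValueError("long-axis views carry exactly 1 slice")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class SegmentationMap:
    """Integer label map on a cine-stack grid under a view-specific scheme."""

    labels: np.ndarray
    scheme: LabelScheme
    spacing_mm: tuple[float, float, float]
    frame_interval_ms: float | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integral")
            lab = lab.astype(np.int64)
        if lab.ndim == 2:
            lab = lab[:, :, None, None]
        elif lab.ndim == 3:
            lab = lab[:, :, :, None]
        elif lab.ndim != 4:
            raise ValueError(f"expected 2D-4D label array, got {lab.ndim}D")
        if lab.size and (lab.min() < 0 or lab.max() >= self.scheme.n_classes):
            raise ValueError("label values outside scheme alphabet")
        self.labels = lab.astype(np.uint8 if self.scheme.n_classes <= 255 else np.uint16)
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive components, got {sp}")
        self.spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.labels.shape

    @property
    def n_frames(self) -> int:
        return self.labels.shape[3]

    def mask(self, structure: str, frame: int | None = None) -> np.ndarray:
        """Binary mask of ``structure`` (whole 4D grid or one frame)."""
        idx = self.scheme.index(structure)
        lab = self.labels if frame is None else self.labels[:, :, :, frame]
        return lab == idx

    def annotated_frames(self) -> np.ndarray:
        """Indices of frames containing at least one foreground voxel."""
        fg = (self.labels > 0).any(axis=(0, 1, 2))
        return np.flatnonzero(fg)


@dataclass(frozen=True)
class CropRecord:
    """Bookkeeping to invert the crop/pad step of :func:`preprocess`."""

    original_shape: tuple[int, int]
    crop_offset: tuple[int, int]   # top-left of the window in the original image
    pad_before: tuple[int, int]    # zero padding applied on the top/left of output
    size: int = MODEL_INPUT_SIZE


def _crop_pad_params(n: int, size: int, offset: int | None) -> tuple[int, int]:
    """Return (crop_offset, pad_before) along one axis."""
    if n >= size:
        off = (n - size) // 2 if offset is None else offset
        if off < 0 or off + size > n:
            raise ValueError("crop window outside image")
        return off, 0
    return 0, (size - n) // 2


def preprocess(
    stack: CineStack,
    size: int = MODEL_INPUT_SIZE,
    center_offset: tuple[int, int] | None = None,
) -> tuple[np.ndarray, CropRecord]:
    """Crop/pad every slice to ``size x size`` and min-max normalise to [0, 1].

    Returns a model-ready batch of shape ``(n_slices * n_frames, size, size)``
    (slice-major ordering: batch index = slice * n_frames + frame) and the
    :class:`CropRecord` inverting the geometric transform.  Each 2D slice is
    normalised independently; constant slices map to all zeros.
    """
    rows, cols, n_slices, n_frames = stack.shape
    ro = co = None
    if center_offset is not None:
        ro, co = center_offset
    r_off, r_pad = _crop_pad_params(rows, size, ro)
    c_off, c_pad = _crop_pad_params(cols, size, co)
    rec = CropRecord((rows, cols), (r_off, c_off), (r_pad, c_pad), size)

    batch = np.zeros((n_slices * n_frames, size, size), dtype=np.float32)
    src = stack.voxels[r_off : r_off + min(size, rows), c_off : c_off + min(size, cols)]
    h, w = src.shape[:2]
    for s in range(n_slices):
        for f in range(n_frames):
            sl = src[:, :, s, f]
            lo, hi = float(sl.min()), float(sl.max())
            out = np.zeros((size, size), dtype=np.float32)
            if hi > lo:
                out[r_pad : r_pad + h, c_pad : c_pad + w] = (sl - lo) / (hi - lo)
            batch[s * n_frames + f] = out
    return batch, rec


def restore_geometry(labels: np.ndarray, rec: CropRecord) -> np.ndarray:
    """Invert the crop/pad of :func:`preprocess` on a label array.

    ``labels`` has leading spatial dims ``(size, size, ...)``; the output has
    leading dims ``rec.original_shape`` with out-of-window pixels set to 0.
    """
    labels = np.asarray(labels)
    if labels.shape[:2] != (rec.size, rec.size):
        raise ValueError(
            f"expected leading dims {(rec.size, rec.size)}, got {labels.shape[:2]}"
        )
    rows, cols = rec.original_shape
    r_off, c_off = rec.crop_offset
    r_pad, c_pad = rec.pad_before
    h = min(rec.size, rows)
    w = min(rec.size, cols)
    out = np.zeros((rows, cols) + labels.shape[2:], dtype=labels.dtype)
    out[r_off : r_off + h, c_off : c_off + w] = labels[
        r_pad : r_pad + h, c_pad : c_pad + w
    ]
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O.  Geometry convention: affine = diag(spacing); pixdim[4] carries
# the frame interval with msec time units.
# ---------------------------------------------------------------------------


def _make_nifti(data: np.ndarray, spacing, frame_interval_ms) -> nib.Nifti1Image:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = list(spacing[: data.ndim])
    if data.ndim == 4:
        zooms.append(frame_interval_ms if frame_interval_ms else 0.0)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "msec")
    return img


def save_cine(stack: CineStack, path: str | Path) -> None:
    img = _make_nifti(stack.voxels.astype(np.float32), stack.spacing_mm,
                      stack.frame_interval_ms)
    nib.save(img, str(path))


def load_cine(path: str | Path, view: str = "short_axis") -> CineStack:
    """Read a 2D/3D/4D NIfTI file into a :class:`CineStack`.

    Spacing comes from the header zooms; for 4D files the fourth zoom is the
    frame interval (converted to ms from the header time units).  Missing or
    zero temporal metadata leaves ``frame_interval_ms`` unset with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (2, 3, 4):
        raise FormatError(f"expected 2D-4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    spacing += (1.0,) * (3 - len(spacing))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    frame_interval = None
    if data.ndim == 4:
        t = float(zooms[3]) if len(zooms) > 3 else 0.0
        _, t_unit = img.header.get_xyzt_units()
        factor = {"sec": 1000.0, "msec": 1.0, "usec": 1e-3}.get(t_unit)
        if t > 0 and factor is not None:
            frame_interval = t * factor
        else:
            warnings.warn(
                f"{path.name}: no usable temporal metadata; frame interval unset",
                stacklevel=2,
            )
    return CineStack(data.astype(np.float32), spacing, frame_interval, view)


def save_segmentation(seg: SegmentationMap, path: str | Path) -> None:
    """Write a label map as an unsigned-integer NIfTI plus a scheme sidecar YAML."""
    path = Path(path)
    img = _make_nifti(seg.labels, seg.spacing_mm, seg.frame_interval_ms)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        yaml.safe_dump(
            {"view": seg.scheme.view, "structures": list(seg.scheme.structures)},
            sort_keys=False,
        )
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".scheme.yaml")
    return path.with_suffix(".scheme.yaml")


def load_segmentation(path: str | Path, scheme: LabelScheme | None = None) -> SegmentationMap:
    """Read a label map; the scheme comes from the sidecar YAML unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: label map is not integer-valued")
        data = np.round(data).astype(np.int64)
    if scheme is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"no scheme given and no sidecar found at {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        scheme = LabelScheme(meta["view"], tuple(meta["structures"]))
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    spacing += (1.0,) * (3 - len(spacing))
    frame_interval = None
    if data.ndim == 4 and len(zooms) > 3 and zooms[3] > 0:
        _, t_unit = img.header.get_xyzt_units()
        factor = {"sec": 1000.0, "msec": 1.0, "usec": 1e-3}.get(t_unit)
        if factor is not None:
            frame_interval = float(zooms[3]) * factor
    return SegmentationMap(data, scheme, spacing, frame_interval)
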