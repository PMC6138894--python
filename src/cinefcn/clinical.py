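"""Clinical measures derived from segmentations.

Chamber volumes are voxel counts times the volume per voxel; LV mass is the
myocardial volume times the density 1.05 g/mL.  End-diastole / end-systole
are located on the cavity volume curve (argmax / argmin), and stroke volume,
ejection fraction and cardiac output follow from the ED/ES volumes and the
cardiac cycle duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import SegmentationMap

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "ClinicalMeasures",
    "chamber_volume",
    "lv_mass",
    "volume_curve",
    "ed_es_frames",
    "measures_report",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class ClinicalMeasures:
    """Ventricular/atrial volumes, LV mass and derived functional measures.

    Volumes in mL, mass in gram, EF in percent, CO in L/min.  Fields are
    ``None`` when the scheme lacks the structure or the quantity is
    undefined (e.g. EF with zero EDV).
    """

    ed_frame: int
    es_frame: int
    LVEDV_mL: float | None = None
    LVESV_mL: float | None = None
    LVM_g: float | None = None
    RVEDV_mL: float | None = None
    RVESV_mL: float | None = None
    LVSV_mL: float | None = None
    LVEF_pct: float | None = None
    LVCO_Lmin: float | None = None
    RVSV_mL: float | None = None
    RVEF_pct: float | None = None
    RVCO_Lmin: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def chamber_volume(seg: SegmentationMap, structure: str, frame: int) -> float:
    """Volume (mL) of a structure at one frame: voxel count x volume per voxel."""
    idx = seg.scheme.index(structure)  # raises KeyError for unknown structures
    n_vox = int((seg.labels[:, :, :, frame] == idx).sum())
    voxel_mm3 = float(np.prod(seg.spacing_mm))
    return n_vox * voxel_mm3 / 1000.0


def lv_mass(seg: SegmentationMap, frame: int) -> float:
    """LV myocardial mass (gram) = myocardial volume x 1.05 g/mL."""
    if "lv_myocardium" not in seg.scheme:
        raise KeyError("scheme has no lv_myocardium structure")
    return chamber_volume(seg, "lv_myocardium", frame) * MYOCARDIAL_DENSITY_G_PER_ML


def _primary_cavity(seg: SegmentationMap) -> str:
    for name in ("lv_cavity", "la_cavity"):
        if name in seg.scheme:
            return name
    raise KeyError("scheme has no LV/LA cavity structure")


def volume_curve(seg: SegmentationMap, structure: str | None = None) -> np.ndarray:
    """Per-frame volume (mL) of a structure (default: the primary cavity)."""
    structure = structure or _primary_cavity(seg)
    return np.array(
        [chamber_volume(seg, structure, f) for f in range(seg.n_frames)]
    )


def ed_es_frames(seg: SegmentationMap, structure: str | None = None) -> tuple[int, int]:
    """(ED, ES) frame indices: argmax / argmin of the cavity volume curve.

    Ties resolve to the earliest frame.  A constant-zero curve is an error.
    """
    if seg.n_frames < 2:
        raise ValueError("need at least 2 segmented frames")
    curve = volume_curve(seg, structure)
    if np.all(curve == 0):
        raise ValueError("cavity volume curve is identically zero")
    return int(np.argmax(curve)), int(np.argmin(curve))


def measures_report(
    seg: SegmentationMap,
    frame_interval_ms: float | None = None,
    heart_rate_bpm: float | None = None,
    lvm_frame: str = "ed",
) -> ClinicalMeasures:
    """Full clinical report from a segmented cine sequence.

    SV = EDV - ESV; EF = 100 * SV / EDV; CO (L/min) = SV * heart rate / 1000
    with heart rate = 60 / cycle seconds and cycle seconds = n_frames *
    frame interval.  ``heart_rate_bpm`` overrides the temporal metadata.
    LV mass is evaluated at ED by default (``lvm_frame`` in {"ed", "es"}).
    """
    ed, es = ed_es_frames(seg)
    interval = frame_interval_ms if frame_interval_ms is not None else seg.frame_interval_ms
    if heart_rate_bpm is not None:
        rate = heart_rate_bpm
    elif interval:
        rate = 60.0 / (seg.n_frames * interval / 1000.0)
    else:
        rate = None

    m = ClinicalMeasures(ed_frame=ed, es_frame=es)
    scheme = seg.scheme
    if "lv_cavity" in scheme:
        m.LVEDV_mL = chamber_volume(seg, "lv_cavity", ed)
        m.LVESV_mL = chamber_volume(seg, "lv_cavity", es)
        m.LVSV_mL = m.LVEDV_mL - m.LVESV_mL
        m.LVEF_pct = 100.0 * m.LVSV_mL / m.LVEDV_mL if m.LVEDV_mL > 0 else None
        m.LVCO_Lmin = m.LVSV_mL * rate / 1000.0 if rate else None
    if "lv_myocardium" in scheme:
        m.LVM_g = lv_mass(seg, ed if lvm_frame == "ed" else es)
    if "rv_cavity" in scheme:
        m.RVEDV_mL = chamber_volume(seg, "rv_cavity", ed)
        m.RVESV_mL = chamber_volume(seg, "rv_cavity", es)
        m.RVSV_mL = m.RVEDV_mL - m.RVESV_mL
        m.RVEF_pct = 100.0 * m.RVSV_mL / m.RVEDV_mL if m.RVEDV_mL > 0 else None
        m.RVCO_Lmin = m.RVSV_mL * rate / 1000.0 if rate else None
    return m
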