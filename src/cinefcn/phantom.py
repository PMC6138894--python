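"""Synthetic cine phantom with exact ground truth and analytic volumes.

The short-axis phantom places a contracting left-ventricular disk (cavity +
myocardial annulus) and a right-ventricular crescent on every slice of a
cylinder-like stack; the cavity radius follows a cosine between its
end-diastolic and end-systolic values, chosen so the analytic volume curve
attains a requested ejection fraction.  Long-axis variants are single-slice
atrial ellipses.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .image_io import (
    CineStack,
    LabelScheme,
    SegmentationMap,
    save_cine,
    save_segmentation,
    scheme_for_view,
)

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "generate_phantom",
    "analytic_lv_volume",
    "simulate_observer",
    "write_phantom_set",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of a synthetic cine case.

    Defaults emulate the target acquisition: 1.8 x 1.8 mm in-plane spacing,
    10 mm slice separation (8 mm thickness + 2 mm gap), ~10 slices and 50
    frames per cardiac cycle.
    """

    shape: tuple[int, int, int, int] = (192, 192, 10, 50)
    spacing_mm: tuple[float, float, float] = (1.8, 1.8, 10.0)
    frame_interval_ms: float = 20.0
    view: str = "short_axis"
    lv_radius_ed_mm: float = 25.0
    myo_thickness_mm: float = 8.0
    ejection_fraction: float = 0.6
    rv_offset_mm: float = 38.0     # RV centre displacement along -col from LV centre
    rv_radius_mm: float = 26.0
    noise_sigma: float = 0.03
    blur_sigma_mm: float = 1.2
    intensity_background: float = 0.2
    intensity_myocardium: float = 0.5
    intensity_blood: float = 0.9
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols, n_slices, n_frames = self.shape
        if min(rows, cols, n_slices) < 1 or n_frames < 2:
            raise ValueError("grid must be nonempty with >= 2 frames")
        if self.lv_radius_ed_mm <= 0 or self.myo_thickness_mm <= 0:
            raise ValueError("radii and thickness must be positive")
        if not 0.0 < self.ejection_fraction < 1.0:
            raise ValueError("ejection fraction must lie in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.view.startswith("long_axis") and n_slices != 1:
            raise ValueError("long-axis phantoms are single-slice")
        # outermost structure must fit inside the grid
        extent = self.lv_radius_ed_mm + self.myo_thickness_mm
        if self.view == "short_axis":
            extent = max(extent, self.rv_offset_mm + self.rv_radius_mm)
        half_rows = rows * self.spacing_mm[0] / 2.0
        half_cols = cols * self.spacing_mm[1] / 2.0
        if extent >= min(half_rows, half_cols):
            raise ValueError(
                f"structures (extent {extent:.1f} mm) exceed the grid "
                f"({2 * half_rows:.0f} x {2 * half_cols:.0f} mm)"
            )

    @property
    def lv_radius_es_mm(self) -> float:
        # cavity volume scales with r^2 (fixed stack height)
        return self.lv_radius_ed_mm * math.sqrt(1.0 - self.ejection_fraction)

    def radius_at(self, frame: int) -> float:
        """Cavity radius (mm) at a frame; cosine contraction, ED at frame 0."""
        n = self.shape[3]
        phase = 0.5 * (1.0 + math.cos(2.0 * math.pi * frame / n))
        return self.lv_radius_es_mm + (self.lv_radius_ed_mm - self.lv_radius_es_mm) * phase

    @property
    def ed_frame(self) -> int:
        return 0

    @property
    def es_frame(self) -> int:
        return self.shape[3] // 2


@dataclass
class PhantomCase:
    """A generated phantom: image stack, exact truth, analytic volume curve."""

    stack: CineStack
    truth: SegmentationMap
    lv_volume_ml: np.ndarray        # analytic cavity volume per frame
    ed_frame: int
    es_frame: int
    params: PhantomParams | None = None


def analytic_lv_volume(params: PhantomParams, frame: int) -> float:
    """Closed-form LV cavity volume (mL) of the continuous phantom geometry."""
    n_frames = params.shape[3]
    if not 0 <= frame < n_frames:
        raise IndexError(f"frame {frame} out of range [0, {n_frames})")
    r = params.radius_at(frame)
    height = params.shape[2] * params.spacing_mm[2]
    return math.pi * r * r * height / 1000.0


def _grid_mm(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = params.shape[:2]
    cy = (rows - 1) / 2.0 + params.center_offset_px[0]
    cx = (cols - 1) / 2.0 + params.center_offset_px[1]
    y = (np.arange(rows) - cy) * params.spacing_mm[0]
    x = (np.arange(cols) - cx) * params.spacing_mm[1]
    return np.meshgrid(y, x, indexing="ij")


def _truth_frame(params: PhantomParams, frame: int) -> np.ndarray:
    """2D label map of one frame (identical across slices)."""
    yy, xx = _grid_mm(params)
    r = params.radius_at(frame)
    dist_lv = np.hypot(yy, xx)
    scheme = scheme_for_view(params.view)
    lab = np.zeros(params.shape[:2], dtype=np.uint8)
    if params.view == "short_axis":
        scale = r / params.lv_radius_ed_mm
        cavity = dist_lv <= r
        epi = dist_lv <= r + params.myo_thickness_mm
        rv_center_x = -params.rv_offset_mm * scale
        dist_rv = np.hypot(yy, xx - rv_center_x)
        rv = (dist_rv <= params.rv_radius_mm * scale) & ~epi
        lab[rv] = scheme.index("rv_cavity")
        lab[epi] = scheme.index("lv_myocardium")
        lab[cavity] = scheme.index("lv_cavity")
    else:
        # atrial ellipse(s); reuse the LV radius parameters for sizing
        ell = (yy / (1.3 * r)) ** 2 + (xx / r) ** 2 <= 1.0
        lab[ell] = scheme.index("la_cavity")
        if params.view == "long_axis_4ch":
            dist_ra = (yy / (1.3 * r)) ** 2 + ((xx + 2.4 * r) / r) ** 2 <= 1.0
            lab[dist_ra & ~ell] = scheme.index("ra_cavity")
    return lab


def generate_phantom(params: PhantomParams | None = None, **overrides) -> PhantomCase:
    """Generate a phantom case; identical seeds give bit-identical output."""
    if params is None:
        params = PhantomParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rows, cols, n_slices, n_frames = params.shape
    scheme = scheme_for_view(params.view)
    rng = np.random.default_rng(params.seed)

    labels = np.zeros(params.shape, dtype=np.uint8)
    voxels = np.empty(params.shape, dtype=np.float32)
    levels = np.array(
        [params.intensity_background, params.intensity_myocardium, params.intensity_blood],
        dtype=np.float32,
    )
    intensity_of = {"background": 0, "lv_myocardium": 1}
    blur_px = params.blur_sigma_mm / params.spacing_mm[0]
    for f in range(n_frames):
        lab2d = _truth_frame(params, f)
        img2d = np.empty(lab2d.shape, dtype=np.float32)
        for idx, name in enumerate(scheme.structures):
            img2d[lab2d == idx] = levels[intensity_of.get(name, 2)]
        if blur_px > 0:
            img2d = ndimage.gaussian_filter(img2d, blur_px)
        for s in range(n_slices):
            labels[:, :, s, f] = lab2d
            img = img2d
            if params.noise_sigma > 0:
                img = img + rng.normal(0.0, params.noise_sigma, img2d.shape)
            voxels[:, :, s, f] = img

    stack = CineStack(voxels, params.spacing_mm, params.frame_interval_ms, params.view)
    truth = SegmentationMap(labels, scheme, params.spacing_mm, params.frame_interval_ms)
    vol = np.array([analytic_lv_volume(params, f) for f in range(n_frames)])
    return PhantomCase(stack, truth, vol, params.ed_frame, params.es_frame, params)


# ---------------------------------------------------------------------------
# Simulated observers: smooth random radial boundary perturbation.
# ---------------------------------------------------------------------------


def _radial_field(rng: np.random.Generator, rms_mm: float, n_harmonics: int = 4):
    """Random band-limited function of polar angle with the requested RMS."""
    a = rng.normal(size=n_harmonics)
    b = rng.normal(size=n_harmonics)
    norm = math.sqrt((a @ a + b @ b) / 2.0)
    if norm == 0:
        a[0] = 1.0
        norm = math.sqrt(0.5)
    a *= rms_mm / norm
    b *= rms_mm / norm

    def field(theta: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta)
        for m in range(n_harmonics):
            out += a[m] * np.cos((m + 1) * theta) + b[m] * np.sin((m + 1) * theta)
        return out

    return field


def _perturb_mask(mask: np.ndarray, field, spacing: tuple[float, float]) -> np.ndarray:
    """Shift a 2D mask boundary radially by ``field(theta)`` mm (positive = dilate)."""
    if not mask.any():
        return mask.copy()
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    sdf = d_out - d_in  # positive outside the structure
    cy, cx = ndimage.center_of_mass(mask)
    yy, xx = np.meshgrid(
        (np.arange(mask.shape[0]) - cy) * spacing[0],
        (np.arange(mask.shape[1]) - cx) * spacing[1],
        indexing="ij",
    )
    theta = np.arctan2(yy, xx)
    return sdf <= field(theta)


def simulate_observer(
    truth: SegmentationMap, jitter_mm: float, seed: int | np.random.Generator = 0
) -> SegmentationMap:
    """Emulate an independent human observer by jittering structure boundaries.

    Each structure boundary is displaced by a smooth random radial field with
    RMS amplitude ``jitter_mm`` (constant across slices and frames of a case,
    as one observer traces a case consistently).  ``jitter_mm == 0`` returns
    an identical copy.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    if jitter_mm == 0:
        return SegmentationMap(
            truth.labels.copy(), truth.scheme, truth.spacing_mm, truth.frame_interval_ms
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = truth.scheme
    spacing2d = truth.spacing_mm[:2]
    sa = scheme.view == "short_axis"
    # one radial field per independently-traced boundary
    if sa:
        fields = {k: _radial_field(rng, jitter_mm) for k in ("endo", "epi", "rv")}
    else:
        fields = {name: _radial_field(rng, jitter_mm) for name in scheme.foreground()}

    out = np.zeros_like(truth.labels)
    rows, cols, n_slices, n_frames = truth.labels.shape
    for s in range(n_slices):
        for f in range(n_frames):
            lab = truth.labels[:, :, s, f]
            if not lab.any():
                continue
            new = np.zeros_like(lab)
            if sa:
                endo = lab == scheme.index("lv_cavity")
                epi = endo | (lab == scheme.index("lv_myocardium"))
                rv = lab == scheme.index("rv_cavity")
                epi_new = _perturb_mask(epi, fields["epi"], spacing2d)
                endo_new = _perturb_mask(endo, fields["endo"], spacing2d) & epi_new
                rv_new = _perturb_mask(rv, fields["rv"], spacing2d) & ~epi_new
                new[rv_new] = scheme.index("rv_cavity")
                new[epi_new] = scheme.index("lv_myocardium")
                new[endo_new] = scheme.index("lv_cavity")
            else:
                for name in scheme.foreground():
                    m = _perturb_mask(lab == scheme.index(name), fields[name], spacing2d)
                    m &= new == 0
                    new[m] = scheme.index(name)
            out[:, :, s, f] = new
    return SegmentationMap(out, scheme, truth.spacing_mm, truth.frame_interval_ms)


def write_phantom_set(
    out_dir: str | Path,
    n_cases: int,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> list[dict]:
    """Write ``n_cases`` paired image/label NIfTI files plus a manifest YAML.

    Cases vary mildly in LV radius, thickness and EF around the base params.
    Returns the manifest entries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = params or PhantomParams()
    rng = np.random.default_rng(seed)
    manifest = []
    for i in range(n_cases):
        case_params = replace(
            base,
            lv_radius_ed_mm=base.lv_radius_ed_mm * float(rng.uniform(0.85, 1.1)),
            myo_thickness_mm=base.myo_thickness_mm * float(rng.uniform(0.9, 1.1)),
            ejection_fraction=float(np.clip(
                base.ejection_fraction + rng.uniform(-0.08, 0.08), 0.2, 0.8)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom(case_params)
        img_path = out_dir / f"case{i:03d}_image.nii.gz"
        seg_path = out_dir / f"case{i:03d}_label.nii.gz"
        save_cine(case.stack, img_path)
        save_segmentation(case.truth, seg_path)
        manifest.append(
            {
                "case": i,
                "image": img_path.name,
                "label": seg_path.name,
                "view": case_params.view,
                "ed_frame": case.ed_frame,
                "es_frame": case.es_frame,
                "ejection_fraction": case_params.ejection_fraction,
                "lv_volume_ml": [round(float(v), 4) for v in case.lv_volume_ml],
            }
        )
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
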