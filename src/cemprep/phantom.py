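"""Synthetic contrast-enhanced-mammography phantoms with known ground truth.

The generator emulates the nuisance structure the pipeline is designed to
control: a half-elliptical breast attached to one chest-wall border, a
pectoral wedge on MLO views, smooth parenchymal texture, bright lesions of
two morphology classes (smooth benign blobs vs. spiculated malignant
masses), bright non-anatomical background markers whose presence can be
coupled to the class label, per-"scanner" multiplicative gain, and additive
Gaussian noise.  Every record carries its ground-truth breast mask and
lesion map, so segmentation and confounder-removal claims are testable
without any external dataset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

from .io import GrayImage, write_gray_png, write_gray_dicom, write_manifest

VIEWS = ("CC", "MLO")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters.

    Intensities live on a unit scale before quantization to 16 bits; breast
    tissue sits roughly in the 20--80% band of the dynamic range so that
    percentile windowing has real work to do.
    """

    n_patients: int = 50
    malignant_fraction: float = 0.3
    views_per_patient: int = 2
    image_size: int = 512
    lesion_contrast: float = 0.35
    lesion_radius_px: int | None = None  # default: 6% of image_size
    spiculation_strength: float = 1.2
    benign_lesion_fraction: float = 0.5  # benign patients w/ a smooth blob; rest negative
    benign_contrast_fraction: float = 0.6  # benign blobs enhance less than malignant
    artifact_rate: float = 0.3
    confound_strength: float = 0.0
    scanner_count: int = 3
    scanner_gain_range: tuple[float, float] = (0.85, 1.15)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("malignant_fraction", "artifact_rate", "confound_strength",
                     "benign_lesion_fraction", "benign_contrast_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_patients", "views_per_patient", "image_size", "scanner_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scanner_gain_range[0] > self.scanner_gain_range[1]:
            raise ValueError("scanner_gain_range must be (low, high) with low <= high")
        if round(self.n_patients * self.malignant_fraction) < 1:
            raise ValueError(
                "n_patients * malignant_fraction rounds to zero malignant patients; "
                "no positive class"
            )

    @property
    def effective_lesion_radius(self) -> int:
        if self.lesion_radius_px is not None:
            return int(self.lesion_radius_px)
        return max(3, round(0.06 * self.image_size))


@dataclass
class PhantomRecord:
    patient_id: str
    image_id: str
    view: str
    laterality: str
    label: str
    image: GrayImage
    truth_mask: np.ndarray  # bool raster, the anatomically valid breast region
    lesion_map: np.ndarray  # bool raster, subset of truth_mask
    marker_map: np.ndarray = field(repr=False, default=None)  # bool raster, outside truth_mask
    scanner_id: int = 0


def _marker_probability(label: str, cfg: PhantomConfig) -> float:
    """P(background marker | label).

    Symmetric rate skew around the base artifact rate a: malignant images
    carry markers with probability min(1, a*(1+c)), benign with a*(1-c).
    c=0 decouples marker from label; c=1 makes markers exclusive to the
    malignant class while keeping them a spurious (imperfect) cue.
    """
    a, c = cfg.artifact_rate, cfg.confound_strength
    if label == "malignant":
        return min(1.0, a * (1.0 + c))
    return a * (1.0 - c)


def _half_ellipse(size: int, chest_side: str, rng: np.random.Generator) -> np.ndarray:
    """Breast region: half ellipse attached to one lateral border, axes +-~12-15%."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    a = 0.55 * size * (1.0 + rng.uniform(-0.15, 0.15))
    b = 0.40 * size * (1.0 + rng.uniform(-0.12, 0.12))
    cy = size * (0.5 + rng.uniform(-0.025, 0.025))
    x0 = 0.0 if chest_side == "left" else size - 1.0
    mask = ((xx - x0) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return mask


def _pectoral_wedge(size: int, chest_side: str, rng: np.random.Generator) -> np.ndarray:
    """Triangular pectoral-muscle wedge in the upper chest-wall corner (MLO)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    w = size * (0.30 + rng.uniform(-0.04, 0.04))
    h = size * (0.45 + rng.uniform(-0.05, 0.05))
    if chest_side == "left":
        return xx / w + yy / h < 1.0
    return (size - 1 - xx) / w + yy / h < 1.0


def _sample_interior_point(region: np.ndarray, clearance: float,
                           rng: np.random.Generator) -> tuple[int, int] | None:
    """Uniform pixel of ``region`` at least ``clearance`` px from its complement."""
    dist = ndimage.distance_transform_edt(region)
    candidates = np.flatnonzero(dist >= clearance)
    if candidates.size == 0:
        candidates = np.flatnonzero(dist >= dist.max())
        if candidates.size == 0:
            return None
    idx = int(rng.integers(candidates.size))
    r, c = np.unravel_index(candidates[idx], region.shape)
    return int(r), int(c)


def _draw_lesion(canvas: np.ndarray, lesion_map: np.ndarray, center: tuple[int, int],
                 radius: int, contrast: float, malignant: bool,
                 spiculation: float, rng: np.random.Generator) -> None:
    size = canvas.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    sigma = radius / 2.0
    canvas += contrast * np.exp(-r2 / (2.0 * sigma**2))
    lesion_map |= r2 <= radius**2
    if malignant and spiculation > 0:
        n_spicules = int(rng.integers(6, 11))
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n_spicules)
        length = spiculation * radius
        for ang in angles:
            r0 = center[0] + 0.6 * radius * np.sin(ang)
            c0 = center[1] + 0.6 * radius * np.cos(ang)
            r1 = center[0] + (radius + length) * np.sin(ang)
            c1 = center[1] + (radius + length) * np.cos(ang)
            rr, cc = draw_line(int(round(r0)), int(round(c0)),
                               int(round(r1)), int(round(c1)))
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            rr, cc = rr[ok], cc[ok]
            canvas[rr, cc] += contrast
            lesion_map[rr, cc] = True


def _stamp_square(canvas: np.ndarray, marker_map: np.ndarray,
                  r: int, c: int, side: int) -> None:
    size = canvas.shape[0]
    r0, r1 = max(0, r - side // 2), min(size, r + side - side // 2)
    c0, c1 = max(0, c - side // 2), min(size, c + side - side // 2)
    canvas[r0:r1, c0:c1] = 0.92
    marker_map[r0:r1, c0:c1] = True


def _draw_view_tag(canvas: np.ndarray, marker_map: np.ndarray, anatomy: np.ndarray,
                   size: int, scanner_id: int, rng: np.random.Generator) -> None:
    """Burned-in view/laterality tag: present on every image, label-independent.

    Each scanner stamps its tag in a characteristic corner (with jitter),
    always outside the breast, mimicking the textual annotations real
    acquisitions burn into the background.
    """
    side = max(3, round(0.05 * size))
    corners = [(0.12, 0.85), (0.85, 0.85), (0.12, 0.6), (0.85, 0.6)]
    fr, fc = corners[scanner_id % len(corners)]
    background = ~anatomy
    dist = ndimage.distance_transform_edt(background)
    clearance = side / 2.0 + max(4.0, 0.025 * size)
    for _ in range(8):  # jittered tries near the scanner's corner
        r = int(fr * size + rng.normal(0.0, 0.03 * size))
        c = int(fc * size + rng.normal(0.0, 0.03 * size))
        if 0 <= r < size and 0 <= c < size and dist[r, c] >= clearance:
            _stamp_square(canvas, marker_map, r, c, side)
            return
    pt = _sample_interior_point(background, clearance, rng)
    if pt is not None:
        _stamp_square(canvas, marker_map, pt[0], pt[1], side)


def _draw_markers(canvas: np.ndarray, marker_map: np.ndarray, anatomy: np.ndarray,
                  size: int, rng: np.random.Generator) -> None:
    """1-3 bright square markers strictly in the air background (outside the
    breast and, on MLO views, outside the pectoral wedge).  The clearance
    keeps a visible air gap so nearby bright structures are never smoothed
    into the anatomy by downstream filters."""
    side = max(3, round(0.05 * size))
    background = ~anatomy
    clearance = side / 2.0 + max(4.0, 0.025 * size)
    n_markers = int(rng.integers(1, 4))
    for _ in range(n_markers):
        pt = _sample_interior_point(background, clearance, rng)
        if pt is None:
            continue
        _stamp_square(canvas, marker_map, pt[0], pt[1], side)


def generate_cohort(config: PhantomConfig) -> list[PhantomRecord]:
    """Generate a deterministic cohort of phantom records.

    Exactly ``round(n_patients * malignant_fraction)`` patients are
    malignant; all images of one patient share a label, laterality and
    scanner.  Per-scanner multiplicative gain is applied before additive
    Gaussian noise and 16-bit quantization.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    n_mal = round(config.n_patients * config.malignant_fraction)

    labels = ["malignant"] * n_mal + ["benign_negative"] * (config.n_patients - n_mal)
    rng.shuffle(labels)
    scanner_gains = rng.uniform(*config.scanner_gain_range, size=config.scanner_count)

    views = [VIEWS[i % len(VIEWS)] for i in range(config.views_per_patient)]
    radius = config.effective_lesion_radius
    records: list[PhantomRecord] = []
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        label = labels[p]
        laterality = "L" if rng.random() < 0.5 else "R"
        chest_side = "left" if laterality == "L" else "right"
        scanner_id = int(rng.integers(config.scanner_count))
        has_lesion = label == "malignant" or rng.random() < config.benign_lesion_fraction
        for v, view in enumerate(views):
            image_id = f"{patient_id}_{view}_{v}"
            breast = _half_ellipse(size, chest_side, rng)
            wedge = _pectoral_wedge(size, chest_side, rng) if view == "MLO" else np.zeros_like(breast)
            truth_mask = breast & ~wedge

            texture = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                              sigma=max(1.0, size / 32.0))
            texture = texture / (texture.std() + 1e-12) * 0.10
            canvas = np.full((size, size), 0.03)
            canvas[breast] = 0.45 + texture[breast]
            canvas[wedge] = 0.67 + 0.5 * texture[wedge]

            lesion_map = np.zeros((size, size), dtype=bool)
            if has_lesion:
                total_r = radius * (1.0 + (config.spiculation_strength if label == "malignant" else 0.0))
                center = _sample_interior_point(truth_mask, total_r + 2, rng)
                if center is not None:
                    contrast = config.lesion_contrast * (
                        1.0 if label == "malignant" else config.benign_contrast_fraction)
                    _draw_lesion(canvas, lesion_map, center, radius,
                                 contrast, label == "malignant",
                                 config.spiculation_strength, rng)
            lesion_map &= truth_mask

            marker_map = np.zeros((size, size), dtype=bool)
            anatomy = breast | wedge
            _draw_view_tag(canvas, marker_map, anatomy, size, scanner_id, rng)
            if rng.random() < _marker_probability(label, config):
                _draw_markers(canvas, marker_map, anatomy, size, rng)

            canvas = canvas * scanner_gains[scanner_id]
            if config.noise_sigma > 0:
                canvas = canvas + rng.normal(0.0, config.noise_sigma, canvas.shape)
            canvas = np.clip(canvas, 0.0, 1.0)
            pixels = np.round(canvas * 65535.0).astype(np.uint16)
            records.append(PhantomRecord(
                patient_id=patient_id,
                image_id=image_id,
                view=view,
                laterality=laterality,
                label=label,
                image=GrayImage(pixels, "u16"),
                truth_mask=truth_mask,
                lesion_map=lesion_map,
                marker_map=marker_map,
                scanner_id=scanner_id,
            ))
    return records


def write_phantom_dataset(records: list[PhantomRecord], out_dir: str | os.PathLike,
                          image_format: str = "png") -> Path:
    """Write a cohort to disk and return the manifest path.

    Images go to ``images/`` as 16-bit PNG (or DICOM on request), truth masks
    to ``masks/`` as 8-bit 0/255 PNG; the manifest holds paths relative to
    its own directory so the dataset is relocatable.
    """
    if not records:
        raise ValueError("no records to write")
    ids = [r.image_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image_id in records")
    if image_format not in ("png", "dicom"):
        raise ValueError(f"unsupported image_format {image_format!r}")

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ext = "png" if image_format == "png" else "dcm"
        img_rel = f"images/{rec.image_id}.{ext}"
        mask_rel = f"masks/{rec.image_id}.png"
        if image_format == "png":
            write_gray_png(rec.image, out / img_rel)
        else:
            write_gray_dicom(rec.image, out / img_rel)
        mask_u8 = GrayImage(rec.truth_mask.astype(np.uint8) * 255, "u8")
        write_gray_png(mask_u8, out / mask_rel)
        rows.append({
            "image_id": rec.image_id,
            "patient_id": rec.patient_id,
            "view": rec.view,
            "laterality": rec.laterality,
            "label": rec.label,
            "image_path": img_rel,
            "mask_path": mask_rel,
        })
    manifest_path = out / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path
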