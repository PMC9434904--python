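"""Co-registration preprocessing: from raw report images to paired crops.

The pipeline mirrors every left eye to right-eye orientation, finds the
color-coded thickness square on the OCT report (its center is the presumed
fovea there), segments the foveal avascular zone (FAZ) on the grayscale FA
frame (its centroid is the presumed fovea there), cuts fovea-centered
square crops of identical retinal extent from both modalities, resizes them
to a common canvas (512 x 512 by default) and concatenates them side by
side into the 2:1 composites the translator trains on.  Samples whose FAZ
cannot be segmented are routed to a manual-review list instead of aborting.

Conventions: 0-based coordinates, x = column, y = row, rectangles half-open.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_multiotsu, threshold_otsu

from .errors import NoColorMapFound, NoFAZFound, ParameterError
from .image import RasterImage, as_pixels, gray_float, resize_image

#: Final side of each modality crop; composites are twice as wide.
CANVAS_SIDE = 512

#: Default chroma threshold (max-min channel spread) for "colored" pixels.
SATURATION_THRESHOLD = 30

#: Canonical grade ordering used by the stratified split.
GRADE_ORDER = ("no_DR", "mild_NPDR", "moderate_NPDR", "severe_NPDR", "PDR")


@dataclasses.dataclass(frozen=True)
class ScanWindow:
    """Half-open pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ParameterError("scan window must be nonempty")

    def clipped_to(self, height: int, width: int) -> "ScanWindow":
        return ScanWindow(max(self.x0, 0), max(self.y0, 0),
                          min(self.x1, width), min(self.y1, height))

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.y0:self.y1, self.x0:self.x1]


def default_oct_window(img) -> ScanWindow:
    """Central square of half the report dimension (avoids the color bar)."""
    px = as_pixels(img)
    h, w = px.shape[:2]
    side = min(h, w) // 2
    cx, cy = w // 2, h // 2
    return ScanWindow(cx - side // 2, cy - side // 2,
                      cx - side // 2 + side, cy - side // 2 + side)


def default_fa_window(img) -> ScanWindow:
    """Square of half the frame dimension, shifted 10% of width leftward."""
    px = as_pixels(img)
    h, w = px.shape[:2]
    side = min(h, w) // 2
    cx = w // 2 - int(round(0.10 * w))
    cy = h // 2
    win = ScanWindow(cx - side // 2, cy - side // 2,
                     cx - side // 2 + side, cy - side // 2 + side)
    return win.clipped_to(h, w)


@dataclasses.dataclass(frozen=True)
class ColorMapRegion:
    """Detected color-coded square: tight bbox + its midpoint (presumed fovea)."""

    bbox: ScanWindow
    center: tuple


@dataclasses.dataclass(frozen=True)
class FAZSegmentation:
    """Binary FAZ mask (255 = FAZ), its contour and centroid (presumed fovea)."""

    binary_mask: np.ndarray
    contour: np.ndarray  # ordered (x, y) float points
    centroid: tuple


@dataclasses.dataclass(frozen=True)
class PairedSample:
    """Fovea-centered 512x512 crops of both modalities plus their composite."""

    fa_crop: RasterImage
    oct_crop: RasterImage
    composite: RasterImage
    grade_label: str
    source_id: str = ""

    def __post_init__(self):
        if self.composite.width != self.fa_crop.width + self.oct_crop.width:
            raise ParameterError("composite width must equal fa + oct widths")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def mirror_to_right(img, laterality: str) -> RasterImage:
    """Horizontally flip left-eye images so all data is right-eye oriented."""
    if laterality not in ("left", "right"):
        raise ParameterError(f"unknown laterality {laterality!r}")
    img = img if isinstance(img, RasterImage) else RasterImage.from_array(as_pixels(img))
    return img.mirrored() if laterality == "left" else img


def detect_color_square(oct_report, window: ScanWindow = None,
                        saturation_threshold: int = SATURATION_THRESHOLD) -> ColorMapRegion:
    """Locate the color-coded thickness square on an OCT report.

    A pixel is "colored" when its chroma — max(R,G,B) - min(R,G,B) — exceeds
    the threshold; the red-free fundus background is gray (chroma ~ 0).  The
    bbox is the tight axis-aligned box of colored pixels inside the scan
    window (which must exclude the color bar); its midpoint is the presumed
    foveal location.
    """
    px = as_pixels(oct_report)
    if px.ndim != 3:
        raise ParameterError("OCT report must be RGB")
    window = window or default_oct_window(px)
    window = window.clipped_to(px.shape[0], px.shape[1])
    sub = window.crop(px).astype(np.int16)
    chroma = sub.max(axis=2) - sub.min(axis=2)
    ys, xs = np.nonzero(chroma > saturation_threshold)
    if ys.size == 0:
        raise NoColorMapFound("no colored pixel inside the scan window")
    x0 = int(xs.min()) + window.x0
    x1 = int(xs.max()) + 1 + window.x0
    y0 = int(ys.min()) + window.y0
    y1 = int(ys.max()) + 1 + window.y0
    center = ((x0 + x1) / 2.0 - 0.5, (y0 + y1) / 2.0 - 0.5)
    return ColorMapRegion(ScanWindow(x0, y0, x1, y1), center)


def segment_faz(fa_frame, window: ScanWindow = None,
                threshold_policy="otsu") -> FAZSegmentation:
    """Segment the hypofluorescent FAZ inside the scan window.

    The frame is converted to grayscale; pixels darker than the threshold
    are the candidate FAZ and are mapped to white (255) on a black
    background.  The default ``"otsu"`` policy adapts the threshold to the
    windowed content: a three-class Otsu whose lowest cut separates the
    hypofluorescent FAZ from the perfused background even when bright
    leakage makes the histogram trimodal (plain two-class Otsu would then
    cut between background and leakage and swallow the FAZ); it falls back
    to two-class Otsu on degenerate histograms.  ``("fixed", v)`` selects a
    fixed threshold.  The largest connected component wins (ties to the
    smallest bbox top-left in scan order); the centroid comes from the
    first-order spatial moments of the filled component.
    """
    gray = gray_float(as_pixels(fa_frame))
    h, w = gray.shape
    window = (window or default_fa_window(gray)).clipped_to(h, w)
    sub = window.crop(gray)
    if isinstance(threshold_policy, tuple) and threshold_policy[0] == "fixed":
        thr = float(threshold_policy[1])
    elif threshold_policy == "otsu":
        if np.ptp(sub) == 0:
            raise NoFAZFound("uniform window: nothing to threshold")
        try:
            thr = threshold_multiotsu(sub, classes=3)[0]
        except ValueError:  # fewer distinct gray levels than classes
            thr = threshold_otsu(sub)
    else:
        raise ParameterError(f"unknown threshold policy {threshold_policy!r}")
    dark = sub < thr
    if not dark.any():
        raise NoFAZFound("no pixel below threshold inside the scan window")
    labels = measure.label(dark, connectivity=2)
    regions = measure.regionprops(labels)
    regions.sort(key=lambda r: (-r.area, r.bbox[0], r.bbox[1]))
    best = regions[0]
    comp = labels == best.label

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[window.y0:window.y1, window.x0:window.x1][comp] = 255
    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:
        raise NoFAZFound("degenerate component without a traceable contour")
    longest = max(contours, key=len)  # (row, col) points, window-local
    contour_xy = np.column_stack([longest[:, 1] + window.x0,
                                  longest[:, 0] + window.y0])
    cy, cx = best.centroid  # filled-region moments, window-local (row, col)
    centroid = (cx + window.x0, cy + window.y0)
    return FAZSegmentation(mask, contour_xy, centroid)


def crop_fovea_centered(img, fovea: tuple, side_px: int) -> RasterImage:
    """Square crop of side ``side_px`` centered at the fovea.

    When the square overruns the frame it is padded by edge replication so
    the fovea stays at the crop center.
    """
    px = as_pixels(img)
    h, w = px.shape[:2]
    fx, fy = fovea
    if not (0 <= fx < w and 0 <= fy < h):
        raise ParameterError(f"fovea {fovea} outside image {w}x{h}")
    if side_px <= 0:
        raise ParameterError("side_px must be positive")
    x0 = int(round(fx)) - side_px // 2
    y0 = int(round(fy)) - side_px // 2
    x1, y1 = x0 + side_px, y0 + side_px
    pad_l, pad_t = max(-x0, 0), max(-y0, 0)
    pad_r, pad_b = max(x1 - w, 0), max(y1 - h, 0)
    if pad_l or pad_t or pad_r or pad_b:
        pad = ((pad_t, pad_b), (pad_l, pad_r)) + (((0, 0),) if px.ndim == 3 else ())
        px = np.pad(px, pad, mode="edge")
        x0, y0 = x0 + pad_l, y0 + pad_t
        x1, y1 = x0 + side_px, y0 + side_px
    return RasterImage.from_array(px[y0:y1, x0:x1])


def scale_for_magnification(img, scale_factor: float) -> RasterImage:
    """Bilinear resize correcting the fundus-camera / OCT magnification gap."""
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    px = as_pixels(img)
    h, w = px.shape[:2]
    return resize_image(px, int(round(h * scale_factor)), int(round(w * scale_factor)))


def finalize_crop(img, side: int = CANVAS_SIDE) -> RasterImage:
    """Resize to the final square canvas (512 x 512 default), 3 channels."""
    out = resize_image(as_pixels(img), side, side)
    return out.to_rgb()


def concatenate_pair(fa, oct_img) -> RasterImage:
    """Side-by-side composite: FA on the left, OCT map on the right (2:1)."""
    a, b = as_pixels(fa), as_pixels(oct_img)
    if a.shape != b.shape:
        raise ParameterError(f"crop shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] != a.shape[1]:
        raise ParameterError("crops must be square")
    return RasterImage.from_array(np.concatenate([a, b], axis=1))


def split_composite(composite) -> tuple:
    """Invert :func:`concatenate_pair` (bit-exact on lossless images)."""
    px = as_pixels(composite)
    half = px.shape[1] // 2
    return (RasterImage.from_array(px[:, :half]),
            RasterImage.from_array(px[:, half:]))


def build_readers_folder(sample: PairedSample, color_fundus, fa_frame,
                         seg: FAZSegmentation, out_dir) -> Path:
    """Write the per-eye QC folder the human readers review.

    Four QC images — color fundus, the FA frame, the FA frame with the
    fovea marked, and the binary FAZ image with its centroid marked — plus
    the concatenated pair.  Overwrites are idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    RasterImage.from_array(as_pixels(color_fundus)).save(out / "1_color_fundus.png")
    fa_img = RasterImage.from_array(as_pixels(fa_frame))
    fa_img.save(out / "2_fa_frame.png")
    _with_mark(fa_img.to_rgb(), seg.centroid).save(out / "3_fa_fovea_marked.png")
    binary_rgb = RasterImage.from_array(
        np.repeat(seg.binary_mask[:, :, None], 3, axis=2))
    _with_mark(binary_rgb, seg.centroid).save(out / "4_faz_binary_centroid.png")
    sample.composite.save(out / "5_composite.png")
    return out


def _with_mark(img: RasterImage, point: tuple, arm: int = 4) -> RasterImage:
    """Red cross at ``point`` (clamped to the image)."""
    px = img.to_rgb().pixels.copy()
    h, w = px.shape[:2]
    x, y = int(round(point[0])), int(round(point[1]))
    x, y = min(max(x, 0), w - 1), min(max(y, 0), h - 1)
    px[max(y - arm, 0):y + arm + 1, x] = (255, 0, 0)
    px[y, max(x - arm, 0):x + arm + 1] = (255, 0, 0)
    return RasterImage.from_array(px)


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------


def split_dataset(samples: Sequence, n_test: int, stratify_by_grade: bool = True,
                  seed: int = 0) -> tuple:
    """Deterministic train/test split with a grade-balanced test set.

    The test set takes per-grade counts as equal as arithmetic allows
    (quota ``n_test // k`` each, remainder spread one-per-stratum); when a
    stratum is too small for its quota the split falls back to proportional
    rounding with a warning.  Train and test are disjoint and exhaustive.
    """
    samples = list(samples)
    if not 0 < n_test < len(samples):
        raise ParameterError("need 0 < n_test < n_samples")
    rng = np.random.default_rng(seed)
    if not stratify_by_grade:
        order = rng.permutation(len(samples))
        test_idx = set(order[:n_test].tolist())
        return ([s for i, s in enumerate(samples) if i not in test_idx],
                [s for i, s in enumerate(samples) if i in test_idx])

    def grade_of(s):
        return s.grade_label if hasattr(s, "grade_label") else s[-1]

    strata = {}
    for i, s in enumerate(samples):
        strata.setdefault(grade_of(s), []).append(i)
    grades = sorted(strata, key=lambda g: (GRADE_ORDER.index(g)
                                           if g in GRADE_ORDER else len(GRADE_ORDER), g))
    if any(len(v) == 0 for v in strata.values()):
        raise ParameterError("every stratum must be nonempty")
    k = len(grades)
    base, rem = divmod(n_test, k)
    bonus = rng.permutation(k)[:rem]
    quotas = {g: base + (1 if j in bonus else 0) for j, g in enumerate(grades)}
    if any(quotas[g] > len(strata[g]) for g in grades):
        warnings.warn("equal per-grade test counts not attainable; "
                      "falling back to proportional rounding", stacklevel=2)
        total = len(samples)
        quotas = {g: int(round(n_test * len(strata[g]) / total)) for g in grades}
        drift = n_test - sum(quotas.values())
        for g in grades:  # absorb rounding drift where room remains
            if drift == 0:
                break
            room = len(strata[g]) - quotas[g] if drift > 0 else quotas[g]
            step = int(np.sign(drift))
            take = min(abs(drift), room)
            quotas[g] += step * take
            drift -= step * take
    test_idx = set()
    for g in grades:
        members = np.array(strata[g])
        picked = members[rng.permutation(len(members))[:quotas[g]]]
        test_idx.update(picked.tolist())
    train = [s for i, s in enumerate(samples) if i not in test_idx]
    test = [s for i, s in enumerate(samples) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# full per-pair pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the co-registration pipeline."""

    canvas_side: int = CANVAS_SIDE
    saturation_threshold: int = SATURATION_THRESHOLD
    faz_threshold_policy: object = "otsu"
    magnification_scale: float = 1.0  # FA px per OCT px; 1.0 for phantoms


def preprocess_pair(fa_report, oct_report, laterality: str,
                    grade_label: str = "no_DR", source_id: str = "",
                    config: PreprocessConfig = None):
    """Run the whole per-eye pipeline; returns (PairedSample, record).

    The record carries the detected fovea locations and the intermediate
    segmentation, for the manifest and reader's-folder QC outputs.  Raises
    :class:`NoFAZFound` / :class:`NoColorMapFound` on failure — callers
    batch-processing a dataset catch these and route the id to manual review.
    """
    cfg = config or PreprocessConfig()
    fa = mirror_to_right(fa_report, laterality)
    oct_img = mirror_to_right(oct_report, laterality)

    region = detect_color_square(oct_img, default_oct_window(oct_img),
                                 cfg.saturation_threshold)
    bb = region.bbox
    oct_square = RasterImage.from_array(as_pixels(oct_img)[bb.y0:bb.y1, bb.x0:bb.x1])
    oct_crop = finalize_crop(oct_square, cfg.canvas_side)

    fa_scaled = scale_for_magnification(fa, cfg.magnification_scale)
    seg = segment_faz(fa_scaled, default_fa_window(fa_scaled),
                      cfg.faz_threshold_policy)
    side = int(round((bb.x1 - bb.x0) * cfg.magnification_scale))
    fa_square = crop_fovea_centered(fa_scaled, seg.centroid, max(side, 1))
    fa_crop = finalize_crop(fa_square, cfg.canvas_side)

    composite = concatenate_pair(fa_crop, oct_crop)
    sample = PairedSample(fa_crop, oct_crop, composite, grade_label, source_id)
    record = {
        "id": source_id, "laterality": laterality, "grade_label": grade_label,
        "faz_centroid_x": seg.centroid[0], "faz_centroid_y": seg.centroid[1],
        "map_center_x": region.center[0], "map_center_y": region.center[1],
        "qc_status": "auto",
    }
    return sample, record, seg


def preprocess_dataset(records, config: PreprocessConfig = None):
    """Batch pipeline over (fa, oct, laterality, grade, id) records.

    Returns (samples, manifest rows, manual ids); failures are routed to
    the manual list, mirroring a manual-correction workflow, not raised.
    """
    samples, rows, manual = [], [], []
    for rec in records:
        fa, oct_img, lat, grade, sid = rec
        try:
            sample, row, _ = preprocess_pair(fa, oct_img, lat, grade, sid, config)
        except (NoFAZFound, NoColorMapFound) as exc:
            rows.append({"id": sid, "laterality": lat, "grade_label": grade,
                         "faz_centroid_x": np.nan, "faz_centroid_y": np.nan,
                         "map_center_x": np.nan, "map_center_y": np.nan,
                         "qc_status": f"manual:{type(exc).__name__}"})
            manual.append(sid)
            continue
        samples.append(sample)
        rows.append(row)
    return samples, rows, manual
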