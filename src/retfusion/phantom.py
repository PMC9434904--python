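"""Synthetic co-registered FA / OCT-thickness-map phantoms.

Real training data for this problem is a paired clinical archive: mid-phase
fluorescein angiography (FA) frames, and OCT 3-D macular reports whose
color-coded square encodes retinal thickness (0-500 um) over a red-free
fundus photograph.  Such archives are private, so this module generates
seeded phantoms carrying the one statistical dependency the translation
model must learn: vascular leakage on FA (bright halos around microaneurysm
dots) co-occurs, at exactly the same retinal location, with macular
thickening on the OCT map (warm colors).  Everything else — vessel trees,
background texture — is cosmetic context.

All generators are pure functions of (params, seed): same inputs, bit-equal
outputs.  Right-eye geometry is canonical; left-eye phantoms are exact
horizontal mirrors, so the downstream mirroring stage is exactly invertible.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .image import RasterImage

GRADES = ("no_DR", "mild_NPDR", "moderate_NPDR", "severe_NPDR", "PDR")

#: Default appearance constants (8-bit gray levels).
FA_BACKGROUND = 170.0
FA_VESSEL = 225.0
FA_FAZ = 45.0
FA_DOT = 255.0
OCT_FUNDUS_BACKGROUND = 115.0
OCT_FUNDUS_VESSEL = 60.0

#: Baseline (normal) central retinal thickness used by the phantoms, in um.
BASELINE_THICKNESS_UM = 250.0


# ---------------------------------------------------------------------------
# thickness color scale
# ---------------------------------------------------------------------------

#: Piecewise-linear color stops (thickness um -> RGB), low -> high:
#: violet/blue -> green -> yellow -> orange -> red -> white.  The device
#: colormap's true breakpoints are proprietary; these are configurable.
DEFAULT_COLOR_STOPS = (
    (0.0, (148, 0, 211)),    # violet
    (100.0, (0, 0, 255)),    # blue
    (225.0, (0, 200, 0)),    # green (normal thickness band)
    (300.0, (255, 255, 0)),  # yellow
    (350.0, (255, 165, 0)),  # orange
    (425.0, (255, 0, 0)),    # red
    (500.0, (255, 255, 255)),  # white
)


@dataclasses.dataclass(frozen=True)
class ThicknessColorScale:
    """Mapping thickness (um) <-> RGB used by the color-coded square.

    Thickness above ``max_thickness_um`` clips to the top color; below the
    first stop, to the bottom color.  ``decode`` inverts the map by nearest
    color over a 1-um lookup table, so a render/decode round trip is exact
    to within ~1 um (one quantization step).
    """

    stops: tuple = DEFAULT_COLOR_STOPS
    min_thickness_um: float = 0.0
    max_thickness_um: float = 500.0

    def __post_init__(self):
        ts = [t for t, _ in self.stops]
        if len(ts) < 2 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ParameterError("color stops must be strictly increasing")
        if ts[0] != self.min_thickness_um or ts[-1] != self.max_thickness_um:
            raise ParameterError("stops must span [min, max] thickness")

    # lookup table at 1-um resolution, built lazily and cached per instance
    def _lut(self) -> np.ndarray:
        cached = getattr(self, "_lut_cache", None)
        if cached is None:
            t = np.arange(self.min_thickness_um, self.max_thickness_um + 1.0)
            cached = self.to_rgb(t).astype(np.float64)
            object.__setattr__(self, "_lut_cache", cached)
        return cached

    def to_rgb(self, thickness) -> np.ndarray:
        """Map thickness (um, any array shape) to uint8 RGB."""
        t = np.clip(np.asarray(thickness, dtype=np.float64),
                    self.min_thickness_um, self.max_thickness_um)
        ts = np.array([s for s, _ in self.stops])
        cs = np.array([c for _, c in self.stops], dtype=np.float64)
        out = np.empty(t.shape + (3,), dtype=np.float64)
        for ch in range(3):
            out[..., ch] = np.interp(t, ts, cs[:, ch])
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    def decode(self, rgb) -> np.ndarray:
        """Invert the map: nearest LUT color, thickness in um."""
        px = np.asarray(rgb, dtype=np.float64)
        flat = px.reshape(-1, 3)
        lut = self._lut()  # (n_t, 3)
        # squared distance to every LUT color; argmin -> thickness index
        d = ((flat[:, None, :] - lut[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d, axis=1)
        t = self.min_thickness_um + idx.astype(np.float64)
        return t.reshape(px.shape[:-1])


# ---------------------------------------------------------------------------
# parameters and field
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Everything needed to draw one co-registered FA/OCT phantom pair.

    Leakage halos (FA) and edema bumps (OCT thickness) share the same
    centers — this co-location is the signal the translator can learn.

    Units: pixel coordinates on a ``canvas_size`` square canvas; edema
    amplitudes in um; ``noise_sd`` in 8-bit gray levels on the FA frame.
    """

    canvas_size: int = 256
    vessel_depth: int = 5
    vessel_width: int = 2
    faz_radius: float = 11.0
    fovea_center: tuple = None  # (x, y); default canvas center
    n_microaneurysms: int = 0
    leakage_mode: str = "none"  # none | focal | diffuse
    ma_centers: tuple = ()      # (x, y) dot sites; also edema centers
    edema_amplitudes_um: tuple = ()
    edema_radii_px: tuple = ()
    map_square_half_px: int = None  # default canvas_size // 8
    laterality: str = "right"
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.canvas_size < 64:
            raise ParameterError("canvas_size must be >= 64")
        if self.faz_radius <= 0:
            raise ParameterError("faz_radius must be positive")
        if self.faz_radius >= self.canvas_size / 4:
            raise ParameterError("faz_radius must be < canvas/4")
        if self.leakage_mode not in ("none", "focal", "diffuse"):
            raise ParameterError(f"unknown leakage_mode {self.leakage_mode!r}")
        if self.laterality not in ("left", "right"):
            raise ParameterError(f"unknown laterality {self.laterality!r}")
        if any(a < 0 for a in self.edema_amplitudes_um):
            raise ParameterError("edema amplitudes must be non-negative")
        if self.fovea_center is None:
            c = self.canvas_size / 2.0
            object.__setattr__(self, "fovea_center", (c, c))
        if self.map_square_half_px is None:
            object.__setattr__(self, "map_square_half_px", self.canvas_size // 8)
        if len(self.edema_amplitudes_um) != len(self.ma_centers) and self.edema_amplitudes_um:
            raise ParameterError("edema amplitudes must match ma_centers")


@dataclasses.dataclass(frozen=True)
class ThicknessField:
    """Retinal thickness (um) on a pixel grid, ILM to RPE-junction sense."""

    values: np.ndarray
    fovea_center: tuple
    grade_label: str = "no_DR"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ParameterError("thickness values must be finite and >= 0")
        x, y = self.fovea_center
        if not (0 <= x < v.shape[1] and 0 <= y < v.shape[0]):
            raise ParameterError("fovea_center outside grid")
        if self.grade_label not in GRADES:
            raise ParameterError(f"unknown grade {self.grade_label!r}")
        object.__setattr__(self, "values", v)


def generate_thickness_field(params: PhantomParams,
                             grade_label: str = "no_DR") -> ThicknessField:
    """Baseline thickness plus Gaussian edema bumps at the configured centers.

    The field is ``BASELINE + sum_i amp_i * exp(-(d_i/r_i)^2)`` with an
    optional smooth noise floor tied to ``noise_sd`` (scaled to um); it is a
    deterministic function of the params (seeded noise).
    """
    n = params.canvas_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    field = np.full((n, n), BASELINE_THICKNESS_UM)
    amps = params.edema_amplitudes_um
    radii = params.edema_radii_px or tuple([n / 10.0] * len(params.ma_centers))
    if amps:
        for (cx, cy), amp, r in zip(params.ma_centers, amps, radii):
            if r <= 0:
                raise ParameterError("edema radius must be positive")
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            field += amp * np.exp(-d2 / (r * r))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        rough = rng.standard_normal((n, n))
        field += gaussian_filter(rough, sigma=n / 32.0) * params.noise_sd
    return ThicknessField(np.clip(field, 0.0, None), params.fovea_center,
                          grade_label)


# ---------------------------------------------------------------------------
# cosmetic drawing helpers
# ---------------------------------------------------------------------------


def _vessel_tree_mask(n: int, depth: int, width: int, seed: int,
                      exclude_center: tuple, exclude_radius: float) -> np.ndarray:
    """Boolean mask of a branching vessel tree (midpoint-displacement).

    Purely cosmetic.  Branches never enter the avascular exclusion disc
    around the fovea, so the FAZ stays capillary-free as in real FA.
    """
    rng = np.random.default_rng(seed)
    canvas = np.zeros((n, n), dtype=bool)
    cx, cy = exclude_center

    def draw_segment(p0, p1, w):
        length = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]), 1)) * 2
        ts = np.linspace(0.0, 1.0, length)
        xs = p0[0] + (p1[0] - p0[0]) * ts
        ys = p0[1] + (p1[1] - p0[1]) * ts
        keep = (xs - cx) ** 2 + (ys - cy) ** 2 > (exclude_radius + w) ** 2
        xs, ys = xs[keep], ys[keep]
        for dx in range(-w, w + 1):
            for dy in range(-w, w + 1):
                if dx * dx + dy * dy <= w * w:
                    xi = np.clip(np.rint(xs) + dx, 0, n - 1).astype(int)
                    yi = np.clip(np.rint(ys) + dy, 0, n - 1).astype(int)
                    canvas[yi, xi] = True

    def branch(p0, angle, length, w, level):
        if level <= 0 or length < 3:
            return
        mid_angle = angle + rng.uniform(-0.5, 0.5)
        p1 = (p0[0] + length * np.cos(mid_angle), p0[1] + length * np.sin(mid_angle))
        draw_segment(p0, p1, w)
        branch(p1, mid_angle + rng.uniform(0.2, 0.8), length * 0.72,
               max(w - 1, 0), level - 1)
        branch(p1, mid_angle - rng.uniform(0.2, 0.8), length * 0.72,
               max(w - 1, 0), level - 1)

    # arcades entering from the nasal side (left edge of a right eye)
    for start_y, ang in ((0.3, 0.35), (0.7, -0.35)):
        branch((2.0, n * start_y), ang, n * 0.3, width, depth)
    return canvas


def _disc(n: int, center: tuple, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def _soft_blob(n: int, center: tuple, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _mirror_x(points: Sequence[tuple], n: int) -> tuple:
    return tuple((n - 1 - x, y) for x, y in points)


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------


def render_fa_frame(field: ThicknessField, params: PhantomParams) -> RasterImage:
    """Grayscale mid-phase FA frame phantom.

    Bright perfused background and vessel tree, a dark disc at the fovea
    (the FAZ), bright microaneurysm dots, and leakage halos around the dots
    when ``leakage_mode`` is focal (tight halos) or diffuse (wide, confluent
    halos).  Left-eye frames are exact mirrors of the right-eye geometry.
    """
    n = params.canvas_size
    fovea = field.fovea_center
    ma = params.ma_centers
    frame = np.full((n, n), FA_BACKGROUND)

    vessels = _vessel_tree_mask(n, params.vessel_depth, params.vessel_width,
                                params.seed + 17, fovea, params.faz_radius * 2.2)
    frame[vessels] = FA_VESSEL

    if params.leakage_mode != "none":
        sigma = params.faz_radius * (0.9 if params.leakage_mode == "focal" else 2.2)
        gain = 55.0 if params.leakage_mode == "focal" else 70.0
        halo = np.zeros((n, n))
        for c in ma:
            halo += _soft_blob(n, c, sigma)
        frame = frame + gain * np.clip(halo, 0, 1.4)

    # FAZ drawn after any leakage: mid-phase frames are chosen before
    # dye pooling can mask the avascular zone, so it stays dark and
    # symmetric regardless of surrounding hyperfluorescence
    faz_soft = _soft_blob(n, fovea, params.faz_radius / 1.8)
    frame = frame * (1 - 0.25 * faz_soft)
    frame[_disc(n, fovea, params.faz_radius)] = FA_FAZ

    for c in ma:  # hyperfluorescent dots on top of any halo
        frame[_disc(n, c, 2.0)] = FA_DOT

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed + 5)
        frame = frame + rng.standard_normal((n, n)) * params.noise_sd

    img = RasterImage.from_array(frame)
    if params.laterality == "left":
        img = img.mirrored()
    return img


def render_thickness_map(field: ThicknessField,
                         scale: ThicknessColorScale = None,
                         params: PhantomParams = None,
                         alpha: float = 1.0) -> RasterImage:
    """OCT 3-D-macular-report phantom: red-free fundus + color-coded square.

    The square of side ``2 * map_square_half_px`` centered on the fovea is
    colored through ``scale``; thickness above the scale maximum clips to
    the top color.  A vertical color bar is drawn along the right margin
    (outside the default central scan window).  ``alpha`` is the overlay
    opacity of the square; the default 1.0 keeps decode(render) exact to
    one quantization step of the scale.
    """
    scale = scale or ThicknessColorScale()
    n = field.values.shape[0]
    params = params or PhantomParams(canvas_size=n, fovea_center=field.fovea_center)
    fovea = field.fovea_center

    fundus = np.full((n, n), OCT_FUNDUS_BACKGROUND)
    vessels = _vessel_tree_mask(n, params.vessel_depth, params.vessel_width,
                                params.seed + 17, fovea, params.faz_radius * 2.2)
    fundus[vessels] = OCT_FUNDUS_VESSEL
    rgb = np.repeat(fundus[:, :, None], 3, axis=2)

    half = params.map_square_half_px
    cx, cy = int(round(fovea[0])), int(round(fovea[1]))
    y0, y1 = max(cy - half, 0), min(cy + half, n)
    x0, x1 = max(cx - half, 0), min(cx + half, n)
    square = scale.to_rgb(field.values[y0:y1, x0:x1]).astype(np.float64)
    rgb[y0:y1, x0:x1] = alpha * square + (1 - alpha) * rgb[y0:y1, x0:x1]

    # color bar: right margin, top = max thickness
    bar_w = max(n // 40, 3)
    bar = np.linspace(scale.max_thickness_um, scale.min_thickness_um, n)
    rgb[:, n - bar_w:] = scale.to_rgb(bar)[:, None, :]

    img = RasterImage.from_array(rgb)
    if params.laterality == "left":
        img = img.mirrored()
    return img


def virtual_fa_dots(canvas_size: int, n_rings: int = 3,
                    faz_radius: float = None,
                    outer_radius: float = None) -> tuple:
    """Dot layout of the virtual-FA diagrams: (dot centers, ring radii).

    Rings are concentric around the canvas center with a constant radial
    increment out to ``outer_radius`` (default 55% of the half-canvas);
    ring k carries 6k dots, staggered so dots never align radially.
    """
    n = canvas_size
    faz_radius = faz_radius or n / 24.0
    outer_radius = outer_radius or n / 2.0 * 0.55
    center = (n / 2.0, n / 2.0)
    spacing = (outer_radius - faz_radius) / n_rings
    dots, radii = [], []
    for k in range(1, n_rings + 1):
        r = faz_radius + k * spacing
        radii.append(r)
        n_dots = 6 * k
        phase = 0.5 / k
        for j in range(n_dots):
            a = 2 * np.pi * (j + phase) / n_dots
            dots.append((center[0] + r * np.cos(a), center[1] + r * np.sin(a)))
    return dots, radii


def generate_virtual_fa(mode: str, canvas_size: int = 256,
                        n_rings: int = 3, faz_radius: float = None,
                        outer_radius: float = None) -> RasterImage:
    """Diagrammatic 'virtual FA' drawing of a right macula.

    Bright dots mimicking hyperfluorescent microaneurysms sit on concentric
    rings of equal radial spacing around a central presumed FAZ.  ``mode``
    selects the surrounding hyperfluorescence: ``dots`` (none), ``focal``
    (tight halos), ``diffuse`` (wide confluent halos).  The drawing is
    deterministic — three modes, three canonical diagrams.  ``outer_radius``
    confines the rings (e.g. to the area a fovea-centered crop will keep).
    """
    if mode not in ("dots", "focal", "diffuse"):
        raise ParameterError(f"unknown virtual-FA mode {mode!r}")
    n = canvas_size
    faz_radius = faz_radius or n / 24.0
    center = (n / 2.0, n / 2.0)
    frame = np.full((n, n), FA_BACKGROUND)
    frame[_disc(n, center, faz_radius)] = FA_FAZ

    dots, radii = virtual_fa_dots(n, n_rings, faz_radius, outer_radius)
    spacing = radii[0] - faz_radius

    if mode != "dots":
        sigma = spacing * (0.28 if mode == "focal" else 0.85)
        gain = 55.0 if mode == "focal" else 70.0
        halo = np.zeros((n, n))
        for c in dots:
            halo += _soft_blob(n, c, sigma)
        frame = frame + gain * np.clip(halo, 0, 1.4)

    for c in dots:
        frame[_disc(n, c, max(n / 128.0, 1.5))] = FA_DOT
    return RasterImage.from_array(frame)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PhantomPair:
    """One raw report-style phantom pair with its ground-truth geometry."""

    fa_report: RasterImage
    oct_report: RasterImage
    laterality: str
    grade_label: str
    params: PhantomParams
    field: ThicknessField


#: microaneurysm count range and leakage mode per ETDRS-style grade
GRADE_PROFILE = {
    "no_DR": (0, 0, "none"),
    "mild_NPDR": (1, 3, "none"),
    "moderate_NPDR": (3, 6, "focal"),
    "severe_NPDR": (6, 10, "focal"),
    "PDR": (8, 14, "diffuse"),
}


def sample_params(rng: np.random.Generator, canvas_size: int = 256,
                  grade_label: str = None, laterality: str = None) -> tuple:
    """Draw one (params, grade) pair from the default study distribution.

    Fovea jitter is +-canvas/16 so the colored square always stays inside
    the central scan window; microaneurysm (= edema) sites fall in a
    perifoveal annulus inside the square.
    """
    n = canvas_size
    grade = grade_label or GRADES[rng.integers(len(GRADES))]
    lat = laterality or ("left" if rng.random() < 0.5 else "right")
    jitter = n / 16.0
    fovea = (n / 2.0 + rng.uniform(-jitter, jitter),
             n / 2.0 + rng.uniform(-jitter, jitter))
    lo, hi, leak = GRADE_PROFILE[grade]
    n_ma = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    faz_radius = n / 24.0 * rng.uniform(0.85, 1.15)
    half = n // 8
    centers, amps, radii = [], [], []
    r_hi = 0.85 * half
    r_lo = min(1.6 * faz_radius, 0.55 * r_hi)
    for _ in range(n_ma):
        r = rng.uniform(r_lo, r_hi)
        a = rng.uniform(0, 2 * np.pi)
        centers.append((fovea[0] + r * np.cos(a), fovea[1] + r * np.sin(a)))
        amps.append(rng.uniform(50.0, 250.0))
        radii.append(rng.uniform(half * 0.25, half * 0.5))
    if leak == "none":
        amps = [0.0] * n_ma  # no leakage -> no edema, flat normal map
    params = PhantomParams(
        canvas_size=n, faz_radius=faz_radius, fovea_center=fovea,
        n_microaneurysms=n_ma, leakage_mode=leak, ma_centers=tuple(centers),
        edema_amplitudes_um=tuple(amps), edema_radii_px=tuple(radii),
        laterality=lat, seed=int(rng.integers(2 ** 31)),
    )
    return params, grade


def generate_pair(params: PhantomParams, grade_label: str = "no_DR",
                  scale: ThicknessColorScale = None) -> PhantomPair:
    """Render one co-registered FA/OCT report pair from explicit params."""
    field = generate_thickness_field(params, grade_label)
    fa = render_fa_frame(field, params)
    oct_img = render_thickness_map(field, scale, params)
    return PhantomPair(fa, oct_img, params.laterality, grade_label, params, field)


def generate_dataset(n_pairs: int, params_distribution=None,
                     seed: int = 0, canvas_size: int = 256,
                     scale: ThicknessColorScale = None) -> list:
    """Generate ``n_pairs`` raw report-style phantom pairs, seeded.

    ``params_distribution`` may override the default sampler; it receives
    the dataset RNG and must return ``(PhantomParams, grade_label)``.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = params_distribution or (
        lambda r: sample_params(r, canvas_size=canvas_size))
    pairs = []
    for _ in range(n_pairs):
        params, grade = sampler(rng)
        pairs.append(generate_pair(params, grade, scale))
    return pairs


def write_dataset(pairs: Sequence[PhantomPair], out_dir, fmt: str = "png"):
    """Write pairs as zero-padded digit-named files (JPEG or PNG)."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "fa").mkdir(parents=True, exist_ok=True)
    (out / "oct").mkdir(parents=True, exist_ok=True)
    ext = ".jpg" if fmt.lower() in ("jpg", "jpeg") else ".png"
    names = []
    for i, p in enumerate(pairs):
        name = f"{i:04d}{ext}"
        p.fa_report.save(out / "fa" / name)
        p.oct_report.save(out / "oct" / name)
        names.append(name)
    return names
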