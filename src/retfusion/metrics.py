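"""Objective paired-image quality suite: PSNR, SSIM, perceptual-hash
Hamming distance, and an LPIPS-style learned-feature distance with
spatial distance maps, plus per-set aggregation (mean +- sd).

Conventions shared by all metrics: images are 8-bit (peak 255); RGB is
converted to grayscale with BT.601 luma weights where a metric is defined
on intensity; identical inputs score perfectly (PSNR +inf sentinel,
SSIM 1, HD 0, feature distance 0).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d, zoom

from . import _nn
from .errors import ParameterError
from .image import RasterImage, as_pixels, gray_float

#: SSIM stabilizers (k1, k2) and window, the field-standard parameterization.
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_SIGMA = 1.5
SSIM_WIN = 11  # 2 * ceil(3.5 * sigma - 0.5) + 1

#: Hamming-distance interpretation bands on the raw 64-bit count.
HD_SIMILAR_MAX = 0
HD_VARIATION_MAX = 10


# ---------------------------------------------------------------------------
# MSE / PSNR
# ---------------------------------------------------------------------------


def _check_same_shape(a, b):
    pa, pb = as_pixels(a), as_pixels(b)
    if pa.shape != pb.shape:
        raise ParameterError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    return pa, pb


def mse(a, b) -> float:
    """Mean squared pixel difference over all pixels and channels."""
    pa, pb = _check_same_shape(a, b)
    d = pa.astype(np.float64) - pb.astype(np.float64)
    return float(np.mean(d * d))


def psnr(a, b, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio, dB; identical images -> +inf sentinel."""
    m = mse(a, b)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / m))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SSIMParams:
    """Window and stabilization constants for the local SSIM statistics."""

    window_size: int = SSIM_WIN
    sigma: float = SSIM_SIGMA
    k1: float = SSIM_K1
    k2: float = SSIM_K2
    data_range: float = 255.0

    def __post_init__(self):
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ParameterError("window must be odd-sized and >= 3")
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise ParameterError("constants must be positive")


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _local_mean(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = correlate1d(img, kernel, axis=0, mode="nearest")
    return correlate1d(out, kernel, axis=1, mode="nearest")


def ssim(a, b, params: SSIMParams = None) -> float:
    """Structural similarity in [-1, 1]; 1 means identical structure.

    Gaussian-weighted local means/variances/covariance combined into the
    luminance * contrast * structure product, averaged over the interior
    (a window-radius border is cropped to avoid edge effects).
    """
    p = params or SSIMParams()
    pa, pb = _check_same_shape(a, b)
    x, y = gray_float(pa), gray_float(pb)
    r = (p.window_size - 1) // 2
    if min(x.shape) < p.window_size:
        raise ParameterError("image smaller than the SSIM window")
    kern = _gaussian_kernel(p.sigma, r)
    ux, uy = _local_mean(x, kern), _local_mean(y, kern)
    uxx, uyy, uxy = _local_mean(x * x, kern), _local_mean(y * y, kern), _local_mean(x * y, kern)
    vx, vy = uxx - ux * ux, uyy - uy * uy
    cov = uxy - ux * uy
    c1 = (p.k1 * p.data_range) ** 2
    c2 = (p.k2 * p.data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    return float(s[r:-r, r:-r].mean())


# ---------------------------------------------------------------------------
# perceptual hash / Hamming distance
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PerceptualHash:
    """64-bit average-hash fingerprint (8x8 grid, row-major)."""

    bits: np.ndarray
    source_shape: tuple = ()

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8).ravel()
        if bits.size != 64 or not np.isin(bits, (0, 1)).all():
            raise ParameterError("fingerprint must be 64 bits of 0/1")
        object.__setattr__(self, "bits", bits)


@dataclasses.dataclass(frozen=True)
class HDResult:
    """Raw and normalized Hamming distance with its interpretation band."""

    raw: int
    normalized: float
    category: str  # similar | potential_variation | likely_different


def _area_resample(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Exact fractional-area averaging (float), any input size."""

    def weights(n_in, n_out):
        w = np.zeros((n_out, n_in))
        step = n_in / n_out
        for i in range(n_out):
            lo, hi = i * step, (i + 1) * step
            j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
            for j in range(j0, min(j1, n_in)):
                overlap = min(hi, j + 1) - max(lo, j)
                if overlap > 0:
                    w[i, j] = overlap / step
        return w

    wr = weights(img.shape[0], out_h)
    wc = weights(img.shape[1], out_w)
    return wr @ img @ wc.T


def average_hash(img) -> PerceptualHash:
    """8x8/64-pixel average hash: bit = 1 iff the pixel exceeds the mean.

    The downscale is an exact area average in float, so any intensity
    shift that preserves the above-mean set leaves the fingerprint
    unchanged; a constant image hashes to all zeros (strict inequality).
    """
    px = as_pixels(img)
    g = gray_float(px)
    tiny = _area_resample(g, 8, 8)
    bits = (tiny > tiny.mean()).astype(np.uint8)
    return PerceptualHash(bits.ravel(), px.shape)


def hamming(a: PerceptualHash, b: PerceptualHash) -> HDResult:
    """Bit-difference count between fingerprints, banded: 0 similar,
    1-10 potential variation, >10 likely a different image."""
    if a.bits.size != b.bits.size:
        raise ParameterError("fingerprint lengths differ")
    raw = int(np.count_nonzero(a.bits != b.bits))
    if raw <= HD_SIMILAR_MAX:
        cat = "similar"
    elif raw <= HD_VARIATION_MAX:
        cat = "potential_variation"
    else:
        cat = "likely_different"
    return HDResult(raw, raw / a.bits.size, cat)


def hash_distance(a, b) -> HDResult:
    """Convenience: hash both images and return their Hamming distance."""
    return hamming(average_hash(a), average_hash(b))


# ---------------------------------------------------------------------------
# LPIPS-style feature distance
# ---------------------------------------------------------------------------


class DeskBackbone:
    """Small fixed 3-layer conv stack with seeded deterministic weights.

    Even untrained convolutional features rank perceptual similarity far
    better than pixel metrics, which is what licenses a weight-seeded
    backbone here; a pretrained classification network can be plugged in
    through the same interface (a callable returning a list of NCHW
    activation arrays).
    """

    def __init__(self, seed: int = 777):
        rng = np.random.default_rng(seed)
        self.convs = [
            _nn.Conv2d(3, 8, k=3, stride=1, pad=1, rng=rng, std=0.2),
            _nn.Conv2d(8, 16, k=3, stride=2, pad=1, rng=rng, std=0.2),
            _nn.Conv2d(16, 32, k=3, stride=2, pad=1, rng=rng, std=0.2),
        ]
        self.act = np.tanh  # bounded, keeps activations comparable in scale

    def __call__(self, x: np.ndarray) -> list:
        feats = []
        h = x
        for conv in self.convs:
            h = self.act(conv.forward(h))
            feats.append(h)
        return feats


def _to_backbone_tensor(img) -> np.ndarray:
    px = as_pixels(img)
    if px.ndim == 2:
        px = np.repeat(px[:, :, None], 3, axis=2)
    t = px.astype(np.float64) / 127.5 - 1.0
    return t.transpose(2, 0, 1)[None].astype(_nn.DTYPE)


def feature_distance(a, b, backbone=None):
    """LPIPS-style distance: (scalar, distance map as a RasterImage field).

    Channel activations are unit-normalized at each spatial site; squared
    differences are averaged within each layer and summed across layers.
    The per-pixel layer sums, upsampled to the input size, form the
    spatial distance map.  Identity gives 0; the measure is symmetric.
    """
    pa, pb = _check_same_shape(a, b)
    backbone = backbone or DeskBackbone()
    fa = backbone(_to_backbone_tensor(pa))
    fb = backbone(_to_backbone_tensor(pb))
    h, w = pa.shape[:2]
    scalar = 0.0
    dmap = np.zeros((h, w), dtype=np.float64)
    for xa, xb in zip(fa, fb):
        na = xa / (np.linalg.norm(xa, axis=1, keepdims=True) + 1e-10)
        nb = xb / (np.linalg.norm(xb, axis=1, keepdims=True) + 1e-10)
        sq = ((na - nb) ** 2).mean(axis=1)[0]  # (h_l, w_l)
        scalar += float(sq.mean())
        dmap += zoom(sq, (h / sq.shape[0], w / sq.shape[1]), order=1,
                     grid_mode=True, mode="nearest")
    return scalar, dmap


def distance_map_image(dmap: np.ndarray) -> RasterImage:
    """Render a distance map as an inferno heat image."""
    import matplotlib.cm as cm

    top = dmap.max()
    norm = dmap / top if top > 0 else dmap
    rgba = cm.inferno(norm)
    return RasterImage.from_array(rgba[..., :3] * 255.0)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetricReport:
    """Per-pair metric table plus mean +- sd aggregates.

    Infinite PSNR values (bit-identical pairs) are excluded from the PSNR
    aggregate; the count of such pairs is reported alongside.
    """

    table: pd.DataFrame
    aggregates: dict
    n_infinite_psnr: int

    def to_csv(self, path) -> None:
        """n per-pair rows followed by one aggregate (mean +- sd) row."""
        agg = {"id": "mean±sd"}
        for col in ("psnr_db", "ssim", "hd_raw", "hd_norm", "lpips"):
            m, s = self.aggregates[col]
            agg[col] = f"{m:.4f}±{s:.4f}"
        agg["hd_category"] = f"n_inf_psnr={self.n_infinite_psnr}"
        out = pd.concat([self.table, pd.DataFrame([agg])], ignore_index=True)
        out.to_csv(path, index=False)


def evaluate_pairs(pairs, ssim_params: SSIMParams = None,
                   backbone=None, ids=None) -> MetricReport:
    """Score (ground-truth, synthesized) pairs with all four metrics.

    ``hd_raw`` (0-64) feeds the interpretation bands; ``hd_norm``
    (raw / 64) is what the aggregates use.
    """
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("need at least one pair")
    backbone = backbone or DeskBackbone()
    rows = []
    for i, (truth, synth) in enumerate(pairs):
        hd = hash_distance(truth, synth)
        lp, _ = feature_distance(truth, synth, backbone)
        rows.append({
            "id": ids[i] if ids else str(i),
            "psnr_db": psnr(truth, synth),
            "ssim": ssim(truth, synth, ssim_params),
            "hd_raw": hd.raw,
            "hd_norm": hd.normalized,
            "hd_category": hd.category,
            "lpips": lp,
        })
    table = pd.DataFrame(rows)
    finite = table["psnr_db"][np.isfinite(table["psnr_db"])]
    aggregates = {}
    for col in ("psnr_db", "ssim", "hd_raw", "hd_norm", "lpips"):
        vals = finite if col == "psnr_db" else table[col]
        mean = float(vals.mean()) if len(vals) else float("nan")
        sd = float(vals.std(ddof=0)) if len(vals) else float("nan")
        aggregates[col] = (mean, sd)
    return MetricReport(table, aggregates, int(len(table) - len(finite)))
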