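"""8-bit raster images: the universal currency of the pipeline.

Coordinates are 0-based with x = column, y = row; rectangles are half-open
``[x0, x1) x [y0, y1)``.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import ParameterError

#: ITU-R BT.601 luma weights, used for every RGB->gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: JPEG quality used for report-style outputs; fixtures use lossless PNG.
JPEG_QUALITY = 95


@dataclasses.dataclass(frozen=True)
class RasterImage:
    """An 8-bit image, grayscale ``(H, W)`` or RGB ``(H, W, 3)``.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``uint8`` array; 2-D for grayscale, 3-D with three channels for RGB.
    colorspace : str
        ``"gray"`` or ``"rgb"``; kept consistent with the array shape.
    """

    pixels: np.ndarray
    colorspace: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise ParameterError(f"pixels must be uint8, got {px.dtype}")
        if px.ndim == 2:
            cs = "gray"
        elif px.ndim == 3 and px.shape[2] == 3:
            cs = "rgb"
        else:
            raise ParameterError(f"unsupported image shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("image must be at least 1x1")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "colorspace", cs)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RasterImage":
        """Wrap an array, clipping/rounding floats into the 8-bit range."""
        arr = np.asarray(arr)
        if arr.dtype != np.uint8:
            arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        cs = "gray" if arr.ndim == 2 else "rgb"
        return cls(arr, cs)

    @classmethod
    def open(cls, path: str | Path) -> "RasterImage":
        with Image.open(path) as im:
            if im.mode in ("L", "I;16"):
                return cls.from_array(np.asarray(im.convert("L")))
            return cls.from_array(np.asarray(im.convert("RGB")))

    # -- basic properties --------------------------------------------------
    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    # -- conversions -------------------------------------------------------
    def to_gray(self) -> "RasterImage":
        if self.colorspace == "gray":
            return self
        return RasterImage.from_array(gray_float(self.pixels))

    def to_rgb(self) -> "RasterImage":
        if self.colorspace == "rgb":
            return self
        return RasterImage(np.repeat(self.pixels[:, :, None], 3, axis=2), "rgb")

    def mirrored(self) -> "RasterImage":
        """Horizontal flip (column order reversed)."""
        return RasterImage(np.ascontiguousarray(self.pixels[:, ::-1]), self.colorspace)

    def save(self, path: str | Path) -> Path:
        """Write PNG (lossless) or JPEG (quality 95) depending on suffix."""
        path = Path(path)
        im = Image.fromarray(self.pixels)
        if path.suffix.lower() in (".jpg", ".jpeg"):
            im.convert("RGB").save(path, quality=JPEG_QUALITY)
        else:
            im.save(path)
        return path


def as_pixels(img) -> np.ndarray:
    """Accept a RasterImage or a bare array; return the uint8 pixel array."""
    if isinstance(img, RasterImage):
        return img.pixels
    return RasterImage.from_array(np.asarray(img)).pixels


def gray_float(pixels: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale as float64 (identity for 2-D input)."""
    px = np.asarray(pixels, dtype=np.float64)
    if px.ndim == 2:
        return px
    r, g, b = LUMA_WEIGHTS
    return r * px[..., 0] + g * px[..., 1] + b * px[..., 2]


def resize_image(img, out_h: int, out_w: int) -> RasterImage:
    """Bilinear resize preserving the 8-bit range."""
    px = as_pixels(img).astype(np.float64)
    if out_h < 1 or out_w < 1:
        raise ParameterError("target size must be positive")
    if px.shape[:2] == (out_h, out_w):
        return RasterImage.from_array(px)
    shape = (out_h, out_w) if px.ndim == 2 else (out_h, out_w, px.shape[2])
    out = _sk_resize(px, shape, order=1, preserve_range=True, anti_aliasing=False)
    return RasterImage.from_array(out)
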