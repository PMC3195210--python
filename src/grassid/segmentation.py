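"""Hue-based segmentation of a single seedling from a top-view colour image.

The plant is separated from the soil background by converting the RGB image to
HSV, zeroing low-saturation (near-gray) pixels, and keeping pixels whose hue
falls inside the green foliage window (54°–154° by default). The binary mask is
then combined with the original image to give a colour-segmented plant region
and its grayscale counterpart, which downstream feature extraction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects

from .errors import EmptySegmentation, InvalidGeometry, OutOfBounds

#: Grayscale intensity weights (ITU-R BT.601 luma) used throughout the package.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds controlling plant/background separation.

    hue_low_deg, hue_high_deg
        Inclusive hue window (degrees on the HSV circle) accepted as foliage.
    saturation_min
        Pixels with HSV saturation below this fraction are treated as
        achromatic background noise and zeroed before hue thresholding.
    min_region_px
        Connected components smaller than this many pixels are discarded as
        salt noise. Set to 0 to keep every pixel that passes the colour test.
    contrast_stretch
        Optional cosmetic linear min–max stretch (common scale across the
        three channels, so hue is unchanged) applied before conversion.
    """

    hue_low_deg: float = 54.0
    hue_high_deg: float = 154.0
    saturation_min: float = 0.15
    min_region_px: int = 25
    contrast_stretch: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_low_deg < self.hue_high_deg <= 360.0):
            raise ValueError("require 0 <= hue_low < hue_high <= 360")
        if not (0.0 <= self.saturation_min <= 1.0):
            raise ValueError("saturation_min must lie in [0, 1]")
        if self.min_region_px < 0:
            raise ValueError("min_region_px must be >= 0")


@dataclass
class PlantRegion:
    """A segmented seedling: mask, masked colour pixels and grayscale pixels.

    ``colour`` and ``gray`` are zero wherever ``mask`` is False; ``gray`` is
    the weighted intensity ``0.2989 R + 0.5870 G + 0.1140 B`` rounded to the
    nearest integer (ties away from zero).
    """

    mask: np.ndarray  # (H, W) bool
    colour: np.ndarray  # (H, W, 3) uint8, background zeroed
    gray: np.ndarray  # (H, W) uint8, background zeroed

    def __post_init__(self) -> None:
        if self.mask.shape != self.gray.shape or self.colour.shape[:2] != self.mask.shape:
            raise ValueError("mask, colour and gray dimensions must agree")


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def stretch_contrast(image: np.ndarray) -> np.ndarray:
    """Linear min–max stretch with a single scale shared by all channels.

    Hue is invariant under this map (a common affine rescale of R, G, B), so
    the stretch is cosmetic with respect to segmentation.
    """
    arr = _as_rgb_array(image).astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return arr.astype(np.uint8)
    out = (arr - lo) * (255.0 / (hi - lo))
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def rgb_to_hue_saturation(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel HSV hue (degrees, 0–360) and saturation (fraction, 0–1).

    Achromatic pixels (R = G = B) have saturation 0 and are reported with
    hue 0 by convention.
    """
    arr = _as_rgb_array(image)
    hsv = rgb2hsv(arr)
    return hsv[..., 0] * 360.0, hsv[..., 1]


def grayscale_intensity(image: np.ndarray) -> np.ndarray:
    """Weighted grayscale intensity, rounded half away from zero, as uint8."""
    arr = _as_rgb_array(image).astype(np.float64)
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    return np.floor(gray + 0.5).astype(np.uint8)


def segment_plant(image: np.ndarray, cfg: SegmentationConfig | None = None) -> PlantRegion:
    """Segment the plant by saturation gating plus hue-window thresholding.

    A pixel enters the mask iff its saturation is at least ``saturation_min``
    and its hue lies in ``[hue_low_deg, hue_high_deg]`` (inclusive); connected
    components smaller than ``min_region_px`` pixels are then removed.

    Raises
    ------
    EmptySegmentation
        If no pixel survives, i.e. no plant was found in the image.
    """
    cfg = cfg or SegmentationConfig()
    arr = _as_rgb_array(image)
    if cfg.contrast_stretch:
        arr = stretch_contrast(arr)
    hue, sat = rgb_to_hue_saturation(arr)
    mask = (sat >= cfg.saturation_min) & (hue >= cfg.hue_low_deg) & (hue <= cfg.hue_high_deg)
    if cfg.min_region_px > 1:
        # max_size removes components <= its value, so "smaller than N" is N - 1
        mask = remove_small_objects(mask, max_size=cfg.min_region_px - 1, connectivity=2)
    if not mask.any():
        raise EmptySegmentation("no plant pixels found after hue/saturation filtering")
    colour = arr * mask[..., None].astype(np.uint8)
    gray = grayscale_intensity(arr) * mask.astype(np.uint8)
    return PlantRegion(mask=mask, colour=colour, gray=gray)


def crop_rectangle(image: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Extract a sub-image; 0-based row-major coordinates, half-open extents."""
    arr = _as_rgb_array(image)
    h, w = arr.shape[:2]
    if height < 1 or width < 1 or top < 0 or left < 0 or top + height > h or left + width > w:
        raise OutOfBounds(
            f"rectangle (top={top}, left={left}, h={height}, w={width}) "
            f"does not fit inside a {h}x{w} image"
        )
    return arr[top : top + height, left : left + width].copy()


def ground_resolution(
    fov_w_mm: float, fov_h_mm: float, img_w_px: int, img_h_px: int
) -> tuple[float, float]:
    """Ground sampling resolution of a nadir camera set-up.

    Returns ``(area_per_px, linear_res)`` where ``area_per_px`` is the ground
    area imaged by one pixel (mm²/pixel) and ``linear_res`` its square root
    (mm/pixel). For a 980 × 720 mm field of view on a 3648 × 2736 px sensor
    this gives 0.07 mm²/pixel and 0.266 mm/pixel.
    """
    if min(fov_w_mm, fov_h_mm, img_w_px, img_h_px) <= 0:
        raise InvalidGeometry("field-of-view and image dimensions must be positive")
    area = (fov_w_mm * fov_h_mm) / (img_w_px * img_h_px)
    return area, float(np.sqrt(area))


# ---------------------------------------------------------------------------
# image I/O

def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG/TIFF as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(_as_rgb_array(image), mode="RGB").save(path)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    Image.fromarray((np.asarray(mask, dtype=bool) * np.uint8(255)), mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127
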