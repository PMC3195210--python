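"""The 11 per-plant visual features: colour indices, shape, and texture.

Colour (7): grayscale-normalized channel factors r_i, g_i, b_i; the red–blue
contrast ratio RBI = (r_i − b_i)/(r_i + b_i); and the excess colour indices
ERI = (r_i − g_i)(r_i − b_i), EGI = (g_i − r_i)(g_i − b_i),
EBI = (b_i − g_i)(b_i − r_i). All are computed per pixel and averaged over the
plant mask. Normalizing by the pixel's grayscale intensity makes them invariant
to a common illumination scale factor.

Shape (2): the erosion width W — twice the number of 3×3 morphological
erosions needed to make the plant region vanish, a leaf-width proxy — and the
Waddle Disk Ratio WDR = W / d, where d is the diameter of the circle whose
area equals the region's pixel area. WDR measures roundness versus linearity
of the foliage.

Texture (2): histogram uniformity U_t = Σ p(z_i)² and entropy
E_t = −Σ p(z_i) log₂ p(z_i) of the region's 256-level grayscale histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import EmptySegmentation, ZeroIntensity
from .segmentation import GRAY_WEIGHTS, PlantRegion

#: Canonical feature order used in tables and models.
FEATURE_NAMES = ["r_i", "g_i", "b_i", "RBI", "ERI", "EGI", "EBI", "W", "WDR", "U_t", "E_t"]

COLOUR_FEATURES = FEATURE_NAMES[:7]

#: 3×3 square structuring element: one erosion peels a one-pixel layer.
_EROSION_KERNEL = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PixelIndices:
    """Colour indices of a single pixel.

    ``rbi_defined`` is False for a pure-green pixel (r_i + b_i = 0), where RBI
    has a 0/0 singularity; RBI is reported as 0 by convention and the pixel is
    excluded from the region-level RBI mean.
    """

    r_i: float
    g_i: float
    b_i: float
    RBI: float
    ERI: float
    EGI: float
    EBI: float
    rbi_defined: bool = True


@dataclass(frozen=True)
class FeatureVector:
    """All 11 features of one segmented plant."""

    r_i: float
    g_i: float
    b_i: float
    RBI: float
    ERI: float
    EGI: float
    EBI: float
    W: int
    WDR: float
    U_t: float
    E_t: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def pixel_colour_indices(R: float, G: float, B: float) -> PixelIndices:
    """Colour indices of one pixel with channel intensities in 0–255.

    Raises :class:`ZeroIntensity` for a pure-black pixel, whose grayscale
    intensity (and hence every normalized factor) is undefined.
    """
    wr, wg, wb = GRAY_WEIGHTS
    intensity = wr * R + wg * G + wb * B
    if intensity == 0:
        raise ZeroIntensity("colour indices undefined for a (0, 0, 0) pixel")
    r = R / intensity
    g = G / intensity
    b = B / intensity
    denom = r + b
    defined = denom > 0
    rbi = (r - b) / denom if defined else 0.0
    return PixelIndices(
        r_i=r,
        g_i=g,
        b_i=b,
        RBI=rbi,
        ERI=(r - g) * (r - b),
        EGI=(g - r) * (g - b),
        EBI=(b - g) * (b - r),
        rbi_defined=bool(defined),
    )


def region_colour_features(region: PlantRegion) -> dict[str, float]:
    """Mask-wise arithmetic means of the 7 per-pixel colour indices.

    Pixels where RBI is singular (pure green) are skipped in the RBI mean;
    in-mask pure-black pixels (possible only with a degenerate mask) are
    skipped entirely.
    """
    if not region.mask.any():
        raise EmptySegmentation("cannot compute colour features of an empty region")
    rgb = region.colour[region.mask].astype(np.float64)
    wr, wg, wb = GRAY_WEIGHTS
    intensity = wr * rgb[:, 0] + wg * rgb[:, 1] + wb * rgb[:, 2]
    ok = intensity > 0
    if not ok.any():
        raise EmptySegmentation("all in-mask pixels are pure black")
    rgb, intensity = rgb[ok], intensity[ok]
    r = rgb[:, 0] / intensity
    g = rgb[:, 1] / intensity
    b = rgb[:, 2] / intensity
    rb = r + b
    defined = rb > 0
    rbi = np.where(defined, (r - b) / np.where(rb > 0, rb, 1.0), 0.0)
    rbi_mean = float(rbi[defined].mean()) if defined.any() else 0.0
    return {
        "r_i": float(r.mean()),
        "g_i": float(g.mean()),
        "b_i": float(b.mean()),
        "RBI": rbi_mean,
        "ERI": float(((r - g) * (r - b)).mean()),
        "EGI": float(((g - r) * (g - b)).mean()),
        "EBI": float(((b - g) * (b - r)).mean()),
    }


def erosion_width(mask: np.ndarray) -> int:
    """Leaf-width proxy: twice the erosions needed to empty the region.

    The mask is eroded with a 3×3 square kernel (pixels beyond the image
    border count as background) until no pixel remains; W is twice the number
    of iterations, so a one-pixel-wide line gives W = 2 and a w-pixel-wide bar
    gives W = 2·ceil(w/2).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptySegmentation("cannot erode an empty mask")
    iterations = 0
    while m.any():
        m = ndi.binary_erosion(m, structure=_EROSION_KERNEL, border_value=0)
        iterations += 1
    return 2 * iterations


def waddle_disk_ratio(mask: np.ndarray, W: int | None = None) -> float:
    """Erosion width divided by the equal-area (Waddle) disk diameter."""
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        raise EmptySegmentation("cannot compute WDR of an empty mask")
    if W is None:
        W = erosion_width(m)
    return W / (2.0 * np.sqrt(area / np.pi))


def texture_features(
    gray: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float, np.ndarray]:
    """Histogram uniformity and entropy of the region's grayscale levels.

    Returns ``(U_t, E_t, counts)`` where counts is the 256-bin histogram over
    mask pixels. U_t = Σ p² is maximal (1) for a constant region; E_t =
    −Σ p log₂ p is maximal (8 bits) for a flat histogram.
    """
    g = np.asarray(gray)
    vals = g[np.asarray(mask, dtype=bool)] if mask is not None else g.ravel()
    if vals.size == 0:
        raise EmptySegmentation("cannot compute texture of an empty region")
    counts = np.bincount(vals.astype(np.intp), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float((p**2).sum()), float(-(nz * np.log2(nz)).sum()), counts


def extract_features(region: PlantRegion) -> FeatureVector:
    """Assemble all 11 features of one segmented plant region."""
    colour = region_colour_features(region)
    W = erosion_width(region.mask)
    wdr = waddle_disk_ratio(region.mask, W)
    u_t, e_t, _ = texture_features(region.gray, region.mask)
    return FeatureVector(**colour, W=W, WDR=wdr, U_t=u_t, E_t=e_t)


# ---------------------------------------------------------------------------
# feature tables

def feature_table(
    records: list[tuple[str, str, FeatureVector]],
) -> pd.DataFrame:
    """Build a feature table from (plant_id, species, features) records."""
    rows = [{"plant_id": pid, "species": sp, **fv.as_dict()} for pid, sp, fv in records]
    return pd.DataFrame(rows, columns=["plant_id", "species", *FEATURE_NAMES])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps CSV and in-memory pipelines bit-identical
    return pd.read_csv(path, float_precision="round_trip")
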