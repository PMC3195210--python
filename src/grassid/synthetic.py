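"""Synthetic top-view seedling images with ground-truth masks.

Grass seedlings at the 1–4 leaf stage are emulated as narrow tapered strokes
radiating from a common base point over a soil-coloured background. Each leaf
follows a gently curved (constant-curvature) path with a linear width taper;
pixel colour interpolates from a base colour to a tip colour, with optional
additive red at the leaf base (the reddish bases of ryegrass and brome),
an additive blue tint (brome's bluish-green foliage), and multiplicative
grayscale speckle that drives the histogram texture features without shifting
hue. The geometry is deliberately schematic rather than botanically accurate:
it gives every downstream stage — segmentation, width/shape, colour and
texture features, PCA, thresholds — a controllable, labelled signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CanvasTooSmall
from .segmentation import save_image, save_mask


@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters of one species.

    Lengths and widths are in pixels (mean, sd); curvature is radians per
    pixel of arc length; colour shifts are additive 0–255 channel offsets;
    ``texture_noise_sd`` is the SD of the multiplicative grayscale speckle
    (0 = perfectly uniform leaf surface).
    """

    name: str
    n_leaves_range: tuple[int, int] = (1, 4)
    leaf_length_px: tuple[float, float] = (55.0, 8.0)
    leaf_width_px: tuple[float, float] = (7.5, 0.7)
    curvature: tuple[float, float] = (0.004, 0.003)
    base_rgb: tuple[float, float, float] = (60.0, 130.0, 50.0)
    tip_rgb: tuple[float, float, float] = (80.0, 150.0, 60.0)
    base_red_boost: float = 0.0
    red_boost_sd: float = 5.0
    blue_tint: float = 0.0
    blue_tint_sd: float = 4.0
    texture_noise_sd: float = 0.02
    rgb_jitter_sd: float = 6.0
    background_rgb: tuple[float, float, float] = (120.0, 85.0, 60.0)
    background_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.leaf_width_px[0] < 1:
            raise ValueError("mean leaf width must be at least 1 px")
        if not 1 <= self.n_leaves_range[0] <= self.n_leaves_range[1]:
            raise ValueError("invalid n_leaves_range")


@dataclass
class SyntheticPlant:
    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool
    species: str
    seed: int
    params_used: dict = field(default_factory=dict)


def default_species_params() -> dict[str, SpeciesParams]:
    """The three-species preset the package's study conditions use.

    Wheat: wider, plain green, near-uniform leaf surface. Ryegrass: clearly
    narrower leaves, reddish base, least uniform surface. Brome: bluish-green
    foliage with a milder red base and intermediate texture.
    """
    wheat = SpeciesParams(name="wheat")
    ryegrass = replace(
        wheat,
        name="ryegrass",
        leaf_width_px=(3.5, 0.4),
        leaf_length_px=(60.0, 8.0),
        base_red_boost=50.0,
        texture_noise_sd=0.12,
    )
    brome = replace(
        wheat,
        name="brome",
        leaf_width_px=(6.5, 0.8),
        base_rgb=(50.0, 128.0, 58.0),
        tip_rgb=(65.0, 145.0, 70.0),
        base_red_boost=18.0,
        blue_tint=15.0,
        texture_noise_sd=0.06,
    )
    return {"wheat": wheat, "ryegrass": ryegrass, "brome": brome}


#: Class sizes of the reference study's image set.
REFERENCE_COUNTS = {"wheat": 118, "brome": 122, "ryegrass": 46}


def _stamp_leaf(
    tmap: np.ndarray,
    base: tuple[float, float],
    theta0: float,
    length: float,
    width: float,
    curvature: float,
) -> None:
    """Rasterize one leaf into tmap (per-pixel minimum arc-length fraction)."""
    h, w = tmap.shape
    steps = max(int(2 * length), 8)
    ds = length / steps
    y, x = base
    theta = theta0
    for s in range(steps + 1):
        t = s / steps
        hw = max(0.6, (width / 2.0) * (1.0 - 0.85 * t))
        r = int(np.ceil(hw))
        yy0, yy1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        xx0, xx1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        if yy0 < yy1 and xx0 < xx1:
            gy, gx = np.ogrid[yy0:yy1, xx0:xx1]
            disk = (gy - y) ** 2 + (gx - x) ** 2 <= hw**2
            patch = tmap[yy0:yy1, xx0:xx1]
            patch[disk] = np.minimum(patch[disk], t)
        theta += curvature * ds
        y += ds * np.sin(theta)
        x += ds * np.cos(theta)


def draw_plant(
    params: SpeciesParams, seed: int, canvas_hw: tuple[int, int] = (180, 180)
) -> SyntheticPlant:
    """Render one seedling; deterministic for a given (params, seed) pair."""
    rng = np.random.default_rng(seed)
    h, w = canvas_hw
    max_reach = (
        params.leaf_length_px[0] + 2 * params.leaf_length_px[1] + params.leaf_width_px[0] / 2
    )
    if max_reach > min(h, w) / 2.0 - 2:
        raise CanvasTooSmall(
            f"leaves of reach ~{max_reach:.0f} px do not fit a {h}x{w} canvas"
        )
    n_leaves = int(rng.integers(params.n_leaves_range[0], params.n_leaves_range[1] + 1))
    base_pt = (h / 2.0 + rng.uniform(-3, 3), w / 2.0 + rng.uniform(-3, 3))

    tmap = np.full((h, w), np.inf)
    lengths, widths = [], []
    phase = rng.uniform(0, 2 * np.pi)
    for i in range(n_leaves):
        theta0 = phase + i * 2 * np.pi / n_leaves + rng.normal(0, 0.25)
        length = float(np.clip(rng.normal(*params.leaf_length_px), 12.0, min(h, w) / 2.0 - 3))
        width = float(max(1.2, rng.normal(*params.leaf_width_px)))
        curv = float(rng.normal(*params.curvature)) * rng.choice([-1.0, 1.0])
        _stamp_leaf(tmap, base_pt, theta0, length, width, curv)
        lengths.append(length)
        widths.append(width)

    mask = np.isfinite(tmap)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.background_rgb)
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, size=img.shape)

    t = tmap[mask]
    base_c = np.asarray(params.base_rgb) + rng.normal(0, params.rgb_jitter_sd, 3)
    tip_c = np.asarray(params.tip_rgb) + rng.normal(0, params.rgb_jitter_sd, 3)
    colours = base_c[None, :] * (1.0 - t[:, None]) + tip_c[None, :] * t[:, None]
    # plants vary independently in base redness and overall blue tint
    red_boost = max(0.0, rng.normal(params.base_red_boost, params.red_boost_sd))
    blue_tint = max(0.0, rng.normal(params.blue_tint, params.blue_tint_sd))
    colours[:, 0] += red_boost * np.clip(1.0 - 3.0 * t, 0.0, 1.0)
    colours[:, 2] += blue_tint
    if params.texture_noise_sd > 0:
        colours *= (1.0 + rng.normal(0.0, params.texture_noise_sd, size=t.size))[:, None]
    img[mask] = colours
    image = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    return SyntheticPlant(
        image=image,
        truth_mask=mask,
        species=params.name,
        seed=int(seed),
        params_used={
            "n_leaves": n_leaves,
            "leaf_lengths": lengths,
            "leaf_widths": widths,
        },
    )


def make_dataset(
    params_by_species: dict[str, SpeciesParams] | None = None,
    n_per_species: dict[str, int] | int = 40,
    seed: int = 0,
    canvas_hw: tuple[int, int] = (180, 180),
) -> tuple[list[SyntheticPlant], pd.DataFrame]:
    """Generate a reproducible labelled dataset plus its manifest table."""
    params_by_species = params_by_species or default_species_params()
    if isinstance(n_per_species, int):
        n_per_species = {sp: n_per_species for sp in params_by_species}
    ss = np.random.SeedSequence(seed)
    plants: list[SyntheticPlant] = []
    rows = []
    for sp in sorted(params_by_species):
        n = n_per_species.get(sp, 0)
        children = ss.spawn(1)[0].generate_state(n) % (2**31)
        for i, child in enumerate(children):
            plant = draw_plant(params_by_species[sp], int(child), canvas_hw)
            plants.append(plant)
            rows.append(
                {
                    "plant_id": f"{sp}_{i:04d}",
                    "species": sp,
                    "seed": int(child),
                    "n_leaves": plant.params_used["n_leaves"],
                    "mean_leaf_width": float(np.mean(plant.params_used["leaf_widths"])),
                    "mean_leaf_length": float(np.mean(plant.params_used["leaf_lengths"])),
                }
            )
    return plants, pd.DataFrame(rows)


def write_dataset(
    plants: list[SyntheticPlant], manifest: pd.DataFrame, outdir: str | Path
) -> None:
    """Write images, truth masks and the manifest CSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, plant in zip(manifest["plant_id"], plants):
        save_image(outdir / f"{pid}.png", plant.image)
        save_mask(outdir / f"{pid}_mask.png", plant.truth_mask)
    files = [f"{pid}.png" for pid in manifest["plant_id"]]
    manifest.assign(file=files).to_csv(outdir / "manifest.csv", index=False)
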