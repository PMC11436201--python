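"""Synthetic well-image generator with exact ground truth.

Emulates transmitted-light images of single wells of a 48-well egg-laying
plate: a bright media background, dark ellipsoidal eggs, a high-contrast
circular wall, and (optionally) egg "reflections" in the clear plastic wall
just outside the well boundary — the artifact that motivates restricting
counting to the fitted well mask. Every image comes with an instance label
mask and per-egg areas/centroids, so the whole downstream pipeline is
testable without real data.

All randomness is seeded: an identical spec produces byte-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse

from .plate import PlateGrid, snake_path, well_filename

__all__ = [
    "EggSpec",
    "SyntheticWellSpec",
    "GroundTruth",
    "render_well",
    "render_plate",
    "random_well_spec",
]

WALL_WIDTH = 5  # px, thickness of the rendered well-wall annulus


@dataclass(frozen=True)
class EggSpec:
    """One planted egg: a filled rotated ellipse darker than the background."""

    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (major, minor) pixels
    orientation: float = 0.0  # radians, major axis vs +x
    intensity: int = 60  # 0-255 grey level

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0 <= self.intensity <= 255:
            raise ValueError("intensity must be an 8-bit grey level")

    @property
    def area(self) -> float:
        """Analytic ellipse area pi*a*b in pixels^2."""
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class SyntheticWellSpec:
    image_size: tuple[int, int] = (600, 600)  # (height, width)
    well_center: tuple[float, float] = (300.0, 300.0)  # (x, y)
    well_radius: float = 260.0
    background: int = 180
    eggs: tuple[EggSpec, ...] = ()
    reflections: tuple[EggSpec, ...] = ()  # rendered like eggs, outside the wall
    noise_sigma: float = 0.0
    seed: int = 0

    def with_reflections(self, reflections: tuple[EggSpec, ...]) -> "SyntheticWellSpec":
        return replace(self, reflections=tuple(reflections))


@dataclass(frozen=True)
class GroundTruth:
    """Instance truth for one rendered well (reflections excluded)."""

    labels: np.ndarray  # uint16 label mask; 0 = background, k = k-th egg
    areas: tuple[int, ...]  # rasterized pixels^2 per instance
    centroids: tuple[tuple[float, float], ...]  # (x, y)
    count: int


def _raster_ellipse(egg: EggSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the filled rotated ellipse, clipped to the image."""
    x, y = egg.center
    a, b = egg.semi_axes
    # skimage rotates counter-clockwise around the row axis; map (x, y) -> (row, col)
    return draw_ellipse(y, x, b, a, shape=shape, rotation=-egg.orientation)


def _check_placement(spec: SyntheticWellSpec) -> None:
    cx, cy = spec.well_center
    for egg in spec.eggs:
        rr, cc = _raster_ellipse(egg, spec.image_size)
        if rr.size == 0:
            raise ValueError(f"egg at {egg.center} rasterizes to nothing")
        dist = np.hypot(cc - cx, rr - cy)
        if dist.max() > spec.well_radius - WALL_WIDTH:
            raise ValueError(f"egg at {egg.center} extends outside the well interior")
    for refl in spec.reflections:
        rr, cc = _raster_ellipse(refl, spec.image_size)
        dist = np.hypot(cc - cx, rr - cy)
        if rr.size and dist.min() < spec.well_radius:
            raise ValueError(f"reflection at {refl.center} intrudes into the well")


def render_well(spec: SyntheticWellSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one well image and its ground truth.

    Deterministic for a fixed spec (the seed drives the noise field). Eggs
    are drawn as filled ellipses darker than the background; the well wall
    is a dark annulus at the well radius; reflections are drawn exactly like
    eggs but lie outside the wall and are absent from the ground truth.
    """
    _check_placement(spec)
    h, w = spec.image_size
    img = np.full((h, w), float(spec.background))
    labels = np.zeros((h, w), dtype=np.uint16)

    # wall annulus
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - spec.well_center[0], yy - spec.well_center[1])
    wall = (dist >= spec.well_radius) & (dist < spec.well_radius + WALL_WIDTH)
    img[wall] = 30.0

    areas: list[int] = []
    centroids: list[tuple[float, float]] = []
    for k, egg in enumerate(spec.eggs, start=1):
        rr, cc = _raster_ellipse(egg, spec.image_size)
        img[rr, cc] = float(egg.intensity)
        labels[rr, cc] = k
        areas.append(int(rr.size))
        centroids.append((float(cc.mean()), float(rr.mean())))
    for refl in spec.reflections:
        rr, cc = _raster_ellipse(refl, spec.image_size)
        img[rr, cc] = float(refl.intensity)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(labels, tuple(areas), tuple(centroids), len(spec.eggs))
    return img, truth


# ---------------------------------------------------------------------------
# Randomized specs

def _sample_egg_geometry(rng: np.random.Generator) -> tuple[float, float, float]:
    """Semi-axes and orientation with analytic area inside [2500, 4000] px^2."""
    area = rng.uniform(2600.0, 3900.0)
    aspect = rng.uniform(1.8, 2.6)  # fly eggs are elongated
    b = math.sqrt(area / (math.pi * aspect))
    return aspect * b, b, rng.uniform(0.0, math.pi)


def random_well_spec(
    seed: int,
    n_eggs: int | None = None,
    mean_eggs: float = 12.0,
    n_reflections: int = 0,
    noise_sigma: float = 0.0,
    image_size: tuple[int, int] = (600, 600),
    well_radius: float = 260.0,
    max_overlap: float = 0.0,
    max_attempts: int = 300,
) -> SyntheticWellSpec:
    """Draw a well spec with randomly placed in-range eggs.

    ``n_eggs`` fixes the requested count; otherwise it is Poisson(mean_eggs).
    Placement is rejection sampling against an occupancy raster: a candidate
    is accepted when at most ``max_overlap`` of its pixels are already
    covered (0.0 = strictly non-overlapping instances). At high densities
    placement can saturate before the requested count; the returned spec
    holds the eggs actually placed, which ARE the ground truth.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    center = (w / 2.0, h / 2.0)
    target = int(n_eggs) if n_eggs is not None else int(rng.poisson(mean_eggs))

    occupied = np.zeros(image_size, dtype=bool)
    eggs: list[EggSpec] = []
    for _ in range(target):
        for _ in range(max_attempts):
            a, b, theta = _sample_egg_geometry(rng)
            r_max = well_radius - WALL_WIDTH - a - 2.0
            if r_max <= 0:
                break
            rho = math.sqrt(rng.uniform(0.0, 1.0)) * r_max
            phi = rng.uniform(0.0, 2.0 * math.pi)
            egg = EggSpec(
                center=(center[0] + rho * math.cos(phi), center[1] + rho * math.sin(phi)),
                semi_axes=(a, b),
                orientation=theta,
                intensity=int(rng.integers(45, 80)),
            )
            rr, cc = _raster_ellipse(egg, image_size)
            # 2 px clearance between strictly non-overlapping eggs
            pad = 2 if max_overlap == 0 else 0
            rr_p, cc_p = draw_ellipse(
                egg.center[1], egg.center[0], b + pad, a + pad,
                shape=image_size, rotation=-theta,
            )
            if occupied[rr_p, cc_p].sum() <= max_overlap * rr.size:
                occupied[rr, cc] = True
                eggs.append(egg)
                break

    reflections: list[EggSpec] = []
    diag = rng.permutation([0.25, 0.75, 1.25, 1.75])  # corner directions, in pi units
    for i in range(n_reflections):
        a, b, theta = _sample_egg_geometry(rng)
        phi = (diag[i % 4] + rng.uniform(-0.08, 0.08)) * math.pi
        # clear of the rendered wall so the reflection stays a separate object
        rho = well_radius + WALL_WIDTH + b + 8.0
        # tangential orientation keeps the whole ellipse outside the radius
        reflections.append(
            EggSpec(
                center=(center[0] + rho * math.cos(phi), center[1] + rho * math.sin(phi)),
                semi_axes=(a, b),
                orientation=phi + math.pi / 2.0,
                intensity=int(rng.integers(45, 80)),
            )
        )

    return SyntheticWellSpec(
        image_size=image_size,
        well_center=center,
        well_radius=well_radius,
        eggs=tuple(eggs),
        reflections=tuple(reflections),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Plate-level rendering

def render_plate(
    grid: PlateGrid,
    specs: list[SyntheticWellSpec],
    out_dir: str | Path,
    plate_id: str = "plate01",
    image_format: str = "png",
    write_masks: bool = False,
) -> pd.DataFrame:
    """Render one image per well in snake order plus a truth CSV.

    Filenames follow the ``<plate>_<label>.<ext>`` scheme the counting CLI
    parses. The truth table (well_label, true_count) is written as
    ``<plate>_truth.csv``; label masks go to 16-bit TIFFs when requested.
    """
    if len(specs) != grid.n_wells:
        raise ValueError(f"need {grid.n_wells} specs for this grid, got {len(specs)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for addr, spec in zip(snake_path(grid), specs):
        img, truth = render_well(spec)
        name = well_filename(plate_id, addr, image_format)
        if image_format in ("tif", "tiff"):
            tifffile.imwrite(out / name, img)
        else:
            iio.imwrite(out / name, img)
        if write_masks:
            tifffile.imwrite(out / f"{plate_id}_{addr.label}_mask.tif", truth.labels)
        rows.append({"well_label": addr.label, "true_count": truth.count})
    table = pd.DataFrame(rows)
    table.to_csv(out / f"{plate_id}_truth.csv", index=False)
    return table
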