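"""Filtering detections into per-well egg counts, with table and overlay export.

Two filters turn raw detections into counts: detections must lie inside the
fitted well boundary (this removes reflections of eggs in the clear plastic
wall, which otherwise inflate counts), and their area must fall inside the
plausible single-egg window of 2500-4000 px^2 (this removes debris and
fused blobs). Counts are exported as CSV (canonical) or XLSX, and overlay
images with instance outlines and the burned-in count support visual QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import matplotlib
import numpy as np
import pandas as pd

from .plate import PlateGrid, WellAddress, parse_well_filename, snake_path
from .segment import DetectionSet, DetectorConfig, run_backend
from .wells import WellBoundary, WellDetectionError, detect_well, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "WellCountRecord",
    "filter_detections",
    "count_well",
    "count_plate",
    "export_counts",
    "read_counts",
    "save_overlay",
]

COUNT_COLUMNS = ["plate_id", "well_label", "condition", "day", "count", "n_prefilter", "flags"]


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion rules for a detection to count as one egg.

    Areas are inclusive bounds on the rasterized mask; detections strictly
    below 2500 px^2 or above 4000 px^2 are excluded, as are detections
    outside the (slightly eroded) well boundary.
    """

    area_min: float = 2500.0
    area_max: float = 4000.0
    require_inside_well: bool = True
    inside_rule: str = "centroid"  # or "full-mask"
    boundary_erosion: float = 2.0  # px, excludes wall pixels from the mask

    def __post_init__(self) -> None:
        if not 0 < self.area_min < self.area_max:
            raise ValueError("need 0 < area_min < area_max")
        if self.inside_rule not in ("centroid", "full-mask"):
            raise ValueError("inside_rule must be 'centroid' or 'full-mask'")


@dataclass(frozen=True)
class WellCountRecord:
    well: WellAddress
    plate_id: str
    count: int
    n_prefilter: int
    condition: str = ""
    day: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.count > self.n_prefilter:
            raise ValueError("count cannot exceed the pre-filter detection count")


def filter_detections(
    dets: DetectionSet, boundary: WellBoundary | None, cfg: FilterConfig = FilterConfig()
) -> DetectionSet:
    """Keep detections inside the eroded boundary with area in the egg window."""
    kept = []
    for d in dets:
        if not cfg.area_min <= d.area <= cfg.area_max:
            continue
        if cfg.require_inside_well and boundary is not None:
            if cfg.inside_rule == "centroid":
                inside = bool(
                    boundary.contains(d.centroid[0], d.centroid[1], cfg.boundary_erosion)
                )
            else:
                ys, xs = np.nonzero(d.mask)
                inside = bool(boundary.contains(xs, ys, cfg.boundary_erosion).all())
            if not inside:
                continue
        kept.append(d)
    return replace(dets, instances=tuple(kept))


def count_well(
    image_path: str | Path,
    boundary: WellBoundary | None = None,
    detector_cfg: DetectorConfig = DetectorConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    est_diameter: float | None = None,
    backend: str = "reference",
    plate_id: str | None = None,
    well: WellAddress | None = None,
) -> WellCountRecord:
    """Count eggs in one well image: preprocess, detect, filter, record.

    When no boundary is supplied it is detected from this image using
    ``est_diameter``; a failed detection falls back to the centered
    estimate and flags the record rather than aborting the plate.
    """
    path = Path(image_path)
    if plate_id is None or well is None:
        parsed_plate, parsed_well = parse_well_filename(path.name)
        plate_id = plate_id or parsed_plate
        well = well or parsed_well
    raw = iio.imread(path)
    img = preprocess(raw)
    flags: list[str] = []
    if boundary is None and filter_cfg.require_inside_well:
        if est_diameter is None:
            raise ValueError("est_diameter is required when no boundary is supplied")
        try:
            boundary = detect_well(img, est_diameter)
        except WellDetectionError as err:
            boundary = err.fallback
            flags.append("well_detection_fallback")
            logger.warning("well %s: %s; using fallback boundary", well.label, err)
    dets = run_backend(img, backend, detector_cfg)
    filtered = filter_detections(dets, boundary, filter_cfg)
    return WellCountRecord(
        well=well,
        plate_id=plate_id,
        count=len(filtered),
        n_prefilter=len(dets),
        flags=tuple(flags),
    )


def count_plate(
    image_dir: str | Path,
    layout: pd.DataFrame | None = None,
    grid: PlateGrid = PlateGrid(),
    detector_cfg: DetectorConfig = DetectorConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
    est_diameter: float = 520.0,
    backend: str = "reference",
    propagate: bool = True,
) -> pd.DataFrame:
    """Count every well image in a directory, ordered by the snake path.

    Filenames must follow ``<plate>_<label>.<ext>``; duplicates are a hard
    error. The boundary detected on the first image is propagated to the
    rest (the rig registers every image identically); set
    ``propagate=False`` to re-detect per image. ``layout`` maps well labels
    to condition/day; wells missing from it are flagged and keep defaults.
    """
    image_dir = Path(image_dir)
    paths: dict[str, Path] = {}
    plate_ids = set()
    for p in sorted(image_dir.iterdir()) if image_dir.is_dir() else []:
        if p.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        if p.stem.endswith("_mask"):
            continue
        plate_id, addr = parse_well_filename(p.name)
        if addr.label in paths:
            raise ValueError(f"duplicate well label {addr.label} in {image_dir}")
        paths[addr.label] = p
        plate_ids.add(plate_id)
    if not paths:
        warnings.warn(f"no well images found in {image_dir}", stacklevel=2)
        return pd.DataFrame(columns=COUNT_COLUMNS)

    layout_by_well = {}
    if layout is not None:
        layout_by_well = {str(r["well_label"]): r for _, r in layout.iterrows()}

    shared_boundary: WellBoundary | None = None
    records: list[WellCountRecord] = []
    n_failures = 0
    for addr in snake_path(grid):
        if addr.label not in paths:
            continue
        path = paths[addr.label]
        boundary = shared_boundary if propagate else None
        rec = count_well(
            path, boundary=boundary, detector_cfg=detector_cfg,
            filter_cfg=filter_cfg, est_diameter=est_diameter, backend=backend,
        )
        if propagate and shared_boundary is None and "well_detection_fallback" not in rec.flags:
            img = preprocess(iio.imread(path))
            try:
                shared_boundary = detect_well(img, est_diameter)
            except WellDetectionError as err:
                shared_boundary = err.fallback
        extra_flags: list[str] = []
        meta = layout_by_well.get(addr.label)
        if layout is not None and meta is None:
            extra_flags.append("missing_layout")
        rec = replace(
            rec,
            condition=str(meta["condition"]) if meta is not None else "",
            day=int(meta["day"]) if meta is not None else 0,
            flags=rec.flags + tuple(extra_flags),
        )
        if "well_detection_fallback" in rec.flags:
            n_failures += 1
        records.append(rec)
    if n_failures:
        logger.warning("%d wells used the fallback boundary", n_failures)

    return pd.DataFrame(
        [
            {
                "plate_id": r.plate_id,
                "well_label": r.well.label,
                "condition": r.condition,
                "day": r.day,
                "count": r.count,
                "n_prefilter": r.n_prefilter,
                "flags": ";".join(r.flags),
            }
            for r in records
        ],
        columns=COUNT_COLUMNS,
    )


def export_counts(table: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write the counts table as CSV (canonical) or XLSX (compatibility)."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() == ".xlsx" else "csv")
    out = table.reindex(columns=COUNT_COLUMNS)
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "xlsx":
        out.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df["flags"] = df["flags"].fillna("")
    return df.reindex(columns=COUNT_COLUMNS)


def save_overlay(
    img: np.ndarray,
    dets: DetectionSet,
    boundary: WellBoundary | None,
    path: str | Path,
) -> Path:
    """Save the image with instance outlines, the well circle and the count."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, cmap="gray", vmin=0, vmax=255)
    for d in dets:
        poly = np.vstack([d.polygon, d.polygon[:1]])
        ax.plot(poly[:, 0], poly[:, 1], color="yellow", lw=1.0)
    if boundary is not None:
        theta = np.linspace(0, 2 * np.pi, 256)
        ax.plot(
            boundary.center[0] + boundary.radius * np.cos(theta),
            boundary.center[1] + boundary.radius * np.sin(theta),
            color="red", lw=1.2,
        )
    ax.text(
        8, 20, f"count = {len(dets)}", color="white", fontsize=14,
        bbox=dict(facecolor="black", alpha=0.6, pad=2),
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
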