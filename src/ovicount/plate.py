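"""Plate-grid addressing, corner calibration and snake-path scan ordering.

A 48-well plate is a 6x8 grid of wells. The imaging rig is calibrated by
aligning a target with the four corner wells; every other well center is
obtained by bilinear interpolation between those four points. Images are
acquired in a boustrophedon ("snake") path over the grid, so the scan index
of a file determines which well it shows.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PlateGrid",
    "WellAddress",
    "CornerCalibration",
    "ScanPath",
    "snake_path",
    "interpolate_well_centers",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_scan_path_csv",
    "parse_well_filename",
    "well_filename",
]

_ROW_LETTERS = string.ascii_uppercase


@dataclass(frozen=True)
class PlateGrid:
    """Rectangular well grid; the default is the 48-well (6 rows x 8 cols) format."""

    n_rows: int = 6
    n_cols: int = 8
    well_diameter: float | None = None  # pixels or mm, caller's unit
    diameter_unit: str = "px"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.n_rows > len(_ROW_LETTERS):
            raise ValueError(f"at most {len(_ROW_LETTERS)} rows supported")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def addresses(self) -> list["WellAddress"]:
        """All addresses in row-major order."""
        return [
            WellAddress(r, c) for r in range(self.n_rows) for c in range(self.n_cols)
        ]


@dataclass(frozen=True, order=True)
class WellAddress:
    """0-based (row, col) plus the conventional letter+number label, e.g. A1.

    Row A is the top row in image coordinates (y increasing downward).
    """

    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("row and col must be non-negative")

    @property
    def label(self) -> str:
        return f"{_ROW_LETTERS[self.row]}{self.col + 1}"

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        label = label.strip().upper()
        if not label or label[0] not in _ROW_LETTERS or not label[1:].isdigit():
            raise ValueError(f"malformed well label: {label!r}")
        return cls(_ROW_LETTERS.index(label[0]), int(label[1:]) - 1)


_CORNERS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class CornerCalibration:
    """Planar coordinates of the four corner well centers (one shared unit)."""

    top_left: tuple[float, float]
    top_right: tuple[float, float]
    bottom_left: tuple[float, float]
    bottom_right: tuple[float, float]

    def __post_init__(self) -> None:
        pts = [self.top_left, self.top_right, self.bottom_right, self.bottom_left]
        if len(set(pts)) != 4:
            raise ValueError("corner points must be distinct")
        # shoelace area of the quadrilateral in corner order TL-TR-BR-BL
        area = 0.0
        for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
            area += x1 * y2 - x2 * y1
        if abs(area) < 1e-12:
            raise ValueError("degenerate corner calibration (zero-area quadrilateral)")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in _CORNERS}


@dataclass(frozen=True)
class ScanPath:
    """Ordered (address, coordinate) visit list covering every well once."""

    entries: tuple[tuple[WellAddress, tuple[float, float]], ...] = field()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def snake_path(grid: PlateGrid) -> list[WellAddress]:
    """Boustrophedon traversal: row 0 left-to-right, row 1 right-to-left, etc.

    The camera starts at the top-left well; rows are the slow axis.
    """
    order: list[WellAddress] = []
    for r in range(grid.n_rows):
        cols = range(grid.n_cols) if r % 2 == 0 else range(grid.n_cols - 1, -1, -1)
        order.extend(WellAddress(r, c) for c in cols)
    return order


def interpolate_well_centers(
    calib: CornerCalibration, grid: PlateGrid
) -> dict[WellAddress, tuple[float, float]]:
    """Bilinear interpolation of every well center from the four corner points.

    Fractional coordinates are u = col/(n_cols-1), v = row/(n_rows-1); the
    corner wells map exactly onto the calibration points. Coordinates stay
    floating point in the calibration unit.
    """
    tl, tr = calib.top_left, calib.top_right
    bl, br = calib.bottom_left, calib.bottom_right
    centers: dict[WellAddress, tuple[float, float]] = {}
    for addr in grid.addresses():
        u = addr.col / (grid.n_cols - 1) if grid.n_cols > 1 else 0.0
        v = addr.row / (grid.n_rows - 1) if grid.n_rows > 1 else 0.0
        x = (1 - u) * (1 - v) * tl[0] + u * (1 - v) * tr[0] + (1 - u) * v * bl[0] + u * v * br[0]
        y = (1 - u) * (1 - v) * tl[1] + u * (1 - v) * tr[1] + (1 - u) * v * bl[1] + u * v * br[1]
        centers[addr] = (x, y)
    return centers


def scan_path_with_coords(calib: CornerCalibration, grid: PlateGrid) -> ScanPath:
    centers = interpolate_well_centers(calib, grid)
    return ScanPath(tuple((addr, centers[addr]) for addr in snake_path(grid)))


# ---------------------------------------------------------------------------
# File interchange

def write_calibration_csv(calib: CornerCalibration, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["corner", "x", "y"])
        for name, (x, y) in calib.as_dict().items():
            w.writerow([name, x, y])


def read_calibration_csv(path: str | Path) -> CornerCalibration:
    points: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points[row["corner"]] = (float(row["x"]), float(row["y"]))
    missing = [c for c in _CORNERS if c not in points]
    if missing:
        raise ValueError(f"calibration CSV missing corners: {missing}")
    return CornerCalibration(**{c: points[c] for c in _CORNERS})


def write_scan_path_csv(path_obj: ScanPath, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "label", "x", "y"])
        for i, (addr, (x, y)) in enumerate(path_obj):
            w.writerow([i, addr.label, x, y])


def well_filename(plate_id: str, addr: WellAddress, ext: str = "png") -> str:
    """Canonical image filename, e.g. ``plate01_A1.png``."""
    return f"{plate_id}_{addr.label}.{ext}"


def parse_well_filename(name: str) -> tuple[str, WellAddress]:
    """Parse ``<plate>_<label>.<ext>`` into (plate_id, address)."""
    stem = Path(name).stem
    if "_" not in stem:
        raise ValueError(f"filename {name!r} does not match <plate>_<well>.<ext>")
    plate_id, _, label = stem.rpartition("_")
    return plate_id, WellAddress.from_label(label)
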