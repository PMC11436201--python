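"""Preprocessing and circular well-boundary detection.

The raw camera frames show one well each, under transmitted light: eggs are
dark on a bright media background. Preprocessing inverts the image (eggs
become bright), collapses it to 8-bit grayscale and normalizes intensity by
a robust percentile stretch. The well wall is then located from a Canny
edge map with a seeded RANSAC circle fit, and — because the rig registers
every image of a plate identically — the boundary found on the first image
is simply propagated to the rest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.feature import canny
from skimage.measure import CircleModel, EllipseModel, ransac

__all__ = [
    "WellBoundary",
    "WellDetectionError",
    "preprocess",
    "detect_well",
    "propagate_boundary",
]


@dataclass(frozen=True)
class WellBoundary:
    """Fitted well edge used as the counting mask.

    ``fit_quality`` is the angular coverage of the fitted curve by edge
    pixels within the inlier tolerance: the fraction of angular bins around
    the circle that contain at least one supporting edge pixel.
    """

    center: tuple[float, float]  # (x, y) pixels
    radius: float  # circle model
    fit_quality: float = 0.0
    semi_axes: tuple[float, float] | None = None  # ellipse model, if fitted
    orientation: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.fit_quality <= 1.0:
            raise ValueError("fit_quality must be in [0, 1]")

    def contains(self, x: np.ndarray, y: np.ndarray, erosion: float = 0.0) -> np.ndarray:
        """Point-in-boundary test against the circle eroded by ``erosion`` px."""
        return np.hypot(np.asarray(x) - self.center[0], np.asarray(y) - self.center[1]) <= (
            self.radius - erosion
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "center_x": self.center[0],
            "center_y": self.center[1],
            "radius": self.radius,
            "fit_quality": self.fit_quality,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WellBoundary":
        d = json.loads(Path(path).read_text())
        return cls((d["center_x"], d["center_y"]), d["radius"], d["fit_quality"])


class WellDetectionError(RuntimeError):
    """Raised when no acceptable boundary fit exists; carries a fallback."""

    def __init__(self, message: str, fallback: WellBoundary):
        super().__init__(message)
        self.fallback = fallback


def preprocess(raw: np.ndarray, invert: bool = True) -> np.ndarray:
    """Invert, collapse to 8-bit grayscale, percentile-normalize.

    Color frames are channel-averaged. Inversion makes eggs bright. The
    1st/99th intensity percentiles are mapped linearly onto 0/255 and the
    result clipped — a robust alternative to min–max stretching that ignores
    isolated hot pixels. A constant image has no contrast to stretch; it
    maps to mid-grey 128 with a warning.
    """
    img = np.asarray(raw, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"expected 2D or 3-channel image, got shape {raw.shape}")
    if invert:
        img = 255.0 - img
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi - lo < 1e-9:
        warnings.warn("constant image: normalization degenerates to mid-grey", stacklevel=2)
        return np.full(img.shape, 128, dtype=np.uint8)
    img = (img - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _coverage(edges_xy: np.ndarray, center: tuple[float, float], radius: float,
              tol: float, n_bins: int = 180) -> float:
    """Fraction of angular bins of the circle supported by an inlier edge pixel."""
    dx = edges_xy[:, 0] - center[0]
    dy = edges_xy[:, 1] - center[1]
    r = np.hypot(dx, dy)
    inliers = np.abs(r - radius) <= tol
    if not inliers.any():
        return 0.0
    ang = np.arctan2(dy[inliers], dx[inliers])
    bins = ((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    return np.unique(bins).size / n_bins


def detect_well(
    img: np.ndarray,
    est_diameter: float,
    model: str = "circle",
    sigma: float = 2.0,
    inlier_tol: float = 3.0,
    max_trials: int = 500,
    min_quality: float = 0.5,
    seed: int = 0,
) -> WellBoundary:
    """Locate the well boundary in a preprocessed image.

    Canny edges (Gaussian sigma 2, hysteresis thresholds at the 70th/90th
    gradient-magnitude quantiles) feed a seeded RANSAC circle fit whose
    radius is constrained to ±15% of ``est_diameter/2``; the consensus set
    is refined by a least-squares re-fit. An ellipse model is available via
    ``model="ellipse"`` (the circle's quality gate still applies, computed
    on the mean semi-axis). If angular coverage of the fit falls below
    ``min_quality`` a :class:`WellDetectionError` is raised carrying the
    fallback boundary: image center, radius ``est_diameter/2``.
    """
    h, w = img.shape
    if not 0 < est_diameter <= min(h, w):
        raise ValueError("est_diameter must be in (0, min image dimension]")
    r_est = est_diameter / 2.0
    fallback = WellBoundary((w / 2.0, h / 2.0), r_est, 0.0)

    edges = canny(img.astype(float), sigma=sigma, low_threshold=0.70,
                  high_threshold=0.90, use_quantiles=True)
    ys, xs = np.nonzero(edges)
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) < 3:
        raise WellDetectionError("too few edge pixels for a boundary fit", fallback)

    r_lo, r_hi = 0.85 * r_est, 1.15 * r_est

    def radius_ok(model_inst, *data):
        return r_lo <= model_inst.radius <= r_hi

    try:
        fit, inliers = ransac(
            pts, CircleModel, min_samples=3, residual_threshold=inlier_tol,
            max_trials=max_trials, is_model_valid=radius_ok,
            rng=np.random.default_rng(seed),
        )
    except Exception:
        fit, inliers = None, None
    if fit is None or inliers is None or inliers.sum() < 3:
        raise WellDetectionError("no circle candidate within the radius window", fallback)

    refined = CircleModel.from_estimate(pts[inliers])
    (cx, cy), r = fit.center, fit.radius
    if refined and r_lo <= refined.radius <= r_hi:
        (cx, cy), r = refined.center, refined.radius
    # The wall has finite thickness and contributes an inner and an outer
    # Canny edge; the counting mask must follow the inner one. Iteratively
    # re-fit on the innermost edge band until the selection stabilizes.
    for _ in range(3):
        radii = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        near = np.abs(radii - r) <= 2 * inlier_tol
        if near.sum() < 3:
            break
        anchor = np.percentile(radii[near], 10)
        band = near & (np.abs(radii - anchor) <= 2.0)
        inner = CircleModel.from_estimate(pts[band])
        if inner and r_lo <= inner.radius <= r_hi:
            (cx, cy), r = inner.center, inner.radius
        else:
            break
    quality = _coverage(pts, (cx, cy), r, inlier_tol)
    if quality < min_quality:
        raise WellDetectionError(
            f"boundary fit quality {quality:.2f} below {min_quality}", fallback
        )
    boundary = WellBoundary((float(cx), float(cy)), float(r), float(quality))

    if model == "ellipse":
        near = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) <= 2 * inlier_tol
        ell = EllipseModel.from_estimate(pts[near])
        if ell:
            (exc, eyc), (ea, eb), etheta = ell.center, ell.axis_lengths, ell.theta
            boundary = replace(
                boundary,
                center=(float(exc), float(eyc)),
                radius=float((ea + eb) / 2.0),
                semi_axes=(float(ea), float(eb)),
                orientation=float(etheta),
            )
    return boundary


def propagate_boundary(boundary: WellBoundary, n_images: int) -> list[WellBoundary]:
    """Copy the first-image boundary to every image of a registered plate."""
    if n_images < 0:
        raise ValueError("n_images must be non-negative")
    return [boundary] * n_images
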