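"""Star-convex egg detection: candidates, score threshold, and mask NMS.

The production segmenter in this problem domain is a trained star-convex
deep model; shipping trained weights is out of scope for this toolkit.
Instead a fully deterministic *reference detector* implements the same
contracts: candidates are scored star-convex polygons (a fixed number of
radial rays cast from an intensity-weighted centroid), thresholded on score
and resolved by greedy mask-IoU non-maximum suppression. Any external
learned model can replace the reference detector through the backend
registry (:func:`run_backend`) as long as it emits the same
:class:`DetectionSet` form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import EllipseModel, label as cc_label
from skimage.segmentation import watershed

__all__ = [
    "DetectorConfig",
    "DetectionInstance",
    "DetectionSet",
    "detect_candidates",
    "apply_score_threshold",
    "nms",
    "mask_iou",
    "run_backend",
    "register_backend",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Knobs of the detection stage.

    ``prob_thresh`` is the minimum candidate score kept (default 0.7, the
    standard default of the segmentation framework this pipeline follows;
    the tuned production value 0.706 is a documented preset).
    ``nms_thresh`` is the mask-IoU ceiling between kept instances (0.3).
    """

    prob_thresh: float = 0.7
    nms_thresh: float = 0.3
    n_rays: int = 32
    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"  # or "mean"
    min_candidate_area: int = 400  # px^2, drops noise specks and wall-edge slivers; well below any egg

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_thresh <= 1.0 and 0.0 <= self.nms_thresh <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.n_rays < 8:
            raise ValueError("n_rays must be at least 8")


TUNED_PROB_THRESH = 0.706  # production preset tuned on hand-annotated wells


@dataclass(frozen=True)
class DetectionInstance:
    """One candidate egg: a scored star-convex polygon with its raster mask."""

    centroid: tuple[float, float]  # (x, y)
    polygon: np.ndarray  # (n_rays, 2) vertex array, (x, y)
    mask: np.ndarray  # full-frame bool raster of the polygon
    area: int  # rasterized pixel count
    score: float
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (r0, r1, c0, c1), half-open

    def __post_init__(self) -> None:
        if self.bbox == (0, 0, 0, 0) and self.mask.any():
            ys, xs = np.nonzero(self.mask)
            object.__setattr__(
                self, "bbox",
                (int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1),
            )


@dataclass(frozen=True)
class DetectionSet:
    """All candidate instances of one well image plus their provenance."""

    instances: tuple[DetectionInstance, ...]
    image_shape: tuple[int, int]
    provenance: str = "reference"

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (0 if both are empty)."""
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    union = np.count_nonzero(a) + np.count_nonzero(b) - inter
    return inter / union


def _star_polygon(comp: np.ndarray, centroid_rc: tuple[float, float], n_rays: int) -> np.ndarray:
    """Cast ``n_rays`` rays from the centroid to the component boundary.

    Samples each ray outward in 0.5 px steps and keeps the last run of
    points still inside the component; the resulting vertex list is
    star-convex about the centroid by construction.
    """
    h, w = comp.shape
    cy, cx = centroid_rc
    angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    ys, xs = np.nonzero(comp)
    max_r = float(np.hypot(ys - cy, xs - cx).max()) + 1.0
    radii = np.arange(0.5, max_r + 0.5, 0.5)
    px = np.rint(cx + radii[None, :] * np.cos(angles)[:, None]).astype(int)
    py = np.rint(cy + radii[None, :] * np.sin(angles)[:, None]).astype(int)
    valid = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    inside = np.zeros_like(valid)
    inside[valid] = comp[py[valid], px[valid]]
    # index of the first step outside the component, per ray
    first_out = np.where(inside.all(axis=1), inside.shape[1], np.argmin(inside, axis=1))
    r_in = np.where(first_out > 0, radii[np.maximum(first_out - 1, 0)], 0.0)
    # boundary pixels extend half a pixel past their centers
    r_in = np.where(r_in > 0, r_in + 0.5, 0.0)
    return np.column_stack([cx + r_in * np.cos(angles), cy + r_in * np.sin(angles)])


def _ellipse_residual_score(verts: np.ndarray) -> float:
    """1 for a perfect ellipse outline, decaying with relative radial residual.

    The residual is the rms of (rho - 1), where rho is each vertex's
    normalized elliptical radius in the fitted ellipse's frame — a
    closed-form stand-in for the exact point-to-curve distance that agrees
    with it to first order for near-elliptical outlines.
    """
    model = EllipseModel.from_estimate(verts)
    if not model:
        return 0.0
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if a <= 0 or b <= 0:
        return 0.0
    dx, dy = verts[:, 0] - xc, verts[:, 1] - yc
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    rho = np.hypot(u / a, v / b)
    rel = float(np.sqrt(np.mean((rho - 1.0) ** 2)))
    return float(np.clip(1.0 - 4.0 * rel, 0.0, 1.0))


def _contrast_score(img: np.ndarray, mask: np.ndarray) -> float:
    """Foreground-vs-surround Michelson contrast mapped to [0, 1].

    Medians keep the score robust when the surround ring clips a bright
    neighbour (another egg, the well wall). Computed on a bounding-box
    crop for speed.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return 0.0
    pad = 6
    r0, r1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, mask.shape[0])
    c0, c1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, mask.shape[1])
    m = mask[r0:r1, c0:c1]
    crop = img[r0:r1, c0:c1]
    ring = ndimage.binary_dilation(m, iterations=5) & ~m
    inside = float(np.median(crop[m]))
    outside = float(np.median(crop[ring])) if ring.any() else 0.0
    if inside + outside <= 0:
        return 0.0
    return float(np.clip((inside - outside) / (inside + outside), 0.0, 1.0))


def _split_fused(components: np.ndarray, min_part: int) -> np.ndarray:
    """One-step marker-based watershed split of fused candidates.

    Eggs laid touching each other merge into one thresholded component.
    Every component is probed with a Euclidean distance transform: a single
    convex egg has a unimodal distance ridge (one peak, left untouched),
    while a fused pair has one peak per egg and is split along the
    watershed between them. Peaks closer than the component's own maximum
    thickness count as one object, and a split is only accepted when every
    part is at least ``min_part`` px.
    """
    ids = np.unique(components[components > 0])
    if ids.size == 0:
        return components
    out = components.copy()
    next_id = int(components.max()) + 1
    objects = ndimage.find_objects(components)
    for comp_id in ids:
        sl = objects[comp_id - 1]
        comp = components[sl] == comp_id
        dist = ndimage.distance_transform_edt(np.pad(comp, 1))[1:-1, 1:-1]
        min_dist = max(5, int(round(dist.max())))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=comp, exclude_border=False)
        if len(peaks) < 2:
            continue
        markers = np.zeros(comp.shape, dtype=int)
        for j, (pr, pc) in enumerate(peaks, start=1):
            markers[pr, pc] = j
        parts = watershed(-dist, markers=markers, mask=comp)
        part_ids, part_counts = np.unique(parts[parts > 0], return_counts=True)
        if len(part_ids) < 2 or part_counts.min() < min_part:
            continue
        region = out[sl]
        region[comp] = 0
        for j in part_ids:
            region[parts == j] = next_id
            next_id += 1
    return out


def detect_candidates(img: np.ndarray, cfg: DetectorConfig = DetectorConfig()) -> DetectionSet:
    """Find all candidate instances in a preprocessed (eggs-bright) image.

    The smoothed image is thresholded (Otsu by default), connected
    components become candidates (oversized ones are watershed-split), each
    candidate gets a star-convex polygon from radial rays, and the score is
    the geometric mean of the contrast score and the ellipse-fit residual
    score. Output is unthresholded and pre-NMS; an empty foreground yields
    an empty set, not an error. Fully deterministic.
    """
    arr = np.asarray(img, dtype=float)
    smoothed = gaussian(arr, sigma=cfg.smoothing_sigma, preserve_range=True)
    if smoothed.max() - smoothed.min() < 1e-9:
        return DetectionSet((), arr.shape)
    if cfg.threshold_method == "otsu":
        thresh = threshold_otsu(smoothed)
    elif cfg.threshold_method == "mean":
        thresh = float(smoothed.mean())
    else:
        raise ValueError(f"unknown threshold method {cfg.threshold_method!r}")
    fg = smoothed > thresh
    components = cc_label(fg)

    # pre-filter speckles so the median area reflects real candidates
    ids, counts = np.unique(components[components > 0], return_counts=True)
    small = ids[counts < cfg.min_candidate_area]
    if small.size:
        components[np.isin(components, small)] = 0
    components = _split_fused(components, cfg.min_candidate_area)

    instances: list[DetectionInstance] = []
    for comp_id in np.unique(components[components > 0]):
        comp = components == comp_id
        if np.count_nonzero(comp) < cfg.min_candidate_area:
            continue
        weights = np.where(comp, smoothed, 0.0)
        cy, cx = ndimage.center_of_mass(weights)
        if not comp[int(round(cy)), int(round(cx))]:
            cy, cx = ndimage.center_of_mass(comp)  # fall back to geometric centroid
        verts = _star_polygon(comp, (cy, cx), cfg.n_rays)
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=comp.shape)
        mask = np.zeros(comp.shape, dtype=bool)
        mask[rr, cc] = True
        if not mask.any():
            continue
        score = math.sqrt(_contrast_score(smoothed, mask) * _ellipse_residual_score(verts))
        instances.append(
            DetectionInstance(
                centroid=(float(cx), float(cy)),
                polygon=verts,
                mask=mask,
                area=int(np.count_nonzero(mask)),
                score=float(score),
            )
        )
    # stable raster order: by centroid row, then column
    instances.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    return DetectionSet(tuple(instances), arr.shape)


def apply_score_threshold(dets: DetectionSet, prob_thresh: float) -> DetectionSet:
    """Keep exactly the instances with score >= ``prob_thresh``, order preserved."""
    kept = tuple(d for d in dets if d.score >= prob_thresh)
    return replace(dets, instances=kept)


def _bbox_overlap(a: DetectionInstance, b: DetectionInstance) -> bool:
    ar0, ar1, ac0, ac1 = a.bbox
    br0, br1, bc0, bc1 = b.bbox
    return ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1


def nms(dets: DetectionSet, nms_thresh: float) -> DetectionSet:
    """Greedy mask-IoU non-maximum suppression.

    Instances are visited by descending score (ties: larger area first,
    then centroid raster order) and kept iff their IoU with every
    already-kept instance is <= ``nms_thresh``. The global top-scoring
    instance is therefore always kept.
    """
    order = sorted(
        dets.instances,
        key=lambda d: (-d.score, -d.area, d.centroid[1], d.centroid[0]),
    )
    kept: list[DetectionInstance] = []
    for cand in order:
        if all(
            not _bbox_overlap(cand, k) or mask_iou(cand.mask, k.mask) <= nms_thresh
            for k in kept
        ):
            kept.append(cand)
    return replace(dets, instances=tuple(kept))


# ---------------------------------------------------------------------------
# Backend registry: plug in an external learned model

BackendFn = Callable[[np.ndarray, DetectorConfig], DetectionSet]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def _reference_backend(img: np.ndarray, cfg: DetectorConfig) -> DetectionSet:
    dets = detect_candidates(img, cfg)
    dets = apply_score_threshold(dets, cfg.prob_thresh)
    return nms(dets, cfg.nms_thresh)


register_backend("reference", _reference_backend)


def run_backend(
    img: np.ndarray, backend_spec: str = "reference", cfg: DetectorConfig = DetectorConfig()
) -> DetectionSet:
    """Run a registered detection backend and return its DetectionSet."""
    try:
        fn = _BACKENDS[backend_spec]
    except KeyError:
        raise KeyError(
            f"unknown backend {backend_spec!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    dets = fn(img, cfg)
    return replace(dets, provenance=backend_spec)
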