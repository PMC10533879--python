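"""Classical cell localization: binarize, clean, trace contours, centroids.

A luminance threshold (Otsu or fixed) separates cells from background, a
morphological opening removes speckle, connected components become cell
candidates, and each kept component is reported with its clockwise outer
contour, unweighted pixel-mean centroid, area and bounding box.  Optionally
the image is FACE-enhanced first, which is what makes faint low-contrast
cells separable at all.  A greedy centroid-matching evaluator scores
detections against a known ground truth.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage.filters import threshold_otsu

from .colorspace import luminance
from .enhance import EnhancementResult, FcmConfig, UcevSearchConfig, face_enhance

__all__ = [
    "DetectionConfig",
    "CellDetection",
    "MatchResult",
    "binarize",
    "extract_cells",
    "detect_cells",
    "evaluate_detections",
    "write_detections_csv",
    "write_detections_json",
    "draw_overlay",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Binarization and component-filter settings.

    ``polarity`` says which side of the threshold is cells: ``auto`` takes
    the side occupying less than half the image, ``bright_cells``/
    ``dark_cells`` force it.  Components with pixel area outside
    ``[min_area, max_area]`` are discarded as speckle or background clutter.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float = 128.0
    polarity: str = "auto"
    smooth_sigma: float = 1.0
    open_radius: int = 1
    min_area: int = 30
    max_area: int = 5000
    use_face: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be in [0, 255]")
        if self.polarity not in ("auto", "bright_cells", "dark_cells"):
            raise ValueError("invalid polarity")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")


@dataclass(frozen=True)
class CellDetection:
    """One detected cell, coordinates (x=column, y=row), 0-based."""

    contour: tuple[tuple[int, int], ...] = field(repr=False)
    centroid: tuple[float, float] = (0.0, 0.0)
    area: int = 0
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # x_min, y_min, x_max, y_max


@dataclass(frozen=True)
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    mean_centroid_error: float


def binarize(image: np.ndarray, config: DetectionConfig | None = None) -> np.ndarray:
    """Threshold the luminance plane into a boolean cell mask.

    A constant image yields an empty mask.  For the automatic (Otsu) path
    the luminance is first smoothed with a ``smooth_sigma``-px Gaussian:
    contrast enhancement amplifies background noise along with signal, and
    without denoising the threshold can lock onto the broadened background
    mode instead of the cells-vs-background valley.  A fixed threshold is
    applied to the raw luminance exactly as given.  Opening with a disk of
    ``open_radius`` removes speckle smaller than the cells of interest.
    """
    config = config or DetectionConfig()
    lum = luminance(image)
    if config.threshold_method == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if np.ptp(lum) == 0:
            return np.zeros(lum.shape, dtype=bool)
        if config.smooth_sigma > 0:
            lum = gaussian_filter(lum, config.smooth_sigma)
        thr = float(threshold_otsu(lum))
    bright = lum > thr
    dark = lum < thr
    if config.polarity == "bright_cells":
        mask = bright
    elif config.polarity == "dark_cells":
        mask = dark
    else:
        mask = bright if bright.mean() < 0.5 else dark
    if config.open_radius > 0:
        mask = _skmorph.opening(mask, _skmorph.disk(config.open_radius))
    return mask


# clockwise 8-neighborhood in screen coordinates (y down), starting west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_contour(component: np.ndarray, offset: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    """Moore-neighbor tracing of one component's outer boundary.

    Returns (x, y) pixel coordinates in clockwise order starting from the
    topmost-then-leftmost boundary pixel.
    """
    rows, cols = np.nonzero(component)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    def fg(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < component.shape[0] and 0 <= c < component.shape[1] and component[r, c]

    contour = [start]
    current = start
    backtrack = (start[0], start[1] - 1)  # west of start is background
    seen = {(current, backtrack)}
    while True:
        # scan clockwise starting just after the backtrack direction
        bdir = (backtrack[0] - current[0], backtrack[1] - current[1])
        k0 = _MOORE.index(bdir)
        nxt = None
        prev = backtrack
        for step in range(1, 9):
            dy, dx = _MOORE[(k0 + step) % 8]
            cand = (current[0] + dy, current[1] + dx)
            if fg(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            break
        current, backtrack = nxt, prev
        # the walk is a deterministic function of (pixel, backtrack); a
        # repeated state means the boundary loop has closed
        if (current, backtrack) in seen:
            break
        seen.add((current, backtrack))
        contour.append(current)
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    oy, ox = offset
    return tuple((c + ox, r + oy) for r, c in contour)


def extract_cells(mask: np.ndarray, config: DetectionConfig | None = None) -> list[CellDetection]:
    """Label the mask 8-connectedly and report area-filtered components,
    sorted by centroid (y, x)."""
    config = config or DetectionConfig()
    labels = _skmeasure.label(np.asarray(mask, dtype=bool), connectivity=2)
    detections: list[CellDetection] = []
    for region in _skmeasure.regionprops(labels):
        if not (config.min_area <= region.area <= config.max_area):
            continue
        rmin, cmin, rmax, cmax = region.bbox
        component = labels[rmin:rmax, cmin:cmax] == region.label
        contour = _trace_contour(component, (rmin, cmin))
        cy, cx = region.centroid  # unweighted pixel mean (row, col)
        detections.append(
            CellDetection(
                contour=contour,
                centroid=(float(cx), float(cy)),
                area=int(region.area),
                bbox=(int(cmin), int(rmin), int(cmax - 1), int(rmax - 1)),
            )
        )
    detections.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    return detections


def detect_cells(
    image: np.ndarray,
    det_config: DetectionConfig | None = None,
    fcm_config: FcmConfig | None = None,
    ucev_config: UcevSearchConfig | None = None,
) -> tuple[list[CellDetection], EnhancementResult | None]:
    """Full localization pipeline, optionally FACE-enhancing first.

    Detections are reported on the original image grid (enhancement does not
    move pixels), and the enhancement result is returned for reporting when
    used.
    """
    det_config = det_config or DetectionConfig()
    enhancement = None
    working = image
    if det_config.use_face:
        enhancement = face_enhance(image, fcm_config, ucev_config)
        working = enhancement.enhanced
    mask = binarize(working, det_config)
    return extract_cells(mask, det_config), enhancement


def evaluate_detections(
    detections: list[CellDetection],
    truth_centers: list[tuple[float, float]],
    match_radius: float = 5.0,
) -> MatchResult:
    """Greedy one-to-one centroid matching within ``match_radius`` pixels.

    Pairs are taken in increasing distance order; unmatched detections are
    false positives and unmatched truths false negatives.  Precision and
    recall default to 1 on empty denominators.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    det_pts = np.array([d.centroid for d in detections], dtype=float).reshape(-1, 2)
    tru_pts = np.array(truth_centers, dtype=float).reshape(-1, 2)
    pairs = []
    for i in range(len(det_pts)):
        for j in range(len(tru_pts)):
            dist = float(np.hypot(*(det_pts[i] - tru_pts[j])))
            if dist <= match_radius:
                pairs.append((dist, i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    errors = []
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errors.append(dist)
    tp = len(errors)
    fp = len(det_pts) - tp
    fn = len(tru_pts) - tp
    return MatchResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=tp / (tp + fp) if tp + fp else 1.0,
        recall=tp / (tp + fn) if tp + fn else 1.0,
        mean_centroid_error=float(np.mean(errors)) if errors else 0.0,
    )


def write_detections_csv(detections: list[CellDetection], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "area", "x_min", "y_min", "x_max", "y_max"])
        for i, d in enumerate(detections):
            writer.writerow([i, repr(d.centroid[0]), repr(d.centroid[1]), d.area, *d.bbox])


def write_detections_json(detections: list[CellDetection], path: str | os.PathLike) -> None:
    payload = [
        {
            "id": i,
            "centroid": list(d.centroid),
            "area": d.area,
            "bbox": list(d.bbox),
            "contour": [list(p) for p in d.contour],
        }
        for i, d in enumerate(detections)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def draw_overlay(image: np.ndarray, detections: list[CellDetection]) -> np.ndarray:
    """Contours (green) and centroid crosses (red) drawn on a copy of the raw image."""
    out = np.asarray(image).copy()
    h, w = out.shape[:2]
    for d in detections:
        for x, y in d.contour:
            out[y, x] = (0, 255, 0)
        cx, cy = int(round(d.centroid[0])), int(round(d.centroid[1]))
        for dx in range(-2, 3):
            if 0 <= cx + dx < w and 0 <= cy < h:
                out[cy, cx + dx] = (255, 0, 0)
            if 0 <= cy + dx < h and 0 <= cx < w:
                out[cy + dx, cx] = (255, 0, 0)
    return out
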