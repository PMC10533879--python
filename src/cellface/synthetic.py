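"""Seeded generator of low-contrast yeast-like microscopy scenes.

Emulates brightfield yeast imagery: roughly circular cells (mild ellipses,
axis ratio 0.8–1.0) darker than a uniform gray background, optionally
rimmed with a thin bright halo, then defocused with a Gaussian blur and
corrupted with sensor noise.  The cell-versus-background separation is
deliberately small (default 15% of the 8-bit range) so the scenes are
genuinely low contrast and contrast enhancement has something to do.
Ground-truth centers, radii and a pre-blur label mask come back alongside
the rendered image, enabling quantitative detector evaluation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SynthConfig", "GroundTruth", "PlacementError", "generate_image", "save_truth", "load_truth"]


class PlacementError(RuntimeError):
    """Non-overlapping cell placement could not be satisfied."""


@dataclass(frozen=True)
class SynthConfig:
    """Scene parameters.

    ``contrast`` is the cell-vs-background luminance separation as a
    fraction of 255; ``background_level`` the flat gray level the cells sit
    on; ``halo`` adds a 2-px bright rim around each cell as transmitted
    light does; ``noise_sigma`` is additive Gaussian noise in 8-bit
    luminance units, applied after a ``blur_sigma``-px defocus blur.
    """

    width: int = 500
    height: int = 500
    n_cells: int = 20
    radius_range: tuple[float, float] = (8.0, 20.0)
    contrast: float = 0.15
    background_level: float = 170.0
    halo: bool = True
    blur_sigma: float = 1.5
    noise_sigma: float = 4.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Cell centers (x, y), nominal radii, and an integer label mask
    (0 background, i for cell i, recorded before blur and noise)."""

    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]
    label_mask: np.ndarray


_HALO_WIDTH = 2.0  # px bright rim, matching brightfield halos
_MARGIN = 3.0  # cells kept fully inside the frame


def generate_image(config: SynthConfig | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; bitwise reproducible for a fixed config."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    amplitude = config.contrast * 255.0

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    rmin, rmax = config.radius_range
    attempts_allowed = 1000 * max(config.n_cells, 1)
    attempts = 0
    while len(centers) < config.n_cells:
        if attempts >= attempts_allowed:
            raise PlacementError(
                f"placed {len(centers)}/{config.n_cells} cells in {attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin, rmax)
        cx = rng.uniform(r + _MARGIN, w - r - _MARGIN)
        cy = rng.uniform(r + _MARGIN, h - r - _MARGIN)
        if not config.allow_overlap:
            clash = any(
                np.hypot(cx - px, cy - py) < r + pr + _HALO_WIDTH + 1
                for (px, py), pr in zip(centers, radii)
            )
            if clash:
                continue
        centers.append((cx, cy))
        radii.append(r)

    plane = np.full((h, w), config.background_level, dtype=np.float64)
    label_mask = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        ratio = rng.uniform(0.8, 1.0)  # minor/major axis
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        rho = np.sqrt((u / r) ** 2 + (v / (r * ratio)) ** 2)
        body = rho <= 1.0
        plane[body] = config.background_level - amplitude
        label_mask[body] = i
        if config.halo:
            ring = (rho > 1.0) & (rho <= 1.0 + _HALO_WIDTH / r)
            plane[ring] = config.background_level + 0.5 * amplitude

    if config.blur_sigma > 0:
        plane = gaussian_filter(plane, config.blur_sigma)
    if config.noise_sigma > 0:
        plane = plane + rng.normal(0.0, config.noise_sigma, size=plane.shape)
    plane = np.clip(np.round(plane), 0, 255).astype(np.uint8)
    image = np.repeat(plane[:, :, None], 3, axis=2)
    return image, GroundTruth(
        centers=tuple(centers), radii=tuple(radii), label_mask=label_mask
    )


def save_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    """Write centers and radii as JSON next to the rendered image."""
    with open(path, "w") as fh:
        json.dump(
            {"centers": [list(c) for c in truth.centers], "radii": list(truth.radii)},
            fh,
        )


def load_truth(path: str | os.PathLike) -> tuple[list[tuple[float, float]], list[float]]:
    with open(path) as fh:
        data = json.load(fh)
    return [tuple(c) for c in data["centers"]], list(data["radii"])
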