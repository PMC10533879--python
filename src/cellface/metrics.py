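"""Enhancement quality metrics: RMS deviation and RMS contrast.

RMSD measures how much an enhancement changed the image,

.. math:: \\mathrm{RMSD} = \\sqrt{\\tfrac{1}{n} \\sum_i \\lVert x'_i - x_i \\rVert^2},

and RMSC is the RMS contrast — the population standard deviation of the
pixel vectors about the mean pixel,

.. math:: \\mathrm{RMSC} = \\sqrt{\\tfrac{1}{n} \\sum_i \\lVert x_i - \\bar{x} \\rVert^2}.

Both use the Euclidean norm over the three RGB channels.  A good contrast
enhancement raises RMSC while keeping RMSD moderate: a very large RMSD
signals color tones drifting far from the original.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["MetricsReport", "rmsd", "rmsc", "compare_methods", "write_report"]


@dataclass(frozen=True)
class MetricsReport:
    method_label: str
    rmsd: float
    rmsc_original: float
    rmsc_enhanced: float


def _pixels(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) raster, got shape {arr.shape}")
    return arr.reshape(-1, 3)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-shape RGB rasters."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError("images must have identical shapes")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def rmsc(a: np.ndarray) -> float:
    """Root-mean-square contrast of an RGB raster."""
    p = _pixels(a)
    dev = p - p.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def compare_methods(
    original: np.ndarray, enhanced_by_method: dict[str, np.ndarray]
) -> list[MetricsReport]:
    """One MetricsReport per labeled enhanced image, vs. one original."""
    base = rmsc(original)
    reports = []
    for label, enhanced in enhanced_by_method.items():
        reports.append(
            MetricsReport(
                method_label=label,
                rmsd=rmsd(original, enhanced),
                rmsc_original=base,
                rmsc_enhanced=rmsc(enhanced),
            )
        )
    return reports


def write_report(reports: list[MetricsReport], path: str | os.PathLike) -> None:
    """Serialize reports as CSV (``.csv``) or JSON (anything else)."""
    path = os.fspath(path)
    if path.endswith(".csv"):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["method", "rmsd", "rmsc_original", "rmsc_enhanced"])
            for r in reports:
                writer.writerow(
                    [r.method_label, repr(r.rmsd), repr(r.rmsc_original), repr(r.rmsc_enhanced)]
                )
    else:
        with open(path, "w") as fh:
            json.dump([asdict(r) for r in reports], fh, indent=2)
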