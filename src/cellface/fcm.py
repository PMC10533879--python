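"""Fuzzy C-means clustering of CIELAB pixels.

Each pixel :math:`x_i` receives graded memberships :math:`u_{ij} \\in [0, 1]`
in every cluster, with rows summing to one.  The fit alternates the two
closed-form stationarity conditions of the in-group variance

.. math::

    J = \\sum_{i=1}^{n} \\sum_{j=1}^{k} u_{ij}^m \\lVert x_i - c_j \\rVert^2,

namely the weighted-mean center update

.. math::

    c_j = \\frac{\\sum_i u_{ij}^m x_i}{\\sum_i u_{ij}^m}

and the inverse-distance membership update

.. math::

    u_{ij} = \\Bigl[ \\sum_{l=1}^{k}
        \\bigl( \\lVert x_i - c_j \\rVert / \\lVert x_i - c_l \\rVert
        \\bigr)^{2/(m-1)} \\Bigr]^{-1},

starting from seeded random row-normalized memberships.  The fuzzifier
``m`` controls membership softness; ``m = 3`` with ``k = 2`` clusters
(cells vs. background) is the enhancement pipeline's operating point —
larger ``k`` tends to split the dominant background mode on sparse scenes,
which makes the downstream dispersion fold pixels between the split centers
instead of widening the distribution.  J is non-increasing across
iterations, so convergence is declared on the relative change of J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import LabPixelSet

__all__ = [
    "FcmConfig",
    "FuzzyPartition",
    "DegenerateClusterError",
    "fcm_fit",
    "fcm_memberships",
    "fcm_centers",
    "fcm_objective",
]


class DegenerateClusterError(ValueError):
    """A cluster received zero total membership weight."""


@dataclass(frozen=True)
class FcmConfig:
    """Fuzzy C-means fitting parameters.

    ``subsample`` caps the number of pixels used for center estimation
    (0 fits on all); memberships for the full pixel set are always computed
    in one final pass, so the cap only affects where the centers land.
    ``n_restarts`` runs that many independently seeded initializations and
    keeps the lowest-objective run — the alternation only finds local
    optima, so restarts matter when the global optimum is wanted.
    """

    k: int = 2
    m: float = 3.0
    tol: float = 1e-6
    max_iter: int = 300
    subsample: int = 20000
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class FuzzyPartition:
    """Result of a fuzzy C-means fit."""

    memberships: np.ndarray  # (n, k), rows sum to 1
    centers: np.ndarray  # (k, 3), same space as the input pixels
    objective: float
    n_iter: int
    converged: bool
    objective_history: tuple[float, ...] = field(default=(), repr=False)

    @property
    def n(self) -> int:
        return self.memberships.shape[0]

    @property
    def k(self) -> int:
        return self.memberships.shape[1]


def _pixel_array(pixels: LabPixelSet | np.ndarray) -> np.ndarray:
    if isinstance(pixels, LabPixelSet):
        return pixels.values
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("pixels must be an (n, d) array or LabPixelSet")
    return arr


def fcm_memberships(
    pixels: LabPixelSet | np.ndarray, centers: np.ndarray, m: float
) -> np.ndarray:
    """Membership matrix for fixed centers.

    A pixel coinciding exactly with one or more centers gets membership
    ``1 / (number of coincident centers)`` on those and 0 elsewhere (the
    update's zero-distance limit).
    """
    x = _pixel_array(pixels)
    c = np.asarray(centers, dtype=np.float64)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if not np.all(np.isfinite(c)):
        raise ValueError("centers must be finite")
    d2 = np.maximum(_sq_distances(x, c), 0.0)
    zero = d2 <= 0.0
    power = -1.0 / (m - 1.0)  # u ~ d2^{-1/(m-1)}
    inv = np.where(zero, 1.0, d2) ** power
    u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if np.any(hit):
        z = zero[hit]
        u[hit] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_centers(
    pixels: LabPixelSet | np.ndarray, memberships: np.ndarray, m: float
) -> np.ndarray:
    """Weighted-mean center update for fixed memberships."""
    x = _pixel_array(pixels)
    u = np.asarray(memberships, dtype=np.float64)
    w = u**m
    denom = w.sum(axis=0)
    if np.any(denom <= 0):
        raise DegenerateClusterError(
            "cluster with zero total membership weight"
        )
    return (w.T @ x) / denom[:, None]


def fcm_objective(
    pixels: LabPixelSet | np.ndarray,
    memberships: np.ndarray,
    centers: np.ndarray,
    m: float,
) -> float:
    """In-group variance J for a given partition."""
    x = _pixel_array(pixels)
    u = np.asarray(memberships, dtype=np.float64)
    d2 = _sq_distances(x, np.asarray(centers, dtype=np.float64))
    return float(np.sum(u**m * d2))


def _sq_distances(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, shape (n, k)."""
    diff = x[:, None, :] - c[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def fcm_fit(pixels: LabPixelSet | np.ndarray, config: FcmConfig | None = None) -> FuzzyPartition:
    """Fit fuzzy C-means by alternating the center and membership updates.

    Initial memberships are i.i.d. uniform per row, row-normalized, drawn
    from ``config.seed``; the same seed and config therefore reproduce the
    partition bit-for-bit.  If ``subsample`` is active and smaller than the
    pixel count, centers are fit on a seeded without-replacement sample and
    the final memberships for all pixels are computed once from them.
    """
    config = config or FcmConfig()
    x_full = _pixel_array(pixels)
    n = x_full.shape[0]
    if n < config.k:
        raise ValueError(f"need at least k={config.k} pixels, got {n}")
    if not np.all(np.isfinite(x_full)):
        raise ValueError("pixels must be finite")

    rng = np.random.default_rng(config.seed)
    if 0 < config.subsample < n:
        idx = rng.choice(n, size=config.subsample, replace=False)
        x_fit = x_full[idx]
    else:
        x_fit = x_full

    best: tuple[float, np.ndarray, int, bool, tuple[float, ...]] | None = None
    for restart in range(config.n_restarts):
        run_rng = rng if restart == 0 else np.random.default_rng([config.seed, restart])
        centers, n_iter, converged, history = _fcm_single_run(x_fit, config, run_rng)
        if best is None or history[-1] < best[0]:
            best = (history[-1], centers, n_iter, converged, history)
    _, centers, n_iter, converged, history = best

    u_full = fcm_memberships(x_full, centers, config.m)
    j_full = fcm_objective(x_full, u_full, centers, config.m)
    return FuzzyPartition(
        memberships=u_full,
        centers=centers,
        objective=j_full,
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )


def _fcm_single_run(
    x_fit: np.ndarray, config: FcmConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int, bool, tuple[float, ...]]:
    """One seeded alternation run; returns centers and the J trajectory."""
    u = rng.random((x_fit.shape[0], config.k))
    u /= u.sum(axis=1, keepdims=True)

    history: list[float] = []
    centers = fcm_centers(x_fit, u, config.m)
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        u = fcm_memberships(x_fit, centers, config.m)
        centers = fcm_centers(x_fit, u, config.m)
        j = fcm_objective(x_fit, u, centers, config.m)
        history.append(j)
        if len(history) >= 2:
            prev = history[-2]
            if abs(prev - j) <= config.tol * max(j, 1e-12):
                converged = True
                break
        elif j <= 1e-12:  # constant image: converged immediately
            converged = True
            break
    return centers, n_iter, converged, tuple(history)
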