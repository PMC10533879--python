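# Methods note

## Model

The pipeline enhances contrast by *dispersing* pixels away from the fuzzy
cluster centers they belong to, with the dispersion strength chosen to
maximize image entropy.

**Fuzzy C-Means (FCM).** Pixels are clustered in CIELAB (sRGB, D65), where
Euclidean distance approximates perceptual difference better than in RGB.
For fuzzifier `m > 1` the alternating updates are

- memberships: `u_ij = d_ij^(-2/(m-1)) / Σ_l d_il^(-2/(m-1))`, with a pixel
  coinciding with one or more centers assigning its membership evenly to the
  coincident centers;
- centers: `c_j = Σ_i u_ij^m x_i / Σ_i u_ij^m`.

Each step does not increase the objective `J = Σ_ij u_ij^m ‖x_i − c_j‖²`, so
the run converges; we stop when `|ΔJ| ≤ tol · max(J, ε)`. For speed, centers
are fitted on a deterministic subsample (default 20 000 pixels) and final
memberships are then computed for every pixel.

**Dispersion.** Because memberships sum to 1 over clusters, the update
`x′ = x + α Σ_j u_ij (x − c_j)` simplifies to `x′ = x + α (x − U C)` — each
pixel moves away from its membership-weighted center. Cluster centers for
this step are recomputed in RGB (same `u^m` weights) so that the geometry of
the move matches the space the image lives in. Values are clamped to
`[0, 255]`; all search arithmetic is done on real-valued pixels and the
result is rounded once, at the end.

**Entropy-guided step selection.** `α*` maximizes the Shannon entropy of the
luminance histogram of the dispersed image. The search is a coarse grid
(step 0.25 over `[−1, 8]`, always including 0) followed by an exhaustive
sweep of the bracket around the best coarse point at step 0.01. Ties are
broken toward the smallest `|α|` (the least-distorting enhancement).

**Detection.** Luminance is smoothed with a Gaussian (σ = 1), thresholded
with Otsu's method (polarity = minority side, configurable), cleaned by
morphological opening, and connected components in the area window are kept.
Boundaries are traced with Moore-neighbor tracing (clockwise, starting at
the topmost-then-leftmost boundary pixel, with `(pixel, backtrack)`-state
cycle detection so one-pixel-wide protrusions terminate correctly). Scoring
uses greedy nearest-first one-to-one matching: detection–truth pairs are
accepted in order of increasing distance within the match radius.

**Metrics.** `rmsd(a, b)` is the RMS Euclidean norm of per-pixel RGB
difference vectors; `rmsc(a)` is the population standard deviation of the
pixel vectors around the image mean (RMS contrast). Both are computed in
float64.

## Parameter choices

| Parameter | Default | Rationale |
|---|---|---|
| clusters `k` | 2 | Low-contrast micrographs have two populations (cells, background). `k = 3` splits the dominant background mode; pixels falling between the split centers are then *compressed* by the dispersion and entropy decreases with α. |
| fuzzifier `m` | 3 | Soft memberships so pixels between populations move partially; the standard closed-form updates apply. |
| entropy bins | 64 | Must be coarser than the 8-bit quantum: at 256 bins the dispersion is injective on occupied levels, so it can only permute/merge bins and binned entropy can never increase — the search degenerates to `α* = 0`. At 64 bins (4 levels/bin) spreading a compressed histogram across bins registers as an entropy gain. |
| α grid | `[−1, 8]`, step 0.25, refine 0.01 | Covers identity through heavy clipping; the refine sweep is exhaustive over the bracket because the entropy curve has plateau micro-wiggles that defeat unimodal (golden-section) refinement. |
| `smooth_sigma` | 1.0 (Otsu path only) | Dispersion amplifies background noise along with signal; on some scenes raw Otsu locks onto the noise-widened background mode and recall collapses. One pixel of Gaussian smoothing restores a clean bimodal histogram. Fixed thresholds are applied to the unsmoothed luminance. |
| `n_restarts` | 1 | A single random-membership start almost always reaches the global basin on natural scenes; tests that compare against a restart oracle raise this (the basin probability on adversarial tiny instances can be ~1%). |
| subsample | 20 000 px | Center estimates stabilize well below this; full-image membership pass follows. |

## Observed behavior worth knowing

- **Dispersion paradox.** When FCM finds the clean cells-vs-background
  optimum, cell pixels sit near their own center, so the dispersion mostly
  inflates within-cluster variance (noise) rather than between-cluster
  separation. The entropy gain is real but much of it is noise spreading;
  this is why detection needs the pre-threshold smoothing above, and why
  FACE's RMSC gain is modest next to histogram equalization's (at a much
  smaller RMSD).
- The entropy curve typically rises from `α = 0`, peaks (e.g. `α* ≈ 5` on
  the default seed-42 scene), and declines as clipping flattens the
  histogram.

## Synthetic generator

Scenes are 500×500 RGB by default: a uniform background (level 170) with
`n` non-overlapping ellipses (axis ratio 0.8–1.0, random orientation, radii
8–20 px) darker than the background by `contrast × 255`, an optional bright
halo ring (half the cell amplitude, 2 px wide), Gaussian blur (σ = 1.5), and
i.i.d. Gaussian noise (σ = 4), then clipped and quantized. Ground truth
(centers, radii, integer label mask) is recorded before blurring.

Limitations: cells are homogeneous ellipses — no internal texture, vacuoles,
budding necks, or clumping; illumination is flat (no vignetting or gradient);
noise is white Gaussian, not Poisson/read noise; halos are symmetric rings.
The generator is meant to make contrast and localization claims measurable,
not to be photorealistic.

## Numerical choices

- float64 throughout; images converted from uint8 once at entry.
- Rounding happens exactly once per output raster (`np.rint` then clip).
- Histogram edges span `[0, 255]` inclusive so level 255 falls in the last
  bin; `0 log 0 := 0`.
- FCM avoids divide-by-zero at coincident pixels/centers by masking before
  exponentiation; an empty cluster (all-zero weight column) raises rather
  than silently producing NaN centers.
- Determinism: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); repeated runs are bitwise identical, which
  the test suite asserts end-to-end through the CLI.

## Design decisions

- Library-first: all functionality is importable (`face_enhance`,
  `detect_cells`, `generate_image`, …) and the CLI is a thin `click` wrapper
  that only parses config files and writes artifacts.
- Configs are frozen dataclasses validated at construction; CLI config files
  mirror them section-by-section.
- Histogram equalization and contour tracing are implemented in-package
  (short, fully specified algorithms) so that their exact conventions —
  `floor(cdf·255)` LUT, clockwise Moore tracing — are pinned by unit tests
  rather than inherited from a library's version-dependent behavior.

## Limitations

- `k = 2` is the right default for two-population micrographs but not for
  multi-stain images; `k` is configurable, yet for `k > 2` the dispersion
  can compress pixels between nearby centers (see above).
- Entropy is measured on luminance by default; the joint RGB mode
  (`entropy_mode="rgb_grid"`) is available but slower and coarser.
- Overlapping or touching cells merge into one component; no watershed
  splitting is attempted.
- The detector assumes one global threshold; strongly uneven illumination
  would need local thresholding, which is out of scope.
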