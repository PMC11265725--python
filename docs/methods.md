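# Methods

This note documents the model implemented by `sec`, the choices made where
the design was genuinely open, the synthetic data the tests run on, and the
method's known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model and assumptions

The detector assumes an 8-bit RGB or grayscale raster in which a forger has
copied a rectangular-ish region and pasted it elsewhere in the same image,
possibly rotated a few degrees and possibly followed by global Gaussian
noise. Three stages run in sequence.

**Grayscale conversion.** `GrayImage = 0.299R + 0.583G + 0.116B`. These
weights sum to 0.998 and differ from the ITU-R BT.601 luma weights (0.299,
0.587, 0.114) in the G/B coefficients; both are supported
(`gray_variant = "printed" | "bt601"`), the former being the default the
rest of the pipeline is specified against. Values stay real-valued until
file export so block statistics are not contaminated by rounding.

**SIFT seeding.** Keypoints are detected with scikit-image's SIFT
(difference-of-Gaussians pyramid, 128-d descriptors). The stage treats SIFT
as a black box and performs *no* descriptor matching — keypoints only seed
the block population of the next stage. Hyper-parameters follow the original
SIFT publication: contrast threshold 0.04 (applied per scale step as
`c_dog = 0.04/3`), edge threshold 10. A keypoint at real position (row, col)
is binned to pixel (⌊row⌋, ⌊col⌋), 0-based; keypoints sharing a pixel count
once, capping per-block counts at B².

**Block decomposition.** All stride-1 overlapping B×B windows (B = 8 by
default), row-major, half-open windows `[r, r+B) × [c, c+B)`. Block feature:
*population* standard deviation (divisor B²) — the population convention
makes the constant-block case exactly zero independent of B. Stds are
computed on the 0–255 scale without normalization.

**Equilibrium Optimization Matching.** Candidate particles are exactly the
keypoint-bearing blocks; a full ~255 k-particle population would be
quadratically expensive and contradicts the seeding design. Per iteration:

1. fitness of every candidate u: `(1/N) Σᵢ (σᵤ − σᵢ)²` over the candidate
   population (self included);
2. equilibrium pool: the four lowest-fitness candidates (ties broken by
   row-major block order) plus their element-wise mean;
3. per candidate, draws (λ, r, r₁, r₂) from one shared RNG stream in that
   fixed order; exponential term `F = a₁·sign(r−½)·e^(−λσ) − a₂` with
   sign(0) = 0 (the alternative form `a₁·sign(r−½)(e^(−λσ) − 1)` is
   available as `f_variant = "canonical"`); generation rate
   `G = GCP·(C_eq1 − λC)·F`, `GCP = ½r₁` when r₂ ≥ GP else 0 (the tie takes
   the active branch); update `C' = C_eq1 + (C_eq1 − C)·F + (G/λ)(1 − F)`
   with λ floored at 10⁻⁶ before the division;
4. classification: C' counts as a pool member iff `fit(C') ≤ fit(C_eq4)` —
   i.e. it matches at least as well as the worst pool member; literal
   set-membership would almost never fire on real-valued updates. Members'
   windows are multiplied by σ(C') ("toward white"), non-members' by
   σ(C')/100 ("toward black"), applied sequentially in row-major candidate
   order with clipping to [0, 255] after each application, so overlapping
   windows compound within an iteration.

Candidate windows and stds are re-read from the mutated working image at
each iteration start. After `max_iter` iterations (default 20) the working
image is binarized at 127.5: bright pixels are the suspected region. Fewer
than four candidates short-circuits to "authentic" (the pool needs four
members). The whole stage is deterministic given the seed.

**Color histogram expansion and closing.** Suspected blocks (windows
majority-covered by the binarized map) are processed in descending
keypoint-count order (ties row-major). Each absorbs at most one neighbor:
the in-image compass neighbor (offsets ±B per axis, 8-connected block
neighborhood) with the smallest Euclidean distance between L1-normalized
per-channel 32-bin histograms, provided that distance is ≤ 0.1. Absorbed
blocks join the next round's frontier; expansion runs at most 50 rounds.
Keypoint-count priority implements "more keypoints → more likely to expand"
as a deterministic order rather than a probability, for reproducibility.
Finally a binary closing with a disk of radius 5 (pixels within Euclidean
distance 5 of the center) fills gaps; the mask is padded by the radius
first so border behavior is exact, making closing extensive and idempotent.

**Image-level verdict.** An image is called forged iff the final mask has an
8-connected component of at least `min_region_pixels` (default B² = 64).
The underlying method leaves this rule unstated; a one-block minimum region
is the natural scale of the detector.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `block_size` | 8 | px | stated block size of the method |
| `a1`, `a2`, `gp` | 2, 1, 0.5 | — | stated equilibrium-optimizer values |
| `max_iter` | 20 | iterations | unstated; enough for the re-weighting to converge (the working image stops changing long before) |
| `threshold` | 127.5 | intensity | midpoint of the 8-bit range for the white/black balance |
| `lambda_floor` | 10⁻⁶ | — | guards the division by λ ~ U[0,1] |
| `n_bins` | 32 | bins/channel | unstated; 32 gives 8-intensity-wide bins, robust to mild noise |
| `distance_threshold` | 0.1 | — | unstated; on L1-normalized histograms 0.1 admits only near-identical blocks |
| `max_rounds` | 50 | rounds | termination guarantee for expansion |
| `closing_radius` | 5 | px | stated structuring-element radius |
| `noise_sigma` | 0.1 | unit intensity | stated Gaussian factor of the noisy category |

## Synthetic data: what it emulates and what it does not

`forgery_synth` emulates CT-teaching-file-like material: dark background
(~20), 4–7 overlapping soft-edged ellipses at soft-tissue intensities
(40–120 before blending), and band-limited texture (Gaussian noise smoothed
at σ = 1.5 px, rescaled to std 8) so SIFT fires everywhere tissue is.
Channels are near-grayscale (±2% fixed gains). Forgeries copy a patch
(sides 32–64 px by default, capped at half the image side so disjoint
source/destination pairs exist) and paste it rotated 0/5/10/15° with
bilinear interpolation; the destination mask is the rotated all-ones
indicator at majority coverage (≥ 0.5), so a 48×48 patch rotated 10° covers
≈ 0.93·48² pixels (corners leave the window). Masks mark *both* members of
the duplicated pair. Noise is added globally (the harder case for a
detector) rather than only to the paste.

Not emulated: DICOM acquisition physics, scanner noise spectra, JPEG
artifacts, anatomical plausibility, or splicing from other images. Passing
tests on these fixtures show the pipeline's mechanics are correct and
deterministic; they do not certify performance on real radiology data.

A note on the noise invariant: the folded-normal prediction for the mean
absolute pixel change, σ·255·√(2/π), assumes no clipping. Over the dark
background, clipping at 0 removes roughly a tenth of the global figure, so
the test checks the prediction on mid-range pixels (64–191) where the
derivation applies.

## Numerical choices

- Population (not sample) standard deviation throughout.
- Pool ties broken by row-major block order; GCP tie r₂ = GP takes the
  active branch; sign(0) = 0 in the exponential term.
- Histogram bins are equal-width over [0, 255], right-inclusive last bin.
- Undefined metric ratios (zero denominators) are NaN, never 0, and are
  excluded from table averages; table average rows are computed at full
  precision and *truncated* to two decimals (the convention the published
  average cells follow).
- One RNG stream per run (NumPy PCG64), seeded once; draw order (λ, r, r₁,
  r₂) per candidate per iteration.

## Known limitations

**The equilibrium fitness carries no pairing signal.** This is the
method's central structural limitation, and the package implements the
printed equations faithfully rather than repairing them. The fitness of a
block depends only on its scalar std relative to the population's std
moments, so a duplicated block is indistinguishable from any block whose
std happens to sit near the population mean: nothing links the two copies
of a duplicated region. Moreover, at most a handful of updates per
iteration pass the pool-membership test, so the ×(σ/100) darkening branch
dominates; applied sequentially across stride-1 overlapping windows it
compounds ≈ 64 times per pixel per iteration and drives every
candidate-covered pixel to black. In practice the surviving "white" pixels
are bright pixels never covered by a candidate block. Consequently
pixel-level localization of the duplicated pair is poor (the acceptance
script reports the measured rates; the worked example in the README shows
a representative run), even though image-level verdicts on forged images
are usually correct for the trivial reason that bright uncovered regions
survive thresholding. Users needing reliable localization should treat this
implementation as a faithful reference of the published procedure, not as
a state-of-the-art detector; descriptor matching (g2NN) or richer block
features would be the standard remedies, both deliberately out of scope.

**Other limitations.** Rotation beyond ~15° breaks the exact-duplicate
assumption of the block-std feature entirely; the CHM stage can leak across
regions whose histograms are similar by chance (uniform backgrounds);
16-bit inputs are linearly rescaled, discarding windowing metadata; DICOM
is not parsed.
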