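# Methods note

## Model

A whole-slide image is reduced to a mosaic of representative 1024 × 1024
patches at ×20 magnification. Each mosaic patch is stored as a pair
`(p, h)`:

* **Integer index `p`.** An encoder maps the patch to a 64 × 64 grid of
  discrete codeword indices in `[0, 127]`. Three successive 2 × 2
  average poolings yield grids of 32², 16² and 8² cells; the cell sums
  `s1, s2, s3` are bounded by `130048`, `32512` and `8128` (attained by
  the all-127 grid). The index packs the floored sums into disjoint
  decimal digit blocks, `p = ⌊s1⌋ + ⌊s2⌋·10⁶ + ⌊s3⌋·10¹¹`, so the
  coarsest (most stable) sum occupies the most significant block. The
  maximum composable index is 812 832 512 130 048 < 2^50, giving the
  van Emde Boas universe `M = 2^50 = 1 125 899 906 842 624`.
* **Binary code `h`.** A 1024-dimensional texture descriptor is
  binarized element-wise against its predecessor (the predecessor of the
  first element is +∞, so bit 0 is always 0). The code depends only on
  the ordering of consecutive elements and is therefore invariant under
  strictly increasing affine transforms of the descriptor.

Search walks the vEB tree from anchor indices `m ± t·C` (`C = 50·10¹¹`,
`t ≤ T = 10`), keeping keys whose minimum metadata Hamming distance is
below `θ_h = 128`, with per-anchor walk budgets
`k_succ = k_pred = 375`. Ranking aggregates the per-patch result sets by
weighted label entropy (weights: reciprocal per-diagnosis slide counts
normalized to sum `N = 10`; position-discounted counts clamped below at
1), removes length outliers outside the 5%/95% quantiles, drops patches
beyond the mean top-5 distance `θ_h'`, filters patches whose label
prediction disagrees with the consensus pseudo-label (`k_f = 5` head),
and returns the top `K = 5` slides ordered by (entropy asc, distance
desc, name).

## Parameter defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| universe bits | 50 | smallest power of two above the max index |
| `C` | 50·10¹¹ | steps the 10¹¹ digit block (the coarsest sum) by 50 units |
| `T` | 10 | ±10 anchors span ±500 units of the coarsest sum |
| `θ_h` | 128 | Hamming acceptance threshold on 1024-bit codes |
| `k_succ`, `k_pred` | 375 | per-anchor walk budget; fixes worst-case work |
| `N` | 10 | normalization constant of diagnosis weights |
| `K` | 5 | returned slides per query |
| `O_l`, `O_h` | 0.05, 0.95 | length-outlier quantiles in cleaning |
| `k_f` | 5 | votes consulted by filter-by-prediction |
| k-means (stage 1) | 9 clusters | colour grouping of candidate tiles |
| spatial sample | 5 % | per-cluster mosaic share (take all if < 1 tile) |
| white filter | ≥ 235 on > 90 % pixels | near-white patch rejection |
| LBP | P=8, R=1, 128 bins | debris/smudge texture feature |
| VQ codebook | K=128, D=256 | codeword count fixed by the 0–127 index range |
| training | Adam 1e-3, batch 4, 10 epochs, clip 1.0, α=1 | three-term VQ objective |

## Constant-work accounting

Instrumentation counts (a) successor/predecessor calls that consume a
walk budget and (b) direct membership probes of the `2T + 1` anchors.
Keys whose metadata is fully patient-masked are skipped without
consuming budget (they are invisible to the query), and a walk stops at
the first missing or already-visited key. All `2T + 1` anchors are
membership-checked, but successor walks start only from the `T` lowest
ascending anchors — the farthest anchor is checked, not walked — so the
per-patch bound is exactly `(2T+1) + T·(k_succ + k_pred)` examinations
(7 521 at the defaults), independent of database size. The bound is
verified empirically on databases of 10³–10⁵ patches.

Known structural property: with strict successor/predecessor semantics,
forward walks start at the anchors and move away from the query, so
keys strictly inside `(m − C, m)` are reached only by the backward walk
from `m − C` after it exhausts closer keys. Oracle-equivalence tests
therefore use a unit anchor step (`C = 1`) and budgets at least the
database size, a regime in which full coverage is provable; the
production defaults trade exhaustiveness for bounded work by design.

## Synthetic cohorts

The synthetic generator is the study instrument, not a convenience: its
defaults are the study conditions. A cohort has `n_classes = 4` classes
× 50 slides, 2 slides per patient, 8–12 mosaic patches per slide. Class
structure enters through exactly the two channels the engine exploits:

* **Index locality** — a deterministic mock encoder draws each patch's
  latent-grid sum from a class-specific normal distribution (means
  60 000 + 100 000·c, sd 2 000 → ~25-sd gaps; per-patch streams keyed by
  `(seed, crc32(label), patch_id)`).
* **Hamming similarity** — each class owns a random binary prototype of
  length 1024; patch codes flip each bit i.i.d. with rate ε = 0.02.
  Expected within-class pairwise distance is `2ε(1−ε)·1024` (≈ 40 at the
  default; ≈ 97.3 at ε = 0.05, verified within 5 %), cross-class ≈ 512.

Degradation studies raise ε toward 0.5 (codes lose class information;
accuracy must fall monotonically) and ablate the ranking stages
(naive → +weighted → +clean → +filter must never lose accuracy).
Synthetic patch *images* (pink periodic texture, near-white, dark
smudges) exercise the segmentation, white and debris filters and the
autoencoder without photorealism claims.

## Numerical and engineering choices

* The quantized autoencoder is pure numpy (no GPU frameworks in the
  target environment): non-overlapping 16 × 16 pixel blocks through a
  linear encoder/decoder (×16 downsampling), straight-through gradient
  for the quantizer, manual Adam, global-norm gradient clipping.
  Codebook rows are re-ordered by their first principal component
  (sign fixed by making the largest-magnitude loading positive) so that
  numerically close codewords get close indices; a stored permutation
  keeps old grids consistent.
* Slide archives persist as HDF5 (fixed dataset order, `track_times`
  off, bit codes packed 8-per-byte) plus a JSON manifest with sorted
  keys — re-serializing an unchanged database is byte-identical.
* WSI input is tiled/pyramidal TIFF via `tifffile`, plain rasters via
  Pillow, or directories of pre-cut patches; image operations (median
  filter, morphological closing, LBP, HSV conversion) use scikit-image.
* All randomness flows from explicit integer seeds (< 2³¹) through
  `numpy.random.default_rng` / `SeedSequence`; nothing reads global RNG
  state, so every artifact is reproducible from the command line.

## Problem sizes used in verification

* vEB oracle fuzz: 10 000 mixed operations on a 2²⁰ universe; timing
  probes on 10³ vs 10⁵ keys (medians differ by < 2×).
* Guided-search oracle: 250–300 patches, full-coverage budgets,
  5 random queries per database.
* End-to-end: 200 slides (4 × 50), every slide self-queried under
  leave-one-patient-out → macro mMV@5 = mAP@5 = 1.0; ε-sweep and
  ablation sweep use a fixed 60-query stratified subsample (seed 7) to
  stay inside desk-scale runtimes.
* Constant-work bound: databases of 10³, 10⁴ and 10⁵ patches with
  20 instrumented queries each.

## Known limitations

* The production anchor step `C` leaves the `(m − C, m)` window to the
  tail of one backward walk (see above); retrieval quality relies on the
  index concentrating similar patches near the anchors.
* The numpy autoencoder is a linear-per-block model — adequate for the
  codeword-grid contract and desk-scale training, not a perceptual
  equal of deep convolutional encoders.
* NDPI and other vendor WSI containers are untested; tiled TIFF (and
  SVS as tiled TIFF) is the supported slide format.
* Tie-breaks not fixed by the algorithms are made deterministic and
  documented in code: first-occurrence argmin at a shared key, hit
  sorting by (distance, slide, coords), final ranking by (entropy,
  −distance, name), majority-vote ties by smaller mean distance then
  label.
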