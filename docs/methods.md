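# Methods

## The verification pipeline

Each image passes through four stages: matched-filter enhancement, feature
extraction into two channels, LPP dimensionality reduction fitted on the
enrollment split, and nearest-neighbour scoring. Genuine scores are all
(test sample, enrolled sample of the same subject) pairs; impostor scores
are all cross-subject pairs. A per-claim variant (each test sample scored
against the closest enrolled sample of the claimed subject) is available
via `per_claim_min=True`; both pairings are legitimate protocol choices
and the default all-pairs rule is the more conservative one.

## Matched-filter enhancement

The kernel profile is `−exp(−x′²/σ²) − m` inside the support box
`|x′| ≤ 3σ, |y′| ≤ L/2`. Two conventions for the exponent are common; the
default (`gaussian_convention="paper"`) keeps `σ²` in the denominator,
and `"standard"` switches to `2σ²` — the two differ only by a √2 rescale
of σ. Choices that matter:

- **Zero-sum on the discrete grid.** `m` is the mean of the sampled
  profile over the in-support pixels, not the analytic mean, so the
  discretized kernel sums to zero to machine precision and constant
  backgrounds are annihilated exactly.
- **Support tolerance.** The support test uses a 1e−9 slack so that the
  rasterized box is stable against rotation roundoff (θ = 0 and θ = π
  produce identical kernels).
- **Correlation, reflective padding.** The kernels are even under point
  reflection, so convolution and correlation coincide; `scipy.ndimage`
  correlation with `mode="reflect"` avoids zero-padding halos.
- **Defaults σ = 2 px, L = 9 px,** single scale. These are typical of the
  retinal matched-filter literature and match the synthetic vessel width;
  both are configurable, and a multi-scale per-pixel max is available via
  `sigmas`.

The enhanced image is the orientation-max response min-max rescaled to
[0, 1]; the raw (linear) responses and the winning-orientation map are
exposed for diagnostics and tests.

## Wavelet channel (WLPP)

Level-3 LL subbands of db2 and sym2 (`pywt.wavedec2`, symmetric
half-point extension) are flattened row-major, Z-normalized per dimension
with enrollment-only statistics (zero-variance dimensions map to 0), and
concatenated db2-first. Features are computed on the *enhanced* image.
The feature length depends on the input image size by design; at the
default 64×64 the LL grids are 10×10, so the raw vector has 200
dimensions.

## LBPV channel (LBPV_LPP)

LBP codes use P = 8 neighbours at R = 1 with bilinear interpolation;
`s(0) = 1`, plain (non-uniform) codes, histogram length 2^P = 256 with
bin k accumulating the ring variance `VAR = (1/P) Σ (g_p − u)²`. Pixels
within ceil(R) of the border are skipped rather than padded. Numerical
details:

- The ring is referenced to the center pixel before the variance is
  computed (mathematically a no-op) so constant neighbourhoods give an
  exact zero.
- Interpolated samples are rounded to 8 decimals. Without this, a
  neighbour that is mathematically equal to the center can land on either
  side of the `s()` threshold depending on floating-point evaluation
  order; the snap makes codes reproducible across implementations (the
  vectorized path agrees exactly with a per-pixel brute force and with
  scikit-image's reference LBP).
- Wavelet coefficient grids are min-max scaled to [0, 1] per image before
  LBP: codes are scale invariant but variance weights are not, and the
  rescale makes the three histograms (enhanced, db2 LL, sym2 LL)
  commensurate before Z-normalization. Histograms are not L1-normalized;
  Z-normalization alone is applied.

The three Z-normalized histograms concatenate to a 768-dim raw vector.

## Locality preserving projections

A PCA pre-projection retaining 98% of the enrollment variance (dropping
numerically null directions) precedes LPP so that `X D Xᵀ` is positive
definite. The neighbourhood graph is kNN with k = 5 and OR-symmetrization;
heat-kernel weights use `t` equal to the mean squared pairwise training
distance, a scale-free default. The generalized symmetric eigenproblem is
solved with `scipy.linalg.eigh`; the l = min(100, m−1) eigenvectors of
smallest eigenvalue (capped by the pre-projection rank) form the map, each
column's largest-magnitude entry made positive for reproducible
serialization. Disconnected graphs are detected and warned about — each
extra component contributes a zero eigenvalue when the component indicator
lies in the projected row space.

With few samples per subject the forced k = 5 edges cross subjects and
the embedding degrades; at the benchmark's 6 enrollment samples per
subject most neighbours are genuine.

## Scoring and fusion

Distances are computed with `scipy.spatial.distance.cdist`; undefined
cosine/correlation entries (zero-norm or constant vectors) are set to 1
with a warning. FAR/FRR sweep the union of observed scores; the EER
interpolates linearly between the two sweep points bracketing the
FAR − FRR sign change (below all scores FAR = 0, FRR = 1) and is reported
in percent to 4 decimals. The EER is invariant under strictly monotone
transformations of the scores, which is why the min-max normalization
before fusion leaves single-channel EERs unchanged while making the fusion
weight grid meaningful across metrics of different scales. The weight
search uses a single loop over w ∈ {0, 0.01, …, 1} with the simplex
constraint w₂ = 1 − w₁ (identical optimum to a two-dimensional grid);
ties go to the smallest w. Because the endpoints are in the grid the fused
EER never exceeds either channel's.

Note the EER of a *pathologically inverted* score set (every genuine score
above every impostor score) exceeds 50% under any crossing definition; the
0–50% range holds whenever genuine scores are stochastically smaller.

## Synthetic data: what it emulates, and what it does not

Templates are flat backgrounds (level 0.7) carrying 5 dark vessels:
smoothed random walks (step 2 px, turning angle bounded by ±0.25 rad)
rendered with a Gaussian cross-section of width σ = 2 px and centerline
depth 0.5, overlaps taking the deepest drop. Samples perturb the template
by a rigid jitter (translation ≤ 1.5 px per axis, rotation ≤ 2°, bilinear
resampling with reflective boundary), a multiplicative gain within ±5%,
and additive Gaussian noise (SD 0.02), clipped to [0, 1]. Datasets are
pure functions of the config (seeded per subject and sample), and the
first half of each subject's samples enrolls.

This emulates the geometry and intra-class variation that the matched
filter and the verification protocol are sensitive to. It does **not**
model real acquisition: no illumination gradients or specularities, no
skin texture or hair, no ROI localization or registration error beyond
rigid jitter, no vessel branching or occlusion, and intra-class variation
far more benign than between real capture sessions. Passing the benchmark
therefore demonstrates the pipeline's correctness and internal
consistency — enhancement selects the right orientations, the channels
separate identities under controlled perturbation, fusion helps
structurally — not field-level error rates; EERs on real palm-vein
databases will be worse and depend on acquisition quality.

The default benchmark is 50 subjects × 12 samples at 64×64 px with a 6/6
enroll/test split (300 genuine and 89 700 impostor comparisons), sized so
the full run with all ablations completes in well under a minute on one
CPU.

## Known limitations

- LPP output dimension, k, t and the PCA retention are fixed heuristics,
  not tuned per dataset.
- The LBPV channel discriminates weakly on small noisy images (its
  histograms are dominated by noise variance); it contributes mainly
  through fusion.
- Enhancement rescales per image, so absolute response magnitudes are not
  comparable across images — only within-image structure is.
- The generator produces pre-registered images; the pipeline has no
  registration stage.
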