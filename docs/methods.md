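# Methods

## Problem setting

A Hi-C experiment on one chromosome yields a symmetric matrix of interaction
frequencies (IFs) between fixed-size genomic bins.  "Low resolution" here
means low sequencing coverage at a fixed bin size: the low-coverage matrix is
modeled as a binomial thinning of the high-coverage one (each read retained
independently with probability equal to the downsampling ratio, 1/16 by
default).  The enhancement task is supervised regression from thinned tiles
to their high-coverage counterparts.

All coordinates inside the toolkit are 0-based bin indices with half-open
intervals; base pairs appear only at I/O boundaries.  This removes the
off-by-one ambiguity that plagues mixed bp/bin conventions.

## Network

Tiles are 40×40 (the block size standard in this model family).  The
architecture is:

1. entry 3×3 convolution (1 → C channels) + ReLU;
2. B cascading layers.  Layer *b* applies a residual block — two dilated 3×3
   convolutions each followed by ReLU, a concluding 1×1 convolution, and an
   identity skip (`out = conv1x1(relu(conv(relu(conv(x))))) + x`) — then
   concatenates the block output with all earlier cascade features and fuses
   them through a 1×1 convolution + ReLU.  The concatenative cascade is what
   lets early features reach late layers directly;
3. spatial self-attention after each cascading layer whose 1-based index is
   configured in `attention_blocks`: single-head query/key/value 1×1
   convolutions (key/query width C/8), softmax affinities over the 1600
   flattened positions, output gated as `gamma * attended + input` with a
   learnable scalar `gamma` initialized to 0 (the SAGAN convention).  The
   zero initialization makes the module an exact identity at the start, so
   attention ablations are continuous and the identity case is testable
   bit-for-bit;
4. a tail of dilated 3×3 convolutions + ReLU and a final 1×1 convolution to
   one channel.

Dilated convolutions space kernel taps `dilation_rate` bins apart
(1-D semantics: `out[i] = Σ_k x[i + d·k] w[k]`, taps indexed from 0).  Zero
padding of `d` pixels per side preserves the 40×40 spatial size through every
3×3 layer.  Dilation adds receptive field, not parameters: the analytic
Chebyshev radius is `1 + 2dB + d·T` for B cascades and T tail layers (13 bins
at d=1, 25 at d=2 for the default configuration) while parameter counts are
identical — both facts are asserted in tests, the former by delta
perturbation.

Defaults: B = 5 cascades, dilation rate 2, attention on cascades 1 and 2,
C = 64 channels, tail of 2 dilated convolutions.  Cascade count, rate and
attention placement follow the configuration reported optimal for this
architecture family; channel width, attention-width reduction (8), tail depth
and He-uniform initialization are this package's own choices, made once and
exposed in `ModelConfig`.

## Training

Adam (lr 1e-4 default, β = 0.9/0.999) minimizes tile-level MSE.  After every
epoch the mean SSIM between validation predictions and targets is computed
and the best-scoring weights are retained, with the epoch recorded; the
(epoch, train MSE, validation SSIM) curve is stored in the checkpoint and the
training log.  All randomness (initialization, batch shuffling) derives from
the configured seed, so two runs with the same configuration are bit
identical.  The engine is plain numpy with a small reverse-mode autodiff
core; conv/attention/softmax gradients are verified against central finite
differences in the test suite.  This keeps the package dependency-light and
fully deterministic on CPU; it is not built for GPU-scale training, which is
out of scope.

## Accessibility-based imputation

The imputation model is a linear regression of the pair IF on per-bin mean
DNase signal and genomic separation:

    eps_kl = alpha1 * R_k + alpha2 * R_l + alpha3 * D_kl

- The regression target is the KR-balanced IF by default.  The alternative
  reading — the model output is a spatial-distance proxy, converted to an IF
  by the inverse power law `IF = (dist + eps0)^(-q)` (q = 1 default) — is
  supported behind `regress_target="distance"`, since both readings are
  defensible and the choice is left as configuration rather than guessed.
- Coefficients are fitted per chromosome on the available Hi-C data by least
  squares over unordered near-diagonal pairs (|k−l| ≤ 400 bins, nonzero
  target), each pair used once; an `alpha1 = alpha2` tie is available but off
  by default.  The RMS residual and rank status are stored with the
  coefficients.  Fitting is restricted to the near-diagonal band because the
  linear form is only plausible where signal dominates.
- Prediction is evaluated chunk by chunk over a 2-D grid of bin blocks
  (default 200 bins).  Because the model for a pair depends only on its two
  bins, chunked and unchunked evaluation agree exactly before balancing —
  asserted to <1e-9 in tests.  The assembled matrix is symmetrized, negatives
  are clipped to zero (IF non-negativity), and one whole-chromosome KR
  balance is applied.

KR balancing itself is a symmetric diagonal scaling iteration run until the
coefficient of variation of the unmasked row sums falls below `tol` (1e-6
default, 3000 iterations max; failure raises an error carrying the residual),
then rescaled so row sums equal 1.  All-zero rows are masked first and
returned as zeros.

### Augmentation

The imputed matrix becomes training pairs by rescaling to integer
pseudo-counts (default total 1e6), thinning at the same ratio as the Hi-C
training data, min-max normalizing both versions and tiling — so augmented
pairs are structurally parallel to Hi-C pairs.  Target mode draws imputed
matrices from the target cell line's test chromosomes, source mode from the
source cell line's training chromosomes; every tile carries a provenance tag
and the augmented set is appended once (the training loop reshuffles it per
epoch under the training seed).

## Metrics

All five scores are implemented from their defining formulas (Hi-C-specific
conventions make generic image-library versions unsuitable), and each is
cross-checked against an independent naive reimplementation in the tests:

- **SSIM**: windowed (11×11 uniform window over all fully contained windows,
  population moments), constants C1 = (0.01·L)², C2 = (0.03·L)², L = 1 on
  min-max-normalized matrices; a global single-window mode exists and is used
  automatically for inputs smaller than the window.
- **PSNR**: `10 log10(L²/MSE)`, +inf sentinel at MSE = 0; predictions are
  clipped to [0, L] before scoring since networks may overshoot the range.
- **GenomeDISCO concordance**: each map row-normalized to a transition
  matrix, denoised by t random-walk steps (t = 3 default; t is exposed since
  the formula leaves it open), score `1 − (1/N) Σ|A1_t − A2_t|` with N the
  number of bins with nonzero marginal in either map.
- **HiCRep SCC**: pairs stratified by diagonal offset k = 1..K, population
  covariance/variances pooled as `Σcov / sqrt(Σvar·Σvar)`; strata under
  `scc_min_pairs` (2) are skipped; no pre-smoothing by default (an optional
  mean filter is provided but off, as the pooled formula itself contains no
  smoothing term).
- Per-chromosome values are aggregated as mean ± sample SD (ddof = 1), with a
  single-sample flag when only one chromosome is scored.  Whole-chromosome
  (band) scoring is the default report; per-tile averaging is possible by
  scoring tiles individually and summarizing.

## Synthetic data

The generator emulates exactly the structure the method assumes:
expected IF `λ_ij ∝ (|i−j|+1)^(−γ) · E^[same TAD] · (1 + Σ loop bumps)`,
scaled to a total read depth, with Poisson counts (negative-binomial when
over-dispersion is configured), drawn on the upper triangle and mirrored.
The accessibility track is `coupling · s + (1−coupling) · noise` where `s`
is the expected-IF row marginal rescaled to [0, 1] — at coupling 1 the
signal's tie to structure is exact and known, which is what makes the
augmentation premise testable.

Defaults (400 bins at 10 kb, γ = 1, two-fold TAD enrichment, four loops,
5e6 reads, 1/16 thinning) keep a full generate→tile→train→evaluate cycle
around half a minute on one CPU while every structural feature is present.
The fixture suite writes three such chromosomes (so train/validation/test
splits are pairwise disjoint) in plain-text dialects with SHA-256 manifests;
regeneration from the same seed is byte-identical.

What the generator does **not** emulate: A/B compartments, replication
timing, cell-line-specific accessibility biology, mappability artifacts, and
trans (inter-chromosomal) contacts.  Passing tests therefore demonstrate the
correctness of the machinery and the internal consistency of the method's
premises — not performance on real chromatin.

## Pipeline conventions

The default chromosome split uses autosomes only: validation {2, 6, 10, 12},
test {4, 14, 16, 20}, training the remaining 14 autosomes.  Tiling is
non-overlapping (stride 40) within 400 bins of the diagonal (≈4 Mb at
10 kb) — enhancement models in this family restrict to the near-diagonal
band where counts are informative; edge blocks are dropped rather than
zero-padded so tile/assemble is an exact identity.  Every artifact records
the configuration hash and seed; reruns are bit-identical.

## Numerical choices and degenerate inputs

- Symmetry is validated to 1e-9 relative tolerance and preserved by every
  matrix operation.
- Min-max normalization clips at an upper quantile (0.99 in the pipeline) to
  stop a few extreme counts from compressing the dynamic range; the clip
  value is stored for inversion; all-zero matrices pass through with unit
  scale.
- Read thinning requires integer raw counts and operates per upper-triangle
  entry, so expectation is preserved exactly and symmetry by construction.
- Empty triplet files yield zero matrices; duplicated symmetric triplets are
  reconciled rather than double-counted.
- An all-zero contact map raises an explicit undefined-score error in the
  concordance metric, as does an all-degenerate stratification in the SCC.

## Known limitations

- CPU-only, small-model training; reproducing published full-scale benchmark
  values would require the original datasets and GPU-scale training, both
  out of scope.
- The accessibility regression is deliberately linear; it captures marginal
  accessibility structure, not loop-level specificity.
- Single-resolution cooler files only; no `.hic` binaries, no
  multi-resolution trees, no trans matrices.
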