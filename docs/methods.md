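# Methods

This note documents the models, defaults, and numerical choices behind
`ramanmix`, and what the synthetic benchmarks do and do not demonstrate.

## Mixing models and constraints

Spectra are rows of an `N x b` matrix with a strictly increasing
wavenumber axis. The linear mixing model is `x = M α`; the bilinear Fan
model adds every ordered pairwise Hadamard interaction
`Σ_k Σ_{l≠k} α_k m_k ⊙ α_l m_l`. Both the generator's mixer and the
autoencoder's bilinear decoder evaluate the Fan sum in the identical
closed form `(Mᵀα)² − (M²)ᵀα²` band-wise, so the decoder is the exact
algebraic mirror of the mixer (this equality is tested to machine
precision).

Abundances carry the nonnegativity constraint (ANC) and, when they
represent proportions, the sum-to-one constraint (ASC, enforced to 1e-6).
Endmembers are nonnegative with no all-zero rows. Mixed *intensities* are
deliberately **not** constrained nonnegative: additive dark noise and
baseline subtraction legitimately push individual bands below zero.

Endmembers are stored as rows internally; the textbook `b x n` column
convention appears only at the decoder-weight boundary (a transpose).
Formulas use 1-based band indices (`j = 1..b`); storage is 0-based. Scene
pixel order is row-major, origin top-left, z-layers outermost.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
surface. Defaults: `b = 1000` bands, `n = 5` endmembers, `100 x 100`
scenes (10,000 spectra).

**Endmembers.** Each signature superposes `n_peaks ~ U{5..9}` Gaussian
peaks. Peak height `h = h1·h2` with `h1 = 1 + 5·h_β`, `h_β ~ Beta(1,3)`
(mean 2.25), `h2 ~ U(0.1, 1)`; center `~ U(10, b−10)` in 1-based band
units; width `σ_p = w_p·σ`, `σ ~ U(0.1, 1)` band units. The peak is
written `h·exp(−(j−c)²/2σ_p²)`, i.e. the stated amplitude prefactor is
interpreted as a density rescaled so `h` is the literal peak maximum.
With `w_p = 1` clean peaks are at most one band wide; this is taken at
face value, and a `width_multiplier` knob (default 1) exists for broader,
more visually Raman-like peaks. *Noisy* endmembers add
`U{50..99}` small peaks with `h1` fixed at 1/3, `w_p = 2`, and `h2`
redrawn from the same `U(0.1, 1)` law (the minimal extension of the
clean-peak law; whether the small peaks redraw `h2` was an open choice).

**Scenes.** *Chessboard*: square patches (default edge 20 px), each a
constant one-hot pixel block with the endmember drawn i.i.d. uniformly —
a draw may miss an endmember; benchmark fixtures request
`require_full_coverage`, which redraws the assignment from the scene
stream (logged) until all endmembers appear. *Gaussian*: `n` isotropic
bumps equally spaced along the main diagonal, pixel-wise normalized to
sum one; the spatial spread is not fixed by the scene definition, so the
default is `H/n` pixels (configurable), which produces the intended range
of overlap. *Dirichlet*: each pixel i.i.d. `Dirichlet(1,…,1)` — the
uniform distribution on the simplex — as the canonical "random mixture of
everything" scene; the concentration vector is configurable.

**Artifacts.** Per spectrum: i.i.d. `N(0, σ_N)` noise on every band
(σ_N = 0.1); with probability `p_B = 0.25` an arctan baseline
`B_j = h_B·arctan(π·j/b)`, `h_B = 2`; with probability `p_S = 0.1` a
single cosmic spike of height `h_S·U(0.75, 1.25)`, `h_S = 5`, at a band
drawn from the discrete uniform `{2,…,b−2}` (1-based). Flags record which
spectra received which artifact and the spike band.

**Scenarios.** `ideal` (clean endmembers, linear, no artifacts),
`+artifacts`, `+realistic` (noisy endmembers + artifacts), `+bilinear`
(noisy endmembers, Fan mixing, artifacts). Crossed with the three scenes
minus (bilinear, Chessboard) — one-hot pixels have no cross terms — this
yields the 11 dataset variants.

**Randomness.** One root seed spawns independent child streams per stage
(endmembers / scene / artifacts) via `numpy.random.SeedSequence`, so each
stage is independently reproducible and ground-truth scenes are shared
across scenarios at equal seed.

## Autoencoders

The latent activation is softmax (ANC+ASC) or the soft-rectified tanh
`(1/γ)·log(1+e^{γ·tanh(x)})` with `γ = 10`, computed via a stable
softplus; its range is `(~4.5e-6, ~1.0000454)`. The decoder is bias-free
linear (identity activation); nonnegativity of `W` is enforced by
projection (clipping) after every Adam step — a literal reading of
clip-during-training, rather than a penalty. The decoder can be
pre-initialized from a supplied endmember set and optionally frozen for
nonblind unmixing.

The SAD training loss clips the cosine similarity to `[−1+1e−7, 1−1e−7]`
before `arccos` so gradients stay finite; the gradient is zero in the
clipped region. The optional MSE term averages over bands per pair
(whether the band-average normalization applies to the loss's MSE was
unstated; mean-over-bands is used and recorded in the config), then both
terms average over the batch.

Architectural interpretations where the layer descriptions left room:

- the convolutional block's channel merge is a position-wise linear map
  across the 32 concatenated channels back to one channel of width `b`;
- the transformer treats the spectrum as a length-`b` sequence of scalar
  tokens linearly embedded to width 32, one standard post-LN encoder
  layer (2 heads of size 32, FF 64→32, dropout 0.10), residual
  connections, then a dense layer to `m`; no positional encoding by
  default (a sinusoidal-encoding flag exists). Attention cost is
  O(b²) in time and memory, so transformer encoders are practical for
  cropped/binned spectra or reduced batch sizes.
- batch size is not architecturally determined; the default is 64, which
  is stable on 10k-spectrum datasets at desk scale.

Training defaults: Adam, lr 0.001, 10 epochs, SAD loss, seed-controlled
shuffling; all runs are bit-deterministic given (model seed, config seed,
data). A non-finite loss aborts with the offending epoch/batch.

The neural-network core (`ramanmix.nn`) is a tape-based reverse-mode
autodiff over numpy with exactly the operations these models need;
every operation is checked against central finite differences in the test
suite.

## Classical comparators

- **VCA** uses the conventional SNR-threshold switch
  (`15 + 10·log10(n)` dB) between the projective projection onto an
  `n`-dim SVD subspace (high SNR) and the affine projection onto `n−1`
  principal components with an appended constant (low SNR); random
  projection directions come from the seeded generator; `n = 1`
  degenerates to the max-norm spectrum. Extraction ties break toward the
  lowest pixel index.
- **N-FINDR** reduces to `n−1` principal components, starts from `n`
  random distinct pixels (seeded), and performs replacement sweeps,
  accepting a swap only if the |determinant| volume strictly increases;
  it stops after a sweep with no improvement or `max_sweeps` (10).
- **NNLS** delegates the per-spectrum nonnegative least-squares solve to
  `scipy.optimize.nnls`. **FCLS** uses the standard augmented-row
  construction (constant row of weight δ = 1e5, design matrix rescaled to
  unit max) and renormalizes rows to sum exactly one; the sum constraint
  therefore holds to ~1/δ before renormalization.

Both abundance solvers are verified against dense grid-search oracles on
small instances; both extractors against exhaustive search and exact
pure-pixel geometry.

## Preprocessing

Crop keeps bands whose wavenumber lies in the **closed** interval (band
membership by axis value, never by index). Despiking follows the
modified-z-score-of-first-differences scheme: a difference score beyond
the threshold flags both adjacent bands, which are replaced by the mean
of unflagged neighbors within ±kernel bands (one-sided at borders,
windows widen if no clean neighbor exists; an exactly-zero MAD is
replaced by the smallest positive float so constant spectra with a single
spike are handled). Savitzky–Golay smoothing delegates to scipy.

AsLS and ASPLS baselines are implemented in-repo with sparse
second-difference penalties. AsLS iterates asymmetric weights
(`p` above the baseline, `1−p` below) to convergence (`tol` on the mean
absolute weight change) or `max_iter`, warning and returning the best
iterate on non-convergence. ASPLS additionally adapts the penalty
band-wise by `α_i = |d_i|/max|d|` of the current residual and uses
logistic weights scaled by the standard deviation of the negative
residuals; the ASPLS literature contains minor variants, and this
implementation follows the published description at the stated
parameters. Presets: "sugar" (crop 400–1800 cm⁻¹, ASPLS λ=1e5, order 2,
100 iterations, tol 1e-3, global vector normalization) and "cell" (crop
700–1800 cm⁻¹, despike kernel 3 / z-threshold 8, Savitzky–Golay cubic
window 7, AsLS λ=1e6 / p=0.01 / order 2 / 50 iterations, global min-max).

## Evaluation protocol

Estimates are matched to ground truth by the Hungarian algorithm with SAD
cost; with `n > n_true` extracted endmembers the surplus estimates stay
unmatched and only the `n_true` matched pairs (and the correspondingly
permuted abundance columns) enter the metrics. Per run, SAD is reported
as the **mean** over matched endmembers (the aggregation is recorded in
the output metadata; sum vs mean was unstated) and MSE as the mean over
spectra of `(1/n)·‖α−α̂‖²`.

The benchmark grid crosses methods × 11 variants × (dataset seeds ×
model seeds), reusing the same seed table across scenarios so cells are
comparable. Latent dimension is `n_true` for `ideal` and `n_true + 1`
otherwise (the surplus column absorbs artifacts). The reduced grid
defaults to 50×50 scenes with 2×2 replicates — it preserves the grid
structure of the full 100×100 / 5×5 design at desk scale — and the full
grid is available behind `BenchmarkGrid.full()`. Chessboard patch edges
scale with the scene (largest common divisor keeping ≥ 5×5 patches).
Runtime profiling times each method end to end (including autoencoder
training, excluding dataset generation and I/O) on ideal Chessboard
datasets of increasing size, three repetitions per cell, CPU only.

## What the synthetic benchmarks show — and what they do not

The generator provides exact ground truth, so recovery and ordering
claims are sharply testable: on pure-pixel scenes geometric extractors
are exact and the dense autoencoder recovers endmembers to ~1e-3 rad; on
noisy, highly mixed Dirichlet scenes the dense autoencoder's matched SAD
beats VCA+FCLS. These checks run at reduced problem sizes (50×50 scenes,
2×2 replicates, 10 epochs) chosen as the package's desk-scale defaults.
Synthetic spectra remain idealized: peaks are strictly Gaussian and
narrow, artifacts are limited to three canonical types, there is no
instrument response, wavenumber calibration error, or spatial noise
correlation, and scene geometry is stylized. Passing these benchmarks
demonstrates correctness of the algorithms under the stated generative
law — not performance on any particular instrument's data.

## Known limitations

- The numpy training loop is single-threaded per op; it is fast for dense
  encoders at 10⁴–10⁵ spectra but the transformer encoders scale
  quadratically in band count.
- FCLS's augmented-row construction is a soft ASC enforcement (δ = 1e5)
  followed by exact renormalization, not an active-set simplex solver.
- N-FINDR's replacement search is a local optimizer; global optimality is
  only guaranteed on small instances (verified against brute force).
- The despiking window heuristic assumes isolated spikes; extended
  multi-band saturation events are out of scope.
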