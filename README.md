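# ramanmix

Hyperspectral unmixing for Raman spectroscopy: physics-constrained
autoencoders, classical geometric/least-squares comparators, a synthetic
Raman-mixture generator with full ground truth, preprocessing recipes, and
a quantitative evaluation harness.

## The problem

A Raman measurement `x ∈ R₊ᵇ` (intensities binned over `b` wavenumber
bands) from a chemically mixed sample is modeled as a combination of `n`
pure-component signatures (*endmembers*) `m₁,…,mₙ` weighted by
*fractional abundances* `α`:

- **Linear mixing model (LMM):** `x = M α = Σᵢ αᵢ mᵢ (+ noise)`
- **Bilinear Fan model:** `x = Σᵢ αᵢ mᵢ + Σₖ Σ_{l≠k} αₖ mₖ ⊙ αₗ mₗ`
  (Hadamard cross terms model pairwise nonlinear interactions)

with the abundance nonnegativity constraint (ANC, `αᵢ ≥ 0`) and optionally
the sum-to-one constraint (ASC, `‖α‖₁ = 1`). *Unmixing* is the inverse
problem: recover `M` and `α` from measurements — blind (both unknown) or
nonblind (`M` given). This underlies compositional analysis of imaging and
volumetric Raman scans of cells, solutions, and materials.

## The method

An **unmixing autoencoder** encodes each spectrum to a latent vector
`z = E(x)` of dimension `m` (the abundances) and decodes it back with a
structurally constrained decoder (the mixing model):

- latent activation **softmax** → ANC + ASC; or a **soft-rectified tanh**
  `(1/γ)·log(1 + exp(γ·tanh(x)))`, `γ = 10` → ANC only;
- the decoder is a single bias-free linear map `x̂ = W z` whose weights are
  clipped to `W ≥ 0` after every optimizer step — its columns are the
  learned endmembers; a bilinear decoder adds the Fan cross terms;
- training is self-supervised with the **spectral angle distance**
  `SAD(x, x̂) = arccos(x·x̂ / ‖x‖‖x̂‖)` (optionally `+ λ·MSE`, `λ = 1000`),
  Adam, learning rate 0.001.

Five encoders are provided: `dense` (b→128→m), `deep_dense`
(512-256-128-64-32), `conv` (parallel 1-D banks of 16×3 and 16×5 filters),
`transformer` (2 attention heads of size 32, FF 64→32, dropout 0.10), and
`conv_transformer`. The networks run on a small numpy autodiff core
(`ramanmix.nn`) validated against finite-difference gradients — no
deep-learning framework is required.

Classical comparators are implemented from their definitions: **VCA** and
**N-FINDR** for endmember extraction (pure-pixel geometry), **NNLS** and
**FCLS** for abundance estimation. Evaluation matches estimated to true
endmembers with the Hungarian algorithm under SAD cost and reports matched
mean SAD and abundance MSE `(1/n)·‖α − α̂‖²`.

The synthetic generator emulates Raman data end to end: Gaussian-peak
endmembers (5–9 major peaks; optional 50–99 small peaks for realistic
signatures), Chessboard / Gaussian / Dirichlet abundance scenes (all
ANC+ASC by construction), linear or Fan mixing, and artifact injection
(dark noise σ=0.1, arctan baselines with probability 0.25, cosmic spikes
with probability 0.1).

## Worked example

```bash
python examples/autoencoder_unmixing.py
```

```
training loss: 0.7266 (epoch 1) -> 0.0012 (epoch 10)
matched endmember SAD: 0.0012 rad
abundance MSE:         1.30e-09
```

A dense autoencoder (`m = 5`, linear decoder, 10 epochs) trained on an
ideal Chessboard dataset (10,000 spectra, 1,000 bands) recovers the five
ground-truth endmembers to a matched spectral angle of ~0.001 rad —
visually indistinguishable signatures — and per-pixel abundances to MSE
~10⁻⁹. On the same data the classical route is exact by construction
(`examples/classical_unmixing.py` prints matched SAD ~10⁻⁸ for VCA and
N-FINDR), while on noisy, highly mixed scenes the autoencoders pull ahead
(`examples/benchmark_grid.py`).

Other entry points: `examples/generate_synthetic.py` (generator +
artifact bookkeeping), `examples/preprocess_pipeline.py` (the "cell"
preprocessing recipe), and the `ramanmix` CLI
(`generate | preprocess | unmix | evaluate | benchmark | profile`), which
writes a JSON reproducibility manifest next to every output.

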