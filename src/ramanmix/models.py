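"""Physics-constrained unmixing autoencoders.

An unmixing autoencoder maps a spectrum ``x`` (length ``b``) through an
encoder to a latent vector ``z`` of dimension ``m`` (the candidate
fractional abundances) and decodes it back to a reconstruction ``x_hat``.
The physical interpretation is enforced architecturally:

* **ANC + ASC** -- the latent activation is a softmax, so abundances are
  nonnegative and sum to one.
* **ANC only** -- the latent activation is a "softly rectified" tanh,
  ``(1/gamma) * log(1 + exp(gamma * tanh(x)))`` with ``gamma = 10``,
  keeping abundances in (0, ~1) without the sum constraint.
* **Endmember nonnegativity** -- the decoder is a single bias-free linear
  layer (identity activation) whose weight matrix is projected onto the
  nonnegative orthant after every optimizer step; its columns are the
  learned endmember signatures.
* **Mixing model** -- the linear decoder computes ``W z``; the bilinear
  (Fan) decoder adds every ordered pairwise interaction
  ``sum_{k != l} z_k w_k * z_l w_l`` and is the exact algebraic mirror of
  the generator's Fan mixer.

Training is self-supervised with the spectral angle distance (SAD) between
input and reconstruction, optionally augmented with a lambda-weighted MSE
term that breaks SAD's scale invariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .core import AbundanceMap, EndmemberSet, SpectralDataset
from .errors import (
    DimensionError,
    ModelStateError,
    ParameterError,
    TrainingDivergenceError,
    UndefinedAngleError,
)

__all__ = [
    "ENCODER_KINDS",
    "DECODER_KINDS",
    "EncoderSpec",
    "DecoderSpec",
    "ConstraintSpec",
    "TrainingConfig",
    "soft_rectified_tanh",
    "sad",
    "decode",
    "training_loss",
    "UnmixingAutoencoder",
    "fit",
    "extract_endmembers",
    "infer_abundances",
]

ENCODER_KINDS = ("dense", "deep_dense", "conv", "transformer", "conv_transformer")
DECODER_KINDS = ("linear", "fan_bilinear")

_COS_EPS = 1e-7  # clip for arccos gradients during training


# ---------------------------------------------------------------------------
# Specs / configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the encoder ``E: R^b -> R^m``.

    ``hidden`` defaults to [128] for ``dense`` and [512, 256, 128, 64, 32]
    for ``deep_dense``.  The ``conv`` kinds prepend two parallel 1-D
    convolution banks (16 filters of length 3 and 16 of length 5, ReLU,
    zero padding) merged channel-wise back to width ``b``.  The transformer
    kinds embed the spectrum as a length-``b`` sequence of scalar tokens
    (linear embedding to width 32, no positional encoding by default), one
    standard encoder layer (2 heads of size 32, feed-forward 64 -> 32,
    dropout 0.10, layer normalization), then a final dense layer to ``m``.
    """

    kind: str = "dense"
    input_dim: int = 1000
    latent_dim: int = 5
    hidden: Optional[tuple[int, ...]] = None
    leaky_slope: float = 0.02
    conv_filters: int = 16
    conv_kernels: tuple[int, int] = (3, 5)
    embed_dim: int = 32
    n_heads: int = 2
    head_dim: int = 32
    ff_dim: int = 64
    dropout: float = 0.10
    positional_encoding: bool = False

    def resolved_hidden(self) -> tuple[int, ...]:
        if self.hidden is not None:
            return tuple(self.hidden)
        return (512, 256, 128, 64, 32) if self.kind == "deep_dense" else (128,)

    def validate(self) -> None:
        if self.kind not in ENCODER_KINDS:
            raise ParameterError(f"unknown encoder kind {self.kind!r}")
        if not (1 <= self.latent_dim <= self.input_dim):
            raise ParameterError(
                f"latent_dim must satisfy 1 <= m <= b, got m={self.latent_dim}, "
                f"b={self.input_dim}"
            )


@dataclass
class DecoderSpec:
    """Decoder kind plus its ``b x m`` nonnegative weight matrix (no bias)."""

    kind: str = "linear"
    weights: Optional[np.ndarray] = None  # b x m, columns are endmembers

    def validate(self) -> None:
        if self.kind not in DECODER_KINDS:
            raise ParameterError(f"unknown decoder kind {self.kind!r}")


@dataclass(frozen=True)
class ConstraintSpec:
    """Abundance constraints: ANC always; ASC selects softmax vs soft-tanh."""

    anc: bool = True
    asc: bool = True
    gamma: float = 10.0


@dataclass(frozen=True)
class TrainingConfig:
    """Adam training hyperparameters.

    ``loss`` is ``"sad"`` (scale-invariant) or ``"sad_plus_mse"`` which adds
    ``lambda_mse`` times the band-averaged MSE per spectrum pair.
    """

    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 64
    loss: str = "sad"
    lambda_mse: float = 1000.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.loss not in ("sad", "sad_plus_mse"):
            raise ParameterError(f"unknown loss {self.loss!r}")
        if self.lambda_mse <= 0:
            raise ParameterError("lambda_mse must be > 0")


# ---------------------------------------------------------------------------
# Closed-form pieces (numpy surface shared with evaluation and tests)
# ---------------------------------------------------------------------------


def soft_rectified_tanh(x, gamma: float = 10.0):
    """``(1/gamma) * log(1 + exp(gamma * tanh(x)))``, elementwise.

    Strictly positive and monotone increasing; saturates near
    ``(1/gamma) * log(1 + e^gamma)`` (~1.0000454 for gamma=10) for large x
    and near 0 for large negative x.  Stable for any ``gamma * tanh(x)``.
    """
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    u = gamma * np.tanh(np.asarray(x, dtype=float))
    return np.logaddexp(0.0, u) / gamma


def sad(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle distance: arccos of the cosine similarity (radians).

    Scale-invariant (``sad(a, c*b) == sad(a, b)`` for c > 0) and symmetric.
    Raises :class:`UndefinedAngleError` for a zero-norm vector.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedAngleError("spectral angle undefined for a zero-norm vector")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def decode(z: np.ndarray, spec: DecoderSpec) -> np.ndarray:
    """Apply a decoder to one latent vector (numpy reference path).

    Linear: ``x_hat = W z``.  Fan bilinear: adds all ordered pairwise
    interactions, computed as ``(Wz)^2 - (W^2)(z^2)`` band-wise.
    """
    spec.validate()
    if spec.weights is None:
        raise ModelStateError("decoder weights are not initialized")
    W = np.asarray(spec.weights, dtype=float)  # b x m
    z = np.asarray(z, dtype=float).reshape(-1)
    if W.shape[1] != z.size:
        raise DimensionError(f"W has {W.shape[1]} columns but z has length {z.size}")
    linear = W @ z
    if spec.kind == "fan_bilinear":
        return linear + linear**2 - (W**2) @ (z**2)
    return linear


def training_loss(x: np.ndarray, x_hat: np.ndarray, config: TrainingConfig) -> float:
    """Batch training loss (numpy reference): mean SAD, plus lambda * MSE.

    The MSE per pair is averaged over bands; both terms are then averaged
    over the batch.
    """
    config.validate()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    if x.shape != x_hat.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    angles = np.array([sad(a, b) for a, b in zip(x, x_hat)])
    total = angles.mean()
    if config.loss == "sad_plus_mse":
        total += config.lambda_mse * float(((x - x_hat) ** 2).mean())
    return float(total)


# ---------------------------------------------------------------------------
# Encoder modules
# ---------------------------------------------------------------------------


class _DenseStack(nn.Module):
    def __init__(self, dims: Sequence[int], slope: float, rng):
        super().__init__()
        self.slope = slope
        self.layers = [
            nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])
        ]
        for i, layer in enumerate(self.layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers[:-1]:
            x = layer(x).leaky_relu(self.slope)
        return self.layers[-1](x)


class _ConvBlock(nn.Module):
    """Two parallel 1-D convolution banks merged channel-wise to width b."""

    def __init__(self, spec: EncoderSpec, rng):
        super().__init__()
        k1, k2 = spec.conv_kernels
        self.conv_a = nn.Conv1d(1, spec.conv_filters, k1, rng)
        self.conv_b = nn.Conv1d(1, spec.conv_filters, k2, rng)
        self.merge = nn.Linear(2 * spec.conv_filters, 1, rng)

    def forward(self, x):  # (B, b)
        B, b = x.shape
        xc = x.reshape(B, 1, b)
        feats = nn.concat(
            [self.conv_a(xc).relu(), self.conv_b(xc).relu()], axis=1
        )  # (B, 32, b)
        merged = self.merge(feats.swapaxes(1, 2))  # (B, b, 1)
        return merged.reshape(B, b)


class _TransformerBlock(nn.Module):
    """One standard post-LN transformer encoder layer over scalar tokens."""

    def __init__(self, spec: EncoderSpec, rng, drop_rng):
        super().__init__()
        e = spec.embed_dim
        self.embed = nn.Linear(1, e, rng)
        self.attn = nn.MultiHeadAttention(e, spec.n_heads, spec.head_dim, rng)
        self.norm1 = nn.LayerNorm(e)
        self.norm2 = nn.LayerNorm(e)
        self.ff1 = nn.Linear(e, spec.ff_dim, rng)
        self.ff2 = nn.Linear(spec.ff_dim, e, rng)
        self.drop1 = nn.Dropout(spec.dropout, drop_rng)
        self.drop2 = nn.Dropout(spec.dropout, drop_rng)
        self.final = nn.Linear(spec.input_dim * e, spec.latent_dim, rng)
        if spec.positional_encoding:
            pos = _sinusoidal_encoding(spec.input_dim, e)
            self.pos = nn.Tensor(pos)
        else:
            self.pos = None

    def forward(self, x):  # (B, b)
        B, b = x.shape
        tokens = self.embed(x.reshape(B, b, 1))  # (B, b, e)
        if self.pos is not None:
            tokens = tokens + self.pos
        h = self.norm1(tokens + self.drop1(self.attn(tokens)))
        ff = self.ff2(self.ff1(h).relu())
        h = self.norm2(h + self.drop2(ff))
        return self.final(h.reshape(B, -1))


def _sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class _Encoder(nn.Module):
    def __init__(self, spec: EncoderSpec, rng, drop_rng):
        super().__init__()
        spec.validate()
        self.spec = spec
        b, m = spec.input_dim, spec.latent_dim
        self.conv = (
            _ConvBlock(spec, rng)
            if spec.kind in ("conv", "conv_transformer")
            else None
        )
        if spec.kind in ("transformer", "conv_transformer"):
            self.body = _TransformerBlock(spec, rng, drop_rng)
        else:
            dims = (b, *spec.resolved_hidden(), m)
            self.body = _DenseStack(dims, spec.leaky_slope, rng)

    def forward(self, x):
        if self.conv is not None:
            x = self.conv(x)
        return self.body(x)


# ---------------------------------------------------------------------------
# Full autoencoder
# ---------------------------------------------------------------------------


class UnmixingAutoencoder(nn.Module):
    """Encoder + constrained latent activation + (bi)linear decoder.

    Parameters
    ----------
    n_bands, n_endmembers
        Spectral width ``b`` and latent dimension ``m`` (the number of
        endmembers to learn; may exceed the true number).
    encoder, decoder
        One of :data:`ENCODER_KINDS` / ``"linear"`` or ``"fan_bilinear"``.
    asc
        Enforce the sum-to-one constraint (softmax latent).  With
        ``asc=False`` only nonnegativity is enforced (soft-rectified tanh).
    init_endmembers
        Optional :class:`EndmemberSet` used to pre-initialize the decoder
        columns; with ``freeze_decoder=True`` this performs nonblind
        unmixing against the supplied signatures.
    seed
        Root seed for weight initialization and dropout masks.
    """

    def __init__(
        self,
        n_bands: int,
        n_endmembers: int,
        encoder: str = "dense",
        decoder: str = "linear",
        asc: bool = True,
        gamma: float = 10.0,
        seed: Optional[int] = None,
        encoder_spec: Optional[EncoderSpec] = None,
        init_endmembers: Optional[EndmemberSet] = None,
        freeze_decoder: bool = False,
    ):
        super().__init__()
        if decoder not in DECODER_KINDS:
            raise ParameterError(f"unknown decoder kind {decoder!r}")
        spec = encoder_spec or EncoderSpec(
            kind=encoder, input_dim=n_bands, latent_dim=n_endmembers
        )
        if spec.input_dim != n_bands or spec.latent_dim != n_endmembers:
            spec = dataclasses.replace(
                spec, input_dim=n_bands, latent_dim=n_endmembers
            )
        ss = np.random.SeedSequence(seed)
        init_ss, drop_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        drop_rng = np.random.default_rng(drop_ss)

        self.n_bands = n_bands
        self.n_endmembers = n_endmembers
        self.decoder_kind = decoder
        self.constraints = ConstraintSpec(anc=True, asc=asc, gamma=gamma)
        self.encoder = _Encoder(spec, rng, drop_rng)

        if init_endmembers is not None:
            if init_endmembers.signatures.shape != (n_endmembers, n_bands):
                raise DimensionError(
                    "init_endmembers must be n_endmembers x n_bands, got "
                    f"{init_endmembers.signatures.shape}"
                )
            w0 = np.maximum(init_endmembers.signatures.copy(), 0.0)
        else:
            # Nonnegative at initialization so the W >= 0 invariant holds
            # from the first forward pass onward.
            w0 = np.abs(
                rng.uniform(
                    -1.0, 1.0, size=(n_endmembers, n_bands)
                )
            ) * np.sqrt(6.0 / (n_endmembers + n_bands))
        self.W = self.register("W", w0)  # m x b; rows are endmember signatures
        if freeze_decoder:
            self.W.requires_grad = False
        self.frozen_decoder = freeze_decoder
        self.fitted = False

    # -- pieces ------------------------------------------------------------

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        logits = self.encoder(x)
        if self.constraints.asc:
            return logits.softmax(axis=-1)
        g = self.constraints.gamma
        return (logits.tanh() * g).softplus() * (1.0 / g)

    def decode_latent(self, z: nn.Tensor) -> nn.Tensor:
        linear = z @ self.W
        if self.decoder_kind == "fan_bilinear":
            return linear + linear**2.0 - (z**2.0) @ (self.W**2.0)
        return linear

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        z = self.encode(x)
        return z, self.decode_latent(z)

    def clip_decoder(self) -> None:
        np.maximum(self.W.data, 0.0, out=self.W.data)

    def trainable_parameters(self) -> list[nn.Tensor]:
        return [p for p in self.parameters() if p.requires_grad]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _batch_loss(
    x: nn.Tensor, x_hat: nn.Tensor, config: TrainingConfig
) -> nn.Tensor:
    dot = (x * x_hat).sum(axis=1)
    nx = (x * x).sum(axis=1).sqrt()
    nh = (x_hat * x_hat).sum(axis=1).sqrt()
    cos = dot / (nx * nh)
    loss = cos.acos_clipped(_COS_EPS).mean()
    if config.loss == "sad_plus_mse":
        diff = x_hat - x
        loss = loss + config.lambda_mse * (diff * diff).mean()
    return loss


def fit(
    model: UnmixingAutoencoder,
    d: SpectralDataset,
    config: Optional[TrainingConfig] = None,
    epoch_callback=None,
) -> list[float]:
    """Train in place with Adam; returns the per-epoch mean loss trace.

    After every optimizer step the decoder weights are clipped to the
    nonnegative orthant.  Deterministic given (model seed, config seed,
    data).  Raises :class:`TrainingDivergenceError`, naming the epoch and
    batch, if the loss goes non-finite.  ``epoch_callback(epoch, model)``
    runs after each epoch (checkpoint inspection, logging).
    """
    config = config or TrainingConfig()
    config.validate()
    X = d.intensities
    if X.shape[0] < 1:
        raise ParameterError("need at least one spectrum to train on")
    if X.shape[1] != model.n_bands:
        raise DimensionError(
            f"dataset has {X.shape[1]} bands but model expects {model.n_bands}"
        )
    zero_rows = ~np.abs(X).any(axis=1)
    if zero_rows.any():
        raise UndefinedAngleError(
            f"spectrum {int(np.flatnonzero(zero_rows)[0])} is all-zero; "
            "SAD is undefined"
        )

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.trainable_parameters(), lr=config.learning_rate)
    model.train()
    trace: list[float] = []
    N = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = nn.Tensor(X[idx])
            _, x_hat = model(xb)
            loss = _batch_loss(xb, x_hat, config)
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.clip_decoder()
            epoch_loss += float(loss.data) * idx.size
        trace.append(epoch_loss / N)
        if epoch_callback is not None:
            epoch_callback(epoch, model)
    model.eval()
    model.fitted = True
    return trace


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def extract_endmembers(model: UnmixingAutoencoder) -> EndmemberSet:
    """Learned endmember signatures: the decoder weight columns (row form)."""
    if not model.fitted:
        raise ModelStateError("model has not been fitted; call fit() first")
    return EndmemberSet(np.maximum(model.W.data.copy(), 0.0))


def infer_abundances(
    model: UnmixingAutoencoder, d: SpectralDataset, batch_size: int = 1024
) -> AbundanceMap:
    """Fractional abundances: latent activations of the trained encoder."""
    if not model.fitted:
        raise ModelStateError("model has not been fitted; call fit() first")
    if d.n_bands != model.n_bands:
        raise DimensionError(
            f"dataset has {d.n_bands} bands but model expects {model.n_bands}"
        )
    model.eval()
    chunks = []
    for start in range(0, d.n_spectra, batch_size):
        xb = nn.Tensor(d.intensities[start : start + batch_size])
        chunks.append(model.encode(xb).data)
    values = np.vstack(chunks)
    return AbundanceMap(
        values,
        anc=True,
        asc=model.constraints.asc,
        scene_shape=d.scene_shape,
    )
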