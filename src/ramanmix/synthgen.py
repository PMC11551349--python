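"""Synthetic Raman mixture generator with known ground truth.

The generator composes four stages, each with its own child RNG stream so a
single root seed reproduces every stage independently:

1. **Endmembers** -- each pure-component signature is a superposition of
   ``npeaks ~ U{5..9}`` Gaussian peaks over ``b`` bands.  A peak has height
   ``h = h1 * h2`` with ``h1 = 1 + 5*h_beta``, ``h_beta ~ Beta(1, 3)``,
   ``h2 ~ U(0.1, 1)``; center ``b_p ~ U(10, b-10)`` (1-based band units);
   width ``sigma_p = w_p * sigma`` with ``sigma ~ U(0.1, 1)``.  The peak is
   written as ``h * exp(-(j - b_p)^2 / (2 sigma_p^2))`` so ``h`` is the
   literal peak maximum.  Clean endmembers use ``w_p = 1``; *noisy*
   endmembers add ``U{50..99}`` small peaks with ``h1 = 1/3`` fixed and
   ``w_p = 2``, emulating the subtle secondary structure of experimental
   Raman signatures.
2. **Abundance scenes** -- *Chessboard* (square patches, each a constant
   one-hot vector), *Gaussian* (isotropic bumps equally spaced along the
   scene diagonal, pixel-wise normalized), *Dirichlet* (each pixel i.i.d.
   from a symmetric Dirichlet).  All three satisfy ANC and ASC exactly.
3. **Mixing** -- linear model ``x = M^T a`` or the bilinear Fan model which
   adds all ordered pairwise Hadamard interactions
   ``sum_{k != l} a_k m_k * a_l m_l``.
4. **Artifacts** -- i.i.d. Gaussian dark noise on every band; an arctan
   baseline ``B_j = h_B * arctan(pi * j / b)`` (1-based ``j``) added with
   probability ``p_B``; a single cosmic spike of height ``h_S * U(0.75,
   1.25)`` at a band drawn from ``U{2 .. b-2}`` (1-based) with probability
   ``p_S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import AbundanceMap, EndmemberSet, SpectralAxis, SpectralDataset
from .errors import DimensionError, ParameterError

__all__ = [
    "EndmemberSamplerParams",
    "SceneParams",
    "ArtifactParams",
    "ArtifactFlags",
    "GenerationRecord",
    "sample_endmember",
    "sample_endmembers",
    "make_scene",
    "mix",
    "add_artifacts",
    "generate_dataset",
    "SCENARIOS",
    "SCENES",
    "dataset_variants",
]

SCENARIOS = ("ideal", "artifacts", "realistic", "bilinear")
SCENES = ("chessboard", "gaussian", "dirichlet")


def default_patch_edge(H: int, W: int) -> int:
    """Largest common patch edge keeping a >= 5x5 patch grid.

    Mirrors the 20-pixel patches of the default 100x100 Chessboard scene at
    other scene sizes, so the scene retains enough patches to plausibly
    cover all endmembers."""
    cap = min(H, W) // 5
    for p in range(min(20, cap), 0, -1):
        if H % p == 0 and W % p == 0:
            return p
    return 1


def dataset_variants() -> list[tuple[str, str]]:
    """The 11 benchmark dataset variants: 4 scenarios x 3 scenes, minus the
    bilinear Chessboard combination (one-hot pixels have no cross terms)."""
    return [
        (scenario, scene)
        for scenario in SCENARIOS
        for scene in SCENES
        if not (scenario == "bilinear" and scene == "chessboard")
    ]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndmemberSamplerParams:
    """Law of the random Gaussian-peak endmembers (see module docstring)."""

    b: int = 1000
    n: int = 5
    noisy: bool = False
    npeaks_range: tuple[int, int] = (5, 9)  # inclusive
    small_peaks_range: tuple[int, int] = (50, 99)  # inclusive
    h1_beta: tuple[float, float] = (1.0, 3.0)
    h1_scale: float = 5.0
    h2_range: tuple[float, float] = (0.1, 1.0)
    center_margin: float = 10.0  # bands, 1-based law U(margin, b - margin)
    sigma_range: tuple[float, float] = (0.1, 1.0)
    wp_clean: float = 1.0
    wp_small: float = 2.0
    h1_small: float = 1.0 / 3.0
    width_multiplier: float = 1.0  # broadens all peaks; 1 = faithful law

    def validate(self) -> None:
        if self.b < 2 * self.center_margin + 1:
            raise ParameterError(
                f"b={self.b} too small for center margin {self.center_margin}"
            )
        for name in ("npeaks_range", "small_peaks_range", "h2_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ParameterError(f"{name} is empty: {(lo, hi)}")


@dataclass(frozen=True)
class SceneParams:
    """Geometry and law of the fractional-abundance scene."""

    kind: str = "chessboard"
    H: int = 100
    W: int = 100
    patch: int = 20  # chessboard patch edge (pixels)
    gaussian_sigma: Optional[float] = None  # default H / n (pixels)
    dirichlet_alpha: Optional[np.ndarray] = None  # default symmetric Dir(1)

    def validate(self, n: int) -> None:
        if self.kind not in SCENES:
            raise ParameterError(f"unknown scene kind {self.kind!r}")
        if self.H < 1 or self.W < 1:
            raise ParameterError(f"scene dims must be >= 1, got {self.H}x{self.W}")
        if self.kind == "chessboard" and (
            self.H % self.patch != 0 or self.W % self.patch != 0
        ):
            raise ParameterError(
                f"patch {self.patch} must divide scene dims {self.H}x{self.W}"
            )
        if n < 1:
            raise ParameterError("need n >= 1 endmembers")


@dataclass(frozen=True)
class ArtifactParams:
    """Dark noise / baseline / cosmic spike injection parameters."""

    sigma_noise: float = 0.1
    p_baseline: float = 0.25
    h_baseline: float = 2.0
    p_spike: float = 0.1
    h_spike: float = 5.0

    def validate(self) -> None:
        if not (0.0 <= self.p_baseline <= 1.0 and 0.0 <= self.p_spike <= 1.0):
            raise ParameterError("artifact probabilities must lie in [0, 1]")
        if self.sigma_noise < 0:
            raise ParameterError("sigma_noise must be >= 0")


@dataclass
class ArtifactFlags:
    """Per-spectrum bookkeeping of which artifacts were injected.

    ``spike_band`` holds the 0-based band index of the spike, or -1.
    """

    baseline_added: np.ndarray
    spike_added: np.ndarray
    spike_band: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "ArtifactFlags":
        return cls(
            np.zeros(n, dtype=bool),
            np.zeros(n, dtype=bool),
            np.full(n, -1, dtype=np.int64),
        )


@dataclass
class GenerationRecord:
    """Ground truth and provenance emitted alongside a generated dataset."""

    endmembers: EndmemberSet
    abundances: AbundanceMap
    mixture_model: str  # "linear" | "fan"
    artifact_flags: ArtifactFlags
    seed: Optional[int]
    scenario: Optional[str] = None
    scene: Optional[str] = None


# ---------------------------------------------------------------------------
# Stage 1: endmembers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakDraw:
    """The sampled parameters of one set of Gaussian peaks."""

    heights: np.ndarray  # h = h1 * h2, the literal peak maxima
    h1: np.ndarray
    h2: np.ndarray
    centers: np.ndarray  # 1-based band coordinate
    widths: np.ndarray  # sigma_p = w_p * sigma (band units)


def _draw_peaks(
    b: int,
    n_peaks: int,
    h1: np.ndarray,
    params: EndmemberSamplerParams,
    wp: float,
    rng: np.random.Generator,
) -> PeakDraw:
    h2 = rng.uniform(*params.h2_range, size=n_peaks)
    centers = rng.uniform(params.center_margin, b - params.center_margin, size=n_peaks)
    sigma = rng.uniform(*params.sigma_range, size=n_peaks)
    widths = wp * sigma * params.width_multiplier
    return PeakDraw(h1 * h2, h1, h2, centers, widths)


def _render_peaks(b: int, peaks: PeakDraw) -> np.ndarray:
    """Superpose Gaussian peaks over 1-based bands ``1..b``."""
    j = np.arange(1, b + 1, dtype=float)
    return (
        peaks.heights[:, None]
        * np.exp(
            -((j[None, :] - peaks.centers[:, None]) ** 2)
            / (2.0 * peaks.widths[:, None] ** 2)
        )
    ).sum(axis=0)


def sample_endmember(
    params: EndmemberSamplerParams,
    rng: np.random.Generator,
    return_peaks: bool = False,
):
    """Draw one endmember signature (length-``b`` nonnegative vector).

    With ``return_peaks=True`` also returns the sampled
    ``(major, small)`` :class:`PeakDraw` pair (``small`` is None for clean
    endmembers), exposing the underlying law for distributional checks.
    """
    params.validate()
    lo, hi = params.npeaks_range
    n_major = int(rng.integers(lo, hi + 1))
    beta_a, beta_b = params.h1_beta
    h1 = 1.0 + params.h1_scale * rng.beta(beta_a, beta_b, size=n_major)
    major = _draw_peaks(params.b, n_major, h1, params, params.wp_clean, rng)
    spectrum = _render_peaks(params.b, major)
    small = None
    if params.noisy:
        lo_s, hi_s = params.small_peaks_range
        n_small = int(rng.integers(lo_s, hi_s + 1))
        h1_small = np.full(n_small, params.h1_small)
        small = _draw_peaks(params.b, n_small, h1_small, params, params.wp_small, rng)
        spectrum = spectrum + _render_peaks(params.b, small)
    if return_peaks:
        return spectrum, (major, small)
    return spectrum


def sample_endmembers(
    params: EndmemberSamplerParams, rng: np.random.Generator
) -> EndmemberSet:
    """Draw the full ``n x b`` endmember matrix."""
    sigs = np.stack([sample_endmember(params, rng) for _ in range(params.n)])
    labels = [f"endmember_{i}" for i in range(params.n)]
    return EndmemberSet(sigs, labels=labels)


# ---------------------------------------------------------------------------
# Stage 2: abundance scenes
# ---------------------------------------------------------------------------


def make_scene(params: SceneParams, n: int, rng: np.random.Generator) -> AbundanceMap:
    """Build an ``(H*W) x n`` abundance map satisfying ANC and ASC exactly."""
    params.validate(n)
    H, W = params.H, params.W
    if params.kind == "chessboard":
        ph, pw = H // params.patch, W // params.patch
        assignment = rng.integers(0, n, size=(ph, pw))
        grid = np.kron(assignment, np.ones((params.patch, params.patch), dtype=int))
        values = np.eye(n)[grid.reshape(-1)]
    elif params.kind == "gaussian":
        sigma = params.gaussian_sigma if params.gaussian_sigma is not None else H / n
        # Bump centers equally spaced along the main diagonal of the scene.
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        centers_r = (np.arange(n) + 0.5) * H / n - 0.5
        centers_c = (np.arange(n) + 0.5) * W / n - 0.5
        d2 = (rr[None] - centers_r[:, None, None]) ** 2 + (
            cc[None] - centers_c[:, None, None]
        ) ** 2
        bumps = np.exp(-d2 / (2.0 * sigma**2))  # (n, H, W)
        values = bumps.reshape(n, -1).T
        values = values / values.sum(axis=1, keepdims=True)
    else:  # dirichlet
        alpha = (
            np.asarray(params.dirichlet_alpha, dtype=float)
            if params.dirichlet_alpha is not None
            else np.ones(n)
        )
        if alpha.size != n:
            raise ParameterError(f"dirichlet_alpha length {alpha.size} != n={n}")
        values = rng.dirichlet(alpha, size=H * W)
    return AbundanceMap(values, anc=True, asc=True, scene_shape=(H, W))


# ---------------------------------------------------------------------------
# Stage 3: mixing
# ---------------------------------------------------------------------------


def mix(M: EndmemberSet, A: AbundanceMap, model: str = "linear") -> SpectralDataset:
    """Mix endmembers with abundances under the linear or bilinear Fan model.

    Linear: ``x_i = sum_k a_ik m_k``.  Fan: adds every ordered pairwise
    Hadamard interaction ``sum_{k} sum_{l != k} a_ik m_k * a_il m_l``,
    computed in closed form as ``(M^T a)^2 - (M^2)^T a^2`` band-wise.
    """
    if A.n_endmembers != M.n_endmembers:
        raise DimensionError(
            f"abundance columns ({A.n_endmembers}) != endmembers ({M.n_endmembers})"
        )
    if model not in ("linear", "fan"):
        raise ParameterError(f"unknown mixing model {model!r}")
    linear = A.values @ M.signatures
    if model == "fan":
        intensities = linear + linear**2 - (A.values**2) @ (M.signatures**2)
    else:
        intensities = linear
    axis = SpectralAxis(np.arange(1, M.n_bands + 1, dtype=float))
    return SpectralDataset(intensities, axis, scene_shape=A.scene_shape)


# ---------------------------------------------------------------------------
# Stage 4: artifacts
# ---------------------------------------------------------------------------


def add_artifacts(
    d: SpectralDataset, params: ArtifactParams, rng: np.random.Generator
) -> tuple[SpectralDataset, ArtifactFlags]:
    """Inject dark noise, arctan baselines, and cosmic spikes (module doc)."""
    params.validate()
    N, b = d.intensities.shape
    out = d.intensities.copy()
    flags = ArtifactFlags.empty(N)

    if params.sigma_noise > 0:
        out += rng.normal(0.0, params.sigma_noise, size=(N, b))

    baseline_hit = rng.random(N) < params.p_baseline
    if baseline_hit.any():
        j = np.arange(1, b + 1, dtype=float)  # 1-based band index
        baseline = params.h_baseline * np.arctan(np.pi * j / b)
        out[baseline_hit] += baseline
    flags.baseline_added = baseline_hit

    spike_hit = rng.random(N) < params.p_spike
    if spike_hit.any():
        k = int(spike_hit.sum())
        # 1-based law U{2 .. b-2} -> 0-based storage index.
        bands = rng.integers(2, b - 1, size=k) - 1
        mags = params.h_spike * rng.uniform(0.75, 1.25, size=k)
        rows = np.flatnonzero(spike_hit)
        out[rows, bands] += mags
        flags.spike_band[rows] = bands
    flags.spike_added = spike_hit

    return SpectralDataset(out, d.axis, scene_shape=d.scene_shape), flags


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

_MAX_COVERAGE_REDRAWS = 64


def generate_dataset(
    scenario: str = "ideal",
    scene: str = "chessboard",
    seed: Optional[int] = None,
    endmember_params: Optional[EndmemberSamplerParams] = None,
    scene_params: Optional[SceneParams] = None,
    artifact_params: Optional[ArtifactParams] = None,
    require_full_coverage: bool = False,
) -> tuple[SpectralDataset, GenerationRecord]:
    """Generate one synthetic dataset for a (scenario, scene) variant.

    Scenarios: ``ideal`` (clean endmembers, linear mix, no artifacts),
    ``artifacts`` (clean + artifacts), ``realistic`` (noisy endmembers +
    artifacts), ``bilinear`` (noisy endmembers, Fan mixing, artifacts).
    The (bilinear, chessboard) combination is rejected: one-hot pixels have
    no bilinear cross terms, so the variant would be indistinguishable from
    the linear one.

    ``require_full_coverage`` redraws the Chessboard patch assignment (from
    its own child stream) until every endmember appears at least once; used
    for benchmark fixtures where a missing endmember would make ground-truth
    matching ill-posed.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")
    if scene not in SCENES:
        raise ParameterError(f"unknown scene {scene!r}; expected {SCENES}")
    if scenario == "bilinear" and scene == "chessboard":
        raise ParameterError(
            "the bilinear scenario is undefined on the Chessboard scene: "
            "one-hot abundances produce no bilinear interaction terms"
        )

    noisy = scenario in ("realistic", "bilinear")
    model = "fan" if scenario == "bilinear" else "linear"
    with_artifacts = scenario != "ideal"

    ep = endmember_params or EndmemberSamplerParams()
    if ep.noisy != noisy:
        ep = replace(ep, noisy=noisy)
    sp = scene_params or SceneParams(kind=scene)
    if sp.kind != scene:
        sp = replace(sp, kind=scene)
    ap = artifact_params or ArtifactParams()

    # Independent child streams per stage, all derived from the root seed.
    ss = np.random.SeedSequence(seed)
    em_ss, scene_ss, art_ss = ss.spawn(3)
    em_rng = np.random.default_rng(em_ss)

    M = sample_endmembers(ep, em_rng)
    scene_rng = np.random.default_rng(scene_ss)
    A = make_scene(sp, ep.n, scene_rng)
    if require_full_coverage and scene == "chessboard":
        for _ in range(_MAX_COVERAGE_REDRAWS):
            if len(np.unique(np.argmax(A.values, axis=1))) == ep.n:
                break
            A = make_scene(sp, ep.n, scene_rng)
        else:  # pragma: no cover - 64 misses at default dims is ~impossible
            raise ParameterError(
                "could not draw a chessboard covering all endmembers"
            )

    d = mix(M, A, model=model)
    if with_artifacts:
        d, flags = add_artifacts(d, ap, np.random.default_rng(art_ss))
    else:
        flags = ArtifactFlags.empty(d.n_spectra)

    record = GenerationRecord(
        endmembers=M,
        abundances=A,
        mixture_model=model,
        artifact_flags=flags,
        seed=seed,
        scenario=scenario,
        scene=scene,
    )
    return d, record


def record_arrays(record: GenerationRecord) -> dict[str, np.ndarray]:
    """Flatten a GenerationRecord into named arrays for the npz container."""
    return {
        "endmembers": record.endmembers.signatures,
        "abundances": record.abundances.values,
        "artifact_baseline": record.artifact_flags.baseline_added,
        "artifact_spike": record.artifact_flags.spike_added,
        "artifact_spike_band": record.artifact_flags.spike_band,
    }
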