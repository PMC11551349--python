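"""Composable spectral preprocessing steps and the two named pipelines.

Steps operate on :class:`~ramanmix.core.SpectralDataset` and preserve the
(N, bands-after-crop) shape contract:

* :func:`crop` -- keep bands whose wavenumber lies in a closed interval.
* :func:`despike` -- cosmic-ray removal by the modified z-score of first
  differences (Whitaker & Hayes scheme): flagged bands are replaced by the
  mean of non-spike neighbors within the kernel window.
* :func:`denoise_savgol` -- Savitzky-Golay local polynomial smoothing.
* :func:`baseline_correct` -- subtract a smooth baseline estimated by
  asymmetric penalized least squares, either plain AsLS (fixed asymmetry
  ``p``) or the adaptive ASPLS variant.
* :func:`normalize` -- global vector normalization (divide by the
  dataset-wide max magnitude) or global min-max to [0, 1].

Two presets mirror common recipes for solution measurements ("sugar":
crop 400-1800 cm^-1, ASPLS lambda=1e5, vector normalization) and cellular
volumetric scans ("cell": crop 700-1800 cm^-1, despike, Savitzky-Golay,
AsLS lambda=1e6 / p=0.01, min-max normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .core import SpectralAxis, SpectralDataset
from .errors import DegenerateRangeError, EmptyRangeError, ParameterError

__all__ = [
    "crop",
    "despike",
    "denoise_savgol",
    "baseline_correct",
    "normalize",
    "PipelineConfig",
    "Pipeline",
    "preset_pipeline",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# Individual steps
# ---------------------------------------------------------------------------


def crop(d: SpectralDataset, lo_cm1: float, hi_cm1: float) -> SpectralDataset:
    """Keep exactly the bands with axis value in the closed [lo, hi] cm^-1."""
    if lo_cm1 >= hi_cm1:
        raise ParameterError(f"crop needs lo < hi, got [{lo_cm1}, {hi_cm1}]")
    mask = (d.axis.values >= lo_cm1) & (d.axis.values <= hi_cm1)
    if not mask.any():
        raise EmptyRangeError(
            f"crop [{lo_cm1}, {hi_cm1}] selects no bands of axis "
            f"[{d.axis.values[0]}, {d.axis.values[-1]}]"
        )
    if mask.sum() < 2:
        raise EmptyRangeError(f"crop [{lo_cm1}, {hi_cm1}] leaves fewer than 2 bands")
    return SpectralDataset(
        d.intensities[:, mask], SpectralAxis(d.axis.values[mask]), d.scene_shape
    )


def _despike_row(y: np.ndarray, kernel: int, z_threshold: float) -> np.ndarray:
    diff = np.diff(y)
    med = np.median(diff)
    mad = np.median(np.abs(diff - med))
    if mad == 0.0:
        mad = np.finfo(float).tiny
    with np.errstate(over="ignore"):  # inf z-score simply flags the band
        z = 0.6745 * (diff - med) / mad
    # A spike at band i shows up in differences i-1 and i; flag both ends.
    hits = np.abs(z) > z_threshold
    spiked = np.zeros(y.size, dtype=bool)
    spiked[1:] |= hits
    spiked[:-1] |= hits
    if not spiked.any():
        return y
    out = y.copy()
    for i in np.flatnonzero(spiked):
        lo = max(i - kernel, 0)
        hi = min(i + kernel + 1, y.size)
        neighbors = y[lo:hi][~spiked[lo:hi]]
        if neighbors.size == 0:  # widen until a clean neighbor is found
            width = kernel
            while neighbors.size == 0 and width < y.size:
                width *= 2
                lo = max(i - width, 0)
                hi = min(i + width + 1, y.size)
                neighbors = y[lo:hi][~spiked[lo:hi]]
        out[i] = neighbors.mean() if neighbors.size else y[i]
    return out


def despike(
    d: SpectralDataset, kernel: int = 3, z_threshold: float = 8.0
) -> SpectralDataset:
    """Remove cosmic spikes via the modified z-score of first differences.

    Bands whose score exceeds ``z_threshold`` are replaced by the mean of
    non-spike neighbors within ``+- kernel`` bands (one-sided at borders).
    Spectra without excursions pass through unchanged.
    """
    if kernel < 1:
        raise ParameterError("kernel must be >= 1")
    out = np.stack([_despike_row(row, kernel, z_threshold) for row in d.intensities])
    return SpectralDataset(out, d.axis, d.scene_shape)


def denoise_savgol(
    d: SpectralDataset, window: int = 7, polyorder: int = 3
) -> SpectralDataset:
    """Savitzky-Golay smoothing of every spectrum."""
    if window % 2 != 1:
        raise ParameterError("window must be odd")
    if polyorder >= window:
        raise ParameterError("polyorder must be < window")
    if window > d.n_bands:
        raise ParameterError(f"window {window} exceeds band count {d.n_bands}")
    out = savgol_filter(d.intensities, window, polyorder, axis=1)
    return SpectralDataset(out, d.axis, d.scene_shape)


def _asls_baseline(
    y: np.ndarray, lam: float, p: float, diff_order: int, max_iter: int, tol: float
) -> np.ndarray:
    """Asymmetric least squares baseline (Eilers & Boelens)."""
    b = y.size
    D = sparse.eye_array(b, format="csc")
    for _ in range(diff_order):
        D = D[1:] - D[:-1]
    DtD = lam * (D.T @ D)
    w = np.ones(b)
    z = y
    for _ in range(max_iter):
        Wmat = sparse.diags_array(w, format="csc")
        z = spsolve((Wmat + DtD).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.abs(w_new - w).sum() / b < tol:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("AsLS did not converge within max_iter; best iterate used")
    return z


def _aspls_baseline(
    y: np.ndarray, lam: float, diff_order: int, max_iter: int, tol: float
) -> np.ndarray:
    """Adaptive smoothness-penalized least squares baseline.

    The penalty is modulated band-wise by ``alpha_i = |d_i| / max|d|`` of
    the current residual, and the weights follow a logistic function of the
    residual scaled by the standard deviation of its negative part.
    """
    b = y.size
    D = sparse.eye_array(b, format="csc")
    for _ in range(diff_order):
        D = D[1:] - D[:-1]
    DtD = (D.T @ D).tocsc()
    w = np.ones(b)
    alpha = np.ones(b)
    z = y
    for _ in range(max_iter):
        Wmat = sparse.diags_array(w, format="csc")
        Amat = sparse.diags_array(alpha, format="csc")
        z = spsolve((Wmat + lam * (Amat @ DtD)).tocsc(), w * y)
        d_res = y - z
        neg = d_res[d_res < 0]
        sigma = neg.std() if neg.size else d_res.std() or 1.0
        if sigma == 0:
            sigma = 1.0
        w_new = 1.0 / (1.0 + np.exp(2.0 * (d_res - sigma) / sigma))
        denom = np.abs(d_res).max() or 1.0
        alpha = np.abs(d_res) / denom
        if np.abs(w_new - w).sum() / b < tol:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("ASPLS did not converge within max_iter; best iterate used")
    return z


def baseline_correct(
    d: SpectralDataset,
    method: str = "asls",
    lam: float = 1e6,
    p: Optional[float] = 0.01,
    diff_order: int = 2,
    max_iter: int = 50,
    tol: float = 0.001,
) -> SpectralDataset:
    """Subtract a smooth penalized-least-squares baseline from each spectrum."""
    if lam <= 0:
        raise ParameterError("lam must be > 0")
    if method == "asls":
        if p is None or not (0.0 < p < 1.0):
            raise ParameterError("asls requires 0 < p < 1")
        corrected = np.stack(
            [
                row - _asls_baseline(row, lam, p, diff_order, max_iter, tol)
                for row in d.intensities
            ]
        )
    elif method == "aspls":
        corrected = np.stack(
            [
                row - _aspls_baseline(row, lam, diff_order, max_iter, tol)
                for row in d.intensities
            ]
        )
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    return SpectralDataset(corrected, d.axis, d.scene_shape)


def normalize(d: SpectralDataset, mode: str = "global_vector") -> SpectralDataset:
    """Dataset-wide intensity normalization.

    ``global_vector`` divides every value by the single highest magnitude
    in the dataset; ``global_minmax`` maps the dataset-wide [min, max]
    affinely onto [0, 1].
    """
    X = d.intensities
    if mode == "global_vector":
        peak = np.abs(X).max()
        if peak == 0:
            raise DegenerateRangeError("all-zero dataset cannot be normalized")
        out = X / peak
    elif mode == "global_minmax":
        lo, hi = X.min(), X.max()
        if hi == lo:
            raise DegenerateRangeError("constant dataset has no min-max range")
        out = (X - lo) / (hi - lo)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return SpectralDataset(out, d.axis, d.scene_shape)


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

_STEP_FUNCS: dict[str, Callable[..., SpectralDataset]] = {
    "crop": crop,
    "despike": despike,
    "denoise_savgol": denoise_savgol,
    "baseline_correct": baseline_correct,
    "normalize": normalize,
}


@dataclass
class PipelineConfig:
    """Ordered list of (step name, parameter dict) pairs."""

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    name: Optional[str] = None

    def validate(self) -> None:
        for step, _ in self.steps:
            if step not in _STEP_FUNCS:
                raise ParameterError(f"unknown preprocessing step {step!r}")


class Pipeline:
    """Execute a :class:`PipelineConfig` and keep a per-step run log."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.log: list[str] = []

    def __call__(self, d: SpectralDataset) -> SpectralDataset:
        self.log = []
        for step, params in self.config.steps:
            d = _STEP_FUNCS[step](d, **params)
            kv = ", ".join(f"{k}={v}" for k, v in params.items())
            self.log.append(f"{step}({kv}) -> {d.n_spectra}x{d.n_bands}")
        return d


PRESETS: dict[str, PipelineConfig] = {
    "sugar": PipelineConfig(
        name="sugar",
        steps=[
            ("crop", {"lo_cm1": 400.0, "hi_cm1": 1800.0}),
            (
                "baseline_correct",
                {
                    "method": "aspls",
                    "lam": 1e5,
                    "p": None,
                    "diff_order": 2,
                    "max_iter": 100,
                    "tol": 0.001,
                },
            ),
            ("normalize", {"mode": "global_vector"}),
        ],
    ),
    "cell": PipelineConfig(
        name="cell",
        steps=[
            ("crop", {"lo_cm1": 700.0, "hi_cm1": 1800.0}),
            ("despike", {"kernel": 3, "z_threshold": 8.0}),
            ("denoise_savgol", {"window": 7, "polyorder": 3}),
            (
                "baseline_correct",
                {
                    "method": "asls",
                    "lam": 1e6,
                    "p": 0.01,
                    "diff_order": 2,
                    "max_iter": 50,
                    "tol": 0.001,
                },
            ),
            ("normalize", {"mode": "global_minmax"}),
        ],
    ),
}


def preset_pipeline(name: str) -> Pipeline:
    """Build one of the named pipelines ("sugar" or "cell")."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; expected {tuple(PRESETS)}")
    return Pipeline(PRESETS[name])
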