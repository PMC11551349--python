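"""Ground-truth evaluation: endmember matching, metrics, benchmark grid,
and runtime profiling.

Estimated endmembers are matched to ground truth with the Hungarian
algorithm using the spectral angle distance (SAD) as the assignment cost;
when more endmembers are extracted than exist (``n > n_true``) the surplus
estimates are left unmatched and excluded from the metrics.  Abundance
accuracy is the per-spectrum ``(1/n) * ||a - a_hat||^2`` after applying the
same permutation to the abundance columns, averaged over spectra.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import baselines, models, synthgen
from .core import AbundanceMap, EndmemberSet, SpectralDataset
from .errors import DimensionError, InsufficientDataError
from .models import sad

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "match_endmembers",
    "abundance_mse",
    "score_unmixing",
    "BenchmarkGrid",
    "run_benchmark",
    "profile_runtime",
    "UnmixingResult",
    "run_method",
    "METHODS",
]


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Assignment of estimated endmembers to ground-truth endmembers.

    ``permutation[j]`` is the estimated index matched to true endmember
    ``j``; the mapping is injective with exactly ``n_true`` pairs.
    """

    permutation: np.ndarray  # length n_true, values into estimated set
    pair_sad: np.ndarray  # per-true-endmember SAD (radians)
    unmatched: np.ndarray  # estimated indices left unmatched

    @property
    def total_sad(self) -> float:
        return float(self.pair_sad.sum())

    @property
    def mean_sad(self) -> float:
        return float(self.pair_sad.mean())


def match_endmembers(est: EndmemberSet, truth: EndmemberSet) -> MatchResult:
    """Hungarian matching of estimates to truth minimizing total SAD."""
    n_est, n_true = est.n_endmembers, truth.n_endmembers
    if n_est < n_true:
        raise InsufficientDataError(
            f"{n_est} estimated endmembers cannot cover {n_true} true ones"
        )
    if est.n_bands != truth.n_bands:
        raise DimensionError(
            f"band mismatch: estimated {est.n_bands}, true {truth.n_bands}"
        )
    cost = np.empty((n_true, n_est))
    for j in range(n_true):
        for i in range(n_est):
            cost[j, i] = sad(truth.signatures[j], est.signatures[i])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(n_true, dtype=int)
    perm[rows] = cols
    unmatched = np.setdiff1d(np.arange(n_est), perm)
    return MatchResult(perm, cost[np.arange(n_true), perm], unmatched)


def abundance_mse(a_true: np.ndarray, a_est: np.ndarray) -> float:
    """``(1/n) * ||a - a_hat||^2`` per spectrum, averaged over spectra.

    Inputs must already be in matched column order with only the ``n_true``
    columns retained.
    """
    a_true = np.atleast_2d(np.asarray(a_true, dtype=float))
    a_est = np.atleast_2d(np.asarray(a_est, dtype=float))
    if a_true.shape != a_est.shape:
        raise DimensionError(f"shape mismatch: {a_true.shape} vs {a_est.shape}")
    n = a_true.shape[1]
    per_spectrum = ((a_true - a_est) ** 2).sum(axis=1) / n
    return float(per_spectrum.mean())


def score_unmixing(
    est_endmembers: EndmemberSet,
    est_abundances: Optional[AbundanceMap],
    record: synthgen.GenerationRecord,
) -> dict[str, float]:
    """Matched mean SAD and abundance MSE of one unmixing run vs. truth."""
    match = match_endmembers(est_endmembers, record.endmembers)
    out = {"sad": match.mean_sad}
    if est_abundances is not None:
        permuted = est_abundances.values[:, match.permutation]
        out["mse"] = abundance_mse(record.abundances.values, permuted)
    return out


# ---------------------------------------------------------------------------
# Unmixing method registry (shared by benchmark, profiling, CLI)
# ---------------------------------------------------------------------------


@dataclass
class UnmixingResult:
    """Common output of autoencoder and classical unmixing backends."""

    endmembers: EndmemberSet
    abundances: AbundanceMap
    method: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    loss_trace: Optional[list[float]] = None


_AE_KINDS = {
    "dense": "dense",
    "deep_dense": "deep_dense",
    "conv": "conv",
    "transformer": "transformer",
    "conv_transformer": "conv_transformer",
}

METHODS = (
    "nfindr_fcls",
    "vca_fcls",
    "dense",
    "conv",
    "transformer",
    "conv_transformer",
)


def run_method(
    method: str,
    d: SpectralDataset,
    n: int,
    seed: Optional[int] = None,
    decoder: str = "linear",
    epochs: int = 10,
    batch_size: int = 64,
    asc: bool = True,
    learning_rate: float = 0.001,
    loss: str = "sad",
    lambda_mse: float = 1000.0,
    abundance: str = "fcls",
) -> UnmixingResult:
    """Run one unmixing method end to end on a dataset.

    ``method`` is an encoder kind (autoencoder route), or
    ``"vca"``/``"nfindr"`` optionally suffixed ``"_nnls"``/``"_fcls"`` for
    the classical route.
    """
    base = method
    if method.endswith(("_nnls", "_fcls")):
        base, abundance = method.rsplit("_", 1)
    if base in ("vca", "nfindr"):
        extractor = baselines.vca if base == "vca" else baselines.nfindr
        M = extractor(d, n, seed=seed)
        if abundance == "nnls":
            A = baselines.nnls_abundance(M, d)
        else:
            A = baselines.fcls_abundance(M, d)
        return UnmixingResult(
            M, A, method=f"{base}_{abundance}", seed=seed,
            config={"n": n, "abundance": abundance},
        )
    if base not in _AE_KINDS:
        raise ValueError(f"unknown unmixing method {method!r}")
    model = models.UnmixingAutoencoder(
        n_bands=d.n_bands,
        n_endmembers=n,
        encoder=_AE_KINDS[base],
        decoder=decoder,
        asc=asc,
        seed=seed,
    )
    config = models.TrainingConfig(
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        loss=loss,
        lambda_mse=lambda_mse,
        seed=seed,
    )
    trace = models.fit(model, d, config)
    return UnmixingResult(
        models.extract_endmembers(model),
        models.infer_abundances(model, d),
        method=base,
        seed=seed,
        config={
            "n": n, "decoder": decoder, "epochs": epochs,
            "batch_size": batch_size, "asc": asc, "loss": loss,
        },
        loss_trace=trace,
    )


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkGrid:
    """The (methods x dataset variants x replicates) evaluation grid.

    Replicates are the Cartesian product of dataset seeds and model seeds,
    and the same seed table is reused across mixture scenarios so cells are
    directly comparable.  The latent dimension is ``n_true`` for the ideal
    scenario and ``n_true + 1`` otherwise (the extra endmember absorbs
    artifacts; surplus estimates are discarded during matching).
    """

    methods: tuple[str, ...] = METHODS
    variants: tuple[tuple[str, str], ...] = tuple(synthgen.dataset_variants())
    dataset_seeds: tuple[int, ...] = (0, 1)
    model_seeds: tuple[int, ...] = (0, 1)
    H: int = 50
    W: int = 50
    b: int = 1000
    n_true: int = 5
    epochs: int = 10
    batch_size: int = 64

    @classmethod
    def reduced(cls, **overrides) -> "BenchmarkGrid":
        """Desk-scale defaults: 50x50 scenes, 2 x 2 replicates."""
        return cls(**overrides)

    @classmethod
    def full(cls, **overrides) -> "BenchmarkGrid":
        """Full-scale grid: 100x100 scenes, 5 x 5 replicates."""
        defaults = dict(
            dataset_seeds=tuple(range(5)),
            model_seeds=tuple(range(5)),
            H=100,
            W=100,
        )
        defaults.update(overrides)
        return cls(**defaults)


_patch_edge = synthgen.default_patch_edge


def _generate_cell_dataset(
    grid: BenchmarkGrid, scenario: str, scene: str, dataset_seed: int
) -> tuple[SpectralDataset, synthgen.GenerationRecord]:
    ep = synthgen.EndmemberSamplerParams(b=grid.b, n=grid.n_true)
    sp = synthgen.SceneParams(kind=scene, H=grid.H, W=grid.W,
                              patch=_patch_edge(grid.H, grid.W))
    return synthgen.generate_dataset(
        scenario=scenario,
        scene=scene,
        seed=dataset_seed,
        endmember_params=ep,
        scene_params=sp,
        require_full_coverage=(scene == "chessboard"),
    )


def run_benchmark(
    grid: Optional[BenchmarkGrid] = None,
    scale: str = "reduced",
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Evaluate every (method, variant, dataset seed, model seed) cell.

    Returns one row per cell with matched mean SAD and abundance MSE; a
    method failure is recorded in the ``error`` column and the grid
    continues.  Deterministic given the grid's seed tables.
    """
    if grid is None:
        grid = BenchmarkGrid.reduced() if scale == "reduced" else BenchmarkGrid.full()
    rows = []
    for scenario, scene in grid.variants:
        decoder = "fan_bilinear" if scenario == "bilinear" else "linear"
        m = grid.n_true if scenario == "ideal" else grid.n_true + 1
        for ds_seed in grid.dataset_seeds:
            d, record = _generate_cell_dataset(grid, scenario, scene, ds_seed)
            for method in grid.methods:
                for model_seed in grid.model_seeds:
                    if progress:
                        progress(
                            f"{scenario}/{scene} ds={ds_seed} "
                            f"{method} seed={model_seed}"
                        )
                    row = {
                        "method": method,
                        "scenario": scenario,
                        "scene": scene,
                        "dataset_seed": ds_seed,
                        "model_seed": model_seed,
                        "n_extracted": m,
                        "sad": np.nan,
                        "mse": np.nan,
                        "error": "",
                    }
                    try:
                        result = run_method(
                            method,
                            d,
                            n=m,
                            seed=model_seed,
                            decoder=decoder,
                            epochs=grid.epochs,
                            batch_size=grid.batch_size,
                        )
                        scores = score_unmixing(
                            result.endmembers, result.abundances, record
                        )
                        row.update(scores)
                    except Exception as exc:  # cell failure must not stop the grid
                        logger.warning("cell failed: %s (%s)", row, exc)
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["aggregation"] = "sad = mean over matched endmembers; mse = mean over spectra"
    return df


# ---------------------------------------------------------------------------
# Runtime profiling
# ---------------------------------------------------------------------------


def profile_runtime(
    sizes: Sequence[int],
    methods: Sequence[str] = METHODS,
    repetitions: int = 3,
    n: int = 5,
    b: int = 1000,
    epochs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Wall-time of each method on ideal Chessboard datasets of growing N.

    Dataset generation is excluded from the timing; autoencoder timings
    include the full training time.  ``sizes`` must be ascending and are
    realized as square-ish scenes with ``H*W = N``.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    rows = []
    for N in sizes:
        H = int(np.sqrt(N))
        while N % H != 0:
            H -= 1
        W = N // H
        patch = _patch_edge(H, W)
        ep = synthgen.EndmemberSamplerParams(b=b, n=n)
        sp = synthgen.SceneParams(kind="chessboard", H=H, W=W, patch=patch)
        d, _ = synthgen.generate_dataset(
            "ideal", "chessboard", seed=seed, endmember_params=ep, scene_params=sp,
            require_full_coverage=True,
        )
        for method in methods:
            timings = []
            for rep in range(repetitions):
                t0 = time.perf_counter()
                run_method(method, d, n=n, seed=seed + rep, epochs=epochs)
                timings.append(time.perf_counter() - t0)
            rows.append(
                {
                    "method": method,
                    "n_spectra": N,
                    "mean_seconds": float(np.mean(timings)),
                    "std_seconds": float(np.std(timings)),
                    "timings": timings,
                }
            )
    return pd.DataFrame(rows)
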