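"""Classical unmixing comparators implemented from their definitions.

Endmember extraction (both assume endmembers appear as *pure pixels*):

* **VCA** (vertex component analysis) iteratively projects the data onto a
  direction orthogonal to the subspace spanned by the endmembers found so
  far and takes the extreme point as the next endmember.  The standard
  SNR-dependent preprocessing is used: a projective projection onto an
  ``n``-dimensional SVD subspace for high-SNR data, or an affine
  (mean-removed) projection onto ``n-1`` principal components with a
  constant coordinate appended for low-SNR data.
* **N-FINDR** searches for the set of ``n`` pixels maximizing the volume of
  the simplex they span, by replacement sweeps in an ``(n-1)``-dimensional
  principal-component space.  The volume is monotone non-decreasing across
  accepted swaps.

Abundance estimation per spectrum ``x`` against endmember matrix ``M``
(rows are endmembers):

* **NNLS** solves ``min_{a >= 0} ||M^T a - x||_2`` (ANC only).
* **FCLS** additionally enforces sum-to-one (ASC) via the standard
  augmented-row construction: a constant row of weight ``delta`` is
  appended so the sum constraint is satisfied to ~1/delta, then the
  solution is renormalized exactly.

Both extractors return actual data rows and are deterministic given a seed;
selection ties break toward the lowest pixel index (numpy argmax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .core import AbundanceMap, EndmemberSet, SpectralDataset
from .errors import InsufficientDataError, ParameterError

__all__ = ["BaselineConfig", "vca", "nfindr", "nnls_abundance", "fcls_abundance"]


@dataclass(frozen=True)
class BaselineConfig:
    """Knobs for the classical methods."""

    n: int = 5
    seed: Optional[int] = None
    nfindr_max_sweeps: int = 10
    fcls_delta: float = 1e5

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError("need n >= 1 endmembers")
        if self.fcls_delta <= 0:
            raise ParameterError("fcls_delta must be > 0")


def _check_n(d: SpectralDataset, n: int) -> None:
    if n < 1:
        raise ParameterError("need n >= 1 endmembers")
    if d.n_spectra < n:
        raise InsufficientDataError(
            f"cannot extract {n} endmembers from {d.n_spectra} spectra"
        )


# ---------------------------------------------------------------------------
# VCA
# ---------------------------------------------------------------------------


def _estimate_snr(X: np.ndarray, mean: np.ndarray, Xp: np.ndarray) -> float:
    """SNR estimate (dB) from the energy captured by the n-dim subspace."""
    N, b = X.shape
    n = Xp.shape[1]
    p_x = (X**2).sum() / N
    p_p = (Xp**2).sum() / N + mean @ mean
    noise = p_x - p_p
    if noise <= 0:
        return np.inf
    return float(10.0 * np.log10((p_p - (n / b) * p_x) / noise))


def vca(d: SpectralDataset, n: int, seed: Optional[int] = None) -> EndmemberSet:
    """Vertex component analysis; returns ``n`` data rows as endmembers."""
    _check_n(d, n)
    X = d.intensities  # N x b
    N, b = X.shape
    rng = np.random.default_rng(seed)

    if n == 1:
        # Degenerate simplex: the extreme point is the largest-magnitude
        # spectrum (norm is convex, so the maximum sits at a hull vertex).
        idx = int(np.argmax(np.linalg.norm(X, axis=1)))
        return EndmemberSet(X[idx][None].copy(), labels=[f"vca_{idx}"])

    mean = X.mean(axis=0)
    Xc = X - mean
    # Principal directions of the (mean-removed) data.
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Ud = Vt[:n].T  # b x n
    Xp = Xc @ Ud  # N x n, affine projection coords

    snr = _estimate_snr(X, mean, Xp)
    snr_threshold = 15.0 + 10.0 * np.log10(n)

    if snr >= snr_threshold:
        # High SNR: projective projection onto an n-dim subspace of the raw
        # data, then scale each point onto the hyperplane <y, u> = 1.
        _, _, Vt_raw = np.linalg.svd(X, full_matrices=False)
        U = Vt_raw[:n].T  # b x n
        x_sub = X @ U  # N x n
        u = x_sub.mean(axis=0)
        denom = x_sub @ u
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        Y = x_sub / denom[:, None]  # N x n
    else:
        # Low SNR: affine projection onto n-1 components + constant coord.
        if n > 1:
            x_aff = Xp[:, : n - 1]
            c = np.sqrt((x_aff**2).sum(axis=1)).max()
            Y = np.hstack([x_aff, np.full((N, 1), c)])
        else:
            Y = np.ones((N, 1))

    # Iterative orthogonal-projection search over Y (N x n).
    A = np.zeros((n, n))
    A[-1, 0] = 1.0
    indices = np.zeros(n, dtype=int)
    for i in range(n):
        w = rng.standard_normal(n)
        f = w - A @ (np.linalg.pinv(A) @ w)
        norm = np.linalg.norm(f)
        if norm < 1e-12:  # pragma: no cover - degenerate random draw
            f = w
            norm = np.linalg.norm(f) or 1.0
        f /= norm
        v = Y @ f
        idx = int(np.argmax(np.abs(v)))  # ties -> lowest index
        indices[i] = idx
        A[:, i] = Y[idx]

    return EndmemberSet(X[indices].copy(), labels=[f"vca_{i}" for i in indices])


# ---------------------------------------------------------------------------
# N-FINDR
# ---------------------------------------------------------------------------


def _reduce(X: np.ndarray, n: int) -> np.ndarray:
    """Project mean-removed data onto the first n-1 principal components."""
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = max(n - 1, 1)
    return Xc @ Vt[:k].T  # N x (n-1)


def _volumes(Z: np.ndarray, vertices: np.ndarray, slot: int, Zall: np.ndarray):
    """|det| of the augmented vertex matrix with ``slot`` replaced by every
    candidate pixel; vectorized over candidates."""
    n = vertices.size
    base = np.ones((n, n))
    base[1:, :] = Z[vertices].T  # (n-1+1) x n augmented simplex matrix
    N = Zall.shape[0]
    mats = np.broadcast_to(base, (N, n, n)).copy()
    mats[:, 1:, slot] = Zall
    return np.abs(np.linalg.det(mats))


def nfindr(d: SpectralDataset, n: int, seed: Optional[int] = None,
           max_sweeps: int = 10) -> EndmemberSet:
    """N-FINDR simplex-volume maximization; returns ``n`` data rows."""
    _check_n(d, n)
    X = d.intensities
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    Z = _reduce(X, n)  # N x (n-1)

    vertices = rng.choice(N, size=n, replace=False)
    current = _volumes(Z, vertices, 0, Z[vertices[0]][None])[0]
    for _ in range(max_sweeps):
        improved = False
        for slot in range(n):
            vols = _volumes(Z, vertices, slot, Z)
            best = int(np.argmax(vols))  # ties -> lowest pixel index
            if vols[best] > current * (1.0 + 1e-12) and best not in vertices:
                vertices[slot] = best
                current = vols[best]
                improved = True
        if not improved:
            break
    order = np.sort(vertices)
    return EndmemberSet(X[order].copy(), labels=[f"nfindr_{i}" for i in order])


# ---------------------------------------------------------------------------
# NNLS / FCLS
# ---------------------------------------------------------------------------


def nnls_abundance(M: EndmemberSet, d: SpectralDataset) -> AbundanceMap:
    """Per-spectrum nonnegative least squares against ``M`` (ANC only)."""
    A_mat = M.signatures.T  # b x n design matrix
    if A_mat.shape[0] != d.n_bands:
        raise ParameterError(
            f"endmembers span {A_mat.shape[0]} bands but data has {d.n_bands}"
        )
    out = np.empty((d.n_spectra, M.n_endmembers))
    for i, x in enumerate(d.intensities):
        out[i], _ = _scipy_nnls(A_mat, x)
    return AbundanceMap(out, anc=True, asc=False, scene_shape=d.scene_shape)


def fcls_abundance(
    M: EndmemberSet, d: SpectralDataset, delta: float = 1e5
) -> AbundanceMap:
    """Fully constrained least squares (ANC + ASC) via the augmented row.

    A constant row weighted ``delta`` pushes the solution onto the simplex
    (sum-to-one holds to ~1/delta); the result is renormalized so rows sum
    to one exactly.
    """
    if delta <= 0:
        raise ParameterError("delta must be > 0")
    A_mat = M.signatures.T
    if A_mat.shape[0] != d.n_bands:
        raise ParameterError(
            f"endmembers span {A_mat.shape[0]} bands but data has {d.n_bands}"
        )
    scale = np.abs(A_mat).max() or 1.0
    A_aug = np.vstack([A_mat / scale, np.full((1, M.n_endmembers), delta)])
    out = np.empty((d.n_spectra, M.n_endmembers))
    for i, x in enumerate(d.intensities):
        b_aug = np.append(x / scale, delta)
        sol, _ = _scipy_nnls(A_aug, b_aug)
        total = sol.sum()
        out[i] = sol / total if total > 0 else np.full_like(sol, 1.0 / sol.size)
    return AbundanceMap(out, anc=True, asc=True, scene_shape=d.scene_shape)
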