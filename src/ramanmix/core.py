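"""Domain types, validation, scene reshaping, and dataset serialization.

Conventions used throughout the package:

* Spectra are stored row-wise: an ``N x b`` matrix of ``N`` spectra binned
  over ``b`` wavenumber bands.  Endmembers are likewise rows of an ``n x b``
  matrix; the classical ``b x n`` column convention of the linear mixing
  model is honored only at the decoder-weight boundary (a transpose).
* Pixel order for scenes is row-major with the origin at the top-left;
  for volumetric data the z-layer is outermost, i.e. spectrum ``i`` maps to
  ``(z, h, w)`` with ``z`` varying slowest.
* Band indexing is 1-based in formulas (bands ``1..b``) and 0-based in
  storage; operations that depend on it say which they use.
* Intensities are NOT forced nonnegative: additive dark noise and baseline
  subtraction legitimately push individual bands below zero.  Nonnegativity
  invariants apply to endmembers and abundances only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DimensionError, FormatError

__all__ = [
    "SpectralAxis",
    "SpectralDataset",
    "EndmemberSet",
    "AbundanceMap",
    "validate_dataset",
    "reshape_scene",
    "flatten_scene",
    "save_dataset",
    "load_dataset",
]

ASC_TOL = 1e-6


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavenumber positions (cm^-1) of the spectral bands.

    Values must be strictly increasing with at least two bands.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(-1)
        )

    def __len__(self) -> int:
        return self.values.size

    def violations(self) -> list[str]:
        out = []
        if len(self) < 2:
            out.append(f"axis: length {len(self)} < 2")
        if not np.all(np.isfinite(self.values)):
            idx = int(np.flatnonzero(~np.isfinite(self.values))[0])
            out.append(f"axis: non-finite value at band {idx}")
        elif np.any(np.diff(self.values) <= 0):
            idx = int(np.flatnonzero(np.diff(self.values) <= 0)[0])
            out.append(
                f"axis: not strictly increasing at band {idx} "
                f"({self.values[idx]} -> {self.values[idx + 1]})"
            )
        return out


@dataclass
class SpectralDataset:
    """A stack of ``N`` spectra over ``b`` bands, optionally on a scene grid.

    ``scene_shape`` is pure metadata: ``(H, W)`` or ``(H, W, Z)`` with
    ``H*W*(Z) == N``.  Intensities may be negative (noise, baseline
    subtraction); they must be finite.
    """

    intensities: np.ndarray
    axis: SpectralAxis
    scene_shape: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.scene_shape is not None:
            self.scene_shape = tuple(int(s) for s in self.scene_shape)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[1]

    def as_scene(self) -> np.ndarray:
        """Return intensities as an (H, W[, Z], b) hypercube view."""
        if self.scene_shape is None:
            raise DimensionError("dataset has no scene_shape")
        if len(self.scene_shape) == 3:
            h, w, z = self.scene_shape
            return self.intensities.reshape(z, h, w, self.n_bands).transpose(1, 2, 0, 3)
        return self.intensities.reshape(*self.scene_shape, self.n_bands)


@dataclass
class EndmemberSet:
    """Nonnegative spectral signatures of the pure components, one per row."""

    signatures: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.signatures = np.atleast_2d(np.asarray(self.signatures, dtype=float))

    @property
    def n_endmembers(self) -> int:
        return self.signatures.shape[0]

    @property
    def n_bands(self) -> int:
        return self.signatures.shape[1]

    def violations(self) -> list[str]:
        out = []
        if np.any(self.signatures < 0):
            i, j = np.argwhere(self.signatures < 0)[0]
            out.append(f"endmembers: negative entry at ({i}, {j})")
        zero = ~self.signatures.any(axis=1)
        if zero.any():
            out.append(f"endmembers: all-zero row {int(np.flatnonzero(zero)[0])}")
        return out


@dataclass
class AbundanceMap:
    """Fractional abundances, one row of length ``n`` per spectrum.

    ``anc`` marks the nonnegativity constraint (all entries >= 0); ``asc``
    marks the sum-to-one constraint (rows sum to 1 within 1e-6).
    """

    values: np.ndarray
    anc: bool = True
    asc: bool = True
    scene_shape: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.scene_shape is not None:
            self.scene_shape = tuple(int(s) for s in self.scene_shape)

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_endmembers(self) -> int:
        return self.values.shape[1]

    def violations(self) -> list[str]:
        out = []
        if self.anc and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            out.append(f"abundances: ANC violated at ({i}, {j})")
        if self.asc:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > ASC_TOL
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                out.append(f"abundances: ASC violated at row {i} (sum {sums[i]:.8f})")
        return out


def validate_dataset(d: SpectralDataset) -> list[str]:
    """Collect invariant violations; empty list iff the dataset is well formed.

    Never raises on finite input: every problem is reported as a human-readable
    string naming the invariant and the offending index.
    """
    out: list[str] = []
    try:
        out.extend(d.axis.violations())
        if d.intensities.ndim != 2:
            out.append(f"intensities: expected 2-d matrix, got ndim={d.intensities.ndim}")
            return out
        if d.n_bands != len(d.axis):
            out.append(
                f"shape: {d.n_bands} intensity columns != {len(d.axis)} axis bands"
            )
        if not np.all(np.isfinite(d.intensities)):
            i, j = np.argwhere(~np.isfinite(d.intensities))[0]
            out.append(f"intensities: non-finite value at ({i}, {j})")
        if d.scene_shape is not None:
            if len(d.scene_shape) not in (2, 3) or any(s < 1 for s in d.scene_shape):
                out.append(f"scene_shape: invalid shape {d.scene_shape}")
            elif int(np.prod(d.scene_shape)) != d.n_spectra:
                out.append(
                    f"scene_shape: product of {d.scene_shape} != N={d.n_spectra}"
                )
    except Exception as exc:  # pragma: no cover - validation must be total
        out.append(f"validation: unexpected failure ({exc})")
    return out


def reshape_scene(
    d: SpectralDataset, shape: Optional[tuple[int, ...]]
) -> SpectralDataset:
    """Attach (or, with ``shape=None``, remove) scene geometry metadata.

    Intensities are never touched; only the ``scene_shape`` field changes.
    """
    if shape is not None:
        shape = tuple(int(s) for s in shape)
        if len(shape) not in (2, 3):
            raise DimensionError(f"scene shape must be 2-d or 3-d, got {shape}")
        if int(np.prod(shape)) != d.n_spectra:
            raise DimensionError(
                f"scene shape {shape} has product {int(np.prod(shape))} "
                f"but dataset holds N={d.n_spectra} spectra"
            )
    return SpectralDataset(d.intensities, d.axis, scene_shape=shape)


def flatten_scene(d: SpectralDataset) -> SpectralDataset:
    """Drop scene geometry; inverse of :func:`reshape_scene`."""
    return reshape_scene(d, None)


# ---------------------------------------------------------------------------
# Serialization.
#
# Two formats:
#   * "npz"  -- numpy archive with named arrays ("intensities", "axis",
#     optional "scene_shape", plus any ground-truth arrays the caller adds);
#     lossless round-trip.
#   * "csv"  -- delimited text, first row = wavenumber axis, one spectrum per
#     subsequent row; scene shape in a flat key-value ".meta" sidecar;
#     round-trips to >= 12 significant digits (written at %.17g).
# ---------------------------------------------------------------------------


def save_dataset(
    d: SpectralDataset,
    path: str | Path,
    format: str = "npz",
    extra: Optional[dict[str, np.ndarray]] = None,
) -> Path:
    """Write a dataset to disk; ``extra`` named arrays ride along (npz only)."""
    path = Path(path)
    if format == "npz":
        payload: dict[str, np.ndarray] = {
            "intensities": d.intensities,
            "axis": d.axis.values,
        }
        if d.scene_shape is not None:
            payload["scene_shape"] = np.asarray(d.scene_shape, dtype=np.int64)
        if extra:
            payload.update(extra)
        with open(path, "wb") as fh:
            np.savez(fh, **payload)
    elif format == "csv":
        table = np.vstack([d.axis.values, d.intensities])
        np.savetxt(path, table, delimiter=",", fmt="%.17g")
        if d.scene_shape is not None:
            meta = path.with_suffix(path.suffix + ".meta")
            meta.write_text(
                "scene_shape=" + ",".join(str(s) for s in d.scene_shape) + "\n"
            )
    else:
        raise FormatError(f"unknown format {format!r}; expected 'npz' or 'csv'")
    return path


def _load_npz(path: Path) -> tuple[SpectralDataset, dict[str, np.ndarray]]:
    try:
        with np.load(path, allow_pickle=False) as arch:
            if "intensities" not in arch or "axis" not in arch:
                raise FormatError(
                    f"{path}: missing required arrays 'intensities'/'axis'"
                )
            intens = arch["intensities"]
            axis = arch["axis"]
            shape = (
                tuple(int(s) for s in arch["scene_shape"])
                if "scene_shape" in arch
                else None
            )
            extra = {
                k: arch[k]
                for k in arch.files
                if k not in ("intensities", "axis", "scene_shape")
            }
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable array container ({exc})") from exc
    if intens.ndim != 2 or intens.shape[1] != axis.size:
        raise FormatError(
            f"{path}: intensity columns ({intens.shape}) do not match axis "
            f"length {axis.size}"
        )
    return SpectralDataset(intens, SpectralAxis(axis), scene_shape=shape), extra


def _load_csv(path: Path) -> SpectralDataset:
    try:
        table = np.loadtxt(path, delimiter=",", ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable delimited text ({exc})") from exc
    if table.shape[0] < 2:
        raise FormatError(f"{path}: need an axis row plus >=1 spectrum row")
    shape = None
    meta = path.with_suffix(path.suffix + ".meta")
    if meta.exists():
        for ln, line in enumerate(meta.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            if key.strip() == "scene_shape":
                try:
                    shape = tuple(int(s) for s in val.split(","))
                except ValueError as exc:
                    raise FormatError(f"{meta}: bad scene_shape at line {ln}") from exc
    return SpectralDataset(table[1:], SpectralAxis(table[0]), scene_shape=shape)


def load_dataset(
    path: str | Path, with_extra: bool = False
) -> SpectralDataset | tuple[SpectralDataset, dict[str, np.ndarray]]:
    """Read a dataset written by :func:`save_dataset` (format auto-detected)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix == ".npz" or path.read_bytes()[:2] == b"PK":
        d, extra = _load_npz(path)
    else:
        d, extra = _load_csv(path), {}
    violations = validate_dataset(d)
    if violations:
        raise FormatError(f"{path}: invalid dataset: " + "; ".join(violations))
    return (d, extra) if with_extra else d
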