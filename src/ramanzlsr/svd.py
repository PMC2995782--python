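"""SVD component analysis of hyperspectral stacks.

The cube is flattened to a spectra matrix A with W rows (spectral channels)
and P = X*Y columns (pixels; raster order row-major over (y, x) with x
fastest), so a 77 x 96 x 1340 acquisition becomes a 1,340 x 7,392 matrix.
A = U S V^T separates the data into eigenspectra (columns of U) paired with
eigenimages (columns of V); reconstructing from a subset of components
denoises the stack and isolates constituent spectra.

Component selection is automated by ranking components with an RMS-magnitude
score.  Applied literally to the unit-norm eigenspectra the score is
constant (1/sqrt(W)) and ranks nothing, so the default mode scores the
pixel-averaged rank-1 reconstruction spectrum ``sigma_k * u_k * mean(v_k)``
instead: noise components average toward zero over the field while spatially
coherent signal survives.  The literal mode is retained for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .hyperstack import HyperStack


@dataclass
class SpectraMatrix:
    """W x P matrix view of a stack (channels down rows, pixels across columns)."""

    data: np.ndarray
    x_extent: int
    y_extent: int
    wavenumbers: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("spectra matrix must be 2-D")
        if self.data.shape[1] != self.x_extent * self.y_extent:
            raise ValueError(
                f"matrix has {self.data.shape[1]} columns, expected "
                f"{self.x_extent} * {self.y_extent} = {self.x_extent * self.y_extent}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]


def build_matrix(stack: HyperStack) -> SpectraMatrix:
    """Flatten a stack to its W x (X*Y) spectra matrix.

    Column j holds the spectrum of pixel (x, y) with j = y * X + x
    (x fastest); :func:`unflatten` inverts this losslessly.
    """
    X, Y, W = stack.shape
    # (x, y, w) -> (w, y, x) -> reshape so column index j = y * X + x
    data = np.transpose(stack.data, (2, 1, 0)).reshape(W, Y * X)
    return SpectraMatrix(data=data, x_extent=X, y_extent=Y, wavenumbers=stack.wavenumbers)


def unflatten(
    matrix: np.ndarray,
    x_extent: int,
    y_extent: int,
    wavenumbers: Optional[np.ndarray] = None,
    meta: Optional[dict] = None,
) -> HyperStack:
    """Inverse of :func:`build_matrix`: W x P array back to an (x, y, w) stack."""
    matrix = np.asarray(matrix, dtype=float)
    W = matrix.shape[0]
    data = np.transpose(matrix.reshape(W, y_extent, x_extent), (2, 1, 0))
    if wavenumbers is None:
        wavenumbers = np.arange(W, dtype=float)
    return HyperStack(data=np.ascontiguousarray(data), wavenumbers=wavenumbers,
                      meta=meta or {})


@dataclass
class EigenDecomposition:
    """Thin SVD of a spectra matrix.

    ``U`` (W x K) holds the eigenspectra, ``V`` (P x K) the eigenimages,
    ``singular_values`` (K,) is non-increasing, K = min(W, P).  Each
    component's sign is fixed so the largest-magnitude entry of its
    eigenspectrum is positive, making signal eigenspectra reproducibly
    positive-going across linear-algebra backends.
    """

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    x_extent: int
    y_extent: int
    wavenumbers: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def decompose(matrix: SpectraMatrix) -> EigenDecomposition:
    """Thin SVD with the sign convention above."""
    A = np.asarray(matrix.data, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("spectra matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T
    # sign fix: largest-|.| entry of each eigenspectrum made positive
    lead = np.argmax(np.abs(U), axis=0)
    flip = U[lead, np.arange(U.shape[1])] < 0
    U[:, flip] *= -1.0
    V[:, flip] *= -1.0
    return EigenDecomposition(
        U=U, singular_values=s, V=V,
        x_extent=matrix.x_extent, y_extent=matrix.y_extent,
        wavenumbers=matrix.wavenumbers,
    )


def s_rmsd(x: np.ndarray) -> float:
    """Root-mean-square magnitude ``sqrt((x1^2 + ... + xN^2) / N)``."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else 0.0


@dataclass
class ComponentRanking:
    """Components ordered by descending RMS score (ties by ascending index)."""

    order: np.ndarray
    scores: np.ndarray
    mode: str = "averaged_reconstruction"

    def top(self, k: int) -> list[int]:
        return [int(i) for i in self.order[:k]]


def rank_components(
    decomp: EigenDecomposition, mode: str = "averaged_reconstruction"
) -> ComponentRanking:
    """Rank components by RMS magnitude.

    ``averaged_reconstruction`` (default): score of component k is the RMS of
    the pixel-averaged rank-1 reconstruction ``sigma_k * u_k * mean(v_k)``.
    ``raw_eigenvector``: RMS of the unit eigenspectrum u_k itself — constant
    1/sqrt(W) by construction, kept only to document the degeneracy.
    """
    K = decomp.n_components
    if mode == "averaged_reconstruction":
        vbar = decomp.V.mean(axis=0)  # (K,)
        scores = np.array([
            s_rmsd(decomp.singular_values[k] * vbar[k] * decomp.U[:, k])
            for k in range(K)
        ])
    elif mode == "raw_eigenvector":
        scores = np.array([s_rmsd(decomp.U[:, k]) for k in range(K)])
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    order = np.argsort(-scores, kind="stable")  # stable => ties by ascending index
    return ComponentRanking(order=order, scores=scores, mode=mode)


def reconstruct(
    decomp: EigenDecomposition,
    components: Iterable[int],
    x_extent: Optional[int] = None,
    y_extent: Optional[int] = None,
) -> HyperStack:
    """Rank-restricted reconstruction: sum over selected k of sigma_k u_k v_k^T."""
    idx = np.asarray(sorted(set(int(c) for c in components)), dtype=int)
    if idx.size == 0:
        raise ValueError("component set must be non-empty")
    if idx.min() < 0 or idx.max() >= decomp.n_components:
        raise IndexError(
            f"component indices must lie in [0, {decomp.n_components - 1}]"
        )
    x_extent = decomp.x_extent if x_extent is None else x_extent
    y_extent = decomp.y_extent if y_extent is None else y_extent
    A = (decomp.U[:, idx] * decomp.singular_values[idx]) @ decomp.V[:, idx].T
    return unflatten(A, x_extent, y_extent, decomp.wavenumbers,
                     meta={"svd_components": [int(i) for i in idx]})


def eigenspectra_to_csv(
    decomp: EigenDecomposition, path, components: Optional[Sequence[int]] = None
) -> Path:
    """Export selected eigenspectra as CSV (wavenumber + one column per component)."""
    if components is None:
        components = range(min(decomp.n_components, 10))
    wn = (decomp.wavenumbers if decomp.wavenumbers is not None
          else np.arange(decomp.U.shape[0], dtype=float))
    cols = {"wavenumber": wn}
    for k in components:
        cols[f"component_{int(k)}"] = decomp.U[:, int(k)]
    path = Path(path)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
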