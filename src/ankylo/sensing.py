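"""Implicit sensing operator A mapping grid coefficients to Ewald-sphere fields.

Column (l, j*M + m) of A is U_j(|nu_l|) * exp(-i nu_l . q_m): the field a
unit-amplitude sphere of element j at grid site q_m produces at detector l.
The operator exploits the separable phase structure exp(-i nu.q) =
exp(-i nu_x q_x) exp(-i nu_y q_y) exp(-i nu_z q_z) of the regular grid, so
apply/adjoint are dense-BLAS contractions and A is never materialized for
large grids.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .elements import ElementSpec
from .scatter import EwaldSampling, Grid3D, sphere_ft

__all__ = ["SensingOperator", "build_sensing"]


class SensingOperator:
    """The L x (M*T) linear map A, applied implicitly.

    Unknown index convention: element-major blocks, flat index t*M + m with m
    the C-order flat grid index (matching :class:`Grid3D`).
    """

    def __init__(
        self, grid: Grid3D, elements: Sequence[ElementSpec], sampling: EwaldSampling
    ) -> None:
        self.grid = grid
        self.elements = list(elements)
        self.sampling = sampling
        freqs = sampling.frequencies
        numag = np.linalg.norm(freqs, axis=1)
        # radial generating functions, one column per element
        self.radial = np.stack([sphere_ft(e.radius, numag) for e in self.elements], axis=1)
        gx, gy, gz = grid.axes()
        self._Ex = np.exp(-1j * np.outer(freqs[:, 0], gx))
        self._Ey = np.exp(-1j * np.outer(freqs[:, 1], gy))
        self._Ez = np.exp(-1j * np.outer(freqs[:, 2], gz))
        self._krT: np.ndarray | None = None  # (nx*ny, L) Khatri-Rao of Ex,Ey, lazy
        self._krT2: np.ndarray | None = None  # same with squared phases, lazy
        # single-precision copies for the solver's scoring contractions:
        # candidate scores need ~6 significant digits, and cgemm is ~2x zgemm
        self._krT32: np.ndarray | None = None
        self._krT232: np.ndarray | None = None

    # -- basic shape info ---------------------------------------------------

    @property
    def n_detectors(self) -> int:
        return len(self.sampling)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_sites(self) -> int:
        return self.grid.n_sites

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_detectors, self.n_elements * self.n_sites)

    # -- building blocks ----------------------------------------------------

    def _kr(self) -> np.ndarray:
        """(nx*ny, L) transposed row-wise Kronecker of the x and y phase factors."""
        if self._krT is None:
            L = self.n_detectors
            nx = self._Ex.shape[1]
            ny = self._Ey.shape[1]
            kr = (self._Ex[:, :, None] * self._Ey[:, None, :]).reshape(L, nx * ny)
            self._krT = np.ascontiguousarray(kr.T)
        return self._krT

    def columns(self, indices: Sequence[tuple[int, int]]) -> np.ndarray:
        """Explicit columns (L, k) for a list of (element, flat site) indices."""
        nx, ny, nz = self.grid.shape
        cols = np.empty((self.n_detectors, len(indices)), dtype=complex)
        for c, (t, m) in enumerate(indices):
            i, j, k = np.unravel_index(m, self.grid.shape)
            cols[:, c] = (
                self.radial[:, t] * self._Ex[:, i] * self._Ey[:, j] * self._Ez[:, k]
            )
        return cols

    def apply(self, x: np.ndarray) -> np.ndarray:
        """A @ x for a dense coefficient array of shape (T, nx, ny, nz) (or flat)."""
        nx, ny, nz = self.grid.shape
        x = np.asarray(x).reshape(self.n_elements, nx, ny, nz)
        krT = self._kr()
        F = np.zeros(self.n_detectors, dtype=complex)
        for t in range(self.n_elements):
            B = x[t].reshape(nx * ny, nz) @ self._Ez.T  # (nx*ny, L)
            F += self.radial[:, t] * np.einsum("pl,pl->l", krT, B)
        return F

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """A^H @ y, shape (T, nx, ny, nz) complex."""
        out = np.stack(
            [np.conj(self._adjoint_block_conj(y, t)) for t in range(self.n_elements)]
        )
        return out

    def adjoint_real_block(self, y: np.ndarray, t: int, fast: bool = False) -> np.ndarray:
        """Re[(A^H y)] restricted to element block t, shape (nx, ny, nz).

        This is the workhorse of the solver's gradient: one BLAS gemm of
        shape (nx*ny, L) x (L, nz) per call.  ``fast=True`` runs the gemm in
        single precision (used only for candidate scoring).
        """
        if fast:
            if self._krT32 is None:
                self._krT32 = self._kr().astype(np.complex64)
                self._Ez32 = self._Ez.astype(np.complex64)
            nx, ny, nz = self.grid.shape
            w = (self.radial[:, t] * np.conj(np.asarray(y).ravel())).astype(np.complex64)
            Z = w[:, None] * self._Ez32
            return np.real(self._krT32 @ Z).astype(float).reshape(nx, ny, nz)
        return np.real(self._adjoint_block_conj(y, t))

    def _adjoint_block_conj(self, y: np.ndarray, t: int) -> np.ndarray:
        # conj((A_t^H y)) = kr^T @ [u_t * conj(y) * Ez]; real part unaffected.
        nx, ny, nz = self.grid.shape
        w = self.radial[:, t] * np.conj(np.asarray(y).ravel())
        Z = w[:, None] * self._Ez  # (L, nz)
        return (self._kr() @ Z).reshape(nx, ny, nz)

    def adjoint2_real_block(self, y: np.ndarray, t: int, fast: bool = False) -> np.ndarray:
        """Re[ sum_l conj(A_{l,tm}^2) y_l ] over all sites m of element t.

        The squared columns A^2 have radial factor u_t^2 and doubled phases;
        used by the solver's closed-form single-site line-search scores.
        """
        nx, ny, nz = self.grid.shape
        if fast:
            if self._krT232 is None:
                L = self.n_detectors
                Ex2 = (self._Ex * self._Ex).astype(np.complex64)
                Ey2 = (self._Ey * self._Ey).astype(np.complex64)
                kr2 = (Ex2[:, :, None] * Ey2[:, None, :]).reshape(L, nx * ny)
                self._krT232 = np.ascontiguousarray(kr2.T)
                self._Ez232 = (self._Ez * self._Ez).astype(np.complex64)
            w = (self.radial[:, t] ** 2 * np.conj(np.asarray(y).ravel())).astype(np.complex64)
            Z = w[:, None] * self._Ez232
            return np.real(self._krT232 @ Z).astype(float).reshape(nx, ny, nz)
        if self._krT2 is None:
            L = self.n_detectors
            nx_, ny_ = self._Ex.shape[1], self._Ey.shape[1]
            Ex2 = self._Ex * self._Ex
            Ey2 = self._Ey * self._Ey
            kr2 = (Ex2[:, :, None] * Ey2[:, None, :]).reshape(L, nx_ * ny_)
            self._krT2 = np.ascontiguousarray(kr2.T)
        w = self.radial[:, t] ** 2 * np.conj(np.asarray(y).ravel())
        Z = w[:, None] * (self._Ez * self._Ez)
        return np.real(self._krT2 @ Z).reshape(nx, ny, nz)

    def dense_matrix(self) -> np.ndarray:
        """Explicit A for small problems (tests / exhaustive oracles)."""
        if self.n_elements * self.n_sites > 1_000_000:
            raise ValueError("refusing to materialize A for M*T > 1e6")
        idx = [(t, m) for t in range(self.n_elements) for m in range(self.n_sites)]
        return self.columns(idx)


def build_sensing(
    grid: Grid3D, elements: Sequence[ElementSpec], sampling: EwaldSampling
) -> SensingOperator:
    """Construct the sensing operator, warning when the grid is coarser than
    the smallest sphere radius (legal, but sites cannot resolve sub-atomic
    offsets)."""
    min_radius = min(e.radius for e in elements)
    if grid.spacing >= min_radius:
        warnings.warn(
            f"grid spacing {grid.spacing:.3g} A >= smallest element radius "
            f"{min_radius:.3g} A; candidate grid is coarser than the smallest atom",
            stacklevel=2,
        )
    return SensingOperator(grid, elements, sampling)
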