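"""Hybrid input-output (HIO) phase-retrieval baselines.

Classical 3D HIO recovers an object from Fourier-magnitude data with a
support constraint; here the data live only on a thin Ewald shell of the 3D
frequency grid, the regime in which plain HIO is known to fail for
molecule-sized voxel counts.  The sparsity-augmented variant additionally
projects the object estimate onto the sphere dictionary every iteration:
matched-filter correlation with each element's kernel, greedy selection of
the top-S_j peaks (non-maximum suppression within one covalent radius),
joint least-squares amplitudes, and re-rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import ElementSpec
from .metrics import render_molecule
from .scatter import Atom, Grid3D, MeasurementSet, Molecule

__all__ = [
    "VoxelImage",
    "FourierShellData",
    "build_shell",
    "hio_reconstruct",
    "sparse_project",
    "sparse_hio_reconstruct",
]


@dataclass
class VoxelImage:
    """Real 3D image on a cubic FFT grid with its support mask."""

    values: np.ndarray
    voxel_size: float
    support_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.values.shape != self.support_mask.shape:
            raise ValueError("image and support mask shapes differ")

    @property
    def grid(self) -> Grid3D:
        n = self.values.shape[0]
        return Grid3D.centered(extent=(n - 1) * self.voxel_size, n=n)


@dataclass
class FourierShellData:
    """Ewald samples embedded in the 3D FFT frequency grid.

    ``mask`` flags the constrained Fourier voxels (a thin shell, symmetrized
    for a real object); ``magnitudes`` holds the measured |F| per constrained
    voxel (mean over samples landing in one voxel, sqrt of max(C, 0)).
    """

    n: int
    voxel_size: float
    mask: np.ndarray
    magnitudes: np.ndarray  # full (n,n,n) array, zero off-mask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)


def build_shell(measurements: MeasurementSet, n: int, voxel_size: float) -> FourierShellData:
    """Map Ewald-sphere intensity samples onto the nearest 3D FFT voxels.

    Voxels receiving several samples take the mean magnitude; the constraint
    set is symmetrized (|F(-nu)| = |F(nu)| for a real object).  Samples
    beyond the FFT band edge are dropped.
    """
    freqs = measurements.sampling.frequencies
    mags = np.sqrt(np.clip(measurements.intensities, 0.0, None))
    step = 2.0 * np.pi / (n * voxel_size)  # FFT frequency resolution
    idx = np.round(freqs / step).astype(int)
    in_band = np.all(np.abs(idx) <= n // 2 - (n + 1) % 2, axis=1)
    idx = idx[in_band] % n
    mags = mags[in_band]
    acc = np.zeros((n, n, n))
    cnt = np.zeros((n, n, n))
    np.add.at(acc, (idx[:, 0], idx[:, 1], idx[:, 2]), mags)
    np.add.at(cnt, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    midx = (-idx) % n  # Hermitian mirror
    np.add.at(acc, (midx[:, 0], midx[:, 1], midx[:, 2]), mags)
    np.add.at(cnt, (midx[:, 0], midx[:, 1], midx[:, 2]), 1.0)
    mask = cnt > 0
    mag_grid = np.zeros((n, n, n))
    mag_grid[mask] = acc[mask] / cnt[mask]
    return FourierShellData(n=n, voxel_size=voxel_size, mask=mask, magnitudes=mag_grid)


def _fourier_residual(G: np.ndarray, shell: FourierShellData) -> float:
    num = np.linalg.norm(np.abs(G[shell.mask]) - shell.magnitudes[shell.mask])
    den = np.linalg.norm(shell.magnitudes[shell.mask])
    return float(num / den) if den > 0 else 0.0


def _magnitude_replace(G: np.ndarray, shell: FourierShellData) -> np.ndarray:
    Gc = G.copy()
    Gm = G[shell.mask]
    phase = np.where(np.abs(Gm) > 0, Gm / np.maximum(np.abs(Gm), 1e-300), 1.0)
    Gc[shell.mask] = shell.magnitudes[shell.mask] * phase
    return Gc


def hio_reconstruct(
    shell: FourierShellData,
    support_mask: np.ndarray,
    iterations: int = 2000,
    beta: float = 0.9,
    seed: int = 0,
) -> tuple[VoxelImage, np.ndarray]:
    """Standard HIO from (partial) Fourier magnitudes.

    Fourier step: replace magnitudes on constrained voxels, keep phases
    (unconstrained voxels run free).  Object step: keep the inverse transform
    where it satisfies the constraints (inside support, non-negative) and
    apply the feedback x <- x - beta * x' elsewhere.  Returns the final image
    and the per-iteration Fourier-domain residual log.
    """
    support_mask = np.asarray(support_mask, dtype=bool)
    if not support_mask.any():
        raise ValueError("support mask is empty")
    if iterations < 1 or not (0.0 <= beta <= 1.0):
        raise ValueError("need iterations >= 1 and 0 <= beta <= 1")
    rng = np.random.default_rng(seed)
    g = rng.random(support_mask.shape) * support_mask
    residuals = np.empty(iterations)
    for it in range(iterations):
        G = np.fft.fftn(g)
        residuals[it] = _fourier_residual(G, shell)
        gp = np.fft.ifftn(_magnitude_replace(G, shell)).real
        violated = (~support_mask) | (gp < 0)
        g = np.where(violated, g - beta * gp, gp)
    return VoxelImage(values=g, voxel_size=shell.voxel_size, support_mask=support_mask), residuals


# ---------------------------------------------------------------------------
# sparsity-augmented HIO


def _build_kernel_at_origin(n: int, voxel_size: float, e: ElementSpec) -> np.ndarray:
    """Sphere kernel rendered with its centre at voxel (0,0,0), periodically."""
    grid = Grid3D.centered(extent=(n - 1) * voxel_size, n=n)
    gx, gy, gz = grid.axes()
    # distances to the origin voxel of the FFT grid, wrapped periodically
    ax = [np.minimum(np.abs(a - a[0]), n * voxel_size - np.abs(a - a[0])) for a in (gx, gy, gz)]
    d = np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    return np.clip((e.radius - d) / voxel_size + 0.5, 0.0, 1.0)


def sparse_project(
    image: np.ndarray,
    voxel_size: float,
    elements: list[ElementSpec],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, Molecule]:
    """Project an image onto at most S_j spheres per element.

    Matched-filter correlation selects, per element, up to S_j local peaks
    with non-maximum suppression within one covalent radius; amplitudes are
    then fit jointly by non-negative-clipped least squares on the selected
    kernels, and the image is re-rendered from the kept coefficients.
    Returns (rebuilt image, kept spheres as a Molecule).
    """
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    grid = Grid3D.centered(extent=(n - 1) * voxel_size, n=n)
    Gimg = np.fft.fftn(image)
    picked: list[tuple[ElementSpec, np.ndarray]] = []
    for e in elements:
        if e.count == 0:
            continue
        kernel = _build_kernel_at_origin(n, voxel_size, e)
        corr = np.fft.ifftn(Gimg * np.conj(np.fft.fftn(kernel))).real / np.sum(kernel * kernel)
        gx, gy, gz = grid.axes()
        sel = corr.copy()
        for _ in range(e.count):
            m = int(np.argmax(sel))
            if sel.ravel()[m] <= 0:
                break
            ijk = np.unravel_index(m, sel.shape)
            pos = grid.origin + grid.spacing * np.array(ijk)
            picked.append((e, pos))
            # non-maximum suppression within one covalent radius
            d2 = (
                (gx[:, None, None] - pos[0]) ** 2
                + (gy[None, :, None] - pos[1]) ** 2
                + (gz[None, None, :] - pos[2]) ** 2
            )
            sel[d2 <= e.radius**2] = -np.inf
    if not picked:
        specs = [e.with_count(0) for e in elements]
        return np.zeros_like(image), Molecule(specs, [])
    # joint least-squares amplitudes on the selected kernels
    renders = []
    for e, pos in picked:
        spec1 = e.with_count(1)
        renders.append(render_molecule(Molecule([spec1], [Atom(spec1, pos, 1.0)]), grid).ravel())
    K = np.stack(renders, axis=1)
    amps, *_ = np.linalg.lstsq(K, image.ravel(), rcond=None)
    amps = np.clip(amps, 0.0, None)
    rebuilt = (K @ amps).reshape(image.shape)
    counts: dict[str, int] = {}
    atoms = []
    for (e, pos), a in zip(picked, amps):
        counts[e.symbol] = counts.get(e.symbol, 0) + 1
    specs = [e.with_count(counts.get(e.symbol, 0)) for e in elements]
    by_symbol = {s.symbol: s for s in specs}
    for (e, pos), a in zip(picked, amps):
        atoms.append(Atom(by_symbol[e.symbol], pos, float(a)))
    return rebuilt, Molecule(specs, atoms)


def sparse_hio_reconstruct(
    shell: FourierShellData,
    support_mask: np.ndarray,
    elements: list[ElementSpec],
    iterations: int = 300,
    beta: float = 0.9,
    seed: int = 0,
) -> tuple[VoxelImage, Molecule, np.ndarray]:
    """HIO with a per-iteration sphere-dictionary sparsity projection.

    Alternates the Fourier magnitude constraint with the greedy sparse
    projection of :func:`sparse_project` (support- and positivity-restricted
    first).  The lowest-Fourier-residual iterate is returned together with
    its sparse code and the residual log.
    """
    support_mask = np.asarray(support_mask, dtype=bool)
    if not support_mask.any():
        raise ValueError("support mask is empty")
    if iterations < 1 or not (0.0 <= beta <= 1.0):
        raise ValueError("need iterations >= 1 and 0 <= beta <= 1")
    rng = np.random.default_rng(seed)
    g = rng.random(support_mask.shape) * support_mask
    best = None
    residuals = np.empty(iterations)
    code = None
    for it in range(iterations):
        G = np.fft.fftn(g)
        residuals[it] = _fourier_residual(G, shell)
        gp = np.fft.ifftn(_magnitude_replace(G, shell)).real
        gp_obj = np.clip(gp * support_mask, 0.0, None)
        rebuilt, mol = sparse_project(gp_obj, shell.voxel_size, elements, rng=rng)
        if best is None or residuals[it] < best[0]:
            best = (residuals[it], rebuilt.copy(), mol)
        g = rebuilt
        code = mol
    _, g_best, code = best
    img = VoxelImage(values=g_best, voxel_size=shell.voxel_size, support_mask=support_mask)
    return img, code, residuals
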