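"""Bundled fixtures and demonstration geometry.

The 17-atom threonine-like molecule (4 C, 1 N, 3 O, 9 H; synthetic
force-field conformer, see the XYZ comment line) is the standard test
subject.  The demo setup mirrors the coarse single-molecule demonstration: a
9^3 candidate grid spanning the molecule, with the wavelength tied to the
grid spacing so the Ewald sphere reaches the grid's Nyquist frequency.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .scatter import EwaldSampling, Grid3D, Molecule, snap_to_grid
from .xyz import read_xyz

__all__ = ["threonine", "demo_grid", "demo_wavelength", "demo_setup"]


def threonine() -> Molecule:
    """The bundled 17-atom threonine-like fixture (centred, angstrom)."""
    with resources.as_file(resources.files("ankylo") / "data" / "threonine.xyz") as p:
        return read_xyz(p)


def demo_grid(molecule: Molecule, n: int = 9, pad: float = 0.4) -> Grid3D:
    """Cubic n^3 candidate grid covering the molecule's bounding box + pad."""
    pos = molecule.positions()
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    extent = float((hi - lo).max())
    center = (lo + hi) / 2.0
    return Grid3D.centered(extent=extent, n=n, center=center)


def demo_wavelength(spacing: float, theta_max: float = np.deg2rad(160.0)) -> float:
    """Wavelength at which the Ewald sphere reaches nu_max = pi / spacing."""
    return 4.0 * np.sin(theta_max / 2.0) * spacing


def demo_setup(
    n_grid: int = 9, n_theta: int = 64, n_phi: int = 64
) -> tuple[Molecule, Grid3D, EwaldSampling]:
    """On-grid demo: threonine snapped to an n_grid^3 grid plus its sampling.

    Returns (snapped molecule, grid, sampling); the snapped molecule is the
    ground truth for exact-recovery demonstrations.
    """
    mol = threonine()
    grid = demo_grid(mol, n=n_grid)
    snapped = snap_to_grid(mol, grid)
    wavelength = demo_wavelength(grid.spacing)
    sampling = EwaldSampling.from_grid(wavelength, n_theta=n_theta, n_phi=n_phi)
    return snapped, grid, sampling
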