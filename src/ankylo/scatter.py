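"""Forward scattering model on the Ewald sphere.

A molecule is a sum of element-specific uniform balls at continuous
(grid-free) positions.  The far-field scattered intensity of a monochromatic
plane wave incident along +z is |F(nu)|^2, the squared magnitude of the 3D
Fourier transform of the scattering potential, sampled on the Ewald sphere
nu = k_out - k_in with |k| = 2*pi/lambda.  The proportionality constant is
fixed to 1: simulator and solver share the forward model, so every
comparison is scale-consistent.

Units: lengths in angstrom, spatial frequencies in rad/angstrom, angles in
radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .elements import ElementSpec

__all__ = [
    "Atom",
    "Molecule",
    "Grid3D",
    "EwaldSampling",
    "MeasurementSet",
    "sphere_ft",
    "ewald_frequencies",
    "forward_field",
    "forward_intensity",
    "mean_sphere_intensity",
    "add_noise",
    "snap_to_grid",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Atom:
    """One atom: element, continuous 3D position (angstrom), amplitude >= 0."""

    element: ElementSpec
    position: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if self.amplitude < 0:
            raise ValueError(f"atom amplitude must be >= 0, got {self.amplitude}")


@dataclass
class Molecule:
    """A list of atoms plus the element dictionary they are drawn from.

    Per-element atom counts must match the dictionary's stoichiometric
    counts; positions are continuous and never grid-restricted.
    """

    elements: list[ElementSpec]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        by_symbol = {e.symbol: e for e in self.elements}
        counts = {e.symbol: 0 for e in self.elements}
        for a in self.atoms:
            if a.element.symbol not in by_symbol:
                raise ValueError(f"atom element {a.element.symbol!r} not in dictionary")
            counts[a.element.symbol] += 1
        for e in self.elements:
            if counts[e.symbol] != e.count:
                raise ValueError(
                    f"element {e.symbol!r}: {counts[e.symbol]} atoms but stoichiometry says {e.count}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    def grouped(self) -> Iterator[tuple[ElementSpec, np.ndarray, np.ndarray]]:
        """Yield (element, positions (n,3), amplitudes (n,)) per element."""
        for e in self.elements:
            sel = [a for a in self.atoms if a.element.symbol == e.symbol]
            pos = np.array([a.position for a in sel]).reshape(len(sel), 3)
            amp = np.array([a.amplitude for a in sel])
            yield e, pos, amp

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms]).reshape(len(self.atoms), 3)

    def translated(self, shift: np.ndarray) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        return Molecule(
            self.elements,
            [Atom(a.element, a.position + shift, a.amplitude) for a in self.atoms],
        )

    @classmethod
    def from_arrays(
        cls,
        elements: Sequence[ElementSpec],
        symbols: Sequence[str],
        positions: np.ndarray,
        amplitudes: Sequence[float] | None = None,
    ) -> "Molecule":
        by_symbol = {e.symbol: e for e in elements}
        positions = np.asarray(positions, dtype=float).reshape(len(symbols), 3)
        atoms = []
        for i, s in enumerate(symbols):
            e = by_symbol[s]
            amp = e.amplitude if amplitudes is None else float(amplitudes[i])
            atoms.append(Atom(e, positions[i], amp))
        return cls(list(elements), atoms)


@dataclass(frozen=True)
class Grid3D:
    """Regular cubic candidate grid: origin + spacing * (i, j, k), C-order flat index."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")

    @property
    def n_sites(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def site_positions(self, flat_indices: np.ndarray) -> np.ndarray:
        """Cartesian positions (k,3) of flat C-order site indices."""
        ijk = np.stack(np.unravel_index(np.asarray(flat_indices, dtype=int), self.shape), axis=-1)
        return self.origin + self.spacing * ijk

    def all_positions(self) -> np.ndarray:
        gx, gy, gz = self.axes()
        X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    def nearest_site(self, position: np.ndarray) -> int:
        ijk = np.round((np.asarray(position, dtype=float) - self.origin) / self.spacing).astype(int)
        ijk = np.clip(ijk, 0, np.array(self.shape) - 1)
        return int(np.ravel_multi_index(tuple(ijk), self.shape))

    @classmethod
    def centered(cls, extent: float, n: int, center: np.ndarray | None = None) -> "Grid3D":
        """Cube of n^3 sites spanning `extent` angstrom about `center`."""
        center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        spacing = extent / (n - 1) if n > 1 else extent
        origin = center - spacing * (n - 1) / 2.0
        return cls(origin=origin, spacing=spacing, shape=(n, n, n))


# ---------------------------------------------------------------------------
# sphere generating function and Ewald geometry


def sphere_ft(radius: float, freq_magnitude) -> np.ndarray:
    """3D Fourier transform of a unit-amplitude uniform ball.

    Closed form 4*pi*(sin(nu R) - nu R cos(nu R)) / nu^3; for nu*R < 1e-4 a
    series expansion avoids the catastrophic cancellation of the closed form,
    with the exact DC limit 4*pi*R^3/3 (the ball volume).
    """
    if radius <= 0:
        raise ValueError(f"sphere radius must be > 0, got {radius}")
    nu = np.asarray(freq_magnitude, dtype=float)
    scalar = nu.ndim == 0
    nu = np.atleast_1d(nu)
    if np.any(nu < 0):
        raise ValueError("frequency magnitude must be >= 0")
    x = nu * radius
    out = np.empty_like(nu)
    small = x < 1e-4
    xs = x[small]
    out[small] = (4.0 * np.pi * radius**3) * (1.0 / 3.0 - xs**2 / 30.0 + xs**4 / 840.0)
    xl = x[~small]
    out[~small] = 4.0 * np.pi * (np.sin(xl) - xl * np.cos(xl)) / (nu[~small] ** 3)
    return out[0] if scalar else out


def ewald_frequencies(wavelength: float, theta, phi) -> np.ndarray:
    """Spatial frequencies nu = k_out - k_in on the Ewald sphere.

    Incidence along +z: nu = (2*pi/lambda) * (sin t cos p, sin t sin p, cos t - 1).
    The magnitude identity |nu| = (4*pi/lambda) * sin(t/2) holds exactly.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    k = 2.0 * np.pi / wavelength
    st = np.sin(theta)
    return np.stack(
        [k * st * np.cos(phi), k * st * np.sin(phi), k * (np.cos(theta) - 1.0)], axis=-1
    )


@dataclass(frozen=True)
class EwaldSampling:
    """Detector geometry: wavelength, angle lists and induced frequencies.

    theta is the polar scattering angle measured from the incident beam (+z);
    the beamstop masks theta < theta_min.  ``frequencies`` holds the L
    spatial-frequency samples on the Ewald sphere.
    """

    wavelength: float
    theta: np.ndarray
    phi: np.ndarray
    theta_min: float
    theta_max: float

    frequencies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float).ravel())
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float).ravel())
        if self.theta.shape != self.phi.shape:
            raise ValueError("theta and phi must have the same length")
        if np.any(self.theta < 0) or np.any(self.theta > np.pi):
            raise ValueError("theta must lie in [0, pi]")
        object.__setattr__(
            self, "frequencies", ewald_frequencies(self.wavelength, self.theta, self.phi)
        )

    def __len__(self) -> int:
        return self.theta.size

    @classmethod
    def from_grid(
        cls,
        wavelength: float,
        theta_min: float = np.deg2rad(2.0),
        theta_max: float = np.deg2rad(160.0),
        n_theta: int = 64,
        n_phi: int = 64,
        layout: str = "solid_angle",
    ) -> "EwaldSampling":
        """Detector grid of n_theta x n_phi samples (beamstop below theta_min).

        ``layout="solid_angle"`` (default) spaces the polar rings uniformly in
        cos(theta), giving every sample an equal share of the sphere;
        ``layout="equiangular"`` spaces them uniformly in theta, which
        concentrates samples (and the objective's weight) at small angles.
        """
        if layout == "solid_angle":
            t = np.arccos(np.linspace(np.cos(theta_min), np.cos(theta_max), n_theta))
        elif layout == "equiangular":
            t = np.linspace(theta_min, theta_max, n_theta)
        else:
            raise ValueError(f"unknown detector layout {layout!r}")
        p = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
        T, P = np.meshgrid(t, p, indexing="ij")
        return cls(
            wavelength=wavelength,
            theta=T.ravel(),
            phi=P.ravel(),
            theta_min=float(theta_min),
            theta_max=float(theta_max),
        )


@dataclass
class MeasurementSet:
    """Measured intensities C (length L) plus their sampling geometry.

    ``total_signal_power`` is the area-weighted mean intensity over the full
    sphere, including the beamstop-masked low-angle region; it normalizes the
    noise level N (noise variance = N * total_signal_power).  Noisy
    intensities may be negative (no clipping, to keep the power calibration
    unbiased).
    """

    intensities: np.ndarray
    sampling: EwaldSampling
    noise_level: float = 0.0
    seed: int | None = None
    total_signal_power: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.intensities.size != len(self.sampling):
            raise ValueError("intensity vector length does not match sampling")
        if not (0.0 <= self.noise_level < 1.0):
            raise ValueError("noise_level must lie in [0, 1)")

    def __len__(self) -> int:
        return self.intensities.size


# ---------------------------------------------------------------------------
# forward model


def forward_field(molecule: Molecule, frequencies: np.ndarray) -> np.ndarray:
    """Complex scattered field F(nu) = sum_j U_j(|nu|) sum_n c_n exp(-i nu.r_n)."""
    freqs = np.asarray(frequencies, dtype=float).reshape(-1, 3)
    numag = np.linalg.norm(freqs, axis=1)
    F = np.zeros(freqs.shape[0], dtype=complex)
    for element, pos, amp in molecule.grouped():
        if len(amp) == 0:
            continue
        u = sphere_ft(element.radius, numag)
        phases = np.exp(-1j * (freqs @ pos.T))
        F += u * (phases @ amp)
    return F


def forward_intensity(
    molecule: Molecule,
    sampling: EwaldSampling,
    compute_total_power: bool = True,
) -> MeasurementSet:
    """Noiseless intensity I_l = |F(nu_l)|^2 at each detector.

    Computed from continuous atom positions; invariant under rigid
    translation of the molecule (only |F| enters).
    """
    if len(molecule) == 0:
        raise ValueError("molecule has no atoms")
    F = forward_field(molecule, sampling.frequencies)
    intensities = np.abs(F) ** 2
    power = mean_sphere_intensity(molecule, sampling.wavelength) if compute_total_power else 0.0
    return MeasurementSet(
        intensities=intensities,
        sampling=sampling,
        noise_level=0.0,
        seed=None,
        total_signal_power=power,
    )


def mean_sphere_intensity(
    molecule: Molecule, wavelength: float, n_polar: int = 128, n_azimuth: int = 256
) -> float:
    """Area-weighted mean of I over the FULL Ewald sphere (beamstop included).

    Gauss-Legendre in cos(theta) times a uniform azimuthal grid; this is the
    normalization behind the noise level N.
    """
    x, w = np.polynomial.legendre.leggauss(n_polar)
    theta = np.arccos(x)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    freqs = ewald_frequencies(wavelength, T.ravel(), P.ravel())
    I = np.abs(forward_field(molecule, freqs)) ** 2
    I = I.reshape(n_polar, n_azimuth).mean(axis=1)
    return float((w @ I) / 2.0)


def add_noise(measurements: MeasurementSet, noise_level: float, seed: int) -> MeasurementSet:
    """Add zero-mean white Gaussian noise with power N * total_signal_power.

    Reproducible under a fixed seed; negative noisy intensities are retained.
    """
    if not (0.0 <= noise_level < 1.0):
        raise ValueError(f"noise_level must lie in [0, 1), got {noise_level}")
    if noise_level == 0.0:
        noisy = measurements.intensities.copy()
    else:
        sigma = np.sqrt(noise_level * measurements.total_signal_power)
        rng = np.random.default_rng(seed)
        noisy = measurements.intensities + rng.normal(0.0, sigma, size=len(measurements))
    return MeasurementSet(
        intensities=noisy,
        sampling=measurements.sampling,
        noise_level=noise_level,
        seed=seed,
        total_signal_power=measurements.total_signal_power,
    )


def snap_to_grid(molecule: Molecule, grid: Grid3D) -> Molecule:
    """Return the molecule with every atom moved to its nearest grid site.

    Raises if two atoms collapse onto the same site (grid too coarse).
    """
    sites = [grid.nearest_site(a.position) for a in molecule.atoms]
    if len(set(sites)) != len(sites):
        raise ValueError("grid too coarse: two atoms snap to the same site")
    atoms = [
        Atom(a.element, grid.site_positions(np.array([s]))[0], a.amplitude)
        for a, s in zip(molecule.atoms, sites)
    ]
    return Molecule(molecule.elements, atoms)
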