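"""Shared fixtures: small, fast synthetic problem instances."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import ankylo as ak


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def threonine():
    return ak.threonine()


@pytest.fixture()
def small_problem():
    """1-element, 3-atom, 5^3-grid instance with its operator and noiseless data."""
    elements = ak.element_dictionary({"C": 3})
    grid = ak.Grid3D.centered(3.0, 5)
    sampling = ak.EwaldSampling.from_grid(
        ak.fixtures.demo_wavelength(grid.spacing), n_theta=16, n_phi=24
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        operator = ak.build_sensing(grid, elements, sampling)
    molecule = ak.random_molecule(elements, box=2.2, min_distance=1.0, seed=7, on_grid=grid)
    measurements = ak.forward_intensity(molecule, sampling)
    return dict(
        elements=elements,
        grid=grid,
        sampling=sampling,
        operator=operator,
        molecule=molecule,
        measurements=measurements,
    )


@pytest.fixture()
def two_element_problem():
    """2-element (C2, H2) on-grid instance on a 5^3 grid."""
    elements = ak.element_dictionary({"C": 2, "H": 2})
    grid = ak.Grid3D.centered(3.0, 5)
    sampling = ak.EwaldSampling.from_grid(
        ak.fixtures.demo_wavelength(grid.spacing), n_theta=16, n_phi=24
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        operator = ak.build_sensing(grid, elements, sampling)
    molecule = ak.random_molecule(elements, box=2.2, min_distance=1.0, seed=3, on_grid=grid)
    measurements = ak.forward_intensity(molecule, sampling)
    return dict(
        elements=elements,
        grid=grid,
        sampling=sampling,
        operator=operator,
        molecule=molecule,
        measurements=measurements,
    )


def true_support(molecule, grid, elements):
    """Per-element sorted true site lists for an on-grid molecule."""
    sym2t = {e.symbol: t for t, e in enumerate(elements)}
    sup = [[] for _ in elements]
    for a in molecule.atoms:
        sup[sym2t[a.element.symbol]].append(grid.nearest_site(a.position))
    return [sorted(s) for s in sup]
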