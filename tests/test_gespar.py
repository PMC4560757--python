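"""GESPAR solver: objective, gradient, refinement, greedy moves, full solve."""

import itertools
import warnings

import numpy as np
import pytest

import ankylo as ak
from ankylo.gespar import (
    SolverConfig,
    SparseSolution,
    cost,
    gauss_newton_refine,
    gradient,
    index_swap,
    solve,
    subgrid_refine,
    support_update,
)
from conftest import true_support


def dense_truth(problem):
    """Dense ground-truth coefficient vector for an on-grid instance."""
    op = problem["operator"]
    x = np.zeros(op.shape[1])
    sym2t = {e.symbol: t for t, e in enumerate(problem["elements"])}
    for a in problem["molecule"].atoms:
        t = sym2t[a.element.symbol]
        x[t * op.n_sites + problem["grid"].nearest_site(a.position)] = a.amplitude
    return x


class TestCost:
    def test_zero_at_ground_truth(self, small_problem):
        x = dense_truth(small_problem)
        C = small_problem["measurements"].intensities
        f = cost(x, small_problem["operator"], small_problem["measurements"])
        assert f <= 1e-16 * float(C @ C)

    def test_zero_vector_gives_sum_of_squares(self, small_problem):
        C = small_problem["measurements"].intensities
        f = cost(np.zeros(small_problem["operator"].shape[1]),
                 small_problem["operator"], small_problem["measurements"])
        assert f == pytest.approx(float(C @ C), rel=1e-14)

    def test_matches_explicit_matrix_oracle(self, two_element_problem, rng):
        op = two_element_problem["operator"]
        meas = two_element_problem["measurements"]
        A = op.dense_matrix()
        x = rng.random(op.shape[1]) * 0.2
        brute = float(np.sum((np.abs(A @ x) ** 2 - meas.intensities) ** 2))
        assert cost(x, op, meas) == pytest.approx(brute, rel=1e-10)

    def test_dimension_mismatch(self, small_problem):
        with pytest.raises(ValueError):
            cost(np.zeros(7), small_problem["operator"], small_problem["measurements"])


class TestGradient:
    def test_zero_at_origin(self, small_problem):
        g = gradient(np.zeros(small_problem["operator"].shape[1]),
                     small_problem["operator"], small_problem["measurements"])
        assert np.all(g == 0.0)

    def test_stationary_at_ground_truth(self, small_problem):
        x = dense_truth(small_problem)
        g = gradient(x, small_problem["operator"], small_problem["measurements"])
        assert np.linalg.norm(g) <= 1e-8 * (1.0 + np.linalg.norm(x))

    def test_matches_finite_differences(self, two_element_problem, rng):
        op = two_element_problem["operator"]
        meas = two_element_problem["measurements"]
        x = rng.random(op.shape[1]) * 0.3
        g = gradient(x, op, meas)
        h = 1e-6
        for i in rng.integers(0, x.size, 8):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (cost(xp, op, meas) - cost(xm, op, meas)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestGaussNewton:
    def test_recovers_scaled_amplitude(self, small_problem):
        """1-D case: support = one true site, amplitude started at half."""
        p = small_problem
        op, meas = p["operator"], p["measurements"]
        e = p["elements"][0]
        site = true_support(p["molecule"], p["grid"], p["elements"])[0][0]
        mol1 = ak.Molecule(
            [e.with_count(1)],
            [ak.Atom(e.with_count(1),
                     p["grid"].site_positions(np.array([site]))[0], e.amplitude)],
        )
        meas1 = ak.forward_intensity(mol1, p["sampling"], compute_total_power=False)
        z, f = gauss_newton_refine([(0, site)], np.array([e.amplitude / 2]),
                                   op, meas1, SolverConfig())
        assert z[0] == pytest.approx(e.amplitude, rel=1e-8)

    def test_truth_is_fixed_point(self, small_problem):
        p = small_problem
        sup = true_support(p["molecule"], p["grid"], p["elements"])[0]
        support = [(0, m) for m in sup]
        z0 = np.array([a.amplitude for a in p["molecule"].atoms])
        # align z0 with sorted support order
        order = np.argsort([p["grid"].nearest_site(a.position) for a in p["molecule"].atoms])
        z0 = z0[order]
        z, f = gauss_newton_refine(support, z0, p["operator"], p["measurements"],
                                   SolverConfig())
        C = p["measurements"].intensities
        assert f <= 1e-16 * float(C @ C)
        assert np.allclose(z, z0, rtol=1e-10)

    def test_random_start_converges_often(self, small_problem):
        """On the true support, most random positive starts reach cost ~ 0."""
        p = small_problem
        sup = [(0, m) for m in true_support(p["molecule"], p["grid"], p["elements"])[0]]
        C = p["measurements"].intensities
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z0 = rng.uniform(0.5, 3.0, len(sup))
            _, f = gauss_newton_refine(sup, z0, p["operator"], p["measurements"],
                                       SolverConfig(gn_max_iter=200))
            ok += f < 1e-10 * float(C @ C)
        assert ok >= 8

    def test_cost_never_increases(self, small_problem, rng):
        p = small_problem
        sup = [(0, int(m)) for m in rng.integers(0, p["operator"].n_sites, 3)]
        z0 = rng.uniform(0, 2, 3)
        cols = p["operator"].columns(sup)
        f0 = float(((np.abs(cols @ z0) ** 2 - p["measurements"].intensities) ** 2).sum())
        _, f = gauss_newton_refine(sup, z0, p["operator"], p["measurements"], SolverConfig())
        assert f <= f0 + 1e-12 * f0


class TestSubgridRefine:
    def test_offsets_recover_off_grid_geometry(self, small_problem):
        """Two atoms, one placed off-grid: the relaxed fit reaches ~zero cost
        and recovers the true relative position (absolute position is gauge)."""
        p = small_problem
        e = p["elements"][0].with_count(2)
        base = p["grid"].site_positions(np.array([31]))[0]
        delta_true = np.array([1.45, -0.1, 0.65])  # off-grid relative vector
        mol = ak.Molecule([e], [ak.Atom(e, base, e.amplitude),
                                ak.Atom(e, base + delta_true, e.amplitude)])
        meas = ak.forward_intensity(mol, p["sampling"], compute_total_power=False)
        sites = [p["grid"].nearest_site(a.position) for a in mol.atoms]
        amps, offs, f = subgrid_refine([sites], np.full(2, e.amplitude),
                                       p["operator"], meas, SolverConfig(), max_iter=120)
        C = meas.intensities
        assert f <= 1e-10 * float(C @ C)
        q = p["grid"].site_positions(np.array(sites))
        delta_got = (q[1] + offs[1]) - (q[0] + offs[0])
        assert np.allclose(delta_got, delta_true, atol=1e-3)

    def test_offsets_bounded_to_cell(self, small_problem, rng):
        p = small_problem
        sups = [[int(m) for m in rng.integers(0, p["operator"].n_sites, 3)]]
        amps, offs, _ = subgrid_refine(sups, rng.uniform(0.5, 2, 3),
                                       p["operator"], p["measurements"], SolverConfig())
        assert np.all(np.abs(offs) <= 0.5 * p["grid"].spacing)


class TestGreedyMoves:
    def test_support_update_respects_caps_and_noop(self, small_problem):
        p = small_problem
        cfg = SolverConfig(subgrid=False)
        sol = SparseSolution(
            supports=[np.array(true_support(p["molecule"], p["grid"], p["elements"])[0])],
            coefficients=[np.full(3, 2.0)],
            cost=np.inf,
            n_sites=p["operator"].n_sites,
        )
        out, changed = support_update(sol, p["operator"], p["measurements"], cfg)
        assert not changed  # already at the stoichiometric cap

    def test_support_update_grows_and_never_increases_cost(self, small_problem):
        p = small_problem
        cfg = SolverConfig(subgrid=False)
        sol = SparseSolution([np.zeros(0, dtype=int)], [np.zeros(0)],
                             np.inf, p["operator"].n_sites)
        C = p["measurements"].intensities
        last = float(C @ C)
        for _ in range(3):
            sol, changed = support_update(sol, p["operator"], p["measurements"], cfg)
            assert changed
            assert sol.cost <= last * (1 + 1e-12)
            last = sol.cost
        assert sol.support_sizes() == [3]
        assert all(np.all(c >= 0) for c in sol.coefficients)

    def test_index_swap_no_op_at_truth(self, small_problem):
        p = small_problem
        cfg = SolverConfig(subgrid=False)
        sol = SparseSolution(
            supports=[np.array(true_support(p["molecule"], p["grid"], p["elements"])[0])],
            coefficients=[np.full(3, 2.0)],
            cost=np.inf,
            n_sites=p["operator"].n_sites,
        )
        out, improved = index_swap(sol, p["operator"], p["measurements"], cfg)
        assert not improved

    def test_index_swap_strictly_decreases(self, small_problem):
        p = small_problem
        cfg = SolverConfig(subgrid=False)
        truth = true_support(p["molecule"], p["grid"], p["elements"])[0]
        wrong = list(truth)
        wrong[0] = truth[0] + 1 if truth[0] + 1 < p["operator"].n_sites else truth[0] - 1
        if wrong[0] in truth:
            wrong[0] = truth[0] - 1
        sol = SparseSolution([np.array(wrong)], [np.full(3, 2.0)],
                             np.inf, p["operator"].n_sites)
        before_cost = None
        for _ in range(6):
            out, improved = index_swap(sol, p["operator"], p["measurements"], cfg)
            if not improved:
                break
            assert out.cost < sol.cost
            sol = out
        # the sequence of committed costs decreased strictly and caps held
        assert sol.support_sizes() == [3]


class TestSolve:
    def test_zero_measurements_returns_zero(self, small_problem):
        p = small_problem
        meas = ak.MeasurementSet(
            intensities=np.zeros(len(p["sampling"])), sampling=p["sampling"]
        )
        sol = solve(p["operator"], meas, config=SolverConfig(restarts=1, seed=0))
        assert sol.n_nonzero() == 0
        assert sol.cost == 0.0

    def test_exact_recovery_small_instance(self, small_problem):
        p = small_problem
        sol = solve(p["operator"], p["measurements"],
                    config=SolverConfig(restarts=3, seed=0))
        rep = ak.normalized_error(p["molecule"], sol, p["grid"], p["elements"])
        assert rep.epsilon <= 1e-6
        assert sol.support_sizes() == [3]
        assert all(np.all(c >= 0) for c in sol.coefficients)

    def test_two_element_caps_partition(self, two_element_problem):
        p = two_element_problem
        sol = solve(p["operator"], p["measurements"],
                    config=SolverConfig(restarts=3, seed=1))
        assert sol.support_sizes() == [2, 2]

    def test_matches_exhaustive_enumeration(self):
        """On a tiny instance the best-of-restarts cost matches brute-force
        enumeration of all supports (grid-locked refinement on both sides)."""
        elements = ak.element_dictionary({"C": 2})
        grid = ak.Grid3D.centered(2.4, 4)
        sampling = ak.EwaldSampling.from_grid(
            ak.fixtures.demo_wavelength(grid.spacing), n_theta=8, n_phi=16
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            op = ak.build_sensing(grid, elements, sampling)
        mol = ak.random_molecule(elements, box=1.8, min_distance=1.0, seed=5, on_grid=grid)
        meas = ak.forward_intensity(mol, sampling)
        cfg = SolverConfig(restarts=20, seed=0, subgrid=False)
        sol = solve(op, meas, config=cfg)
        best = np.inf
        for pair in itertools.combinations(range(op.n_sites), 2):
            sup = [(0, pair[0]), (0, pair[1])]
            _, f = gauss_newton_refine(sup, np.full(2, 2.0), op, meas,
                                       SolverConfig(gn_max_iter=200))
            best = min(best, f)
        C = meas.intensities
        assert sol.cost <= best + 1e-8 * float(C @ C)

    def test_element_mismatch_rejected(self, small_problem):
        p = small_problem
        other = ak.element_dictionary({"O": 3})
        with pytest.raises(ValueError):
            solve(p["operator"], p["measurements"], elements=other)


class TestSolverConfigValidation:
    def test_rejects_bad_budgets(self):
        with pytest.raises(ValueError):
            SolverConfig(restarts=0)
        with pytest.raises(ValueError):
            SolverConfig(gn_tol=0.0)
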