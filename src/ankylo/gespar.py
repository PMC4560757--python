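"""Stoichiometry-constrained greedy sparse phase retrieval (modified GESPAR).

The problem: find per-element supports s_j (|s_j| <= S_j, the stoichiometric
atom count) and non-negative amplitudes x on the candidate grid minimizing

    f(x) = sum_l ( |a_l^H x|^2 - C_l )^2,

the sum of squared residuals between the quadratic forward model and the
measured Ewald-sphere intensities.  The solver combines

* greedy support growth: trial-add, per eligible element, the off-support
  sites with the largest exact single-site gains (closed-form quartic line
  search, vectorized over the grid), refine by damped Gauss-Newton plus a
  sub-grid continuous position relaxation, and commit the single trial with
  the lowest relaxed cost;
* correlation-aware index swapping: per element, remove weak support sites,
  recompute the gain map *after zeroing them* (the sphere columns are
  strongly correlated, so scores must come from the reduced model), swap in
  the best off-support candidates, and commit the best strictly improving
  swap, repeating while improving;
* peel-back basin hopping: on stalls, drop a random part of the support and
  regrow with randomized (GRASP-style) candidate pools.

Amplitudes are bounded per element (charge densities are known up to a
modest factor) and atoms carry continuous sub-cell offsets; both are
essential for identifiability on fine grids (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .elements import ElementSpec
from .scatter import Grid3D, MeasurementSet, Molecule
from .sensing import SensingOperator

__all__ = [
    "SolverConfig",
    "SparseSolution",
    "cost",
    "gradient",
    "gauss_newton_refine",
    "support_update",
    "index_swap",
    "solve",
]


@dataclass(frozen=True)
class SolverConfig:
    """GESPAR hyper-parameters (restart count, refinement and swap budgets)."""

    restarts: int = 1
    seed: int = 0
    gn_max_iter: int = 60
    gn_tol: float = 1e-10
    swap_max_rounds: int = 8
    cost_tol_rel: float = 1e-12  # global stop at cost <= cost_tol_rel * sum(C^2)
    branch: int = 6  # score candidates tried per element per growth step
    swap_branch: int = 3  # out/in candidates tried per element per swap round
    pool: int = 40  # randomized-restart candidate pool (GRASP-style)
    swap_every: int = 4  # interleave one swap round every k support additions
    beam: int = 1  # beam width for the initial growth phase (1 = plain greedy)
    beam_depth: int = 8  # growth steps explored with the beam
    amp_max_factor: float = 2.0  # amplitude cap as multiple of the element reference
    subgrid: bool = True  # relax continuous sub-grid position offsets in refinement
    peel_retries: int = 8  # stall escapes per pass (drop weak atoms, regrow)
    peel_frac: float = 0.45  # fraction of the support dropped per peel

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.gn_max_iter < 1 or self.swap_max_rounds < 0:
            raise ValueError("solver budgets must be positive")
        if self.gn_tol <= 0 or self.cost_tol_rel <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass
class SparseSolution:
    """Per-element supports (flat grid indices) and their coefficients.

    Coefficients outside the supports are exactly zero; the dense coefficient
    vector of length M*T is available via :meth:`dense`.
    """

    supports: list[np.ndarray]
    coefficients: list[np.ndarray]
    cost: float
    n_sites: int
    log: dict = field(default_factory=dict)
    #: optional continuous positions (per element, (k, 3) angstrom) from the
    #: final sub-grid relaxation; each lies within its support site's cell
    positions: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.supports = [np.asarray(s, dtype=int).ravel() for s in self.supports]
        self.coefficients = [np.asarray(c, dtype=float).ravel() for c in self.coefficients]

    @property
    def n_elements(self) -> int:
        return len(self.supports)

    def support_sizes(self) -> list[int]:
        return [len(s) for s in self.supports]

    def n_nonzero(self) -> int:
        return int(sum(np.count_nonzero(c) for c in self.coefficients))

    def nonzero_per_element(self) -> list[int]:
        return [int(np.count_nonzero(c)) for c in self.coefficients]

    def dense(self) -> np.ndarray:
        x = np.zeros(self.n_elements * self.n_sites)
        for t, (s, c) in enumerate(zip(self.supports, self.coefficients)):
            x[t * self.n_sites + s] = c
        return x

    def to_molecule(self, grid: Grid3D, elements: Sequence[ElementSpec]) -> Molecule:
        """Render the solution as a molecule (grid sites -> angstrom), dropping
        zero-amplitude entries.  Element counts are relaxed to the recovered
        nonzero counts."""
        from .scatter import Atom

        atoms = []
        specs = []
        for t, e in enumerate(elements):
            keep = self.coefficients[t] > 0
            sites = self.supports[t][keep]
            amps = self.coefficients[t][keep]
            specs.append(e.with_count(int(keep.sum())))
            if self.positions is not None and len(self.positions[t]) == len(keep):
                pos = self.positions[t][keep]
            else:
                pos = grid.site_positions(sites)
            atoms.extend(Atom(specs[-1], p, a) for p, a in zip(pos, amps))
        return Molecule(specs, atoms)


# ---------------------------------------------------------------------------
# objective, gradient


def cost(x: np.ndarray, operator: SensingOperator, measurements: MeasurementSet) -> float:
    """f(x) = sum_l (|a_l^H x|^2 - C_l)^2 via the implicit operator."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != operator.shape[1]:
        raise ValueError(f"coefficient vector has size {x.size}, expected {operator.shape[1]}")
    F = operator.apply(x)
    r = np.abs(F) ** 2 - measurements.intensities
    return float(r @ r)


def gradient(
    x: np.ndarray, operator: SensingOperator, measurements: MeasurementSet
) -> np.ndarray:
    """Exact gradient of :func:`cost` w.r.t. the real coefficients.

    grad = 4 Re( A^H [ (|F|^2 - C) * F ] ) with F = A x.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != operator.shape[1]:
        raise ValueError(f"coefficient vector has size {x.size}, expected {operator.shape[1]}")
    F = operator.apply(x)
    w = (np.abs(F) ** 2 - measurements.intensities) * F
    g = np.concatenate(
        [
            4.0 * operator.adjoint_real_block(w, t).ravel()
            for t in range(operator.n_elements)
        ]
    )
    return g


def _amp_bounds(
    operator: SensingOperator, support: "Sequence[tuple[int, int]]", config: SolverConfig
) -> np.ndarray:
    """Per-coefficient amplitude upper bounds: the element's reference
    charge-density amplitude times ``config.amp_max_factor``.  Bounding the
    amplitudes encodes that the per-element core-electron density is known
    up to a modest factor; without it, clusters of small spheres with huge
    amplitudes can forge the signature of any other structure."""
    return np.array(
        [config.amp_max_factor * operator.elements[t].amplitude for t, _ in support]
    )


def _field(cols: np.ndarray, z: np.ndarray) -> np.ndarray:
    return cols @ z if z.size else np.zeros(cols.shape[0], dtype=complex)


def _cost_sparse(cols: np.ndarray, z: np.ndarray, C: np.ndarray) -> float:
    r = np.abs(_field(cols, z)) ** 2 - C
    return float(r @ r)


def _best_1d_step(F0: np.ndarray, col: np.ndarray, C: np.ndarray) -> float:
    """Exact line search for f(x + alpha * e_new) along one new column.

    The objective is quartic in alpha; its derivative is a cubic solved in
    closed form.  Returns the best alpha >= 0.
    """
    I0 = np.abs(F0) ** 2
    p = I0 - C
    q = 2.0 * np.real(np.conj(F0) * col)
    s = np.abs(col) ** 2
    c3 = 2.0 * np.sum(s * s)
    c2 = 3.0 * np.sum(q * s)
    c1 = np.sum(q * q + 2.0 * p * s)
    c0 = np.sum(p * q)
    if c3 <= 0:
        return 0.0
    roots = np.roots([c3, c2, c1, c0])
    cands = [0.0] + [float(r.real) for r in roots if abs(r.imag) < 1e-9 * (1 + abs(r)) and r.real > 0]
    costs = [np.sum((p + a * q + a * a * s) ** 2) for a in cands]
    return cands[int(np.argmin(costs))]


def _cubic_real_roots(b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Real roots of t^3 + b t^2 + c t + d = 0, vectorized; NaN-padded (n, 3)."""
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    d = np.asarray(d, float)
    p = c - b * b / 3.0
    q = 2.0 * b**3 / 27.0 - b * c / 3.0 + d
    roots = np.full(b.shape + (3,), np.nan)
    disc = -(4.0 * p**3 + 27.0 * q**2)
    three = disc > 0
    if np.any(three):
        pt, qt = p[three], q[three]
        m = 2.0 * np.sqrt(-pt / 3.0)
        th = np.arccos(np.clip(3.0 * qt / (pt * m), -1.0, 1.0)) / 3.0
        for k in range(3):
            roots[three, k] = m * np.cos(th - 2.0 * np.pi * k / 3.0)
    one = ~three
    if np.any(one):
        po, qo = p[one], q[one]
        s = np.sqrt(np.maximum(qo**2 / 4.0 + po**3 / 27.0, 0.0))
        roots[one, 0] = np.cbrt(-qo / 2.0 + s) + np.cbrt(-qo / 2.0 - s)
    return roots - b[..., None] / 3.0


def site_gains(
    operator: SensingOperator,
    t: int,
    F: np.ndarray,
    C: np.ndarray,
    amp_cap: float | None = None,
) -> np.ndarray:
    """Exact cost decrease of the best non-negative single-site addition, for
    every site of element block t.

    For each site the objective along one new column is a quartic in the
    added amplitude; its minimizer is a cubic root.  All per-site cubic
    coefficients reduce to three adjoint-style contractions (two with the
    plain columns, one with the squared columns), so the whole block is
    scored with dense BLAS.  This replaces gradient-magnitude scoring, which
    ignores the sign constraint and the curvature of the quartic.
    """
    u = operator.radial[:, t]
    I0 = np.abs(F) ** 2
    p_res = I0 - C
    S2 = float(np.sum(u**4))
    if S2 <= 0:
        return np.zeros(operator.n_sites)
    Sps = float(np.sum(p_res * u * u))
    Spq = 2.0 * operator.adjoint_real_block(p_res * F, t, fast=True).ravel()
    Sqs = 2.0 * operator.adjoint_real_block((u * u) * F, t, fast=True).ravel()
    Sqq = 2.0 * float(np.sum(u * u * I0)) + 2.0 * operator.adjoint2_real_block(
        F * F, t, fast=True
    ).ravel()
    a3 = 2.0 * S2
    a2 = 3.0 * Sqs
    a1 = Sqq + 2.0 * Sps
    a0 = Spq
    roots = _cubic_real_roots(a2 / a3, a1 / a3, a0 / a3)
    gains = np.zeros(operator.n_sites)
    for k in range(3):
        a = roots[:, k]
        valid = np.isfinite(a) & (a > 0)
        av = np.where(valid, a, 0.0)
        if amp_cap is not None:
            av = np.minimum(av, amp_cap)
        # h(alpha) - h(0) integrated from the cubic derivative
        dh = 2.0 * (a0 * av + a1 * av**2 / 2.0 + a2 * av**3 / 3.0 + a3 * av**4 / 4.0)
        gains = np.maximum(gains, np.where(valid, -dh, 0.0))
    return gains


# ---------------------------------------------------------------------------
# damped Gauss-Newton on a fixed support


def gauss_newton_refine(
    support: Sequence[tuple[int, int]],
    x0: np.ndarray,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    cols: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Damped Gauss-Newton on the coefficients of a fixed support.

    Armijo backtracking (factor 0.5, up to 20 halvings) on the quartic
    objective; negative coefficients are projected to zero after every step;
    a singular Gauss-Newton system falls back to a steepest-descent step.
    Returns (refined coefficients, cost); the cost never exceeds cost(x0).
    """
    C = measurements.intensities
    if cols is None:
        cols = operator.columns(list(support))
    ub = _amp_bounds(operator, list(support), config)
    z = np.clip(np.asarray(x0, dtype=float).ravel().copy(), 0.0, ub)
    if z.size == 0:
        return z, float(C @ C)
    f = _cost_sparse(cols, z, C)
    for _ in range(config.gn_max_iter):
        F = cols @ z
        r = np.abs(F) ** 2 - C
        J = 2.0 * np.real(np.conj(F)[:, None] * cols)  # (L, k)
        g = 2.0 * (J.T @ r)
        JtJ = J.T @ J
        damp = 1e-12 * (np.trace(JtJ) + 1.0)
        try:
            delta = np.linalg.solve(JtJ + damp * np.eye(z.size), -0.5 * g)
        except np.linalg.LinAlgError:
            delta = -g
        if not np.all(np.isfinite(delta)) or g @ delta >= 0:
            delta = -g  # steepest-descent fallback (non-descent GN direction)
            if g @ delta >= 0:
                break
        alpha, accepted = 1.0, False
        for _ in range(20):
            z_new = np.clip(z + alpha * delta, 0.0, ub)
            f_new = _cost_sparse(cols, z_new, C)
            if f_new < f:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        rel_drop = (f - f_new) / max(f, 1e-300)
        z, f = z_new, f_new
        if rel_drop < config.gn_tol:
            break
    return z, f


def subgrid_refine(
    supports: list[list[int]],
    z: np.ndarray,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    max_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint Gauss-Newton over amplitudes and sub-grid position offsets.

    The scattering potential is grid-free: atoms sit at continuous
    positions, and restricting them to lattice sites leaves a discretization
    misfit floor large enough to hide the true structure among spurious
    fits.  Each supported atom therefore carries a continuous offset bounded
    to its own grid cell (so the support site remains its nearest site);
    relaxing the offsets drives the cost of a correct support towards zero
    while structurally wrong supports stay at the misfit floor, which is
    what makes greedy cost comparisons informative.

    Returns (amplitudes, offsets (k, 3), cost).
    """
    sup = [(t, m) for t in range(len(supports)) for m in supports[t]]
    k = len(sup)
    C = measurements.intensities
    if k == 0:
        return np.zeros(0), np.zeros((0, 3)), float(C @ C)
    freqs = operator.sampling.frequencies
    grid = operator.grid
    q = np.array([grid.site_positions(np.array([m]))[0] for _, m in sup])
    u = np.stack([operator.radial[:, t] for t, _ in sup], axis=1)  # (L, k)
    ub = _amp_bounds(operator, sup, config)
    bound = 0.4999 * grid.spacing
    amps = np.clip(np.asarray(z, dtype=float).copy(), 0.0, ub)
    offs = np.zeros((k, 3))

    def model(amps, offs):
        E = np.exp(-1j * (freqs @ (q + offs).T))  # (L, k)
        cols = u * E
        return cols, cols @ amps

    cols, F = model(amps, offs)
    r = np.abs(F) ** 2 - C
    f = float(r @ r)
    for _ in range(max_iter):
        base = 2.0 * np.conj(F)[:, None] * cols  # d|F|^2 precursor
        Jc = np.real(base)  # w.r.t. amplitudes
        Jd = np.empty((len(C), 3 * k))
        for ax in range(3):
            Jd[:, ax::3] = np.real(base * (-1j) * freqs[:, ax : ax + 1]) * amps[None, :]
        J = np.concatenate([Jc, Jd], axis=1)
        g = 2.0 * (J.T @ r)
        JtJ = J.T @ J
        damp = 1e-10 * (np.trace(JtJ) + 1.0)
        try:
            delta = np.linalg.solve(JtJ + damp * np.eye(J.shape[1]), -0.5 * g)
        except np.linalg.LinAlgError:
            delta = -g
        if not np.all(np.isfinite(delta)) or g @ delta >= 0:
            delta = -g
            if g @ delta >= 0:
                break
        step, accepted = 1.0, False
        for _ in range(16):
            amps_n = np.clip(amps + step * delta[:k], 0.0, ub)
            offs_n = np.clip(
                offs + step * delta[k:].reshape(k, 3), -bound, bound
            )
            cols_n, F_n = model(amps_n, offs_n)
            r_n = np.abs(F_n) ** 2 - C
            f_n = float(r_n @ r_n)
            if f_n < f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_drop = (f - f_n) / max(f, 1e-300)
        amps, offs, cols, F, r, f = amps_n, offs_n, cols_n, F_n, r_n, f_n
        if rel_drop < config.gn_tol:
            break
    return amps, offs, f


# ---------------------------------------------------------------------------
# internal solver state


class _State:
    """Mutable solver state: per-element supports, aligned coefficients,
    cached columns and cost."""

    def __init__(self, operator: SensingOperator, measurements: MeasurementSet):
        self.op = operator
        self.C = measurements.intensities
        self.meas = measurements
        T = operator.n_elements
        self.supports: list[list[int]] = [[] for _ in range(T)]
        self.coeffs: list[np.ndarray] = [np.zeros(0) for _ in range(T)]
        self.cost = float(self.C @ self.C)

    def support_list(self) -> list[tuple[int, int]]:
        return [(t, m) for t in range(self.op.n_elements) for m in self.supports[t]]

    def z(self) -> np.ndarray:
        return np.concatenate(self.coeffs) if self.coeffs else np.zeros(0)

    def set(self, supports, z, cost_val):
        self.supports = [list(s) for s in supports]
        sizes = [len(s) for s in self.supports]
        splits = np.cumsum(sizes)[:-1]
        self.coeffs = [np.asarray(c, dtype=float) for c in np.split(np.asarray(z, dtype=float), splits)]
        self.cost = float(cost_val)

    def field(self) -> np.ndarray:
        sup = self.support_list()
        if not sup:
            return np.zeros(self.op.n_detectors, dtype=complex)
        return self.op.columns(sup) @ self.z()

    def block_gradient(self, t: int, F: np.ndarray) -> np.ndarray:
        """Gradient of the cost restricted to element block t, flat (M,)."""
        w = (np.abs(F) ** 2 - self.C) * F
        return 4.0 * self.op.adjoint_real_block(w, t).ravel()

    def solution(self) -> SparseSolution:
        return SparseSolution(
            supports=[np.array(s, dtype=int) for s in self.supports],
            coefficients=[c.copy() for c in self.coeffs],
            cost=self.cost,
            n_sites=self.op.n_sites,
        )


def _state_from_solution(
    sol: SparseSolution,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig | None = None,
) -> _State:
    st = _State(operator, measurements)
    st.set(
        [list(s) for s in sol.supports],
        np.concatenate(sol.coefficients) if sol.coefficients else np.zeros(0),
        sol.cost,
    )
    # recompute the cost only when the stored value is unknown; commits
    # always store the sub-grid-relaxed cost the trials are scored with
    sup = st.support_list()
    if np.isfinite(sol.cost):
        return st
    if not sup:
        st.cost = float(st.C @ st.C)
    elif config is not None and config.subgrid:
        _, _, st.cost = subgrid_refine(st.supports, st.z(), operator, measurements, config)
    else:
        cols = operator.columns(sup)
        st.cost = _cost_sparse(cols, st.z(), st.C)
    return st


def _argmax_jitter(scores: np.ndarray, rng: np.random.Generator | None) -> int:
    """Deterministic argmax with optional uniform 1e-12 tie-breaking jitter."""
    if rng is not None and scores.size:
        finite = scores[np.isfinite(scores)]
        scale = float(np.max(np.abs(finite))) if finite.size else 1.0
        scores = scores + rng.uniform(0.0, 1e-12 * (scale + 1.0), size=scores.shape)
    return int(np.argmax(scores))


def _candidates(
    scores: np.ndarray,
    n: int,
    pool: int,
    rng: np.random.Generator | None,
    explore: bool,
) -> list[int]:
    """Top-score candidate indices; exploring restarts keep the greedy best
    and sample the remainder uniformly from the top-``pool`` (GRASP-style)."""
    order = np.argsort(scores)[::-1]
    order = [int(i) for i in order[: max(pool, n)] if np.isfinite(scores[i])]
    if not order:
        return []
    if rng is None or not explore or len(order) <= n:
        return order[:n]
    rest = order[1:pool]
    k = min(n - 1, len(rest))
    picks = [int(p) for p in rng.choice(rest, size=k, replace=False)] if k else []
    return [order[0]] + picks


def _refine_trial(
    st: _State,
    supports: list[list[int]],
    z0: np.ndarray,
    config: SolverConfig,
) -> tuple[np.ndarray, float]:
    sup = [(t, m) for t in range(len(supports)) for m in supports[t]]
    cols = st.op.columns(sup)
    return gauss_newton_refine(sup, z0, st.op, st.meas, config, cols=cols)


# ---------------------------------------------------------------------------
# greedy support growth and index swapping


def _growth_trials(
    st: _State,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    rng: np.random.Generator | None,
    explore: bool,
) -> list[tuple[float, list[list[int]], np.ndarray]]:
    """Refined single-atom additions for every eligible element: a list of
    (cost, supports, coefficients) trials.  Empty when all caps are full."""
    caps = [e.count for e in operator.elements]
    eligible = [t for t in range(operator.n_elements) if len(st.supports[t]) < caps[t]]
    if not eligible:
        return []
    F = st.field()
    empty_model = not np.any(np.abs(F))
    trials = []
    for t in eligible:
        if empty_model:
            # The quartic objective has an exactly zero gradient at x = 0 and
            # the intensity is translation invariant, so every site is an
            # equivalent first choice; seed at the grid centre (most room for
            # the rest of the structure to grow).
            grid = operator.grid
            center = grid.origin + grid.spacing * (np.array(grid.shape) - 1) / 2.0
            d2 = np.sum((grid.all_positions() - center) ** 2, axis=1)
            scores = -d2
        else:
            scores = site_gains(
                operator, t, F, st.C,
                amp_cap=config.amp_max_factor * operator.elements[t].amplitude,
            )
        if st.supports[t]:
            scores[np.asarray(st.supports[t], dtype=int)] = -np.inf
        n_cand = 1 if empty_model else config.branch
        for k in _candidates(scores, n_cand, config.pool, rng, explore):
            new_supports = [list(s) for s in st.supports]
            new_supports[t] = new_supports[t] + [k]
            new_col = operator.columns([(t, k)])[:, 0]
            alpha = _best_1d_step(F, new_col, st.C)
            if rng is not None:
                alpha *= rng.uniform(0.5, 1.5)
            # insert the new coefficient at the end of block t
            z0_parts = [st.coeffs[s].copy() for s in range(operator.n_elements)]
            z0_parts[t] = np.concatenate([z0_parts[t], [max(alpha, 0.0)]])
            z0 = np.concatenate(z0_parts)
            z, f = _refine_trial(st, new_supports, z0, config)
            trials.append((f, new_supports, z))
    return trials


def _signature(supports: list[list[int]]) -> tuple:
    return tuple(tuple(sorted(s)) for s in supports)


def _beam_grow(
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    caps: list[int],
    rng: np.random.Generator,
    explore: bool,
) -> SparseSolution:
    """Beam search over the first ``config.beam_depth`` growth steps.

    Early (mostly heavy-atom) placements are where the greedy commits its
    irreversible mistakes; a modest beam of distinct partial supports,
    ranked by the sub-grid-relaxed cost, explores alternatives there.  The
    best member is returned once every member reaches the depth or its caps,
    and plain greedy growth finishes the structure.
    """
    beam = [_State(operator, measurements).solution()]
    depth = 0
    while depth < config.beam_depth:
        is_done = [all(len(sup) >= c for sup, c in zip(s.supports, caps)) for s in beam]
        done = [s for s, d in zip(beam, is_done) if d]
        todo = [s for s, d in zip(beam, is_done) if not d]
        if not todo:
            break
        raw: dict[tuple, tuple[float, list[list[int]], np.ndarray]] = {}
        for sol in todo:
            st = _state_from_solution(sol, operator, measurements, config)
            for f, sup, z in _growth_trials(st, operator, measurements, config, rng, explore):
                sig = _signature(sup)
                if sig not in raw or f < raw[sig][0]:
                    raw[sig] = (f, sup, np.asarray(z))
        # relax the most promising expansions; rank the beam by relaxed cost
        st0 = _State(operator, measurements)
        ranked_raw = sorted(raw.values(), key=lambda tr: tr[0])[: 2 * config.beam]
        scored: list[tuple[float, list[list[int]], np.ndarray]] = []
        for f, sup, z in ranked_raw:
            if config.subgrid:
                amps, _, f = subgrid_refine(sup, z, operator, measurements, config)
            else:
                amps = z
            scored.append((f, sup, amps))
        scored.sort(key=lambda tr: tr[0])
        beam = [s for s in done]
        for f, sup, amps in scored[: config.beam]:
            sizes = [len(x) for x in sup]
            splits = np.cumsum(sizes)[:-1]
            beam.append(
                SparseSolution(
                    supports=[np.array(x, dtype=int) for x in sup],
                    coefficients=[np.asarray(c) for c in np.split(np.asarray(amps), splits)],
                    cost=f,
                    n_sites=operator.n_sites,
                )
            )
        beam = sorted(beam, key=lambda s: s.cost)[: config.beam]
        depth += 1
    return min(beam, key=lambda s: s.cost)


def _relax_best(
    trials: list[tuple[float, list[list[int]], np.ndarray]],
    st: _State,
    config: SolverConfig,
    top: int = 3,
) -> tuple[float, list[list[int]], np.ndarray]:
    """Sub-grid-relax the ``top`` lowest (amplitude-refined) trials and
    return the overall best as (relaxed cost, supports, amplitudes)."""
    trials = sorted(trials, key=lambda tr: tr[0])
    if not config.subgrid:
        return trials[0]
    best = None
    for f, sup, z in trials[: max(1, top)]:
        amps, _, f_rel = subgrid_refine(sup, z, st.op, st.meas, config)
        if best is None or f_rel < best[0]:
            best = (f_rel, sup, amps)
    return best


def support_update(
    solution: SparseSolution,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    rng: np.random.Generator | None = None,
    explore: bool = False,
) -> tuple[SparseSolution, bool]:
    """One greedy support-growth step.

    For every element below its stoichiometric cap, trial-add up to
    ``config.branch`` off-support sites with the largest absolute gradient
    entries, refine each by Gauss-Newton, and commit the single
    (element, site) trial that minimizes the cost.  Returns (solution,
    changed); a no-op (all elements at capacity) sets changed=False.
    """
    st = _state_from_solution(solution, operator, measurements, config)
    trials = _growth_trials(st, operator, measurements, config, rng, explore)
    if not trials:
        return solution, False
    f, new_supports, z = _relax_best(trials, st, config)
    old_supports = list(st.supports)
    if f <= st.cost:
        st.set(new_supports, z, f)
    else:
        # adding a site at zero amplitude keeps old coefficients and cost;
        # guarantees the committed cost never increases
        grown = [
            np.concatenate([st.coeffs[t], [0.0]])
            if len(new_supports[t]) > len(old_supports[t])
            else st.coeffs[t].copy()
            for t in range(operator.n_elements)
        ]
        st.set(new_supports, np.concatenate(grown) if grown else np.zeros(0), st.cost)
    return st.solution(), True


def index_swap(
    solution: SparseSolution,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    rng: np.random.Generator | None = None,
    explore: bool = False,
) -> tuple[SparseSolution, bool]:
    """One round of correlation-aware index swapping.

    Per element: zero the smallest-|coefficient| support site, recompute that
    element's gradient at the reduced model, and trial-swap in the
    largest-|gradient| off-support site; commit the best swap across elements
    only if it strictly decreases the cost.  Returns (solution, improved).
    """
    st = _state_from_solution(solution, operator, measurements, config)
    swap_trials: list[tuple[float, list[list[int]], np.ndarray]] = []
    for t in range(operator.n_elements):
        if not st.supports[t]:
            continue
        out_locals = np.argsort(np.abs(st.coeffs[t]))[: config.swap_branch]
        scores_cache: np.ndarray | None = None
        for local in out_locals:
            out_site = st.supports[t][int(local)]
            red_supports = [list(s) for s in st.supports]
            red_supports[t] = [m for m in red_supports[t] if m != out_site]
            red_coeffs = [c.copy() for c in st.coeffs]
            red_coeffs[t] = np.delete(red_coeffs[t], int(local))
            sup_red = [(tt, m) for tt in range(len(red_supports)) for m in red_supports[tt]]
            cols_red = operator.columns(sup_red)
            z_red = np.concatenate(red_coeffs)
            F_red = _field(cols_red, z_red)
            # score AFTER zeroing the out-index: the sphere columns are
            # correlated, so candidate gains must come from the reduced model.
            # The map is computed for the weakest out-candidate and reused for
            # the rest (a selection heuristic, not a cost).
            if scores_cache is None:
                scores_cache = site_gains(
                    operator, t, F_red, st.C,
                    amp_cap=config.amp_max_factor * operator.elements[t].amplitude,
                )
            scores = scores_cache.copy()
            scores[np.asarray(st.supports[t], dtype=int)] = -np.inf  # exclude original support
            for k in _candidates(scores, config.swap_branch, config.pool, rng, explore):
                new_supports = [list(s) for s in red_supports]
                new_supports[t] = new_supports[t] + [k]
                new_col = operator.columns([(t, k)])[:, 0]
                alpha = _best_1d_step(F_red, new_col, st.C)
                if rng is not None:
                    alpha *= rng.uniform(0.5, 1.5)
                z0_parts = [red_coeffs[s].copy() for s in range(operator.n_elements)]
                z0_parts[t] = np.concatenate([z0_parts[t], [max(alpha, 0.0)]])
                z0 = np.concatenate(z0_parts)
                z, f = _refine_trial(st, new_supports, z0, config)
                swap_trials.append((f, new_supports, z))
    if not swap_trials:
        return solution, False
    f, new_supports, z = _relax_best(swap_trials, st, config)
    if f < st.cost * (1.0 - 1e-14) and f < st.cost:
        st.set(new_supports, z, f)
        return st.solution(), True
    return solution, False




def _grow_and_polish(
    sol: SparseSolution,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    caps: list[int],
    rng: np.random.Generator,
    explore: bool,
    cost_tol: float,
    traj: list[float],
) -> SparseSolution:
    """Grow the support to the stoichiometric caps (with interleaved swap
    rounds every ``swap_every`` additions), then swap until stalled."""
    added = 0
    while any(len(s) < c for s, c in zip(sol.supports, caps)):
        sol, changed = support_update(sol, operator, measurements, config, rng, explore=explore)
        traj.append(sol.cost)
        if not changed:
            break
        added += 1
        if config.swap_every and added % config.swap_every == 0:
            sol, improved = index_swap(sol, operator, measurements, config, rng, explore=explore)
            if improved:
                traj.append(sol.cost)
    rounds = 0
    while sol.cost > cost_tol and rounds < config.swap_max_rounds:
        sol, improved = index_swap(sol, operator, measurements, config, rng, explore=explore)
        rounds += 1
        if not improved:
            break
        traj.append(sol.cost)
    return sol


def _peel(
    sol: SparseSolution, frac: float, rng: np.random.Generator, uniform: bool = False
) -> SparseSolution:
    """Remove about ``frac`` of the supported atoms to restart growth.

    Two alternating strategies: sample from the smallest-amplitude half
    (weak atoms are usually the misplaced ones), or uniformly across the
    whole support (the only way a confidently wrong heavy atom ever gets
    evicted)."""
    entries = [
        (t, i, abs(c))
        for t in range(sol.n_elements)
        for i, c in enumerate(sol.coefficients[t])
    ]
    if not entries:
        return sol
    total = len(entries)
    k = max(2, int(round(frac * total)))
    k = min(k, total)
    entries.sort(key=lambda e: e[2])
    pool = entries if uniform else entries[: max(k, (total + 1) // 2)]
    sel = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    drop = {(pool[int(i)][0], pool[int(i)][1]) for i in sel}
    supports, coeffs = [], []
    for t in range(sol.n_elements):
        keep = [i for i in range(len(sol.supports[t])) if (t, i) not in drop]
        supports.append(sol.supports[t][keep])
        coeffs.append(sol.coefficients[t][keep])
    return SparseSolution(
        supports=supports, coefficients=coeffs, cost=np.inf, n_sites=sol.n_sites
    )


def _activate_zeros(
    sol: SparseSolution,
    operator: SensingOperator,
    measurements: MeasurementSet,
    config: SolverConfig,
    rng: np.random.Generator | None,
) -> SparseSolution:
    """Relocate support sites whose refined amplitude collapsed to zero.

    A zero coefficient means the site explains nothing where it sits; as
    long as the residual is nonzero some single-site addition still lowers
    the cost, so each dead entry is re-tried at the best-gain sites of its
    element and moved there when that strictly improves the fit."""
    st = _state_from_solution(sol, operator, measurements, config)
    changed = False
    for t in range(operator.n_elements):
        for local in range(len(st.coeffs[t])):
            if st.coeffs[t][local] > 0:
                continue
            red_supports = [list(s) for s in st.supports]
            dead = red_supports[t].pop(local)
            red_coeffs = [c.copy() for c in st.coeffs]
            red_coeffs[t] = np.delete(red_coeffs[t], local)
            sup_red = [(tt, m) for tt in range(len(red_supports)) for m in red_supports[tt]]
            F_red = _field(operator.columns(sup_red), np.concatenate(red_coeffs))
            scores = site_gains(
                operator, t, F_red, st.C,
                amp_cap=config.amp_max_factor * operator.elements[t].amplitude,
            )
            scores[np.asarray(st.supports[t], dtype=int)] = -np.inf
            trials = []
            for k in _candidates(scores, config.branch, config.pool, rng, False):
                new_supports = [list(s) for s in red_supports]
                new_supports[t] = new_supports[t] + [k]
                col = operator.columns([(t, k)])[:, 0]
                alpha = max(_best_1d_step(F_red, col, st.C), 0.0)
                z0_parts = [red_coeffs[s].copy() for s in range(operator.n_elements)]
                z0_parts[t] = np.concatenate([z0_parts[t], [alpha]])
                z, f = _refine_trial(st, new_supports, np.concatenate(z0_parts), config)
                trials.append((f, new_supports, z))
            if trials:
                f, new_supports, z = _relax_best(trials, st, config)
                if f < st.cost and np.concatenate(z if isinstance(z, list) else [z]).size:
                    st.set(new_supports, z, f)
                    changed = True
    return st.solution() if changed else sol


# ---------------------------------------------------------------------------
# full solve


def solve(
    operator: SensingOperator,
    measurements: MeasurementSet,
    elements: Sequence[ElementSpec] | None = None,
    config: SolverConfig | None = None,
) -> SparseSolution:
    """Run the full stoichiometry-constrained GESPAR solver.

    ``config.restarts`` independent seeded passes each grow the support from
    empty until every element reaches its cap, then run index-swap rounds
    while they improve (bounded by ``swap_max_rounds``); the lowest-cost
    solution over all passes is returned, with per-pass cost trajectories in
    ``solution.log``.
    """
    if elements is not None:
        if [e.symbol for e in elements] != [e.symbol for e in operator.elements]:
            raise ValueError("element dictionary does not match the sensing operator")
        caps = [e.count for e in elements]
    else:
        caps = [e.count for e in operator.elements]
    if sum(caps) < 1:
        raise ValueError("at least one atom is required (sum of element counts >= 1)")

    C = measurements.intensities
    cost_tol = (config or SolverConfig()).cost_tol_rel * float(C @ C)
    config = config or SolverConfig()

    best: SparseSolution | None = None
    logs = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.restarts)
    for p in range(config.restarts):
        rng = np.random.default_rng(children[p])
        st = _State(operator, measurements)
        sol = st.solution()
        traj = [sol.cost]
        if sol.cost <= cost_tol:  # degenerate all-zero measurements
            logs.append({"pass": p, "costs": traj, "stopped": "trivial"})
            best = sol if best is None or sol.cost < best.cost else best
            continue
        if config.beam > 1:
            sol = _beam_grow(operator, measurements, config, caps, rng, explore=p > 0)
            traj.append(sol.cost)
        sol = _grow_and_polish(
            sol, operator, measurements, config, caps, rng, explore=p > 0,
            cost_tol=cost_tol, traj=traj,
        )
        # peel-back retries: escape stalls by dropping the least-confident
        # atoms and regrowing with randomized candidates
        from dataclasses import replace as _replace

        retry_cfg = _replace(config, swap_max_rounds=min(3, config.swap_max_rounds))
        stale = 0
        for retry in range(config.peel_retries):
            if sol.cost <= cost_tol or stale >= 4:
                break
            peeled = _peel(sol, config.peel_frac, rng, uniform=retry % 2 == 1)
            cand = _grow_and_polish(
                peeled, operator, measurements, retry_cfg, caps, rng, explore=True,
                cost_tol=cost_tol, traj=traj,
            )
            if cand.cost < sol.cost:
                sol = cand
                stale = 0
            else:
                stale += 1
        # deep swap polish on the retained solution: every support site is
        # an eviction candidate, so a single confidently-wrong atom that is
        # not among the weakest amplitudes can still be fixed
        from dataclasses import replace as _replace2

        deep_cfg = _replace2(config, swap_branch=max(caps))
        rounds = 0
        while sol.cost > cost_tol and rounds < config.swap_max_rounds:
            sol, improved = index_swap(sol, operator, measurements, deep_cfg, rng, explore=p > 0)
            rounds += 1
            if not improved:
                break
            traj.append(sol.cost)
        sol = _activate_zeros(sol, operator, measurements, config, rng)
        logs.append(
            {"pass": p, "costs": traj, "supports": [list(map(int, s)) for s in sol.supports]}
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= cost_tol:
            break
    if config.subgrid and any(len(s) for s in best.supports):
        for _ in range(3):
            amps, offs, f = subgrid_refine(
                [list(s) for s in best.supports], np.concatenate(best.coefficients),
                operator, measurements, config, max_iter=80,
            )
            sizes = [len(s) for s in best.supports]
            splits = np.cumsum(sizes)[:-1]
            best.coefficients = [np.asarray(c) for c in np.split(amps, splits)]
            sites = [(t, m) for t in range(len(best.supports)) for m in best.supports[t]]
            q = np.array([operator.grid.site_positions(np.array([m]))[0] for _, m in sites])
            pos = q + offs
            best.positions = [p for p in np.split(pos, splits)]
            best.cost = f
            if all(np.all(c > 0) for c in best.coefficients):
                break
            # dead sites (amplitude clipped to zero) are relocated to the
            # best-gain sites of their element, then the fit is re-polished
            rng_fin = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
            relocated = _activate_zeros(best, operator, measurements, config, rng_fin)
            if relocated.cost >= best.cost and relocated.n_nonzero() <= best.n_nonzero():
                break
            relocated.positions = None
            best = relocated
    best.log = {"passes": logs, "cost_tol": cost_tol}
    return best
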