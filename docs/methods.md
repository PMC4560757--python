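# Methods

## The model

A molecule is represented as a sum of element-specific uniform balls
("hovering spheres"): the scattering potential is

    f(r) = sum_j sum_n  c_n^j  U_j(|r - r_n^j|),

where `U_j` is the unit ball of element *j*'s covalent radius `R_j`, the
centre positions `r_n^j` are continuous (never grid-restricted), and the
non-negative amplitudes `c_n^j` model the core-electron charge density that
scatters hard X-rays.  The chemical composition is assumed known: element
*j* contributes exactly `S_j` atoms (stoichiometry), which is the hard
sparsity constraint that makes single-shot 3D recovery tractable.

A monochromatic plane wave incident along +z scatters elastically; to first
order the far-field intensity is the squared magnitude of the 3D Fourier
transform of `f` sampled on the Ewald sphere,

    I(theta, phi) = | F(nu) |^2,   nu = (2*pi/lambda) (sin t cos p, sin t sin p, cos t - 1),

with `|nu| = (4*pi/lambda) sin(t/2)`.  The ball transform has the closed
form `U_hat(nu) = 4*pi (sin(nu R) - nu R cos(nu R)) / nu^3`; below
`nu R < 1e-4` a series expansion replaces it to avoid cancellation.  The
overall proportionality constant is fixed to 1: the simulator and the
solver share the forward model, so all comparisons are scale-consistent.

Two exact symmetries matter throughout: the intensity is invariant under
rigid translation of the molecule, and (because `f` is real) under point
inversion.  A reconstruction is therefore only defined modulo those
transforms, and the error metric registers them out (below).

## Detector model and noise

Detectors sit on the Ewald sphere between a beamstop angle `theta_min`
(default 2 deg; the direct beam saturates smaller angles) and an aperture
`theta_max`.  The default layout spaces polar rings uniformly in
cos(theta) ("equal solid angle") so each sample owns an equal patch of the
sphere; a uniform-in-theta layout is available (`layout="equiangular"`) but
concentrates both samples and the least-squares weight in the small-angle
lobe, which measurably degrades the solver's candidate ranking.

At hard-X-ray wavelengths almost all usable signal lives in the forward
cone: the sphere form factors decay like `nu^-2`, so samples beyond
`nu ~ 2*pi / (1 A)` are essentially empty.  The performance-study
configuration therefore uses `theta <= 30 deg` at `lambda = 0.35 A`
(frequency reach 9.3 rad/A, i.e. 0.34 A half-period resolution) with 24
polar x 96 azimuthal samples; the azimuthal density is what Nyquist-samples
the intensity oscillations of a ~6-7 A molecule — with 3-4x fewer azimuthal
samples, structurally wrong molecules reproduce the data to within the
discretization floor and the inverse problem loses identifiability.

Noise is zero-mean white Gaussian added to the intensities, distributed
uniformly over the sphere.  The level `N` is the fraction of the noise
power `E[n^2]` to the total signal power, where total signal power is the
area-weighted mean intensity over the FULL sphere, including the
beamstop-masked low-angle region that carries most of the energy.  This
normalization makes the quoted `N` look small while the effective
per-sample noise at structure-carrying angles is substantial: at `N = 1e-3`
the per-hydrogen interference terms are comparable to the noise floor, so
hydrogens are the first atoms to misplace as noise grows.  (The alternative
reading — normalizing by the mean *squared* intensity — makes the
`N = 1e-3` operating point unrecoverable by orders of magnitude and is
inconsistent with the reported behaviour, so it was rejected.)
Negative noisy intensities are kept: clipping would bias the power
calibration, and the solver's quartic cost tolerates them.

## The inverse problem and the solver

On a candidate grid of `M` sites repeated for `T` elements, the unknowns
form a non-negative vector `x` (length `M*T`) with per-element supports
capped at `S_j`.  The sensing operator has columns
`U_hat_j(|nu_l|) exp(-i nu_l . q_m)` and is applied implicitly through
separable BLAS contractions (it is never materialized for large grids).
The objective is the quartic least squares

    f(x) = sum_l ( |a_l^H x|^2 - C_l )^2 ,

whose exact gradient is `4 Re(A^H[(|Ax|^2 - C) . Ax])`.

The solver is a stoichiometry-constrained greedy sparse phase-retrieval
search (GESPAR family) with the following stages:

* **Growth.**  Starting from the empty support (where the quartic gradient
  vanishes identically; the first atom is seeded at the grid centre, all
  translates being equivalent), each step trial-adds, for every element
  below its cap, a handful of candidate sites and commits the single trial
  with the lowest refined cost.  Candidates are ranked by the *exact
  single-site gain*: the closed-form optimum of the quartic along one new
  column (a cubic root), vectorized over all sites via three adjoint-style
  contractions (two with the plain columns, one with the squared columns,
  run in single precision).  Gradient-magnitude ranking — the textbook
  choice — ignores the sign constraint and the quartic curvature and was
  found to rank true sites far down the list.
* **Amplitude refinement.**  On a fixed support, damped Gauss-Newton with
  Armijo backtracking (factor 0.5, up to 20 halvings), negative
  coefficients projected to zero, singular systems falling back to steepest
  descent.  Amplitudes are additionally capped at `amp_max_factor` (default
  2) times the element's reference charge density: without the cap,
  clusters of small spheres with inflated amplitudes can forge the
  signature of any other structure and destroy identifiability.
* **Sub-grid relaxation.**  The spheres are physically off-grid, so a
  grid-locked fit has a misfit floor large enough to hide the true support
  among spurious ones.  After amplitude refinement, a joint Gauss-Newton
  over amplitudes and per-atom continuous offsets (each bounded to its own
  grid cell, so the support site remains the atom's nearest site) drives a
  correct support's cost towards zero while wrong supports stay at the
  floor.  All commit/compare decisions use this relaxed cost; only the
  best few amplitude-ranked trials are relaxed, for speed.
* **Index swapping.**  Per element: remove one of the smallest-amplitude
  support sites, recompute the gain map at the *reduced* model (the sphere
  columns are strongly correlated, so scores taken at the full model are
  meaningless), trial-insert the best off-support candidates, and commit
  the best strictly improving swap across elements, repeating while
  improving.  One swap round is interleaved into the growth every few
  additions, and a full swap phase runs after the caps are filled.
* **Peel-back restarts.**  When swapping stalls, a random subset of the
  support (~45%, alternating between the smallest-amplitude half and the
  whole support — the latter is the only way a confidently wrong heavy
  atom is ever evicted) is removed and the structure regrown with
  randomized candidate pools (GRASP-style).  Improvements are kept;
  several such basin hops run per pass.

The returned solution carries the grid supports, the refined amplitudes,
the final sub-grid positions, the relaxed cost and per-pass cost
trajectories.  Committed costs never increase within a pass; accepted
swaps decrease the cost strictly.

## Error metric and registration

Reconstruction quality is the correlation dissimilarity

    epsilon = 1 - <f_source, f_recovery> / (||f_source|| ||f_recovery||)

between the two structures rendered as voxel images of their sphere
potentials (uniform ball with a one-voxel linear edge, so off-grid centres
render smoothly).  `epsilon` lies in [0, 1] for non-negative images,
vanishes iff the images are proportional, and is invariant to global
amplitude rescaling.  Before scoring, the recovery is aligned over the
forward model's exact ambiguities — the best integer-voxel translation and
inversion found by FFT cross-correlation.  An atom is counted "misplaced"
when, after registration, it lies more than one grid unit from every true
atom of its element.

## Synthetic data generator

Random benchmark molecules place exactly the stoichiometric atom counts
uniformly in a cubic box with a minimum pairwise centre distance of 1 A
(the resolution of the study), by seeded rejection sampling; compositions
follow the threonine-like H:C:O:N = 9:4:3:1 ratio by largest remainder.
The generator emulates the geometry and composition statistics of small
organic molecules, not their chemistry: there are no bonds, no preferred
valences and no conformational preferences, so passing benchmarks show the
solver handles molecule-like sparsity and packing, not that it understands
chemistry.  The bundled 17-atom threonine-like fixture is a force-field
optimized synthetic conformer with the canonical 4 C / 1 N / 3 O / 9 H
stoichiometry.

## Scaled-down study conditions

Desk-scale defaults (full-scale values remain reachable through
configuration): recovery grid 41^3 at 0.2 A spacing (8.2 A box); detector
24 x 96 samples in the theta <= 30 deg cone; molecules in a 6.6 A box;
5 trials per benchmark condition; solver budgets of 1 restart, 8 swap
rounds and 8 peel retries.  At these budgets exact recovery of noiseless
on-grid instances is routine, and off-grid recovery at `N = 1e-3` is
reliable to roughly 5-10 atoms, degrading beyond — a smaller reach than
the full-scale configuration (finer grid, larger box, more measurements
and much larger search budgets), whose behaviour the scaled trends
reproduce qualitatively rather than point-by-point.

## HIO baselines

The classical baseline embeds the Ewald samples into a 3D FFT grid by
nearest-voxel gridding (mean magnitude per voxel, Hermitian-symmetrized)
and iterates standard hybrid input-output: magnitude replacement on the
constrained shell, inverse transform, and the feedback `x <- x - beta x'`
outside the support/positivity constraints (beta = 0.9).  With data only
on the thin Ewald shell of a 55^3 grid this fails, as expected for
voxel counts far beyond what shell data determine.  The sparsity-augmented
variant additionally projects each iterate onto the sphere dictionary:
matched-filter correlation per element, greedy selection of at most `S_j`
peaks with non-maximum suppression within one covalent radius, joint
least-squares amplitudes (clipped non-negative), and re-rendering; the
lowest-residual iterate is returned.  It improves markedly on plain HIO
and still falls short of the greedy sparse solver, which is the expected
ordering.

## Numerical choices and limitations

* Tie-breaks: equal candidate scores resolve to the lowest site index
  (deterministic under a fixed seed); exploring restarts add seeded
  uniform jitter and sample candidate pools.
* Degenerate inputs: all-zero measurements return the zero solution;
  elements at cap make the growth step a no-op; an empty recovery scores
  `epsilon = 1` and is flagged.
* The grid must be finer than the smallest covalent radius for sub-site
  resolution; a coarser demonstration grid is allowed with a warning.
* Determinism: every randomized stage draws an explicit seed; identical
  seeds give identical outputs (single-precision scoring contractions are
  deterministic).
* Known limitations: recovery reach at fixed desk-scale budgets is below
  the full-scale configuration's; the greedy search can stall on
  misfolded intermediate structures (the peel/swap machinery recovers
  many, not all); rotational multi-atom dictionaries (amino-acid building
  blocks) are out of scope, although the solver's dictionary interface
  does not preclude them.
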