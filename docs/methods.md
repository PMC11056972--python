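# Methods

## Model

The package implements multicomponent restricted Hartree–Fock for a system
of electrons plus a chosen subset of protons treated quantum mechanically
(NEO-RHF).  The total wave function is a single product of an electronic
closed-shell determinant and a protonic determinant; both species are
expanded in atom-centered Gaussian bases.  Assumptions inherited from this
ansatz:

* no electron–proton correlation (mean-field coupling only), which is
  known to over-localize protonic densities — energies are qualitative;
* electrons are closed-shell (even counts; a bare one-electron system is
  supported as a special case with the exact one-electron Fock operator);
* quantum nuclei are protons (mass 1836.15267343 m_e, CODATA);
  heavier/isotopic quantum nuclei would only require a different mass but
  are not exposed in v1;
* multiple quantum protons occupy distinct spatial orbitals and interact
  through Coulomb only.  Same-species proton exchange is omitted (standard
  practice for spatially separated protons); consequently the mean-field
  J_pp is kept as-is for ≥ 2 protons and dropped entirely for a single
  proton, where it would be pure self-interaction.

Nuclei are partitioned into classical point charges `r_c` and quantum
centers `r_q`.  A quantum center is a basis anchor, not a point charge:
its proton enters the Hamiltonian through the protonic density, and its
*electronic* functions are attached to the same movable center, so an
adaptive update moves both together.

## Stepwise SCF

Each macrocycle (i) converges the nuclear Roothaan–Hall subproblem at
fixed electronic density, then (ii) converges the electronic problem at
fixed protonic density.  Both stages use Pulay DIIS (error vector
FDS − SDF, history depth 10, active after the first iteration; a singular
DIIS system falls back to the latest Fock with a warning).  The
generalized eigenproblems are solved by canonical orthogonalization with
overlap eigenvalues below 1e-10 projected out.  Initial guesses: core
Hamiltonian for the electrons, kinetic + classical-field for the protons.

Convergence thresholds (all configurable, defaults in atomic units):

| criterion                            | default |
|--------------------------------------|---------|
| subcycle energy change               | 1e-8    |
| subcycle density RMS change          | 1e-8    |
| orbital gradient ‖FDS − SDF‖_F       | 1e-8    |
| macrocycle energy change             | 1e-6    |
| centroid displacement (adaptive)     | 1e-5 Bohr |
| nuclear / electronic / macro cycle caps | 50 / 100 / 200 |

The interleaving granularity is "converge each stage per macrocycle"
(rather than single interleaved iterations); the subcycle caps make the
other limit reachable by configuration.

## Adaptive centroid relocation

After each converged nuclear subcycle, the charge centroid
⟨φ_i|r|φ_i⟩ of every occupied nuclear orbital is computed from the
position-operator matrices.  Orbitals are mapped one-to-one to quantum
centers by maximizing summed per-center Mulliken populations (optimal
bipartite matching, `scipy.optimize.linear_sum_assignment`; equal optima
resolve to the lowest center index; a best population below 0.5 logs an
ambiguity warning).  Each center then moves by
`damping_factor * (centroid − r_q)` — damping defaults to 1 (off) and
exists to quench oscillatory walks — and *all* position-dependent
integrals are rebuilt, two-particle tensors included, since electronic
functions ride on the moved center.  A single step larger than 1 Bohr
aborts with a diagnostic (runaway guard).  Convergence of the adaptive
run requires the SCF criteria *and* the 1e-5 Bohr displacement criterion
simultaneously.

The centroid update is a heuristic fixed-point iteration, not a
variational step: centroid stationarity and energy stationarity coincide
only in the limit of a flexible basis and a locally harmonic proton well.
Correctness is therefore certified against the numerical-gradient
optimizer (below), and the macrocycle energy is allowed to creep upward at
the 1e-8 hartree level during the final approach to the fixed point.
In degenerate double wells the iteration converges to the basin of the
starting point; exactly at a symmetric transition state the centroid force
vanishes and the procedure converges in place (the method is
Hessian-free and cannot distinguish minima from saddles).

## Numerical-gradient oracle and scans

The extended-PES energy `E(r_q)` is a fully converged coupled SCF at fixed
quantum-center positions (tightened thresholds 1e-10 during gradient
work, so finite-difference noise stays below the optimizer's criteria).
Gradients are central differences with step 1e-3 Bohr; displaced SCFs are
warm-started from the reference densities.  Optimization uses BFGS with
gradient norm threshold 1e-5 hartree/Bohr; classical centers stay frozen.
1-D scans pin the scanned center on a grid (window ±1 Å), converge the
full SCF per point (stateless; failures are recorded as missing and the
scan continues), and optionally compute the conventional RHF curve with
the proton demoted to a classical nucleus at the same grid point.

## Integrals

A McMurchie–Davidson engine (Hermite expansion coefficients, Hermite
Coulomb R-tensor, Boys function by downward series / upward asymptotic
recursion switched at x = 30) evaluates all classes over raw Cartesian
primitives with numba-jitted kernels; solid-harmonic (spherical) functions
up to l = 4 are produced by the standard two-term real-solid-harmonic
recursion, and contracted functions are normalized exactly via closed-form
monomial overlaps.  Kinetic matrices are stored divided by the particle
mass; point-charge matrices carry the species' sign; Coulomb tensors are
stored with positive kernels (signs live in the Fock builds).  Tensors are
conventional 4-index arrays with a configurable memory cap (default
2 GB) that errors with a pointer toward integral-direct strategies; no
density fitting is used.  Every class is tested against an independent
quadrature oracle (Gauss–Hermite for polynomial×Gaussian factors, the
resolvent identity 1/r = 2/√π ∫ exp(−t²r²) dt for Coulomb kernels) to
1e-8.

## Bases and fixtures

Electronic STO-3G (H, He, C, N, O, F) is bundled in the repository's
basis-file format, plus `sto-3g-aug`, which adds diffuse s/p and
polarization d shells for compact hydrogen-bond models.  Protonic bases
use an even-tempered fallback `alpha0 · beta^k` replicated over angular
momenta (names like `et-6s3p`, default exponent window 2–64; the window's
lower edge is a documented free parameter, chosen as 2 so that an 8s set
reproduces the printed upper edge of 64).  Published protonic sets remain
loadable from user-supplied files.

The bundled fixtures define the study conditions for all tests:

* `h_atom` — 1 electron + 1 quantum proton, no classical nuclei; the
  exact nonrelativistic energy −μ/2 = −0.49972784 hartree is a strict
  lower bound for the mean-field product ansatz.  With even-tempered
  10s/8s bases the package obtains −0.46641 hartree; the ~21 kcal/mol gap
  is the missing electron–proton correlation (center-of-mass separation),
  not a basis artifact.
* `h2_1q` — H₂ at 1.4 Bohr with one quantum proton.
* `hehhe_cation` — symmetric linear [He–H–He]⁺; the midpoint is an exact
  fixed point by symmetry, used for stay-put, return-to-center and
  equivariance tests.
* `hbond_toy` — compressed linear F–H···He (F–He = 3.8 Bohr), a
  single-well *asymmetric* donor–H–acceptor model in the low-barrier
  hydrogen-bond regime.  The compression is a deliberate design choice:
  in stiff, strongly anharmonic wells (e.g. F–He ≳ 4.3 Bohr) the centroid
  fixed point and the energy minimum genuinely separate by ~0.006 Å with
  these bases — the same few-thousandths-of-an-Ångström regime reported
  for production systems — while the soft compressed well keeps them
  within 1e-3 Å, letting the oracle-equivalence test assert a tight bound.
  The diffuse/polarization augmentation on F matters most here: with bare
  minimal bases, dragging the quantum center's electronic functions
  toward the acceptor lowers the energy spuriously (a superposition
  artifact) and the two stationary points drift ~0.05 Å apart.

What the fixtures do *not* emulate: multi-proton wires, double wells with
competing basins, open-shell electronics, and production-size bases.
Passing tests therefore demonstrate the correctness of the machinery and
the fixed-point/oracle agreement in single-well regimes, not quantitative
accuracy for hydrogen-bond networks.

## Problem sizes

Tests and the acceptance script run on 1–3 heavy atoms with 12–31
electronic and 8–18 protonic functions, 21-point scans at 0.01 Å spacing,
and three-start determinism checks; a full run of the suite plus the
acceptance script completes in a few minutes on one CPU.

## Known limitations

* NEO-HF energies are qualitative (no electron–proton correlation).
* Proton–proton exchange is omitted; with ≥ 2 quantum protons the
  mean-field J_pp retains self-interaction.
* The adaptive fixed point inherits a small, basis- and
  anharmonicity-dependent offset from the true standard-PES minimum; the
  numerical-gradient optimizer is the arbiter where this matters.
* Conventional 4-index tensors limit basis sizes to a few hundred
  functions; no density fitting or integral-direct Fock builds.
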