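# Methods

This note documents the models, conventions, numerical choices and known
limitations of parmfit.  Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing below is an external claim.

## Potential energy function

The full CHARMM additive form is evaluated term by term (bond, angle,
Urey–Bradley, dihedral, improper, Lennard-Jones, Coulomb), in kcal/mol,
Å, degrees and elementary charge throughout.

* **Coulomb constant.** 332.0716 kcal·Å·mol⁻¹·e⁻², the value hard-wired
  into the CHARMM ecosystem, realizing q_iq_j/4πε₀r in the working units.
  Using the CODATA-exact value instead would shift energies by ~10⁻⁵
  relative and break bit-compatibility with existing parameter files.
* **Lennard-Jones sign convention.** Internally ε ≥ 0 and
  V(r) = ε[(R_min/r)¹² − 2(R_min/r)⁶], so V(R_min) = −ε.  CHARMM parameter
  files print ε with a negative sign; it is normalized on read.  Pair
  parameters combine as R_min,ij = R_min,i/2 + R_min,j/2 and
  ε_ij = √(ε_i ε_j) (the CHARMM rule).
* **Exclusions.** 1-2 and 1-3 pairs (by minimum bond-graph distance) are
  excluded; 1-4 pairs interact at full strength, with the per-type 1-4
  Lennard-Jones overrides when a parameter file supplies them.  No scaling
  factor is applied to 1-4 electrostatics.
* **No cutoff, no periodicity.**  The targets are single small molecules
  in vacuum; truncation schemes belong to condensed-phase simulation,
  which this package does not do.
* **Urey–Bradley terms** are an optional attribute of an angle type (as in
  CHARMM): angle types without UB parameters simply contribute none, which
  is not an error.
* **Degenerate geometry.**  Dihedrals with a collinear atom triple and
  nonbonded pairs closer than 10⁻⁶ Å raise errors rather than returning
  huge numbers.

Dihedral angles follow the convention that the angle is positive clockwise
looking from the second atom toward the third, computed as the atan2 of
the two plane normals; reversing the quadruple leaves the value unchanged.
Because fitted phases are restricted to 0°/180°, every torsion energy is
even in φ and independent of this sign choice.

## Torsion scans

Scans are **rigid rotations**: the side of the central bond containing the
fourth atom rotates as a rigid body; the other side is untouched.  A scan
covers 0–360° in 20° steps (19 points, both endpoints present).  Reference
quantum scans are typically *relaxed* (all other degrees of freedom
re-optimized at each step); supporting that would require an optimizer and
an objective surface, so relaxed-scan geometries are instead accepted from
file as externally supplied conformer series.  Consequences: rigid-scan
classical profiles can overestimate barriers (clashes that relaxation
would relieve), but the fitting contract — a difference profile on a fixed
grid in, cosine terms out — is unchanged.

The classical profile is evaluated **with the scanned torsion's own terms
zeroed** (an explicit option, default on).  This is the construction under
which "classical + fitted torsion" reproduces the reference curve; if the
existing terms were left in, the fit would double-count them.  Profiles
are shifted so their minimum is exactly 0 before differencing, and the
difference is shifted again; additive constants in either input therefore
never reach the fitter.

## Torsion fitting

With δ_n ∈ {0°, 180°}, k_n[1 + cos(nφ − δ_n)] = k_n ± k_n cos(nφ), so the
fit is ordinary linear least squares on the basis {1} ∪ {cos(nφ)} — the
same optimum a nonlinear optimizer would find, without initialization or
convergence concerns.  The test suite cross-checks this against an
iterative curve fit and against a brute-force search over all 2^m sign
assignments with non-negative amplitudes.

* The duplicate 0°/360° sample is collapsed before solving; keeping it
  would silently double-weight one point and bias the constant and even-n
  terms.
* Output conventions: `canonical_nonnegative_k` folds signs into phases
  (k = |a|, δ from sign(a); a = 0 ties to k = 0, δ = 0);  `signed_k` keeps
  the supplied phase and a signed constant.  The two differ only by an
  additive offset in the reconstructed curve.  The signed convention
  exists because published tables print, e.g., a (k = −0.3572, δ = 180°)
  term, which equals (+0.3572, δ = 0°) plus a constant.
* Rank deficiency (e.g. n = 4 on a 90°-step grid, where cos(4φ) is
  constant) is detected and reported, not silently pseudo-inverted.
* Multiplicity selection (`select_multiplicities`) is a deliberately
  simple deterministic heuristic: fit all candidates with free signs, drop
  |k| < 0.05 kcal/mol, refit the survivors.  Published parameter sets do
  not document how their multiplicity subsets were chosen; this heuristic
  reproduces them on round-trip data but is not a claim about anyone
  else's procedure.
* Equal division: the fitted total constant is divided by the number of
  quadruples sharing the central bond (hydrogen-bearing quadruples are
  counted by default; an option excludes them, since published workflows
  rarely state the choice).  The divided terms reproduce the fitted total
  pointwise when the quadruple phase offsets are commensurate with the
  term's multiplicity (a 3-fold rotor with n = 3 terms); for
  incommensurate multiplicities the off-symmetry harmonics partially
  cancel across quadruples — an intrinsic property of the representation,
  not of the division.

## ESP charge fitting

Charges minimize Σ_p (V(p) − Σ_i C q_i/|p − x_i|)² subject to Σq_i = Q and
optionally Σq_i x_i = μ/f with f = 4.80320 Debye per e·Å.  The solver is
LAPACK `GGLSE` (equality-constrained least squares via generalized RQ
factorization), chosen over the normal-equations KKT system because the
design matrix carries the Coulomb constant (~10² per entry over ~10³
points) and squaring it costs half the available precision.  Constraint
rank and solvability are checked first and reported with the offending
dimension (e.g. one atom cannot satisfy four constraints).  Constraints
hold to ~10⁻¹⁵ regardless of noise in the potential values; the
noise-free recovery error on synthetic cases is at the 10⁻¹⁶–10⁻⁶ e
level depending on grid conditioning.

Grid construction follows the Merz–Singh–Kollman recipe: points on scaled
van-der-Waals spheres (default scales 1.4, 1.6, 1.8, 2.0; density 1.0
point·Å⁻²), discarding points inside any atom's innermost shell.  Point
placement is a deterministic Fibonacci lattice; the seed only sets one
global random orientation, so grids are exactly reproducible.  The precise
shell scales and densities used by specific quantum-chemistry codes vary
and are rarely published; these defaults follow the original scheme and
are configurable.

## Synthetic data

The synthetic module supplies everything a development or validation run
needs without any quantum chemistry:

* **Toy butane** — 14 atoms, idealized staggered geometry (C–C 1.53 Å,
  C–H 1.09 Å, 112° backbone angle, methyl hydrogens at exact ±120°
  offsets), hand-set parameters in the style of CHARMM alkane values, and
  a central bond with exactly 9 equivalent quadruples.
* **Fragments** — three idealized surrogates of the linkers that dominate
  ligand torsion work: an aromatic-ring amide (N-methylbenzamide-like), an
  exocyclic double bond (styrene-like) and an N-benzyl-like linker.
  Geometries are built from standard bond lengths/angles; harmonic
  equilibria are taken from the built geometry itself and force constants
  are generic, which is sufficient for scan-and-fit exercises.  The ring
  is twofold-symmetric about the substitution axis, so the amide scan's
  180°-periodicity is an exact symmetry test.
* **Synthetic "QM" profiles** — classical profile + a chosen term set +
  i.i.d. Gaussian noise per grid point.  Real quantum scans have no noise
  model; the noise exists purely to characterize fitter robustness (the
  fit is linear, so recovered constants are unbiased with error ∝ σ, which
  the suite verifies at σ = 0.01/0.1/0.5 kcal/mol and, at σ = 0.1, over
  200 seeds).
* **Synthetic ESP cases** — random non-degenerate geometries with charges
  summing exactly to −1, 0 or +1, and exact Coulomb potentials on an MK
  grid.

What passing these tests shows: the fitting mathematics, conventions and
I/O are correct.  What they do not show: anything about the quality of a
specific quantum level of theory, relaxed-scan geometries, conformational
averaging of charges, or condensed-phase behavior of the resulting
parameters.

## Packaged reference parameters

The published torsion tables for the two PPARγ ligands are shipped as
parameter-file fixtures (six torsions; SR1664 T1–T3 and GQ16 T1–T3, three
to four cosine terms each, phases all 0°/180°, one negative signed
constant).  The acceptance script regenerates each torsion's difference
profile from its own terms and refits it — a round trip that is exact to
linear-algebra precision (~10⁻¹⁵), far inside the 4-decimal precision of
the printed tables.  The ligands' net charges (−1 e for the carboxylate-
bearing SR1664, 0 for GQ16) are recorded alongside; the per-atom published
charge tables were not available in the source text and are not packaged.

## Problem sizes

Defaults are chosen so the full suite runs in seconds on one core: 19-point
torsion grids (the standard 20° scan), 200-seed Monte-Carlo noise checks,
MK grids of ~10³ points for 3–10 atoms.  All scale linearly if larger runs
are wanted.

## Known limitations

* No quantum chemistry, no geometry optimization, no molecular dynamics.
* Rigid scans only (relaxed geometries must be supplied externally).
* Single-molecule vacuum energies; no cutoffs, PBC or Ewald.
* CMAP and NBFIX parameter-file sections are recognized but skipped.
* PSF reading supports the X-PLOR (string-typed) dialect only.
* One torsion is fitted at a time; simultaneous multi-torsion fitting and
  Boltzmann-weighted fitting are out of scope.
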