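# parmfit

A small-molecule force-field parameterization toolkit in the CHARMM
additive idiom, built around the workflow used to parameterize drug-like
nuclear-receptor ligands (the PPARγ partial agonist GQ16 and the
non-agonist SR1664 serve as the packaged reference cases): evaluate the
classical potential, scan a rotatable bond, fit torsion Fourier terms to
the quantum-minus-classical energy difference, divide the fitted constants
among equivalent dihedrals, and derive partial charges by constrained
electrostatic-potential fitting.

It is aimed at people who build CHARMM-compatible ligand parameters and
want the fitting stage — not the quantum chemistry — as a reproducible,
testable library: QM inputs enter as plain tables (torsion-profile CSVs,
ESP grid CSVs), and a synthetic module generates stand-ins with known
ground truth for development and validation.

## The model

The potential is the standard CHARMM additive form

```
V = Σ_bonds k_b (b − b₀)² + Σ_angles k_θ (θ − θ₀)² + Σ_UB k_u (u − u₀)²
  + Σ_dihedrals k_φn [1 + cos(n φ − δ_n)] + Σ_impropers k_ω (ω − ω₀)²
  + Σ_pairs ε_ij [(R_min,ij/r_ij)¹² − 2 (R_min,ij/r_ij)⁶] + Σ_pairs C q_i q_j / r_ij
```

with C = 332.0716 kcal·Å·mol⁻¹·e⁻², 1-2/1-3 nonbonded exclusions and
full-strength 1-4 interactions.

**Torsion fitting.** A full-revolution rigid scan (0–360° in 20° steps)
gives a classical profile with the target torsion's own terms zeroed; the
difference ΔE(φ) = E_QM(φ) − E_MM(φ), each curve shifted to a zero
minimum, is the potential the new cosine terms must supply.  Restricting
the phases δ_n to 0° or 180° turns k·cos(nφ − δ) into ±k·cos(nφ), so the
"nonlinear" fit is an exact linear least squares on {1} ∪ {cos(nφ)} — one
global optimum, no iteration.  A negative fitted constant with δ = 180° is
the same curve as the positive constant with δ = 0° up to an additive
offset; both conventions are supported because published tables use both.
Because the potential sums over every dihedral quadruple that shares the
central bond, the total fitted constant is divided equally among them.

**Charge fitting.** Point charges are fitted to ESP samples on nested
scaled van-der-Waals shells (the Merz–Singh–Kollman construction, default
scales 1.4/1.6/1.8/2.0 at 1 point·Å⁻²), minimizing the squared potential
error subject to an exact net-charge constraint and, optionally, exact
dipole-component constraints — an equality-constrained least-squares
problem solved through LAPACK's generalized RQ factorization (`GGLSE`).

## Worked example

Fit a torsion for the toy butane system, playing both roles: the synthetic
"QM" profile hides a known 3-fold term (k = 1.40 kcal/mol) plus 0.1
kcal/mol of Gaussian noise.

```python
from parmfit.ffio import DihedralTerm
from parmfit.synthetic import make_toy_butane, synth_qm_profile, SyntheticTorsionSpec
from parmfit.torsion_scan import generate_scan, mm_profile, delta_profile
from parmfit.torsion_fit import fit_torsion, count_equivalent_dihedrals, divide_terms

system, conf, params, torsion = make_toy_butane()
conformers = generate_scan(system, conf, torsion, step=20.0)
mm = mm_profile(system, conformers, params, [system.type_tuple(torsion)])
truth = (DihedralTerm(1.40, 3, 0.0),)
qm = synth_qm_profile(SyntheticTorsionSpec(truth, noise_sd=0.1, seed=7), mm)
delta = delta_profile(qm, mm)
result = fit_torsion(delta, {1, 2, 3}, phase_policy={1: 0.0, 2: 0.0, 3: 0.0},
                     convention="signed_k")
for t in result.terms:
    print(f"n={t.n}  k={t.k:+.4f} kcal/mol  delta={t.delta:.0f}")
print(f"rmse = {result.rmse:.4f} kcal/mol")
n_equiv = count_equivalent_dihedrals(system, (torsion[1], torsion[2]))
print("equivalent dihedrals:", n_equiv)
print("per-quadruple k3 =", f"{divide_terms(result, n_equiv)[2].k:.4f}")
```

prints

```
n=1  k=-0.0222 kcal/mol  delta=0
n=2  k=+0.0172 kcal/mol  delta=0
n=3  k=+1.4205 kcal/mol  delta=0
rmse = 0.0610 kcal/mol
equivalent dihedrals: 9
per-quadruple k3 = 0.1578
```

The fit recovers the hidden 3-fold term (1.4205 vs 1.40; the spurious
n = 1, 2 amplitudes are at the noise floor), and the total constant is
split over the nine quadruples sharing the central C–C bond, so each PRM
line carries k = 0.1578 kcal/mol.

The same pipeline is available from the shell — `parmfit scan`,
`parmfit fit-torsion`, `parmfit fit-charges`, `parmfit energy`,
`parmfit fixtures` (the packaged published torsion tables) and
`parmfit make-fixture` (synthetic test molecules); see `parmfit --help`.

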