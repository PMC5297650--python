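"""Torsion Fourier-term fitting, multiplicity selection, equal division."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from parmfit.ffio import DihedralTerm, load_fixture, fixture_names
from parmfit.mm_energy import dihedral_term_energy, measure_dihedral
from parmfit.synthetic import synth_delta_from_terms
from parmfit.torsion_fit import (
    CANONICAL,
    SIGNED,
    RankDeficiencyError,
    count_equivalent_dihedrals,
    divide_terms,
    fit_torsion,
    fitted_profile,
    select_multiplicities,
)
from parmfit.torsion_scan import Provenance, TorsionProfile


def _flat_profile():
    angles = np.arange(0.0, 361.0, 20.0)
    return TorsionProfile(angles, np.zeros_like(angles), Provenance.DELTA)


class TestFitTorsion:
    def test_zero_profile_gives_zero_terms(self):
        res = fit_torsion(_flat_profile(), {1, 2, 3})
        assert all(t.k == 0.0 for t in res.terms)
        assert res.rmse == 0.0

    def test_single_cosine_recovered_exactly(self):
        delta = synth_delta_from_terms([DihedralTerm(1.0, 2, 0.0)])
        res = fit_torsion(delta, {1, 2, 3})
        by_n = {t.n: t for t in res.terms}
        assert by_n[2].k == pytest.approx(1.0, abs=1e-10)
        assert by_n[2].delta == 0.0
        assert by_n[1].k == pytest.approx(0.0, abs=1e-10)
        assert by_n[3].k == pytest.approx(0.0, abs=1e-10)
        assert res.rmse < 1e-10

    @pytest.mark.parametrize("name", sorted(fixture_names()))
    def test_published_term_sets_round_trip(self, name):
        """Noise-free difference profiles built from each published torsion
        reproduce every printed force constant."""
        terms = load_fixture(name)
        delta = synth_delta_from_terms(terms)
        res = fit_torsion(
            delta,
            [t.n for t in terms],
            phase_policy={t.n: t.delta for t in terms},
            convention=SIGNED,
        )
        for fitted, ref in zip(res.terms, terms):
            assert fitted.k == pytest.approx(ref.k, abs=5e-4)
            assert fitted.delta == ref.delta

    def test_matches_brute_force_sign_search(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            mults = sorted(
                rng.choice(np.arange(1, 7), size=rng.integers(1, 4), replace=False)
            )
            true = [
                DihedralTerm(
                    float(rng.uniform(0.05, 3.0)), int(n),
                    float(rng.choice([0.0, 180.0])),
                )
                for n in mults
            ]
            delta = synth_delta_from_terms(true, seed=int(rng.integers(2**31)))
            res = fit_torsion(delta, mults, convention=CANONICAL)
            ref_terms, ref_sse = oracles.brute_force_torsion_fit(
                res.grid, delta.energies[: len(res.grid)], mults
            )
            my_sse = res.rmse**2 * len(res.grid)
            assert my_sse <= ref_sse + 1e-9
            for t in res.terms:
                k_ref, d_ref = ref_terms[int(t.n)]
                assert t.k == pytest.approx(k_ref, abs=1e-6)
                if t.k > 1e-9:
                    assert t.delta == d_ref

    def test_matches_iterative_nonlinear_refit(self):
        terms = load_fixture("GQ16_T2")
        delta = synth_delta_from_terms(terms, noise_sd=0.05, seed=7)
        phases = {t.n: t.delta for t in terms}
        res = fit_torsion(delta, phases.keys(), phase_policy=phases, convention=SIGNED)
        ref = oracles.nonlinear_refit(
            res.grid, delta.energies[: len(res.grid)], phases.keys(), phases
        )
        for t in res.terms:
            assert t.k == pytest.approx(ref[t.n], abs=1e-6)

    def test_signed_and_canonical_differ_only_by_constant(self):
        """(k, 180) and (-k, 0) describe the same curve up to an offset."""
        delta = synth_delta_from_terms([DihedralTerm(-0.3572, 4, 180.0)])
        signed = fit_torsion(delta, {4}, phase_policy={4: 180.0}, convention=SIGNED)
        canon = fit_torsion(delta, {4}, convention=CANONICAL)
        assert signed.terms[0].k == pytest.approx(-0.3572, abs=1e-10)
        assert canon.terms[0].k == pytest.approx(0.3572, abs=1e-10)
        assert canon.terms[0].delta == 0.0
        curve_s = fitted_profile(signed.terms, signed.grid).energies
        curve_c = fitted_profile(canon.terms, canon.grid).energies
        diff = curve_s - curve_c
        assert np.ptp(diff) < 1e-10  # constant offset only

    def test_duplicate_endpoint_collapsed(self):
        delta = synth_delta_from_terms([DihedralTerm(0.8, 1, 0.0)])
        res = fit_torsion(delta, {1})
        assert len(res.grid) == 18
        assert res.terms[0].k == pytest.approx(0.8, abs=1e-10)

    def test_aliasing_on_coarse_grid_rejected(self):
        angles = np.arange(0.0, 361.0, 90.0)
        prof = TorsionProfile(angles, np.zeros_like(angles), Provenance.DELTA)
        with pytest.raises(RankDeficiencyError):
            fit_torsion(prof, {4})  # cos(4 phi) is constant on a 90-degree grid

    def test_empty_multiplicities_rejected(self):
        with pytest.raises(ValueError):
            fit_torsion(_flat_profile(), set())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ks=st.lists(st.floats(0.01, 8.0), min_size=1, max_size=6),
        deltas=st.data(),
    )
    def test_exact_recovery_property(self, ks, deltas):
        """Any noise-free term set with phases 0/180 and multiplicities <= 6
        is recovered to linear-algebra precision on the 19-point grid."""
        mults = list(range(1, len(ks) + 1))
        terms = [
            DihedralTerm(k, n, deltas.draw(st.sampled_from([0.0, 180.0])))
            for k, n in zip(ks, mults)
        ]
        delta = synth_delta_from_terms(terms)
        res = fit_torsion(
            delta, mults, phase_policy={t.n: t.delta for t in terms}, convention=SIGNED
        )
        for fitted, ref in zip(res.terms, terms):
            assert fitted.k == pytest.approx(ref.k, abs=1e-8)

    def test_noise_scaling_is_monotone(self):
        """Recovered-k error grows with the noise level."""
        true = [DihedralTerm(1.5, 1, 0.0), DihedralTerm(0.7, 3, 0.0)]
        errors = []
        for sd in (0.01, 0.1, 0.5):
            errs = []
            for seed in range(200):
                delta = synth_delta_from_terms(true, noise_sd=sd, seed=seed)
                res = fit_torsion(
                    delta, {1, 3}, phase_policy={1: 0.0, 3: 0.0}, convention=SIGNED
                )
                errs.append(
                    np.mean([abs(t.k - r.k) for t, r in zip(res.terms, true)])
                )
            errors.append(np.mean(errs))
        assert errors[0] < errors[1] < errors[2]


class TestSelectMultiplicities:
    def test_pure_cosine_selects_its_multiplicity(self):
        delta = synth_delta_from_terms([DihedralTerm(1.0, 2, 0.0)])
        assert select_multiplicities(delta) == {2}

    def test_published_sr1664_t1_subset_recovered(self):
        delta = synth_delta_from_terms(load_fixture("SR1664_T1"))
        assert select_multiplicities(delta) == {1, 3, 4}

    def test_flat_signal_returns_empty_set(self):
        assert select_multiplicities(_flat_profile()) == set()


class TestEquivalentDihedrals:
    def test_butane_central_bond_has_nine(self, butane):
        assert count_equivalent_dihedrals(butane.system, (1, 2)) == 9

    def test_four_atom_chain_has_one(self, four_atom_chain):
        system, _, _ = four_atom_chain
        assert count_equivalent_dihedrals(system, (1, 2)) == 1

    def test_asymmetric_substitution(self):
        from parmfit.ffio import system_from_bonds
        from conftest import atom

        # 2 substituents on one side, 1 on the other
        atoms = [atom(i) for i in range(5)]
        system = system_from_bonds(atoms, [(0, 1), (2, 1), (1, 3), (3, 4)])
        assert count_equivalent_dihedrals(system, (1, 3)) == 2

    def test_hydrogen_exclusion_option(self, butane):
        assert (
            count_equivalent_dihedrals(butane.system, (1, 2), include_hydrogens=False)
            == 1
        )

    def test_unbonded_pair_rejected(self, butane):
        with pytest.raises(ValueError, match="not bonded"):
            count_equivalent_dihedrals(butane.system, (0, 3))


class TestDivideTerms:
    def test_division_scales_k_only(self):
        divided = divide_terms([DihedralTerm(0.9, 3, 180.0)], 3)
        assert divided == (DihedralTerm(0.3, 3, 180.0),)

    def test_identity_for_one_equivalent(self):
        terms = (DihedralTerm(1.2, 1, 0.0),)
        assert divide_terms(terms, 1) == terms

    def test_division_preserves_total_under_rigid_rotation(self, butane):
        """All nine central quadruples advance in lockstep under a rigid
        rotation, so the divided terms applied to all of them reproduce the
        undivided single-quadruple potential."""
        from parmfit.mm_energy import rotate_dihedral

        # 3-fold terms: the nine quadruples sit at exact +/-120-degree phase
        # offsets, so off-symmetry harmonics would cancel while multiples of
        # 3 add coherently; with n=3 the 9-fold divided sum equals the
        # undivided single-quadruple potential pointwise.
        total_terms = (DihedralTerm(0.9, 3, 0.0), DihedralTerm(0.27, 6, 180.0))
        divided = divide_terms(total_terms, 9)
        central = [
            q for q in butane.system.dihedrals if {q[1], q[2]} == {1, 2}
        ]
        assert len(central) == 9
        conf0 = butane.conformation
        phi0 = {q: measure_dihedral(conf0, q) for q in central}
        for target in (0.0, 40.0, 100.0, 160.0):
            conf = rotate_dihedral(conf0, butane.system, butane.torsion, target)
            shift = (target - measure_dihedral(conf0, butane.torsion)) % 360.0
            # rigid sides: every quadruple advances by the same increment
            for q in central:
                moved = (measure_dihedral(conf, q) - phi0[q]) % 360.0
                assert min(abs(moved - shift), 360 - abs(moved - shift)) < 1e-6
            undivided = sum(
                dihedral_term_energy(t, measure_dihedral(conf, butane.torsion))
                for t in total_terms
            )
            summed = sum(
                dihedral_term_energy(t, measure_dihedral(conf, q))
                for q in central
                for t in divided
            )
            assert summed == pytest.approx(undivided, abs=1e-9)
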