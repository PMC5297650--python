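"""Parameter-file, topology and coordinate I/O."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parmfit import ffio
from parmfit.ffio import (
    AngleParam,
    BondParam,
    DihedralTerm,
    ImproperParam,
    LJParam,
    ParameterSet,
    ParseError,
    UreyBradleyParam,
)


class TestReadPrm:
    def test_single_bond_record(self, tmp_path):
        p = tmp_path / "one.prm"
        p.write_text("BONDS\nCT CT 300.0 1.50\nEND\n")
        params = ffio.read_prm(p)
        assert params.bonds == {("CT", "CT"): BondParam(300.0, 1.50)}
        assert not params.angles and not params.dihedrals

    def test_gq16_fixture_has_three_t2_terms(self):
        params = ffio.read_prm(ffio.fixture_path("GQ16"))
        terms = params.dihedral_terms(("C6", "C7", "C8", "C9"))
        assert [t.n for t in terms] == [1, 2, 3]
        assert terms[0] == DihedralTerm(2.8584, 1, 0.0)

    def test_comments_and_continuation(self, tmp_path):
        p = tmp_path / "c.prm"
        p.write_text(
            "! leading comment\nBONDS\nCT CT 300.0 1.50 ! inline\n"
            "CT -\nHA 309.0 1.09\nEND\n"
        )
        params = ffio.read_prm(p)
        assert params.bond("CT", "HA") == BondParam(309.0, 1.09)

    def test_malformed_numeric_field_names_line(self, tmp_path):
        p = tmp_path / "bad.prm"
        p.write_text("BONDS\nCT CT 3x0.0 1.50\nEND\n")
        with pytest.raises(ParseError, match=r":2"):
            ffio.read_prm(p)

    def test_conflicting_duplicate_lists_both_lines(self, tmp_path):
        p = tmp_path / "dup.prm"
        p.write_text("BONDS\nCT CT 300.0 1.50\nCT CT 310.0 1.50\nEND\n")
        with pytest.raises(ParseError, match=r"line 2"):
            ffio.read_prm(p)

    def test_unknown_section_skipped(self, tmp_path, caplog):
        p = tmp_path / "cmap.prm"
        p.write_text("CMAP\n1 2 3\nBONDS\nCT CT 300.0 1.50\nEND\n")
        params = ffio.read_prm(p)
        assert ("CT", "CT") in params.bonds

    def test_lj_sign_normalized_on_read(self, tmp_path):
        p = tmp_path / "nb.prm"
        p.write_text("NONBONDED\nCT 0.0 -0.078 2.04 0.0 -0.01 1.90\nEND\n")
        lj = ffio.read_prm(p).lj_param("CT")
        assert lj.well_depth == 0.078 and lj.well_depth_14 == 0.01
        assert lj.r_min_half == 2.04 and lj.r_min_half_14 == 1.90


class TestWritePrm:
    def test_empty_set_gives_headers_only(self, tmp_path):
        out = tmp_path / "empty.prm"
        ffio.write_prm(ParameterSet(), out)
        text = out.read_text()
        for header in ("BONDS", "ANGLES", "DIHEDRALS", "IMPROPER", "NONBONDED"):
            assert header in text
        assert ffio.read_prm(out) == ParameterSet()

    def test_sr1664_fixture_line_present(self, tmp_path):
        params = ffio.read_prm(ffio.fixture_path("SR1664"))
        out = tmp_path / "sr.prm"
        ffio.write_prm(params, out)
        line = next(
            l for l in out.read_text().splitlines()
            if l.startswith("C13") and " 1 " in f" {l.split()[5]} "
        )
        assert "0.179500" in line

    def test_fixture_files_round_trip_losslessly(self, tmp_path):
        for ligand in ("SR1664", "GQ16"):
            params = ffio.read_prm(ffio.fixture_path(ligand))
            out = tmp_path / f"{ligand}.prm"
            ffio.write_prm(params, out)
            assert ffio.read_prm(out) == params

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_randomized_round_trip(self, data, tmp_path_factory):
        """write_prm followed by read_prm is the identity on valid sets."""
        val = st.decimals(
            min_value="0.0001", max_value="999.9999", places=4
        ).map(float)
        types = st.sampled_from(["CT", "HA", "CA", "NX", "OY"])
        params = ParameterSet()
        for _ in range(data.draw(st.integers(1, 4))):
            params.add_bond(data.draw(types), data.draw(types), BondParam(data.draw(val), data.draw(val)))
        for _ in range(data.draw(st.integers(0, 3))):
            t = (data.draw(types), data.draw(types), data.draw(types))
            params.angles[ffio._canon_triple(t)] = AngleParam(
                data.draw(val), data.draw(st.decimals("1.0", "180.0", places=4).map(float))
            )
        for _ in range(data.draw(st.integers(0, 3))):
            quad = tuple(data.draw(types) for _ in range(4))
            term = DihedralTerm(
                data.draw(val), data.draw(st.integers(1, 6)),
                data.draw(st.sampled_from([0.0, 180.0])),
            )
            key = ffio._canon_quad(quad)
            if not any(t.n == term.n for t in params.dihedrals.get(key, ())):
                params.add_dihedral_term(quad, term)
        for t in ("CT", "HA"):
            params.add_lj(t, LJParam(data.draw(val), data.draw(val)))
        out = tmp_path_factory.mktemp("prm") / "rt.prm"
        ffio.write_prm(params, out)
        assert ffio.read_prm(out) == params


_CHAIN_PSF = textwrap.dedent(
    """\
    PSF

           1 !NTITLE
     REMARKS four-atom chain

           4 !NATOM
           1 LIG  1    LIG  C1   CT     -0.180000       12.0110           0
           2 LIG  1    LIG  C2   CT      0.090000       12.0110           0
           3 LIG  1    LIG  C3   CT      0.090000       12.0110           0
           4 LIG  1    LIG  C4   CT      0.000000       12.0110           0

           3 !NBOND: bonds
           1       2       2       3       3       4

           2 !NTHETA: angles
           1       2       3       2       3       4

           1 !NPHI: dihedrals
           1       2       3       4

           0 !NIMPHI: impropers

           0 !NDON

           0 !NACC
    """
)


class TestReadPsf:
    def test_four_atom_chain_counts(self, tmp_path):
        p = tmp_path / "chain.psf"
        p.write_text(_CHAIN_PSF)
        system = ffio.read_psf(p)
        assert system.n_atoms == 4
        assert len(system.bonds) == 3
        assert len(system.angles) == 2
        assert len(system.dihedrals) == 1
        assert system.atoms[0].type_label == "CT"
        assert system.atoms[0].charge == pytest.approx(-0.18)

    def test_toy_butane_fixture_has_nine_central_dihedrals(self):
        from importlib import resources

        psf = resources.files("parmfit.fixtures") / "toy_butane.psf"
        system = ffio.read_psf(str(psf))
        central = {
            q for q in system.dihedrals
            if {q[1], q[2]} == {1, 2}
        }
        assert len(central) == 9  # 3 substituents x 3 substituents

    def test_bond_index_beyond_natom_rejected(self, tmp_path):
        bad = _CHAIN_PSF.replace(
            "       1       2       2       3       3       4",
            "       1       2       2       3       3       9",
        )
        p = tmp_path / "bad.psf"
        p.write_text(bad)
        with pytest.raises(ParseError):
            ffio.read_psf(p)

    def test_numeric_type_psf_rejected(self, tmp_path):
        numeric = _CHAIN_PSF.replace("CT ", "22 ")
        p = tmp_path / "numeric.psf"
        p.write_text(numeric)
        with pytest.raises(ParseError, match="numeric atom types"):
            ffio.read_psf(p)

    def test_write_read_round_trip(self, tmp_path, butane):
        out = tmp_path / "butane.psf"
        ffio.write_psf(butane.system, out)
        back = ffio.read_psf(out)
        assert back.bonds == butane.system.bonds
        assert {a.type_label for a in back.atoms} == {"CT", "HC"}
        norm = lambda trips: {min(t, t[::-1]) for t in trips}
        assert norm(back.angles) == norm(butane.system.angles)
        assert norm(back.dihedrals) == norm(butane.system.dihedrals)


class TestCoordinates:
    def test_xyz_distance(self, tmp_path):
        p = tmp_path / "two.xyz"
        p.write_text("2\npair\nC 0.0 0.0 0.0\nC 1.5 0.0 0.0\n")
        coords = ffio.read_coordinates(p)
        assert np.linalg.norm(coords[1] - coords[0]) == pytest.approx(1.5)

    def test_xyz_round_trip_precision(self, tmp_path, butane):
        out = tmp_path / "b.xyz"
        ffio.write_xyz(butane.conformation.coordinates, out)
        back = ffio.read_coordinates(out)
        assert np.abs(back - butane.conformation.coordinates).max() < 1e-3

    def test_pdb_read_tolerates_minimal_records(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            "ATOM      1  C1  LIG A   1       0.000   0.000   0.000\n"
            "ATOM      2  C2  LIG A   1       1.500   0.000   0.000\n"
            "END\n"
        )
        coords = ffio.read_coordinates(p)
        assert coords.shape == (2, 3)
        assert coords[1, 0] == pytest.approx(1.5, abs=1e-3)

    def test_letters_in_coordinate_field_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nbad\nC abc 0.0 0.0\n")
        with pytest.raises(ParseError):
            ffio.read_coordinates(p)


class TestFixtures:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("GQ16_T1", [(-0.3572, 4, 180.0)]),
            ("GQ16_T2", [(2.8584, 1, 0.0), (5.6498, 2, 180.0), (0.8824, 3, 0.0)]),
            ("GQ16_T3", [(2.4869, 1, 0.0), (10.3926, 2, 180.0), (0.6072, 3, 0.0), (0.8350, 4, 0.0)]),
            ("SR1664_T1", [(0.1795, 1, 0.0), (0.3623, 3, 0.0), (0.4022, 4, 0.0)]),
            ("SR1664_T2", [(0.1000, 1, 180.0), (0.7100, 2, 180.0)]),
            ("SR1664_T3", [(1.5000, 1, 180.0), (0.1900, 2, 0.0), (0.2000, 3, 0.0), (0.7000, 4, 0.0)]),
        ],
    )
    def test_published_terms(self, name, expected):
        terms = ffio.load_fixture(name)
        assert [(t.k, t.n, t.delta) for t in terms] == expected
        assert all(t.delta in (0.0, 180.0) for t in terms)

    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(KeyError, match="GQ16_T1"):
            ffio.load_fixture("RSG_T9")

    def test_net_charges(self):
        assert ffio.FIXTURE_NET_CHARGES == {"SR1664": -1, "GQ16": 0}


class TestParameterSet:
    def test_reversed_lookup_symmetric(self):
        params = ParameterSet()
        params.add_dihedral_term(("A", "B", "C", "D"), DihedralTerm(1.0, 2, 180.0))
        assert params.dihedral_terms(("D", "C", "B", "A")) == params.dihedral_terms(
            ("A", "B", "C", "D")
        )

    def test_exact_beats_wildcard(self):
        params = ParameterSet()
        params.add_dihedral_term(("X", "B", "C", "X"), DihedralTerm(9.0, 1, 0.0))
        params.add_dihedral_term(("A", "B", "C", "D"), DihedralTerm(1.0, 1, 0.0))
        assert params.dihedral_terms(("A", "B", "C", "D"))[0].k == 1.0
        assert params.dihedral_terms(("Z", "B", "C", "Q"))[0].k == 9.0

    def test_one_term_per_multiplicity(self):
        params = ParameterSet()
        params.add_dihedral_term(("A", "B", "C", "D"), DihedralTerm(1.0, 2, 0.0))
        with pytest.raises(ValueError, match="multiplicity"):
            params.add_dihedral_term(("D", "C", "B", "A"), DihedralTerm(2.0, 2, 0.0))

    def test_phase_restricted_to_0_or_180(self):
        with pytest.raises(ValueError):
            DihedralTerm(1.0, 2, 90.0)

    def test_missing_parameter_names_types(self):
        with pytest.raises(KeyError, match="CT"):
            ParameterSet().bond("CT", "HA")
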