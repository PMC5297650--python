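"""Synthetic inputs for the parameterization pipeline.

Quantum-chemical reference data (relaxed torsion profiles, ESP grids) cannot
be computed here, so this module generates stand-ins with known ground
truth: idealized toy molecules with self-consistent parameters, "QM"-role
torsion profiles built from a chosen cosine-term set (plus optional Gaussian
noise), and ESP grids evaluated exactly from known point charges.  Every
generator is a pure function of its seed.

The three named fragments mirror the kind of surrogate used when a large
ligand is cut down for a torsion scan: an aromatic ring amide-linked to a
methyl group, an exocyclic-double-bond (benzylidene-like) linker, and an
N-benzyl-like linker.  Geometries are idealized (standard bond lengths and
angles), and the parameters are generated from the geometry itself, which is
all a scan-and-fit exercise requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .ffio import (
    AngleParam,
    AtomRecord,
    BondParam,
    DihedralTerm,
    LJParam,
    MolecularSystem,
    ParameterSet,
    UreyBradleyParam,
    system_from_bonds,
)
from .mm_energy import Conformation, measure_angle
from .esp_charges import ESPGrid, build_mk_grid, esp_from_point_charges
from .torsion_fit import fitted_profile
from .torsion_scan import Provenance, TorsionProfile

__all__ = [
    "SyntheticCase",
    "SyntheticTorsionSpec",
    "make_toy_butane",
    "make_fragment",
    "FRAGMENT_NAMES",
    "synth_qm_profile",
    "synth_delta_from_terms",
    "synth_esp_case",
]


class SyntheticCase(NamedTuple):
    """A generated molecule: topology, geometry, parameters and the torsion
    quadruple (0-based indices) intended for scanning."""

    system: MolecularSystem
    conformation: Conformation
    params: ParameterSet
    torsion: tuple[int, int, int, int]


# ---------------------------------------------------------------------------
# internal-coordinate atom placement
# ---------------------------------------------------------------------------


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(phi),
         bond * math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# toy butane
# ---------------------------------------------------------------------------

_LJ_TABLE = {
    "CT": LJParam(0.0780, 2.0400),
    "HC": LJParam(0.0240, 1.3400),
    "CA": LJParam(0.0700, 1.9924),
    "HP": LJParam(0.0300, 1.3582),
    "C": LJParam(0.1100, 2.0000),
    "O": LJParam(0.1200, 1.7000),
    "NT": LJParam(0.2000, 1.8500),
    "NA": LJParam(0.2000, 1.8500),
    "HN": LJParam(0.0460, 0.2245),
    "CE1": LJParam(0.0680, 2.0900),
    "CE2": LJParam(0.0640, 2.0800),
    "HE": LJParam(0.0310, 1.2500),
}


def make_toy_butane() -> SyntheticCase:
    """A 14-atom butane-like chain with full connectivity, hand-set
    self-consistent parameters and a staggered (anti) starting geometry.

    The central C2-C3 bond carries 9 equivalent dihedral quadruples
    (3 substituents on each side)."""
    cc, ch = 1.530, 1.090
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([cc, 0.0, 0.0])
    ang = math.radians(180.0 - 112.0)
    c3 = c2 + cc * np.array([math.cos(ang), math.sin(ang), 0.0])
    c4 = _place(c1, c2, c3, cc, 112.0, 180.0)

    h = {}
    for tag, dih in (("H11", 60.0), ("H12", 180.0), ("H13", 300.0)):
        h[tag] = _place(c3, c2, c1, ch, 110.0, dih)
    for tag, dih in (("H21", 60.0), ("H22", 300.0)):
        h[tag] = _place(c4, c3, c2, ch, 110.0, dih)
    for tag, dih in (("H31", 60.0), ("H32", 300.0)):
        h[tag] = _place(c1, c2, c3, ch, 110.0, dih)
    for tag, dih in (("H41", 60.0), ("H42", 180.0), ("H43", 300.0)):
        h[tag] = _place(c2, c3, c4, ch, 110.0, dih)

    names = ["C1", "C2", "C3", "C4"] + list(h)
    coords = np.array([c1, c2, c3, c4] + [h[k] for k in h])
    atoms = []
    for i, name in enumerate(names):
        is_c = name.startswith("C")
        if is_c:
            charge = -0.27 if name in ("C1", "C4") else -0.18
        else:
            charge = 0.09
        atoms.append(
            AtomRecord(
                index=i + 1,
                name=name,
                type_label="CT" if is_c else "HC",
                charge=charge,
                mass=12.011 if is_c else 1.008,
                element="C" if is_c else "H",
            )
        )
    bonds = [(0, 1), (1, 2), (2, 3)]
    h_parent = {"H1": 0, "H2": 1, "H3": 2, "H4": 3}
    for i, name in enumerate(names[4:], start=4):
        bonds.append((h_parent[name[:2]], i))
    system = system_from_bonds(atoms, bonds)

    params = ParameterSet()
    params.add_bond("CT", "CT", BondParam(222.5, cc))
    params.add_bond("CT", "HC", BondParam(309.0, ch))
    u0 = cc * math.sqrt(2.0 * (1.0 - math.cos(math.radians(112.0))))
    params.add_angle("CT", "CT", "CT", AngleParam(58.35, 112.0), ub=UreyBradleyParam(11.16, u0))
    params.add_angle("CT", "CT", "HC", AngleParam(33.43, 110.0))
    params.add_angle("HC", "CT", "HC", AngleParam(35.50, 108.8))
    params.add_dihedral_term(("X", "CT", "CT", "X"), DihedralTerm(0.16, 3, 0.0))
    params.add_lj("CT", _LJ_TABLE["CT"])
    params.add_lj("HC", _LJ_TABLE["HC"])
    return SyntheticCase(system, Conformation(coords), params, (0, 1, 2, 3))


# ---------------------------------------------------------------------------
# surrogate fragments
# ---------------------------------------------------------------------------

FRAGMENT_NAMES = ("amide_T2_like", "benzylidene_T3_like", "n_benzyl_T1_like")

_RING_CC = 1.396
_RING_CH = 1.080


def _benzene_ring(substituted: int = 0) -> tuple[list[str], list[str], np.ndarray, list[tuple[int, int]]]:
    """Planar hexagon in the xy-plane with H on every carbon except index 0.

    Returns (names, types, coords, bonds); carbon 0 sits on the +x axis so a
    substituent attached along +x makes the ring C2-symmetric about the
    substitution axis."""
    names, types, coords, bonds = [], [], [], []
    for i in range(6):
        a = math.radians(60.0 * i)
        names.append(f"C{i + 1}")
        types.append("CA")
        coords.append([_RING_CC * math.cos(a), _RING_CC * math.sin(a), 0.0])
        bonds.append((i, (i + 1) % 6))
    idx = 6
    for i in range(6):
        if i == substituted:
            continue
        a = math.radians(60.0 * i)
        r = _RING_CC + _RING_CH
        names.append(f"H{i + 1}")
        types.append("HP")
        coords.append([r * math.cos(a), r * math.sin(a), 0.0])
        bonds.append((i, idx))
        idx += 1
    return names, types, np.array(coords), bonds


def _default_params_from_geometry(
    system: MolecularSystem,
    conf: Conformation,
    central_terms: Optional[dict[tuple[str, str], DihedralTerm]] = None,
) -> ParameterSet:
    """Placeholder parameters generated from the geometry itself: harmonic
    equilibria at the mean measured value per type key, generic force
    constants, wildcard torsion terms per central type pair, LJ from a small
    per-type table.  Sufficient for rigid-scan and fitting exercises."""
    params = ParameterSet()
    central_terms = central_terms or {}
    x = conf.coordinates

    bond_obs: dict[tuple[str, str], list[float]] = {}
    for i, j in system.bonds:
        key = tuple(sorted(system.type_tuple((i, j))))
        bond_obs.setdefault(key, []).append(float(np.linalg.norm(x[i] - x[j])))
    for (t1, t2), vals in bond_obs.items():
        params.add_bond(t1, t2, BondParam(300.0, float(np.mean(vals))))

    angle_obs: dict[tuple[str, str, str], list[float]] = {}
    for i, j, k in system.angles:
        t = system.type_tuple((i, j, k))
        key = min(t, t[::-1])
        angle_obs.setdefault(key, []).append(measure_angle(conf, (i, j, k)))
    for key, vals in angle_obs.items():
        params.add_angle(*key, AngleParam(50.0, min(float(np.mean(vals)), 180.0)))

    sp2 = {"CA", "C", "CE1", "CE2", "NA"}
    seen_centrals = set()
    for _, b, c, _ in system.dihedrals:
        tb, tc = system.atoms[b].type_label, system.atoms[c].type_label
        key = tuple(sorted((tb, tc)))
        if key in seen_centrals:
            continue
        seen_centrals.add(key)
        term = central_terms.get(key)
        if term is None:
            if tb in sp2 and tc in sp2:
                term = DihedralTerm(1.20, 2, 180.0)
            else:
                term = DihedralTerm(0.16, 3, 0.0)
        params.add_dihedral_term(("X", key[0], key[1], "X"), term)

    for t in {a.type_label for a in system.atoms}:
        params.add_lj(t, _LJ_TABLE[t])
    return params


def _finish_fragment(
    names: list[str],
    types: list[str],
    coords: list | np.ndarray,
    bonds: list[tuple[int, int]],
    charges: dict[str, float],
    torsion: tuple[int, int, int, int],
) -> SyntheticCase:
    coords = np.asarray(coords, dtype=float)
    masses = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
    atoms = [
        AtomRecord(
            index=i + 1,
            name=nm,
            type_label=tp,
            charge=charges.get(nm, 0.0),
            mass=masses[nm[0]],
            element=nm[0],
        )
        for i, (nm, tp) in enumerate(zip(names, types))
    ]
    system = system_from_bonds(atoms, bonds)
    conf = Conformation(coords)
    params = _default_params_from_geometry(system, conf)
    return SyntheticCase(system, conf, params, torsion)


def make_fragment(name: str) -> SyntheticCase:
    """Build one of the named surrogate fragments.

    * ``amide_T2_like`` — N-methylbenzamide-like: aromatic ring, amide link,
      methyl cap; the designated torsion rotates the amide group against the
      (C2-symmetric) ring, so a symmetric parameter set gives a
      180-degree-periodic profile with minima at the planar conformations.
    * ``benzylidene_T3_like`` — styrene-like exocyclic double-bond linker.
    * ``n_benzyl_T1_like`` — benzylamine-like N-CH2-aryl linker.
    """
    if name == "amide_T2_like":
        names, types, ring_xyz, bonds = _benzene_ring()
        coords = list(ring_xyz)
        c1, c2 = coords[0], coords[1]
        c7 = c1 + np.array([1.49, 0.0, 0.0])
        o = _place(c2, c1, c7, 1.23, 121.0, 0.0)
        n = _place(c2, c1, c7, 1.35, 115.0, 180.0)
        hn = _place(c1, c7, n, 1.01, 119.0, 0.0)
        c8 = _place(c1, c7, n, 1.45, 122.0, 180.0)
        extra = [c7, o, n, hn, c8]
        names += ["C7", "O1", "N1", "HN1", "C8"]
        types += ["C", "O", "NA", "HN", "CT"]
        i_c7, i_o, i_n, i_hn, i_c8 = range(len(coords), len(coords) + 5)
        bonds += [(0, i_c7), (i_c7, i_o), (i_c7, i_n), (i_n, i_hn), (i_n, i_c8)]
        coords += extra
        for tag, dih in (("HM1", 60.0), ("HM2", 180.0), ("HM3", 300.0)):
            coords.append(_place(c7, n, c8, 1.09, 109.5, dih))
            names.append(tag)
            types.append("HC")
            bonds.append((i_c8, len(coords) - 1))
        charges = {"C7": 0.50, "O1": -0.50, "N1": -0.31, "HN1": 0.31}
        torsion = (1, 0, i_c7, i_o)  # C2-C1-C7-O: ring vs amide plane
    elif name == "benzylidene_T3_like":
        names, types, ring_xyz, bonds = _benzene_ring()
        coords = list(ring_xyz)
        c1, c2 = coords[0], coords[1]
        c7 = c1 + np.array([1.47, 0.0, 0.0])
        h7 = _place(c2, c1, c7, 1.08, 116.0, 180.0)
        c8 = _place(c2, c1, c7, 1.34, 127.0, 0.0)
        i_c7, i_h7, i_c8 = len(coords), len(coords) + 1, len(coords) + 2
        coords += [c7, h7, c8]
        names += ["C7", "H7", "C8"]
        types += ["CE1", "HE", "CE2"]
        bonds += [(0, i_c7), (i_c7, i_h7), (i_c7, i_c8)]
        for tag, dih in (("H8A", 0.0), ("H8B", 180.0)):
            coords.append(_place(c1, c7, c8, 1.08, 120.0, dih))
            names.append(tag)
            types.append("HE")
            bonds.append((i_c8, len(coords) - 1))
        charges = {}
        torsion = (1, 0, i_c7, i_c8)  # ring vs vinyl plane
    elif name == "n_benzyl_T1_like":
        names, types, ring_xyz, bonds = _benzene_ring()
        coords = list(ring_xyz)
        c1, c2 = coords[0], coords[1]
        c7 = c1 + np.array([1.50, 0.0, 0.0])
        i_c7 = len(coords)
        coords.append(c7)
        names.append("C7")
        types.append("CT")
        bonds.append((0, i_c7))
        n = _place(c2, c1, c7, 1.47, 111.0, 90.0)
        i_n = len(coords)
        coords.append(n)
        names.append("N1")
        types.append("NT")
        bonds.append((i_c7, i_n))
        for tag, dih in (("H7A", 90.0 + 120.0), ("H7B", 90.0 - 120.0)):
            coords.append(_place(c2, c1, c7, 1.09, 109.5, dih))
            names.append(tag)
            types.append("HC")
            bonds.append((i_c7, len(coords) - 1))
        for tag, dih in (("HN1", 60.0), ("HN2", 300.0)):
            coords.append(_place(c1, c7, n, 1.01, 109.5, dih))
            names.append(tag)
            types.append("HN")
            bonds.append((i_n, len(coords) - 1))
        charges = {"N1": -0.62, "HN1": 0.31, "HN2": 0.31}
        torsion = (0, i_c7, i_n, len(coords) - 2)  # C1-C7-N1-HN1
    else:
        raise KeyError(
            f"unknown fragment {name!r}; valid names: {', '.join(FRAGMENT_NAMES)}"
        )
    return _finish_fragment(names, types, coords, bonds, charges, torsion)


# ---------------------------------------------------------------------------
# synthetic torsion profiles
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTorsionSpec:
    """Ground truth for a synthetic "QM"-role profile."""

    true_terms: tuple[DihedralTerm, ...]
    noise_sd: float = 0.0  # kcal/mol, i.i.d. Gaussian per grid point
    seed: int = 0
    grid_step: float = 20.0  # degrees

    def __post_init__(self) -> None:
        self.true_terms = tuple(self.true_terms)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_step <= 0 or abs(360.0 / self.grid_step - round(360.0 / self.grid_step)) > 1e-9:
            raise ValueError("grid_step must divide 360")


def synth_qm_profile(spec: SyntheticTorsionSpec, mm: TorsionProfile) -> TorsionProfile:
    """A quantum-role profile: the classical profile plus the true torsion
    terms plus optional Gaussian noise, minimum-shifted.  Deterministic for a
    fixed seed."""
    grid = mm.angles
    series = fitted_profile(spec.true_terms, grid).energies
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(grid)) if spec.noise_sd > 0 else 0.0
    energies = mm.energies + series + noise
    energies = energies - energies.min()
    return TorsionProfile(angles=grid.copy(), energies=energies, provenance=Provenance.SYNTHETIC)


def synth_delta_from_terms(
    terms: Sequence[DihedralTerm],
    grid_step: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TorsionProfile:
    """Noisy or noise-free difference profile generated directly from a term
    set on the full-revolution grid (0..360 inclusive)."""
    spec = SyntheticTorsionSpec(tuple(terms), noise_sd=noise_sd, seed=seed, grid_step=grid_step)
    angles = np.arange(0.0, 360.0 + 0.5 * grid_step, grid_step)
    flat = TorsionProfile(
        angles=angles, energies=np.zeros_like(angles), provenance=Provenance.FITTED
    )
    qm = synth_qm_profile(spec, flat)
    return TorsionProfile(angles=angles, energies=qm.energies, provenance=Provenance.DELTA)


# ---------------------------------------------------------------------------
# synthetic ESP cases
# ---------------------------------------------------------------------------


def synth_esp_case(
    n_atoms: int, seed: int, density: float = 1.0
) -> tuple[np.ndarray, np.ndarray, ESPGrid]:
    """Random non-degenerate point-charge system with an exact MK-style grid.

    Charges sum exactly to an integer net charge in {-1, 0, +1}; grid values
    are the exact Coulomb potential of the generating charges."""
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    positions = []
    while len(positions) < n_atoms:
        cand = rng.uniform(-2.0, 2.0, size=3)
        if all(np.linalg.norm(cand - p) >= 1.5 for p in positions):
            positions.append(cand)
    positions = np.array(positions)
    charges = rng.normal(0.0, 0.3, size=n_atoms)
    net = int(rng.integers(-1, 2))
    charges += (net - charges.sum()) / n_atoms
    radii = rng.uniform(1.4, 1.9, size=n_atoms)
    grid = build_mk_grid(positions, radii, density=density, seed=seed)
    values = esp_from_point_charges(charges, positions, grid)
    return positions, charges, grid.with_values(values)
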