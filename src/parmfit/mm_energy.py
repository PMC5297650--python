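"""Molecular-mechanics energy evaluation for the CHARMM additive potential.

The total energy is the sum of harmonic bond, angle, Urey-Bradley and
improper terms, a cosine-series dihedral term, 12-6 Lennard-Jones and
Coulomb nonbonded terms:

    V = sum_b k_b (b - b0)^2 + sum_th k_th (th - th0)^2
      + sum_UB k_u (u - u0)^2 + sum_phi k_n [1 + cos(n phi - delta_n)]
      + sum_imp k_w (w - w0)^2
      + sum_pairs eps_ij [(Rmin_ij / r)^12 - 2 (Rmin_ij / r)^6]
      + sum_pairs C q_i q_j / r

with C = 332.0716 kcal A / (mol e^2).  1-2 and 1-3 pairs are excluded from
the nonbonded sum; 1-4 pairs are included at full strength, using the 1-4
Lennard-Jones overrides when the parameter set provides them.  No cutoff is
applied: the targets are single small molecules in vacuum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .ffio import (
    DihedralTerm,
    MolecularSystem,
    ParameterSet,
    _canon_quad,
)

__all__ = [
    "Conformation",
    "EnergyBreakdown",
    "GeometryError",
    "measure_dihedral",
    "measure_angle",
    "rotate_dihedral",
    "dihedral_term_energy",
    "eval_energy",
    "lj_pair_params",
]


class GeometryError(ValueError):
    """Degenerate or invalid molecular geometry."""


@dataclass
class Conformation:
    """Cartesian coordinates (Angstrom) aligned to a MolecularSystem's atom order."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coordinates)

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy())


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies, kcal/mol."""

    bond: float
    angle: float
    urey_bradley: float
    dihedral: float
    improper: float
    lennard_jones: float
    coulomb: float

    @property
    def total(self) -> float:
        return (
            self.bond
            + self.angle
            + self.urey_bradley
            + self.dihedral
            + self.improper
            + self.lennard_jones
            + self.coulomb
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "urey_bradley": self.urey_bradley,
            "dihedral": self.dihedral,
            "improper": self.improper,
            "lennard_jones": self.lennard_jones,
            "coulomb": self.coulomb,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# internal coordinates
# ---------------------------------------------------------------------------


def measure_angle(conf: Conformation, triple: tuple[int, int, int]) -> float:
    """Bond angle i-j-k in degrees."""
    x = conf.coordinates
    v1 = x[triple[0]] - x[triple[1]]
    v2 = x[triple[2]] - x[triple[1]]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise GeometryError(f"coincident atoms in angle {triple}")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def measure_dihedral(conf: Conformation, quadruple: tuple[int, int, int, int]) -> float:
    """Dihedral angle of four atoms, degrees in (-180, 180].

    Sign follows the IUPAC convention (positive clockwise looking from atom 2
    toward atom 3); reversing the quadruple leaves the value unchanged.
    """
    i, j, k, l = quadruple
    if len({i, j, k, l}) != 4:
        raise GeometryError(f"dihedral atoms must be distinct: {quadruple}")
    x = conf.coordinates
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError(f"collinear atoms in dihedral {quadruple}")
    b2n = b2 / np.linalg.norm(b2)
    # signed angle between the two plane normals about the central bond axis;
    # positive clockwise looking from atom 2 toward atom 3, invariant under
    # reversal of the quadruple
    angle = math.degrees(
        math.atan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2))
    )
    # fold onto (-180, 180]
    if angle <= -180.0:
        angle += 360.0
    if angle == -180.0:
        angle = 180.0
    return angle


def rotatable_sides(
    system: MolecularSystem, bond: tuple[int, int]
) -> tuple[set[int], set[int]]:
    """Split the bond graph by removing ``bond``; error unless exactly two parts.

    Returns the component containing bond[0] first.
    """
    a, b = bond
    if not system.has_bond(a, b):
        raise ValueError(f"atoms {a} and {b} are not bonded")
    g = nx.Graph()
    g.add_nodes_from(range(system.n_atoms))
    g.add_edges_from(system.bonds)
    g.remove_edge(a, b)
    comps = list(nx.connected_components(g))
    if len(comps) != 2:
        raise GeometryError(
            f"bond ({a}, {b}) is not a rotatable bond: removing it leaves "
            f"{len(comps)} connected component(s) (ring bond or fragmented system)"
        )
    side_a = next(c for c in comps if a in c)
    side_b = next(c for c in comps if b in c)
    return side_a, side_b


def rotate_dihedral(
    conf: Conformation,
    system: MolecularSystem,
    quadruple: tuple[int, int, int, int],
    target: float,
) -> Conformation:
    """Rigidly rotate the far side of a torsion so the dihedral equals ``target``.

    Atoms on the side of the central bond containing atom 1 are unmoved; the
    side containing atoms 3 and 4 rotates as a rigid body about the central
    bond axis.  Both sides keep all their internal distances exactly.
    """
    i, j, k, l = quadruple
    side_j, side_k = rotatable_sides(system, (j, k))
    if i not in side_j or l not in side_k:
        raise GeometryError(
            f"quadruple {quadruple} does not straddle the central bond ({j}, {k})"
        )
    current = measure_dihedral(conf, quadruple)
    delta = math.radians(target - current)
    x = conf.coordinates.copy()
    axis = x[k] - x[j]
    axis = axis / np.linalg.norm(axis)
    # right-hand rotation of the k-side about j->k increases phi
    rot = Rotation.from_rotvec(-delta * axis)
    moving = sorted(side_k)
    x[moving] = rot.apply(x[moving] - x[k]) + x[k]
    out = Conformation(x)
    achieved = measure_dihedral(out, quadruple)
    err = (achieved - target + 180.0) % 360.0 - 180.0
    if abs(err) > 1e-6:
        # sign convention flipped for this geometry: rotate the other way
        rot = Rotation.from_rotvec(2 * delta * axis)
        x[moving] = rot.apply(x[moving] - x[k]) + x[k]
        out = Conformation(x)
        achieved = measure_dihedral(out, quadruple)
        err = (achieved - target + 180.0) % 360.0 - 180.0
        if abs(err) > 1e-6:
            raise GeometryError(
                f"failed to set dihedral {quadruple} to {target} (got {achieved})"
            )
    return out


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------


def dihedral_term_energy(term: DihedralTerm, phi: float) -> float:
    """k * (1 + cos(n*phi - delta)) with phi in degrees."""
    return term.k * (1.0 + math.cos(math.radians(term.n * phi - term.delta)))


def lj_pair_params(
    params: ParameterSet, type_i: str, type_j: str, one_four: bool = False
) -> tuple[float, float]:
    """Combined (eps_ij, Rmin_ij) by the CHARMM rule: arithmetic Rmin/2,
    geometric well depth.  For 1-4 pairs the per-type 1-4 overrides are used
    where present."""
    pi = params.lj_param(type_i)
    pj = params.lj_param(type_j)

    def _eff(p):
        if one_four and p.well_depth_14 is not None and p.r_min_half_14 is not None:
            return p.well_depth_14, p.r_min_half_14
        return p.well_depth, p.r_min_half

    ei, ri = _eff(pi)
    ej, rj = _eff(pj)
    return math.sqrt(ei * ej), ri + rj


@dataclass
class EnergyOptions:
    """Evaluation options.

    ``zeroed_dihedral_type_quadruples`` lists atom-type quadruples whose
    dihedral terms contribute zero — used while fitting a torsion, where the
    classical profile must exclude the terms being (re)fitted.
    """

    zeroed_dihedral_type_quadruples: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.zeroed_dihedral_type_quadruples = frozenset(
            _canon_quad(tuple(q)) for q in self.zeroed_dihedral_type_quadruples
        )


def eval_energy(
    system: MolecularSystem,
    conf: Conformation,
    params: ParameterSet,
    options: Optional[EnergyOptions] = None,
) -> EnergyBreakdown:
    """Evaluate the full additive potential for one conformation.

    Every bonded term of the system must resolve to a parameter (Urey-Bradley
    terms are evaluated only for angle types that carry UB parameters, as in
    CHARMM); dihedral quadruples whose type tuple is listed in
    ``options.zeroed_dihedral_type_quadruples`` contribute zero.
    """
    if options is None:
        options = EnergyOptions()
    if len(conf) != system.n_atoms:
        raise ValueError(
            f"conformation has {len(conf)} atoms, system has {system.n_atoms}"
        )
    x = conf.coordinates

    e_bond = 0.0
    for i, j in system.bonds:
        p = params.bond(*system.type_tuple((i, j)))
        b = float(np.linalg.norm(x[i] - x[j]))
        e_bond += p.force_constant * (b - p.equilibrium) ** 2

    e_angle = 0.0
    e_ub = 0.0
    for i, j, k in system.angles:
        t = system.type_tuple((i, j, k))
        p = params.angle(*t)
        theta = math.radians(measure_angle(conf, (i, j, k)))
        e_angle += p.force_constant * (theta - math.radians(p.equilibrium)) ** 2
        ub = params.urey_bradley_param(*t)
        if ub is not None:
            u = float(np.linalg.norm(x[i] - x[k]))
            e_ub += ub.force_constant * (u - ub.equilibrium) ** 2

    e_dihedral = 0.0
    for quad in system.dihedrals:
        ttup = _canon_quad(system.type_tuple(quad))
        if ttup in options.zeroed_dihedral_type_quadruples:
            continue
        phi = measure_dihedral(conf, quad)
        for term in params.dihedral_terms(ttup):
            e_dihedral += dihedral_term_energy(term, phi)

    e_improper = 0.0
    for quad in system.impropers:
        p = params.improper(system.type_tuple(quad))
        omega = math.radians(measure_dihedral(conf, quad))
        e_improper += p.force_constant * (omega - math.radians(p.equilibrium)) ** 2

    e_lj = 0.0
    e_coul = 0.0
    dist = system.bonded_distances(max_depth=3)
    excluded_depths = {
        "none": set(),
        "1-2": {1},
        "1-2+1-3": {1, 2},
        "1-2+1-3+scaled-1-4-off": {1, 2},
    }[system.exclusion_policy]
    n = system.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            d = dist.get((i, j))
            if d in excluded_depths:
                continue
            r = float(np.linalg.norm(x[i] - x[j]))
            if r < 1e-6:
                raise GeometryError(
                    f"overlapping nonbonded atoms {i} and {j} (r = {r:.2e} A)"
                )
            ti, tj = system.atoms[i].type_label, system.atoms[j].type_label
            eps, rmin = lj_pair_params(params, ti, tj, one_four=(d == 3))
            if eps != 0.0:
                sr6 = (rmin / r) ** 6
                e_lj += eps * (sr6 * sr6 - 2.0 * sr6)
            qi, qj = system.atoms[i].charge, system.atoms[j].charge
            if qi != 0.0 and qj != 0.0:
                e_coul += params.coulomb_constant * qi * qj / r

    return EnergyBreakdown(
        bond=e_bond,
        angle=e_angle,
        urey_bradley=e_ub,
        dihedral=e_dihedral,
        improper=e_improper,
        lennard_jones=e_lj,
        coulomb=e_coul,
    )
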