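"""Force-field file I/O: CHARMM parameter (PRM) files, X-PLOR PSF topologies,
PDB/XYZ coordinates, and the packaged ligand-torsion fixtures.

Conventions
-----------
* Units at every boundary: kcal/mol, Angstrom, degrees, elementary charge, amu.
* Atom indices in connectivity tuples are 0-based; ``AtomRecord.index`` keeps
  the 1-based serial from the source file.
* Lennard-Jones well depths are stored positive (CHARMM files print them
  negative; the sign is normalized on read).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WILDCARD = "X"

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "BondParam",
    "AngleParam",
    "UreyBradleyParam",
    "ImproperParam",
    "DihedralTerm",
    "LJParam",
    "ParameterSet",
    "ParseError",
    "ParameterLookupError",
    "read_prm",
    "write_prm",
    "read_psf",
    "write_psf",
    "read_coordinates",
    "write_xyz",
    "load_fixture",
    "fixture_names",
    "FIXTURE_NET_CHARGES",
]


class ParseError(ValueError):
    """A force-field or topology file could not be parsed."""


class ParameterLookupError(KeyError):
    """A required parameter is missing from a ParameterSet."""

    def __str__(self) -> str:  # KeyError quotes its repr; we want the message
        return self.args[0] if self.args else ""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a molecular system.

    ``index`` is the 1-based serial from the source file; ``type_label`` is the
    force-field atom type that keys every parameter lookup.
    """

    index: int
    name: str
    type_label: str
    charge: float
    mass: float
    element: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be > 0, got {self.mass}")
        if not self.type_label:
            raise ValueError(f"atom {self.index}: empty atom type")


@dataclass(frozen=True)
class BondParam:
    force_constant: float  # kcal/mol/A^2
    equilibrium: float  # A

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("bond force constant must be >= 0")


@dataclass(frozen=True)
class AngleParam:
    force_constant: float  # kcal/mol/rad^2
    equilibrium: float  # degrees

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("angle force constant must be >= 0")
        if not 0.0 < self.equilibrium <= 180.0:
            raise ValueError(f"equilibrium angle must be in (0, 180], got {self.equilibrium}")


@dataclass(frozen=True)
class UreyBradleyParam:
    force_constant: float  # kcal/mol/A^2
    equilibrium: float  # A (1-3 distance)

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("Urey-Bradley force constant must be >= 0")


@dataclass(frozen=True)
class ImproperParam:
    force_constant: float  # kcal/mol/rad^2
    equilibrium: float  # degrees

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("improper force constant must be >= 0")


@dataclass(frozen=True)
class DihedralTerm:
    """One cosine term k*(1 + cos(n*phi - delta)) of a torsion potential.

    ``k`` may be negative under the signed-k convention (a negative amplitude
    with delta=180 equals the positive amplitude with delta=0 up to an additive
    constant).  ``delta`` is restricted to 0 or 180 degrees, which is what
    makes torsion fitting linear in k.
    """

    k: float  # kcal/mol
    n: int
    delta: float  # degrees, 0 or 180

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"multiplicity must be a positive integer, got {self.n}")
        if self.delta not in (0.0, 180.0):
            raise ValueError(f"phase must be 0 or 180 degrees, got {self.delta}")


@dataclass(frozen=True)
class LJParam:
    """Like-pair 12-6 Lennard-Jones parameters, positive well-depth convention."""

    well_depth: float  # kcal/mol, >= 0
    r_min_half: float  # A, half the like-pair minimum distance
    well_depth_14: Optional[float] = None
    r_min_half_14: Optional[float] = None

    def __post_init__(self) -> None:
        if self.well_depth < 0:
            raise ValueError("LJ well depth must be >= 0 (positive convention)")
        if self.r_min_half <= 0:
            raise ValueError("LJ r_min/2 must be > 0")


def _canon_pair(key: tuple[str, str]) -> tuple[str, str]:
    return min(key, tuple(reversed(key)))


def _canon_triple(key: tuple[str, str, str]) -> tuple[str, str, str]:
    return min(key, tuple(reversed(key)))


def _canon_quad(key: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    return min(key, tuple(reversed(key)))


@dataclass
class ParameterSet:
    """All parameters of the CHARMM functional form, keyed by atom-type tuples.

    Lookups are symmetric under reversal of the type tuple.  Dihedral keys
    support the CHARMM ``X`` wildcard in the two outer positions; an exact
    quadruple match takes precedence over a wildcard match.
    """

    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    urey_bradley: dict[tuple[str, str, str], UreyBradleyParam] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], tuple[DihedralTerm, ...]] = field(
        default_factory=dict
    )
    impropers: dict[tuple[str, str, str, str], ImproperParam] = field(default_factory=dict)
    lj: dict[str, LJParam] = field(default_factory=dict)
    coulomb_constant: float = 332.0716  # kcal*A/mol/e^2, CHARMM convention

    # -- record insertion ---------------------------------------------------

    def add_bond(self, t1: str, t2: str, param: BondParam) -> None:
        self.bonds[_canon_pair((t1, t2))] = param

    def add_angle(
        self,
        t1: str,
        t2: str,
        t3: str,
        param: AngleParam,
        ub: Optional[UreyBradleyParam] = None,
    ) -> None:
        key = _canon_triple((t1, t2, t3))
        self.angles[key] = param
        if ub is not None:
            self.urey_bradley[key] = ub

    def add_dihedral_term(self, types: tuple[str, str, str, str], term: DihedralTerm) -> None:
        key = _canon_quad(types)
        terms = list(self.dihedrals.get(key, ()))
        if any(t.n == term.n for t in terms):
            raise ValueError(
                f"dihedral {key}: duplicate term for multiplicity {term.n}"
            )
        terms.append(term)
        self.dihedrals[key] = tuple(sorted(terms, key=lambda t: t.n))

    def add_improper(self, types: tuple[str, str, str, str], param: ImproperParam) -> None:
        self.impropers[_canon_quad(types)] = param

    def add_lj(self, type_label: str, param: LJParam) -> None:
        self.lj[type_label] = param

    # -- lookups ------------------------------------------------------------

    def bond(self, t1: str, t2: str) -> BondParam:
        try:
            return self.bonds[_canon_pair((t1, t2))]
        except KeyError:
            raise ParameterLookupError(f"no bond parameter for types ({t1}, {t2})") from None

    def angle(self, t1: str, t2: str, t3: str) -> AngleParam:
        try:
            return self.angles[_canon_triple((t1, t2, t3))]
        except KeyError:
            raise ParameterLookupError(
                f"no angle parameter for types ({t1}, {t2}, {t3})"
            ) from None

    def urey_bradley_param(self, t1: str, t2: str, t3: str) -> Optional[UreyBradleyParam]:
        """UB terms are an optional part of a CHARMM angle; None means absent."""
        return self.urey_bradley.get(_canon_triple((t1, t2, t3)))

    def dihedral_terms(
        self, types: tuple[str, str, str, str]
    ) -> tuple[DihedralTerm, ...]:
        key = _canon_quad(types)
        if key in self.dihedrals:
            return self.dihedrals[key]
        wild = _canon_quad((WILDCARD, types[1], types[2], WILDCARD))
        if wild in self.dihedrals:
            return self.dihedrals[wild]
        raise ParameterLookupError(f"no dihedral parameters for types {types}")

    def improper(self, types: tuple[str, str, str, str]) -> ImproperParam:
        key = _canon_quad(types)
        if key in self.impropers:
            return self.impropers[key]
        wild = _canon_quad((types[0], WILDCARD, WILDCARD, types[3]))
        if wild in self.impropers:
            return self.impropers[wild]
        raise ParameterLookupError(f"no improper parameter for types {types}")

    def lj_param(self, type_label: str) -> LJParam:
        try:
            return self.lj[type_label]
        except KeyError:
            raise ParameterLookupError(f"no Lennard-Jones parameter for type {type_label}") from None


# ---------------------------------------------------------------------------
# molecular system
# ---------------------------------------------------------------------------


EXCLUSION_POLICIES = ("none", "1-2", "1-2+1-3", "1-2+1-3+scaled-1-4-off")


@dataclass
class MolecularSystem:
    """Atoms plus the connectivity that defines every bonded summation.

    Connectivity uses 0-based atom indices.  ``urey_bradley_pairs`` (the 1-3
    pairs of the angle list) is derived automatically when left empty.
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    angles: set[tuple[int, int, int]] = field(default_factory=set)
    urey_bradley_pairs: set[tuple[int, int]] = field(default_factory=set)
    dihedrals: set[tuple[int, int, int, int]] = field(default_factory=set)
    impropers: set[tuple[int, int, int, int]] = field(default_factory=set)
    exclusion_policy: str = "1-2+1-3"

    def __post_init__(self) -> None:
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        if not self.urey_bradley_pairs:
            self.urey_bradley_pairs = {
                tuple(sorted((i, k))) for i, _, k in self.angles
            }
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.exclusion_policy not in EXCLUSION_POLICIES:
            raise ValueError(f"unknown exclusion policy {self.exclusion_policy!r}")
        n = len(self.atoms)
        for group in (self.bonds, self.angles, self.urey_bradley_pairs, self.dihedrals, self.impropers):
            for tup in group:
                for i in tup:
                    if not 0 <= i < n:
                        raise ValueError(
                            f"connectivity index {i} out of range for {n} atoms: {tup}"
                        )
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
        for i, j, k in self.angles:
            if not (self.has_bond(i, j) and self.has_bond(j, k)):
                raise ValueError(f"angle {(i, j, k)} inconsistent with bond set")
        for i, j, k, l in self.dihedrals:
            if not (self.has_bond(i, j) and self.has_bond(j, k) and self.has_bond(k, l)):
                raise ValueError(f"dihedral {(i, j, k, l)} inconsistent with bond set")

    # -- helpers ------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def has_bond(self, i: int, j: int) -> bool:
        return tuple(sorted((i, j))) in self.bonds

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def type_tuple(self, indices: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.atoms[i].type_label for i in indices)

    def bonded_distances(self, max_depth: int = 3) -> dict[tuple[int, int], int]:
        """Minimum bond-graph distance (1, 2 or 3) per atom pair, for exclusions."""
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        dist: dict[tuple[int, int], int] = {}
        for start in range(self.n_atoms):
            seen = {start: 0}
            frontier = [start]
            for depth in range(1, max_depth + 1):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in seen:
                            seen[v] = depth
                            nxt.append(v)
                frontier = nxt
            for v, d in seen.items():
                if v > start:
                    dist[(start, v)] = d
        return dist


def system_from_bonds(
    atoms: list[AtomRecord],
    bonds: Iterable[tuple[int, int]],
    impropers: Iterable[tuple[int, int, int, int]] = (),
    exclusion_policy: str = "1-2+1-3",
) -> MolecularSystem:
    """Build a MolecularSystem enumerating angles and dihedrals from the bond graph."""
    bond_set = {tuple(sorted(b)) for b in bonds}
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for a, b in bond_set:
        adj[a].add(b)
        adj[b].add(a)
    angles = set()
    for j in adj:
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.add((nb[x], j, nb[y]))
    dihedrals = set()
    for b, c in bond_set:
        for a in adj[b] - {c}:
            for d in adj[c] - {b}:
                if a != d:
                    quad = (a, b, c, d)
                    if quad[::-1] not in dihedrals:
                        dihedrals.add(quad)
    return MolecularSystem(
        atoms=atoms,
        bonds=bond_set,
        angles=angles,
        dihedrals=dihedrals,
        impropers={tuple(q) for q in impropers},
        exclusion_policy=exclusion_policy,
    )


# ---------------------------------------------------------------------------
# PRM reading / writing
# ---------------------------------------------------------------------------

_SECTION_ALIASES = {
    "BONDS": "BONDS",
    "BOND": "BONDS",
    "ANGLES": "ANGLES",
    "ANGLE": "ANGLES",
    "THETAS": "ANGLES",
    "DIHEDRALS": "DIHEDRALS",
    "DIHEDRAL": "DIHEDRALS",
    "PHI": "DIHEDRALS",
    "IMPROPER": "IMPROPER",
    "IMPROPERS": "IMPROPER",
    "IMPHI": "IMPROPER",
    "NONBONDED": "NONBONDED",
    "CMAP": "CMAP",
    "NBFIX": "NBFIX",
    "HBOND": "HBOND",
    "END": "END",
    "ATOMS": "ATOMS",
    "MASS": "ATOMS",
}


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed numeric field {token!r}") from None


def _parse_int(token: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed integer field {token!r}") from None


def read_prm(path: str | Path) -> ParameterSet:
    """Parse a CHARMM 'flat' parameter stream.

    Sections BONDS / ANGLES / DIHEDRALS / IMPROPER / NONBONDED are read;
    CMAP, NBFIX, HBOND and ATOMS sections are recognized and skipped with a
    logged warning.  ``!`` starts a comment; a trailing ``-`` continues the
    line (used on NONBONDED headers).
    """
    path = Path(path)
    section = None
    params = ParameterSet()
    seen_lines: dict[object, tuple[int, tuple]] = {}

    raw_lines = path.read_text().splitlines()
    # join continuation lines, remembering original numbering
    lines: list[tuple[int, str]] = []
    pending = ""
    pending_no = 0
    for lineno, raw in enumerate(raw_lines, start=1):
        text = raw.split("!", 1)[0].rstrip()
        if not pending:
            pending_no = lineno
        if text.endswith("-"):
            pending += text[:-1] + " "
            continue
        lines.append((pending_no, (pending + text).strip()))
        pending = ""

    skip_nonbonded_header_tail = False
    for lineno, line in lines:
        if not line:
            continue
        tokens = line.split()
        head = tokens[0].upper()
        if head in _SECTION_ALIASES and (
            len(tokens) == 1 or head in ("NONBONDED", "CMAP", "HBOND", "END")
        ):
            section = _SECTION_ALIASES[head]
            if section in ("CMAP", "NBFIX", "HBOND", "ATOMS"):
                logger.warning("%s:%d: skipping unsupported section %s", path, lineno, head)
            if section == "END":
                break
            continue
        if section is None:
            logger.warning("%s:%d: line outside any recognized section skipped", path, lineno)
            continue
        if section in ("CMAP", "NBFIX", "HBOND", "ATOMS"):
            continue

        if section == "BONDS":
            if len(tokens) < 4:
                raise ParseError(f"{path}:{lineno}: bond line needs 4 fields")
            key = _canon_pair((tokens[0], tokens[1]))
            rec = BondParam(
                _parse_float(tokens[2], str(path), lineno),
                _parse_float(tokens[3], str(path), lineno),
            )
            _check_duplicate(params.bonds, key, rec, seen_lines, ("bond", key), path, lineno)
            params.bonds[key] = rec
        elif section == "ANGLES":
            if len(tokens) < 5:
                raise ParseError(f"{path}:{lineno}: angle line needs >= 5 fields")
            key = _canon_triple((tokens[0], tokens[1], tokens[2]))
            rec = AngleParam(
                _parse_float(tokens[3], str(path), lineno),
                _parse_float(tokens[4], str(path), lineno),
            )
            _check_duplicate(params.angles, key, rec, seen_lines, ("angle", key), path, lineno)
            params.angles[key] = rec
            if len(tokens) >= 7:
                params.urey_bradley[key] = UreyBradleyParam(
                    _parse_float(tokens[5], str(path), lineno),
                    _parse_float(tokens[6], str(path), lineno),
                )
        elif section == "DIHEDRALS":
            if len(tokens) < 7:
                raise ParseError(f"{path}:{lineno}: dihedral line needs 7 fields")
            key = _canon_quad(tuple(tokens[0:4]))
            term = DihedralTerm(
                k=_parse_float(tokens[4], str(path), lineno),
                n=_parse_int(tokens[5], str(path), lineno),
                delta=_parse_float(tokens[6], str(path), lineno),
            )
            dupkey = ("dihedral", key, term.n)
            existing = params.dihedrals.get(key, ())
            match = next((t for t in existing if t.n == term.n), None)
            if match is not None:
                if match != term:
                    prev = seen_lines[dupkey][0]
                    raise ParseError(
                        f"{path}:{lineno}: conflicting dihedral record for {key} "
                        f"multiplicity {term.n} (previous at line {prev})"
                    )
            else:
                params.dihedrals[key] = tuple(
                    sorted(existing + (term,), key=lambda t: t.n)
                )
            seen_lines[dupkey] = (lineno, (term,))
        elif section == "IMPROPER":
            if len(tokens) < 7:
                raise ParseError(f"{path}:{lineno}: improper line needs 7 fields")
            key = _canon_quad(tuple(tokens[0:4]))
            rec = ImproperParam(
                _parse_float(tokens[4], str(path), lineno),
                _parse_float(tokens[6], str(path), lineno),
            )
            _check_duplicate(params.impropers, key, rec, seen_lines, ("improper", key), path, lineno)
            params.impropers[key] = rec
        elif section == "NONBONDED":
            if head in ("CUTNB", "NBXMOD", "E14FAC", "EPS"):
                continue  # nonbonded header options
            if len(tokens) < 4:
                raise ParseError(f"{path}:{lineno}: nonbonded line needs >= 4 fields")
            type_label = tokens[0]
            eps = _parse_float(tokens[2], str(path), lineno)
            rmin2 = _parse_float(tokens[3], str(path), lineno)
            eps14 = rmin2_14 = None
            if len(tokens) >= 7:
                eps14 = abs(_parse_float(tokens[5], str(path), lineno))
                rmin2_14 = _parse_float(tokens[6], str(path), lineno)
            rec = LJParam(abs(eps), rmin2, eps14, rmin2_14)
            _check_duplicate(params.lj, type_label, rec, seen_lines, ("lj", type_label), path, lineno)
            params.lj[type_label] = rec
    return params


def _check_duplicate(mapping, key, rec, seen_lines, dupkey, path, lineno) -> None:
    if key in mapping and mapping[key] != rec:
        prev = seen_lines[dupkey][0]
        raise ParseError(
            f"{path}:{lineno}: conflicting duplicate record for {key} "
            f"(previous at line {prev})"
        )
    seen_lines[dupkey] = (lineno, (rec,))


def _fmt(x: float) -> str:
    # six decimals normally; full precision when the short form would not
    # re-read to the identical value (keeps write->read lossless)
    short = f"{x:.6f}"
    return short if float(short) == x else f"{x:.17g}"


def write_prm(params: ParameterSet, path: str | Path) -> None:
    """Emit a CHARMM-dialect parameter file that re-reads to an equal set.

    Numeric fields are printed with six decimal places.
    """
    path = Path(path)
    out = ["! parameter file written by parmfit", ""]
    out.append("BONDS")
    for (t1, t2), p in sorted(params.bonds.items()):
        out.append(f"{t1:<6s} {t2:<6s} {_fmt(p.force_constant):>12s} {_fmt(p.equilibrium):>12s}")
    out.append("")
    out.append("ANGLES")
    for key, p in sorted(params.angles.items()):
        t1, t2, t3 = key
        line = f"{t1:<6s} {t2:<6s} {t3:<6s} {_fmt(p.force_constant):>12s} {_fmt(p.equilibrium):>12s}"
        ub = params.urey_bradley.get(key)
        if ub is not None:
            line += f" {_fmt(ub.force_constant):>12s} {_fmt(ub.equilibrium):>12s}"
        out.append(line)
    out.append("")
    out.append("DIHEDRALS")
    for key, terms in sorted(params.dihedrals.items()):
        t1, t2, t3, t4 = key
        for term in terms:
            out.append(
                f"{t1:<6s} {t2:<6s} {t3:<6s} {t4:<6s} "
                f"{_fmt(term.k):>12s} {term.n:>3d} {_fmt(term.delta):>10s}"
            )
    out.append("")
    out.append("IMPROPER")
    for key, p in sorted(params.impropers.items()):
        t1, t2, t3, t4 = key
        out.append(
            f"{t1:<6s} {t2:<6s} {t3:<6s} {t4:<6s} "
            f"{_fmt(p.force_constant):>12s}   0 {_fmt(p.equilibrium):>10s}"
        )
    out.append("")
    out.append("NONBONDED")
    for t, p in sorted(params.lj.items()):
        line = f"{t:<6s} 0.000000 {_fmt(-p.well_depth):>12s} {_fmt(p.r_min_half):>12s}"
        if p.well_depth_14 is not None and p.r_min_half_14 is not None:
            line += f" 0.000000 {_fmt(-p.well_depth_14):>12s} {_fmt(p.r_min_half_14):>12s}"
        out.append(line)
    out.append("")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------


def read_psf(path: str | Path) -> MolecularSystem:
    """Read an X-PLOR PSF topology (string atom types) into a MolecularSystem.

    Parsing is delegated to MDAnalysis; section counts and index ranges are
    validated afterwards.  PSF files with purely numeric (CHARMM-format) atom
    types are rejected.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), topology_format="PSF")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: PSF parse failed: {exc}") from exc

    types = [str(t) for t in u.atoms.types]
    if all(t.isdigit() for t in types):
        raise ParseError(
            f"{path}: numeric atom types found; only the X-PLOR PSF dialect "
            "(string atom types) is supported"
        )
    atoms = [
        AtomRecord(
            index=i + 1,
            name=str(u.atoms.names[i]),
            type_label=types[i],
            charge=float(u.atoms.charges[i]),
            mass=float(u.atoms.masses[i]),
            element=_element_from_mass(float(u.atoms.masses[i])),
        )
        for i in range(len(u.atoms))
    ]
    n = len(atoms)

    def _validated(section: str, tuples: Iterable[tuple[int, ...]]) -> set:
        out = set()
        for tup in tuples:
            for i in tup:
                if not 0 <= i < n:
                    raise ParseError(
                        f"{path}: section {section}: atom index {i + 1} exceeds NATOM={n}"
                    )
            out.add(tuple(int(i) for i in tup))
        return out

    try:
        bonds = _validated("!NBOND", (tuple(b.indices) for b in u.bonds))
        angles = _validated("!NTHETA", (tuple(a.indices) for a in u.angles))
        dihedrals = _validated("!NPHI", (tuple(d.indices) for d in u.dihedrals))
        impropers = _validated("!NIMPHI", (tuple(im.indices) for im in u.impropers))
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001 - out-of-range indices surface here
        raise ParseError(f"{path}: invalid connectivity section: {exc}") from exc
    system = MolecularSystem(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        impropers=impropers,
    )
    return system


_ELEMENT_MASSES = [
    ("H", 1.008), ("C", 12.011), ("N", 14.007), ("O", 15.999),
    ("F", 18.998), ("P", 30.974), ("S", 32.06), ("CL", 35.45), ("BR", 79.904),
]


def _element_from_mass(mass: float) -> str:
    best = min(_ELEMENT_MASSES, key=lambda em: abs(em[1] - mass))
    return best[0] if abs(best[1] - mass) < 1.5 else ""


def write_psf(system: MolecularSystem, path: str | Path, segid: str = "LIG") -> None:
    """Write an X-PLOR PSF topology file."""
    path = Path(path)
    lines = ["PSF", "", f"{1:8d} !NTITLE", " REMARKS written by parmfit", ""]
    lines.append(f"{system.n_atoms:8d} !NATOM")
    for i, a in enumerate(system.atoms):
        lines.append(
            f"{i + 1:8d} {segid:<4s} {1:<4d} {'LIG':<4s} {a.name:<4s} {a.type_label:<6s}"
            f"{a.charge:12.6f}{a.mass:14.4f}{0:12d}"
        )
    lines.append("")

    def _block(tuples: Sequence[tuple[int, ...]], label: str, per_line: int) -> None:
        flat = [i + 1 for tup in tuples for i in tup]
        lines.append(f"{len(tuples):8d} !{label}")
        width = per_line * len(tuples[0]) if tuples else 8
        for start in range(0, len(flat), width):
            lines.append("".join(f"{v:8d}" for v in flat[start : start + width]))
        lines.append("")

    _block(sorted(system.bonds), "NBOND: bonds", 4)
    _block(sorted(system.angles), "NTHETA: angles", 3)
    _block(sorted(system.dihedrals), "NPHI: dihedrals", 2)
    _block(sorted(system.impropers), "NIMPHI: impropers", 2)
    lines.append(f"{0:8d} !NDON")
    lines.append("")
    lines.append(f"{0:8d} !NACC")
    lines.append("")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


def read_coordinates(path: str | Path, fmt: Optional[str] = None) -> np.ndarray:
    """Read Cartesian coordinates (Angstrom) from a PDB or XYZ file.

    Returns an (N, 3) float array in file atom order.  ``fmt`` defaults to the
    file suffix.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdb

        try:
            pdb_file = pdb.PDBFile.read(str(path))
            structure = pdb_file.get_structure(model=1)
            return np.asarray(structure.coord, dtype=float)
        except Exception:  # noqa: BLE001 - fall back for truncated records
            return _read_pdb_minimal(path)
    raise ValueError(f"unknown coordinate format {fmt!r} (expected pdb or xyz)")


def _read_pdb_minimal(path: Path) -> np.ndarray:
    """Fixed-column ATOM/HETATM coordinate extraction, tolerating records
    truncated before the occupancy and B-factor fields."""
    coords = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed PDB coordinate field") from None
    if not coords:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return np.asarray(coords, dtype=float)


def _read_xyz(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: XYZ atom count expected") from None
    coords = []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        tokens = line.split()
        if len(tokens) < 4:
            raise ParseError(f"{path}:{lineno}: XYZ line needs symbol + 3 coordinates")
        try:
            coords.append([float(tokens[1]), float(tokens[2]), float(tokens[3])])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed coordinate field") from None
    if len(coords) != n:
        raise ParseError(f"{path}: header says {n} atoms, found {len(coords)}")
    return np.asarray(coords, dtype=float)


def write_xyz(
    coords: np.ndarray,
    path: str | Path,
    symbols: Optional[Sequence[str]] = None,
    comment: str = "written by parmfit",
    append: bool = False,
) -> None:
    coords = np.asarray(coords, dtype=float)
    symbols = list(symbols) if symbols is not None else ["X"] * len(coords)
    lines = [str(len(coords)), comment]
    for sym, (x, y, z) in zip(symbols, coords):
        lines.append(f"{sym:<4s} {x:14.8f} {y:14.8f} {z:14.8f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures: the published SR1664 / GQ16 torsion parameters
# ---------------------------------------------------------------------------

#: published net charges of the two parameterized ligands (elementary charge)
FIXTURE_NET_CHARGES = {"SR1664": -1, "GQ16": 0}

_FIXTURE_FILES = {"SR1664": "sr1664_torsions.prm", "GQ16": "gq16_torsions.prm"}

#: atom-name quadruple defining each published torsion
FIXTURE_QUADRUPLES = {
    "SR1664_T1": ("C13", "N2", "C20", "C21"),
    "SR1664_T2": ("N1", "C9", "C10", "C11"),
    "SR1664_T3": ("C5", "C7", "N1", "C9"),
    "GQ16_T1": ("C11", "N1", "C12", "C13"),
    "GQ16_T2": ("C6", "C7", "C8", "C9"),
    "GQ16_T3": ("S1", "C9", "C8", "C7"),
}


def fixture_names() -> list[str]:
    return sorted(FIXTURE_QUADRUPLES)


def fixture_path(ligand: str) -> Path:
    """Filesystem path of a packaged torsion-parameter fixture file."""
    ref = resources.files("parmfit.fixtures") / _FIXTURE_FILES[ligand]
    return Path(str(ref))


def load_fixture(name: str) -> tuple[DihedralTerm, ...]:
    """Return the published torsion terms (k, n, delta) for one named torsion.

    Names are ``{SR1664,GQ16}_T{1,2,3}``, e.g. ``"GQ16_T2"``.
    """
    if name not in FIXTURE_QUADRUPLES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
        )
    ligand = name.split("_")[0]
    params = read_prm(fixture_path(ligand))
    return params.dihedral_terms(FIXTURE_QUADRUPLES[name])
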