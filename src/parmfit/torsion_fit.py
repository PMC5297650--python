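"""Fitting CHARMM dihedral Fourier terms to a torsion difference profile.

With the phase angle restricted to 0 or 180 degrees, each cosine term
k*(1 + cos(n*phi - delta)) reduces to a constant plus a signed multiple of
cos(n*phi).  The "nonlinear" curve fit therefore collapses to an exact
linear least-squares problem on the basis {1} U {cos(n*phi)}: there is a
single global optimum, no iteration and no initialization sensitivity.

Two output conventions are supported:

* ``canonical_nonnegative_k`` — report k = |a_n| with delta = 0 for a_n > 0
  and delta = 180 for a_n < 0 (a_n == 0 gives k = 0, delta = 0);
* ``signed_k`` — keep the signed amplitude together with the supplied (or
  zero) phase; a published negative force constant with delta = 180 is the
  same curve as the positive constant with delta = 0, up to a constant.

The total fitted constant of a rotatable bond is divided equally among all
dihedral quadruples sharing that central bond, so that summing the divided
terms over every quadruple restores the fitted torsional potential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .ffio import DihedralTerm, MolecularSystem
from .torsion_scan import Provenance, TorsionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionFitResult",
    "RankDeficiencyError",
    "fit_torsion",
    "select_multiplicities",
    "count_equivalent_dihedrals",
    "divide_terms",
    "fitted_profile",
]

FREE_SIGN = "free_sign"
CANONICAL = "canonical_nonnegative_k"
SIGNED = "signed_k"


class RankDeficiencyError(ValueError):
    """The cosine design matrix is rank deficient on the given grid."""


@dataclass
class TorsionFitResult:
    """Result of a linear torsion fit.

    ``offset`` is the constant basis coefficient (the part of the profile
    absorbed by minimum-shifting, not by any cosine term).  Residual
    statistics are computed on the collapsed grid (duplicate 0/360 endpoint
    counted once).
    """

    terms: tuple[DihedralTerm, ...]
    offset: float
    rmse: float
    max_abs_residual: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        mults = [t.n for t in self.terms]
        if len(mults) != len(set(mults)):
            raise ValueError("each multiplicity may appear at most once")

    def term_for(self, n: int) -> DihedralTerm:
        for t in self.terms:
            if t.n == n:
                return t
        raise KeyError(f"no fitted term with multiplicity {n}")


def _collapse_endpoint(
    angles: np.ndarray, energies: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if len(angles) >= 2 and math.isclose((angles[-1] - angles[0]) % 360.0, 0.0, abs_tol=1e-9):
        return angles[:-1], energies[:-1]
    return angles, energies


def fit_torsion(
    delta: TorsionProfile,
    multiplicities: Iterable[int],
    phase_policy: Union[str, Mapping[int, float]] = FREE_SIGN,
    convention: str = CANONICAL,
) -> TorsionFitResult:
    """Least-squares fit of a cosine series to a difference profile.

    Parameters
    ----------
    delta
        The (QM - MM) difference profile to reproduce.
    multiplicities
        The set of periodicities n to include (each <= 6 on the default
        20-degree grid to stay clear of aliasing).
    phase_policy
        ``"free_sign"`` lets the data pick the sign of each cosine term;
        a mapping ``{n: delta_n}`` fixes the phases (0 or 180) in advance,
        as when reproducing published parameter tables.
    convention
        ``"canonical_nonnegative_k"`` or ``"signed_k"`` (see module docs).
    """
    mults = sorted(set(int(n) for n in multiplicities))
    if not mults:
        raise ValueError("multiplicity set must be non-empty")
    if mults[0] < 1:
        raise ValueError("multiplicities must be positive integers")
    fixed_phases: Optional[Mapping[int, float]] = None
    if isinstance(phase_policy, Mapping):
        fixed_phases = dict(phase_policy)
        for n in mults:
            if n not in fixed_phases:
                raise ValueError(f"phase policy missing multiplicity {n}")
            if fixed_phases[n] not in (0.0, 180.0):
                raise ValueError(f"phase for n={n} must be 0 or 180")
    elif phase_policy != FREE_SIGN:
        raise ValueError(f"unknown phase policy {phase_policy!r}")
    if convention not in (CANONICAL, SIGNED):
        raise ValueError(f"unknown convention {convention!r}")

    angles, energies = _collapse_endpoint(delta.angles, delta.energies)
    if len(angles) < len(mults) + 1:
        raise ValueError(
            f"need at least {len(mults) + 1} grid points for {len(mults)} terms, "
            f"got {len(angles)}"
        )
    phi = np.radians(angles)
    columns = [np.ones_like(phi)]
    for n in mults:
        col = np.cos(n * phi)
        if fixed_phases is not None and fixed_phases[n] == 180.0:
            col = -col
        columns.append(col)
    design = np.column_stack(columns)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise RankDeficiencyError(
            f"cosine design matrix is rank deficient (rank {rank} < "
            f"{design.shape[1]}): multiplicities {mults} alias on this grid"
        )
    coef, *_ = np.linalg.lstsq(design, energies, rcond=None)
    resid = energies - design @ coef

    terms = []
    for n, a in zip(mults, coef[1:]):
        if fixed_phases is not None:
            # a supplied phase is honored verbatim; the sign stays on k
            # (this is how a published negative constant is reproduced)
            terms.append(DihedralTerm(k=float(a), n=n, delta=fixed_phases[n]))
        else:
            if convention == SIGNED:
                terms.append(DihedralTerm(k=float(a), n=n, delta=0.0))
            elif a > 0:
                terms.append(DihedralTerm(k=float(a), n=n, delta=0.0))
            elif a < 0:
                terms.append(DihedralTerm(k=float(-a), n=n, delta=180.0))
            else:
                terms.append(DihedralTerm(k=0.0, n=n, delta=0.0))

    return TorsionFitResult(
        terms=tuple(terms),
        offset=float(coef[0]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        max_abs_residual=float(np.max(np.abs(resid))) if len(resid) else 0.0,
        grid=angles.copy(),
    )


def select_multiplicities(
    delta: TorsionProfile,
    candidates: Iterable[int] = (1, 2, 3, 4, 5, 6),
    threshold_k: float = 0.05,
) -> set[int]:
    """Pick the multiplicities that matter: fit all candidates with free
    signs, drop terms with |k| below ``threshold_k`` kcal/mol, refit with the
    survivors.  Deterministic; returns the surviving set (possibly empty)."""
    cands = sorted(set(int(n) for n in candidates))
    if not cands:
        raise ValueError("candidate set must be non-empty")
    full = fit_torsion(delta, cands, phase_policy=FREE_SIGN, convention=SIGNED)
    survivors = {t.n for t in full.terms if abs(t.k) >= threshold_k}
    if not survivors:
        logger.info("no multiplicity exceeds |k| >= %.3g kcal/mol; refit skipped", threshold_k)
        return set()
    fit_torsion(delta, survivors, phase_policy=FREE_SIGN, convention=SIGNED)
    return survivors


def count_equivalent_dihedrals(
    system: MolecularSystem,
    central_bond: tuple[int, int],
    include_hydrogens: bool = True,
) -> int:
    """Number of distinct dihedral quadruples (i, a, b, j) sharing a central bond.

    The published fitted constant describes the whole bond rotation, while the
    potential sums over every quadruple; the constant is therefore divided by
    this count.  Hydrogen-bearing quadruples are counted by default.
    """
    a, b = central_bond
    if not system.has_bond(a, b):
        raise ValueError(f"atoms {a} and {b} are not bonded")

    def _keep(idx: int) -> bool:
        return include_hydrogens or system.atoms[idx].element != "H"

    left = [i for i in system.neighbors(a) if i != b and _keep(i)]
    right = [j for j in system.neighbors(b) if j != a and _keep(j)]
    count = sum(1 for i in left for j in right if i != j)
    if count < 1:
        raise ValueError(f"bond ({a}, {b}) has no flanking atoms on one side")
    return count


def divide_terms(
    result_or_terms: Union[TorsionFitResult, Sequence[DihedralTerm]],
    n_equivalent: int,
) -> tuple[DihedralTerm, ...]:
    """Divide each fitted force constant equally among equivalent quadruples.

    Applying the divided terms to all ``n_equivalent`` quadruples (which move
    in lockstep under a rigid rotation) reproduces the fitted total exactly.
    """
    if n_equivalent < 1:
        raise ValueError("n_equivalent must be >= 1")
    terms = (
        result_or_terms.terms
        if isinstance(result_or_terms, TorsionFitResult)
        else tuple(result_or_terms)
    )
    return tuple(
        DihedralTerm(k=t.k / n_equivalent, n=t.n, delta=t.delta) for t in terms
    )


def fitted_profile(
    terms: Sequence[DihedralTerm], angles: np.ndarray
) -> TorsionProfile:
    """Evaluate a term set on an angle grid (FITTED provenance, no shifting)."""
    phi = np.radians(np.asarray(angles, dtype=float))
    energies = np.zeros_like(phi)
    for t in terms:
        energies += t.k * (1.0 + np.cos(t.n * phi - math.radians(t.delta)))
    return TorsionProfile(
        angles=np.asarray(angles, dtype=float),
        energies=energies,
        provenance=Provenance.FITTED,
    )
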