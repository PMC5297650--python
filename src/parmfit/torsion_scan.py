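"""Dihedral-angle scans and the energy profiles fed to the torsion fitter.

A scan rigidly rotates one side of a rotatable bond over a full revolution
(default 0-360 degrees in 20-degree steps, 19 grid points including both
endpoints).  The classical profile is evaluated with the scanned torsion's
own cosine terms zeroed, so that the quantum-minus-classical difference
profile isolates exactly the potential the new terms must supply.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ffio import MolecularSystem, ParameterSet, _canon_quad
from .mm_energy import Conformation, EnergyOptions, eval_energy, rotate_dihedral

__all__ = [
    "Provenance",
    "TorsionProfile",
    "generate_scan",
    "mm_profile",
    "delta_profile",
]


class Provenance(enum.Enum):
    QM = "QM"
    MM = "MM"
    DELTA = "DELTA"
    FITTED = "FITTED"
    SYNTHETIC = "SYNTHETIC"


#: provenances whose profiles are re-zeroed (min subtracted) on construction
_SHIFTED = {Provenance.QM, Provenance.MM, Provenance.DELTA}


@dataclass
class TorsionProfile:
    """A 1-D energy curve over a dihedral-angle grid.

    ``angles`` are strictly increasing degrees; for QM / MM / DELTA provenance
    the energies are shifted so their minimum is exactly zero, and the
    subtracted constant is accumulated in ``reference_shift``.
    """

    angles: np.ndarray
    energies: np.ndarray
    provenance: Provenance
    reference_shift: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.ndim != 1 or self.angles.shape != self.energies.shape:
            raise ValueError("angles and energies must be 1-D arrays of equal length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if isinstance(self.provenance, str):
            self.provenance = Provenance(self.provenance)
        if self.provenance in _SHIFTED:
            shift = float(self.energies.min())
            self.energies = self.energies - shift
            self.reference_shift += shift

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def has_duplicate_endpoint(self) -> bool:
        return bool(np.isclose((self.angles[-1] - self.angles[0]) % 360.0, 0.0))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"angle_deg": self.angles, "energy_kcal_mol": self.energies}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, provenance: Provenance = Provenance.QM
    ) -> "TorsionProfile":
        df = pd.read_csv(path)
        required = {"angle_deg", "energy_kcal_mol"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: profile CSV must have columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        return cls(
            angles=df["angle_deg"].to_numpy(),
            energies=df["energy_kcal_mol"].to_numpy(),
            provenance=provenance,
        )


def generate_scan(
    system: MolecularSystem,
    conf: Conformation,
    quadruple: tuple[int, int, int, int],
    step: float = 20.0,
    span: float = 360.0,
) -> list[tuple[float, Conformation]]:
    """Rigid-rotation conformer series at dihedral angles 0, step, ..., span.

    Returns span/step + 1 conformers (both endpoints included, matching a
    full-revolution scan at 20-degree increments).  ``step`` must divide
    ``span`` exactly.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide span {span}")
    out = []
    for idx in range(int(round(n_steps)) + 1):
        target = idx * step
        wrapped = (target + 180.0) % 360.0 - 180.0  # dihedrals live in (-180, 180]
        if wrapped == -180.0:
            wrapped = 180.0
        out.append((target, rotate_dihedral(conf, system, quadruple, wrapped)))
    return out


def mm_profile(
    system: MolecularSystem,
    conformers: Sequence[tuple[float, Conformation]],
    params: ParameterSet,
    zeroed_quadruple_types: Sequence[tuple[str, str, str, str]] = (),
) -> TorsionProfile:
    """Classical energy along a conformer series, minimum shifted to zero.

    ``zeroed_quadruple_types`` normally holds the scanned torsion's atom-type
    quadruple, so existing terms for it are excluded from the profile.
    """
    options = EnergyOptions(
        zeroed_dihedral_type_quadruples=frozenset(
            _canon_quad(tuple(q)) for q in zeroed_quadruple_types
        )
    )
    angles = np.array([a for a, _ in conformers], dtype=float)
    energies = np.array(
        [eval_energy(system, c, params, options).total for _, c in conformers]
    )
    return TorsionProfile(angles=angles, energies=energies, provenance=Provenance.MM)


def delta_profile(qm: TorsionProfile, mm: TorsionProfile) -> TorsionProfile:
    """Pointwise QM minus MM difference profile, re-zeroed at its minimum.

    Both inputs must share the same angle grid.  Because each profile is
    already minimum-shifted and the result is shifted again, the difference
    is invariant under adding any constant to either input.
    """
    if len(qm) != len(mm) or not np.allclose(qm.angles, mm.angles, atol=1e-9):
        raise ValueError("QM and MM profiles must share an identical angle grid")
    qm_e = qm.energies - qm.energies.min()
    mm_e = mm.energies - mm.energies.min()
    return TorsionProfile(
        angles=qm.angles.copy(),
        energies=qm_e - mm_e,
        provenance=Provenance.DELTA,
    )
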