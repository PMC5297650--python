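"""Constrained electrostatic-potential (ESP) charge derivation.

Point charges are fitted to reproduce the molecular electrostatic potential
sampled on nested, scaled van-der-Waals shells (the Merz-Singh-Kollman
construction), subject to an exact net-charge constraint and, optionally,
three dipole-component constraints.  The objective

    min_q  sum_p ( V(p) - sum_i C q_i / |p - x_i| )^2
    s.t.   sum_i q_i = Q_tot          (always)
           sum_i q_i x_i = mu / f     (optional, f = 4.80320 D per e*A)

is an equality-constrained linear least-squares problem solved through the
KKT stationarity system; constraints hold to solver precision regardless of
noise in the sampled potential.

Units: Angstrom for geometry, kcal/(mol e) for potentials, elementary charge
for q, Debye for dipoles.  C = 332.0716 kcal A / (mol e^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

COULOMB_CONSTANT = 332.0716  # kcal*A/mol/e^2
EA_TO_DEBYE = 4.80320  # 1 e*A in Debye
HARTREE_PER_E_TO_KCAL = 627.509474  # 1 hartree/e in kcal/(mol e)
BOHR_TO_ANGSTROM = 0.529177210903

__all__ = [
    "ESPGrid",
    "ChargeFitResult",
    "build_mk_grid",
    "esp_from_point_charges",
    "fit_charges",
    "read_grid_csv",
    "write_grid_csv",
    "esp_au_to_kcal_per_mol_e",
    "esp_kcal_per_mol_e_to_au",
]


@dataclass
class ESPGrid:
    """Electrostatic-potential samples in space.

    ``values`` may be None for a freshly built geometric grid that has not
    yet been evaluated.  ``exclusion_radii`` are the per-atom minimum
    approach distances (innermost shell scale times the vdW radius).
    """

    points: np.ndarray
    values: Optional[np.ndarray] = None
    exclusion_radii: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("grid points must be an (N, 3) array")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (len(self.points),):
                raise ValueError("values length must match point count")
            if not np.all(np.isfinite(self.values)):
                raise ValueError("grid values must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def with_values(self, values: np.ndarray) -> "ESPGrid":
        return ESPGrid(self.points, values, self.exclusion_radii)


@dataclass
class ChargeFitResult:
    charges: np.ndarray  # per atom, e
    fitted_total_charge: float  # e
    fitted_dipole: np.ndarray  # Debye, 3-vector
    rms_esp_residual: float  # kcal/(mol e)
    constraint_violations: np.ndarray  # per active constraint row

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.fitted_dipole = np.asarray(self.fitted_dipole, dtype=float)
        self.constraint_violations = np.asarray(self.constraint_violations, dtype=float)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equal-area unit-sphere points (deterministic)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def build_mk_grid(
    positions: np.ndarray,
    vdw_radii: Sequence[float],
    shell_scales: Sequence[float] = (1.4, 1.6, 1.8, 2.0),
    density: float = 1.0,
    seed: int = 0,
) -> ESPGrid:
    """Sample points on unions of scaled van-der-Waals surfaces.

    Each atom contributes a Fibonacci-sphere shell per scale factor, with a
    point count proportional to ``density`` (points per square Angstrom) and
    the shell area.  A point falling inside any atom's innermost shell
    (``shell_scales[0] * r_vdw``) is discarded.  The seed only perturbs the
    global sphere orientation, so grids are fully reproducible.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(vdw_radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("vdW radii must be positive")
    scales = list(shell_scales)
    if any(s2 <= s1 for s1, s2 in zip(scales, scales[1:])):
        raise ValueError("shell scales must be strictly increasing")
    if density <= 0:
        raise ValueError("density must be positive")

    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))

    inner = scales[0] * radii
    points = []
    for i, (pos, r_vdw) in enumerate(zip(positions, radii)):
        for scale in scales:
            r = scale * r_vdw
            n_pts = max(1, int(round(density * 4.0 * np.pi * r * r)))
            shell = pos + r * rot.apply(_fibonacci_sphere(n_pts))
            # keep points outside every atom's innermost shell
            d = np.linalg.norm(shell[:, None, :] - positions[None, :, :], axis=2)
            keep = np.all(d >= inner[None, :] - 1e-9, axis=1)
            points.append(shell[keep])
    pts = np.vstack(points) if points else np.empty((0, 3))
    if len(pts) == 0:
        raise ValueError(
            "no grid points survive the exclusion filter; use larger shell scales"
        )
    return ESPGrid(points=pts, values=None, exclusion_radii=inner)


def esp_from_point_charges(
    charges: Sequence[float], positions: np.ndarray, grid: ESPGrid
) -> np.ndarray:
    """Exact Coulomb potential of point charges at the grid points."""
    q = np.asarray(charges, dtype=float)
    x = np.asarray(positions, dtype=float)
    if len(q) != len(x):
        raise ValueError("charges and positions must have equal length")
    d = np.linalg.norm(grid.points[:, None, :] - x[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise ValueError("grid point coincident with an atom position")
    return COULOMB_CONSTANT * (q[None, :] / d).sum(axis=1)


def fit_charges(
    grid: ESPGrid,
    positions: np.ndarray,
    total_charge: Optional[float],
    dipole_target: Optional[Sequence[float]] = None,
) -> ChargeFitResult:
    """Equality-constrained least-squares charge fit to an ESP grid.

    ``dipole_target`` is in Debye; when supplied, the three point-charge
    dipole components are constrained exactly (the Merz-Singh-Kollman dipole
    constraint at the point-charge level).  ``total_charge=None`` drops the
    net-charge constraint (plain least squares), which is occasionally useful
    as a diagnostic lower bound on the constrained residual.
    """
    if grid.values is None:
        raise ValueError("grid has no potential values to fit")
    x = np.asarray(positions, dtype=float)
    n_atoms = len(x)
    d = np.linalg.norm(grid.points[:, None, :] - x[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise ValueError("grid point coincident with an atom position")
    design = COULOMB_CONSTANT / d  # (n_points, n_atoms)

    rows, rhs = [], []
    if total_charge is not None:
        rows.append(np.ones(n_atoms))
        rhs.append(float(total_charge))
    if dipole_target is not None:
        mu = np.asarray(dipole_target, dtype=float)
        if mu.shape != (3,):
            raise ValueError("dipole target must be a 3-vector (Debye)")
        for axis in range(3):
            rows.append(x[:, axis])
            rhs.append(mu[axis] / EA_TO_DEBYE)
    constraints = np.vstack(rows) if rows else np.empty((0, n_atoms))
    cvec = np.asarray(rhs, dtype=float)
    n_con = len(cvec)
    if len(grid) < n_atoms + n_con:
        raise ValueError(
            f"need at least {n_atoms + n_con} grid points for {n_atoms} atoms "
            f"and {n_con} constraints, got {len(grid)}"
        )

    # equality-constrained least squares: min ||A q - v|| s.t. B q = c.
    # LAPACK's GGLSE solves the KKT stationarity conditions via a generalized
    # RQ factorization, which avoids squaring the (large, C-scaled) design.
    if n_con > n_atoms or np.linalg.matrix_rank(constraints) < n_con:
        raise np.linalg.LinAlgError(
            f"constraint rows are rank deficient or over-determine the charges "
            f"({n_atoms} atoms, {n_con} constraint rows)"
        )
    if np.linalg.matrix_rank(np.vstack([design, constraints])) < n_atoms:
        raise np.linalg.LinAlgError(
            "stacked design and constraint matrix is rank deficient; "
            "charges are not determined by this grid"
        )
    if n_con == 0:
        q, *_ = np.linalg.lstsq(design, grid.values, rcond=None)
    else:
        from scipy.linalg import lapack

        *_, q, info = lapack.dgglse(design, constraints, grid.values, cvec)
        if info != 0:
            raise np.linalg.LinAlgError(f"constrained solve failed (LAPACK info={info})")

    resid = design @ q - grid.values
    return ChargeFitResult(
        charges=q,
        fitted_total_charge=float(q.sum()),
        fitted_dipole=(q[:, None] * x).sum(axis=0) * EA_TO_DEBYE,
        rms_esp_residual=float(np.sqrt(np.mean(resid**2))),
        constraint_violations=np.abs(constraints @ q - cvec),
    )


# ---------------------------------------------------------------------------
# grid file I/O and unit converters
# ---------------------------------------------------------------------------


def write_grid_csv(grid: ESPGrid, path: str | Path) -> None:
    """Write a grid as CSV with a units header line (x,y,z in A; esp in
    kcal/(mol e))."""
    if grid.values is None:
        raise ValueError("grid has no values to write")
    with open(path, "w") as fh:
        fh.write("# units: x,y,z in angstrom; esp in kcal/(mol e)\n")
        pd.DataFrame(
            {
                "x": grid.points[:, 0],
                "y": grid.points[:, 1],
                "z": grid.points[:, 2],
                "esp": grid.values,
            }
        ).to_csv(fh, index=False)


def read_grid_csv(path: str | Path) -> ESPGrid:
    df = pd.read_csv(path, comment="#")
    required = {"x", "y", "z", "esp"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: grid CSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return ESPGrid(
        points=df[["x", "y", "z"]].to_numpy(),
        values=df["esp"].to_numpy(),
    )


def esp_au_to_kcal_per_mol_e(values_au: np.ndarray) -> np.ndarray:
    """Convert potentials from hartree/e to kcal/(mol e)."""
    return np.asarray(values_au, dtype=float) * HARTREE_PER_E_TO_KCAL


def esp_kcal_per_mol_e_to_au(values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float) / HARTREE_PER_E_TO_KCAL
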