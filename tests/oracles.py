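"""Independent reference implementations used only to cross-check results.

Everything here is deliberately written from scratch against the functional
form, with different formulations than the package (plain Python loops,
projection-based internal coordinates, explicit sign-pattern enumeration),
so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import curve_fit, lsq_linear

COULOMB = 332.0716


def _norm(v):
    return math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


def _sub(a, b):
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def dihedral_cos(x, quad):
    """cos(phi) via projection onto the plane normal to the central bond.

    The torsion terms fitted here are even in phi (phases 0/180), so the
    cosine alone determines every energy.
    """
    i, j, k, l = quad
    u = _sub(x[k], x[j])
    un = _norm(u)
    u = (u[0] / un, u[1] / un, u[2] / un)
    b1 = _sub(x[i], x[j])
    b3 = _sub(x[l], x[k])
    w1 = tuple(b1[m] - _dot(b1, u) * u[m] for m in range(3))
    w2 = tuple(b3[m] - _dot(b3, u) * u[m] for m in range(3))
    return _dot(w1, w2) / (_norm(w1) * _norm(w2))


def dihedral_signed(x, quad):
    """Signed dihedral in degrees: atan2 of the two plane normals, positive
    when the normal cross product points along the central bond."""
    i, j, k, l = quad
    b1 = _sub(x[j], x[i])
    b2 = _sub(x[k], x[j])
    b3 = _sub(x[l], x[k])
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = tuple(c / _norm(b2) for c in b2)
    return math.degrees(math.atan2(_dot(_cross(n1, n2), b2n), _dot(n1, n2)))


def naive_energy(system, conf, params, zeroed_type_quads=frozenset()):
    """Direct term-by-term evaluation of the additive potential with plain
    loops; returns a dict of components."""
    x = [tuple(row) for row in np.asarray(conf.coordinates)]
    types = [a.type_label for a in system.atoms]
    charges = [a.charge for a in system.atoms]
    zeroed = {min(tuple(q), tuple(reversed(q))) for q in zeroed_type_quads}

    e = dict.fromkeys(
        ["bond", "angle", "urey_bradley", "dihedral", "improper", "lennard_jones", "coulomb"],
        0.0,
    )
    for i, j in system.bonds:
        p = params.bond(types[i], types[j])
        e["bond"] += p.force_constant * (_norm(_sub(x[i], x[j])) - p.equilibrium) ** 2
    for i, j, k in system.angles:
        p = params.angle(types[i], types[j], types[k])
        v1, v2 = _sub(x[i], x[j]), _sub(x[k], x[j])
        theta = math.acos(
            max(-1.0, min(1.0, _dot(v1, v2) / (_norm(v1) * _norm(v2))))
        )
        e["angle"] += p.force_constant * (theta - math.radians(p.equilibrium)) ** 2
        ub = params.urey_bradley_param(types[i], types[j], types[k])
        if ub is not None:
            e["urey_bradley"] += ub.force_constant * (
                _norm(_sub(x[i], x[k])) - ub.equilibrium
            ) ** 2
    for quad in system.dihedrals:
        tq = tuple(types[m] for m in quad)
        if min(tq, tq[::-1]) in zeroed:
            continue
        cphi = dihedral_cos(x, quad)
        phi = math.acos(max(-1.0, min(1.0, cphi)))  # |phi|; terms are even
        for term in params.dihedral_terms(tq):
            e["dihedral"] += term.k * (
                1.0 + math.cos(term.n * phi - math.radians(term.delta))
            )
    for quad in system.impropers:
        p = params.improper(tuple(types[m] for m in quad))
        omega = math.radians(dihedral_signed(x, quad))
        e["improper"] += p.force_constant * (omega - math.radians(p.equilibrium)) ** 2

    # exclusions from explicit neighbor-set expansion
    nb = {i: set() for i in range(len(x))}
    for i, j in system.bonds:
        nb[i].add(j)
        nb[j].add(i)
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            one_two = j in nb[i]
            one_three = not one_two and bool(nb[i] & nb[j])
            if one_two or one_three:
                continue
            one_four = any(nb[m] & nb[j] for m in nb[i])
            r = _norm(_sub(x[i], x[j]))
            pi, pj = params.lj_param(types[i]), params.lj_param(types[j])

            def eff(p):
                if one_four and p.well_depth_14 is not None and p.r_min_half_14 is not None:
                    return p.well_depth_14, p.r_min_half_14
                return p.well_depth, p.r_min_half

            ei, ri = eff(pi)
            ej, rj = eff(pj)
            eps = math.sqrt(ei * ej)
            rmin = ri + rj
            if eps:
                e["lennard_jones"] += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
            e["coulomb"] += COULOMB * charges[i] * charges[j] / r
    e["total"] = sum(e.values())
    return e


def brute_force_torsion_fit(angles_deg, energies, multiplicities):
    """Grid search over all 2^m phase assignments with non-negative
    amplitudes, free constant; returns (best_terms, best_sse) where terms is
    a dict n -> (k, delta)."""
    phi = np.radians(np.asarray(angles_deg, dtype=float))
    y = np.asarray(energies, dtype=float)
    mults = sorted(multiplicities)
    best = None
    for signs in itertools.product((1.0, -1.0), repeat=len(mults)):
        cols = [np.ones_like(phi)] + [s * np.cos(n * phi) for s, n in zip(signs, mults)]
        a = np.column_stack(cols)
        res = lsq_linear(
            a, y, bounds=([-np.inf] + [0.0] * len(mults), [np.inf] * (len(mults) + 1))
        )
        sse = float(np.sum((a @ res.x - y) ** 2))
        if best is None or sse < best[1] - 1e-12:
            terms = {
                n: (float(k), 0.0 if s > 0 else 180.0)
                for n, k, s in zip(mults, res.x[1:], signs)
            }
            best = (terms, sse)
    return best


def nonlinear_refit(angles_deg, energies, multiplicities, phases):
    """Iterative curve fit of sum_n k_n (1 + cos(n phi - delta_n)) + c with
    fixed phases, as an independent check of the linear solution."""
    phi = np.radians(np.asarray(angles_deg, dtype=float))
    mults = sorted(multiplicities)
    deltas = [math.radians(phases[n]) for n in mults]

    def model(p, *coeffs):
        ks, c = coeffs[:-1], coeffs[-1]
        out = np.full_like(p, c)
        for k, n, d in zip(ks, mults, deltas):
            out = out + k * (1.0 + np.cos(n * p - d))
        return out

    p0 = [1.0] * len(mults) + [0.0]
    popt, _ = curve_fit(model, phi, np.asarray(energies, dtype=float), p0=p0)
    return {n: float(k) for n, k in zip(mults, popt[:-1])}
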