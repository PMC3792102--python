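"""Molecular-mechanics energy terms and their analytic gradients.

The potential is the CHARMM-style sum of bonded terms (harmonic bond, angle,
Urey-Bradley and improper with E = k(x - x0)^2, periodic dihedral
E = k(1 + cos(n*phi - delta))), Lennard-Jones and Coulomb nonbonded terms,
a pairwise generalized-Born polar solvation term (Still functional form with
fixed input Born radii), an accessible-surface-area nonpolar term
(deterministic Shrake-Rupley), and flat-bottom NOE distance restraints.

All energies in kJ/mol, coordinates in Å, gradients in kJ/(mol·Å).

The Shrake-Rupley surface area is piecewise constant in the coordinates
(a fixed finite point set is classified exposed/buried), so its exact
gradient vanishes almost everywhere; the gradient routines therefore assign
the ASA term zero force.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import (
    EPS_EXTERIOR,
    EPS_INTERIOR,
    K_COULOMB,
    SASA_PROBE_RADIUS,
)
from .system import (
    EnergyBreakdown,
    GeometryError,
    MolecularSystem,
    NOERestraint,
    ParameterError,
)

PairScope = Literal["all", "cross_molecule"]

_N_SPHERE_POINTS = 256


class SingularityError(ValueError):
    """Two interacting atoms coincide (r = 0)."""


# ---------------------------------------------------------------------------
# bonded terms


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("zero-length vector in angle evaluation")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise GeometryError("degenerate dihedral geometry")
    return float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))


def _wrap_pi(x: float) -> float:
    """Wrap an angle difference into (-pi, pi]."""
    return float(np.arctan2(np.sin(x), np.cos(x)))


def bonded_energy(
    system: MolecularSystem, gradient: np.ndarray | None = None
) -> EnergyBreakdown:
    """Bond, angle, Urey-Bradley, dihedral and improper energies.

    If ``gradient`` (an (N, 3) array) is given, the bonded forces are
    accumulated into it.
    """
    x = system.coords
    topo = system.topology
    out = EnergyBreakdown()

    for i, j, k, r0 in topo.bonds:
        out.bond += _harmonic_distance(x, i, j, k, r0, gradient)
    for i, k, kub, s0 in topo.urey_bradley:
        out.urey_bradley += _harmonic_distance(x, i, k, kub, s0, gradient)

    for i, j, k, kt, t0 in topo.angles:
        u, v = x[i] - x[j], x[k] - x[j]
        theta = _angle_between(u, v)
        d = theta - t0
        out.angle += kt * d * d
        if gradient is not None:
            dE = 2.0 * kt * d
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            uh, vh = u / nu, v / nv
            s = np.sqrt(max(1.0 - np.dot(uh, vh) ** 2, 1e-12))
            gi = -dE * (vh - np.dot(uh, vh) * uh) / (nu * s)
            gk = -dE * (uh - np.dot(uh, vh) * vh) / (nv * s)
            gradient[i] += gi
            gradient[k] += gk
            gradient[j] -= gi + gk

    for i, j, k, l, kp, n, delta in topo.dihedrals:
        phi = _dihedral_angle(x[i], x[j], x[k], x[l])
        out.dihedral += kp * (1.0 + np.cos(n * phi - delta))
        if gradient is not None:
            dE = -kp * n * np.sin(n * phi - delta)
            _accumulate_dihedral_gradient(x, i, j, k, l, dE, gradient)

    for i, j, k, l, kp, p0 in topo.impropers:
        psi = _dihedral_angle(x[i], x[j], x[k], x[l])
        d = _wrap_pi(psi - p0)
        out.improper += kp * d * d
        if gradient is not None:
            _accumulate_dihedral_gradient(x, i, j, k, l, 2.0 * kp * d, gradient)

    return out


def _harmonic_distance(x, i, j, k, r0, gradient) -> float:
    rij = x[i] - x[j]
    r = float(np.linalg.norm(rij))
    if r == 0.0 and gradient is not None:
        raise GeometryError(f"coincident atoms {i},{j} in harmonic distance term")
    d = r - r0
    if gradient is not None and r > 0.0:
        g = 2.0 * k * d * rij / r
        gradient[i] += g
        gradient[j] -= g
    return k * d * d


def _accumulate_dihedral_gradient(x, i, j, k, l, dE_dphi, gradient) -> None:
    # Blondel-Karplus torsion derivatives.
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    dphi_dri = -nb2 / np.dot(n1, n1) * n1
    dphi_drl = nb2 / np.dot(n2, n2) * n2
    a = np.dot(b1, b2) / (nb2 * nb2)
    b = np.dot(b3, b2) / (nb2 * nb2)
    dphi_drj = -(1.0 + a) * dphi_dri + b * dphi_drl
    dphi_drk = a * dphi_dri - (1.0 + b) * dphi_drl
    gradient[i] += dE_dphi * dphi_dri
    gradient[j] += dE_dphi * dphi_drj
    gradient[k] += dE_dphi * dphi_drk
    gradient[l] += dE_dphi * dphi_drl


# ---------------------------------------------------------------------------
# nonbonded terms


def _pair_indices(
    system: MolecularSystem, pair_scope: PairScope
) -> tuple[np.ndarray, np.ndarray]:
    n = system.n_atoms
    if n < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ii, jj = np.triu_indices(n, k=1)
    excl = system.exclusions()
    if excl:
        mask = np.array([(int(a), int(b)) not in excl for a, b in zip(ii, jj)])
        ii, jj = ii[mask], jj[mask]
    if pair_scope == "cross_molecule":
        tags = np.array([a.molecule_tag for a in system.atoms])
        mask = tags[ii] != tags[jj]
        ii, jj = ii[mask], jj[mask]
    return ii, jj


def nonbonded_energy(
    system: MolecularSystem,
    pair_scope: PairScope = "all",
    gradient: np.ndarray | None = None,
) -> tuple[float, float]:
    """Lennard-Jones and Coulomb energies over non-excluded pairs.

    LJ uses the rmin convention E = eps_ij[(rmin_ij/r)^12 - 2(rmin_ij/r)^6]
    with Lorentz-Berthelot-style combination eps_ij = sqrt(eps_i eps_j),
    rmin_ij = rmin_half_i + rmin_half_j. Coulomb is unscreened K_e q_i q_j / r.
    ``cross_molecule`` keeps only pairs whose atoms carry different molecule
    tags.
    """
    ii, jj = _pair_indices(system, pair_scope)
    if ii.size == 0:
        return 0.0, 0.0
    x = system.coords
    dx = x[ii] - x[jj]
    r2 = np.einsum("ij,ij->i", dx, dx)
    if np.any(r2 == 0.0):
        bad = int(np.argmin(r2))
        raise SingularityError(f"atoms {ii[bad]} and {jj[bad]} coincide")
    r = np.sqrt(r2)

    eps = np.array([a.lj_epsilon for a in system.atoms])
    rmh = np.array([a.lj_rmin_half for a in system.atoms])
    q = np.array([a.charge for a in system.atoms])

    eps_ij = np.sqrt(eps[ii] * eps[jj])
    rmin_ij = rmh[ii] + rmh[jj]
    s6 = (rmin_ij / r) ** 6
    e_lj = eps_ij * (s6 * s6 - 2.0 * s6)
    e_coul = K_COULOMB * q[ii] * q[jj] / r

    if gradient is not None:
        # dE/dr terms
        dlj = (-12.0 * eps_ij / r) * (s6 * s6 - s6)
        dcoul = -e_coul / r
        f = ((dlj + dcoul) / r)[:, None] * dx  # force on atom ii
        np.add.at(gradient, ii, f)
        np.add.at(gradient, jj, -f)
    return float(e_lj.sum()), float(e_coul.sum())


# ---------------------------------------------------------------------------
# implicit solvation


def _sphere_points(n: int = _N_SPHERE_POINTS) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere points."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


_SPHERE = _sphere_points()


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Center coordinates and rotate into the principal-axes frame.

    Axis signs are fixed by the coordinate skewness along each axis (largest-
    magnitude rule as a fallback), and the third axis completes a right-
    handed frame. This makes the point-sampled surface area exactly
    invariant under global rotation/translation for generic (non-degenerate)
    geometries.
    """
    if len(coords) == 0:
        return coords
    centered = coords - coords.mean(axis=0)
    if len(centered) < 2:
        return centered
    gyration = centered.T @ centered
    _vals, vecs = np.linalg.eigh(gyration)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(2):
        proj = centered @ vecs[:, k]
        skew = float(np.sum(proj**3))
        if skew < 0 or (skew == 0.0 and proj[int(np.argmax(np.abs(proj)))] < 0):
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return centered @ vecs


def shrake_rupley_sasa(system: MolecularSystem, probe: float = SASA_PROBE_RADIUS) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å², via Shrake-Rupley.

    Fixed deterministic 256-point golden-spiral sphere per atom; coordinates
    are canonicalized to a principal-axes frame first so the result does not
    depend on the global orientation of the input.
    """
    x = _canonical_frame(system.coords)
    radii = np.array([a.vdw_radius for a in system.atoms]) + probe
    n = system.n_atoms
    sasa = np.zeros(n)
    for i in range(n):
        pts = x[i] + radii[i] * _SPHERE  # (P, 3)
        others = np.arange(n) != i
        if not others.any():
            sasa[i] = 4.0 * np.pi * radii[i] ** 2
            continue
        diff = pts[:, None, :] - x[others][None, :, :]  # (P, M, 3)
        d2 = np.einsum("pmk,pmk->pm", diff, diff)
        buried = (d2 <= radii[others][None, :] ** 2).any(axis=1)
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * (1.0 - buried.mean())
    return sasa


def solvation_energy(
    system: MolecularSystem, gradient: np.ndarray | None = None
) -> tuple[float, float]:
    """Generalized-Born polar and accessible-area nonpolar solvation terms.

    The polar term is the Still pairwise form over *all* atom pairs
    (self-terms included, no exclusions):

        G_pol = -(K_e/2)(1/eps_in - 1/eps_out) sum_ij q_i q_j / f_ij,
        f_ij  = sqrt(r^2 + a_i a_j exp(-r^2 / (4 a_i a_j))),  f_ii = a_i,

    with fixed user-supplied Born radii a_i. The nonpolar term is
    sum_i sasa_coefficient_i * SASA_i (zero force: SASA is piecewise
    constant under the fixed-point-set algorithm).
    """
    a = np.array([atom.born_radius for atom in system.atoms])
    if np.any(a <= 0):
        raise ParameterError("Born radii must be positive")
    q = np.array([atom.charge for atom in system.atoms])
    tau = K_COULOMB * (1.0 / EPS_INTERIOR - 1.0 / EPS_EXTERIOR)

    gb = -0.5 * tau * float(np.sum(q * q / a))  # self terms
    n = system.n_atoms
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        dx = system.coords[ii] - system.coords[jj]
        r2 = np.einsum("ij,ij->i", dx, dx)
        D = a[ii] * a[jj]
        expo = np.exp(-r2 / (4.0 * D))
        f = np.sqrt(r2 + D * expo)
        qq = q[ii] * q[jj]
        gb += -tau * float(np.sum(qq / f))  # off-diagonal counted twice
        if gradient is not None:
            r = np.sqrt(r2)
            with np.errstate(invalid="ignore", divide="ignore"):
                df_dr = (2.0 * r - 0.5 * r * expo) / (2.0 * f)
                dE_dr = tau * qq / (f * f) * df_dr
                coef = np.where(r > 0.0, dE_dr / r, 0.0)
            fvec = coef[:, None] * dx
            np.add.at(gradient, ii, fvec)
            np.add.at(gradient, jj, -fvec)

    coeffs = np.array([atom.sasa_coefficient for atom in system.atoms])
    asa = float(np.dot(coeffs, shrake_rupley_sasa(system)))
    return gb, asa


# ---------------------------------------------------------------------------
# NOE restraints


def noe_energy(
    system: MolecularSystem,
    restraints: Iterable[NOERestraint],
    gradient: np.ndarray | None = None,
) -> float:
    """Flat-bottom restraint energy: zero in [d_min, d_max], harmonic walls
    with k_min below and k_max above."""
    total = 0.0
    x = system.coords
    for rest in restraints:
        i = system.select_atom(rest.chain_a, rest.residue_a, rest.atom_a)
        j = system.select_atom(rest.chain_b, rest.residue_b, rest.atom_b)
        dx = x[i] - x[j]
        d = float(np.linalg.norm(dx))
        if d < rest.d_min:
            k, edge = rest.k_min, rest.d_min
        elif d > rest.d_max:
            k, edge = rest.k_max, rest.d_max
        else:
            continue
        total += k * (d - edge) ** 2
        if gradient is not None and d > 0.0:
            g = 2.0 * k * (d - edge) * dx / d
            gradient[i] += g
            gradient[j] -= g
    return total


# ---------------------------------------------------------------------------
# assembly


def total_energy(
    system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    include_solvation: bool = True,
) -> EnergyBreakdown:
    """Full energy decomposition; ``total`` is the exact component sum."""
    breakdown, _ = total_energy_and_gradient(
        system, restraints, include_solvation=include_solvation, want_gradient=False
    )
    return breakdown


def total_energy_and_gradient(
    system: MolecularSystem,
    restraints: Sequence[NOERestraint] = (),
    include_solvation: bool = True,
    want_gradient: bool = True,
) -> tuple[EnergyBreakdown, np.ndarray | None]:
    grad = np.zeros_like(system.coords) if want_gradient else None
    out = bonded_energy(system, gradient=grad)
    out.vdw, out.electrostatic = nonbonded_energy(system, "all", gradient=grad)
    if include_solvation:
        out.gb_polar, out.asa_nonpolar = solvation_energy(system, gradient=grad)
    out.noe = noe_energy(system, restraints, gradient=grad)
    return out, grad
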