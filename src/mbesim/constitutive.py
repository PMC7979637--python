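"""Pointwise constitutive laws of the cluster mixture.

All functions are pure and operate either on plain floats/numpy arrays or on
:class:`~mbesim.jet.Jet` duals, in which case they return exact analytic
partial derivatives alongside values.  In the axisymmetric benchmark the
deformation gradient, its inverse Cauchy-Green tensor and the electric
displacements are diagonal/radial, so the API exposes scalar radial
components; the general tensor forms they specialize are noted in the
docstrings for future 2-D/3-D extension.

Sign and bookkeeping conventions
--------------------------------
* Osmotic concentrations sum over *all* species, mobile and fixed.
* Flux sums over mobile species only; the fixed-ion contribution to the
  water flux appears through the ``(sum_fixed C_j / C_w) grad C_w`` term.
* Transmembrane fluxes are positive from the intracellular (IC) to the
  extracellular (EC) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import jet
from .jet import log as jlog
from .jet import value
from .parameters import DerivedConstants, ParameterSet, SpeciesSpec

__all__ = [
    "Kinematics1D",
    "PointState",
    "StressDecomposition",
    "FluxSet",
    "kinematics",
    "water_from_constraint",
    "volume_from_water",
    "chemical_potential_water",
    "electrochemical_potential_ion",
    "mobility_matrices",
    "ic_fluxes",
    "ec_fluxes",
    "fluxes_via_mobility",
    "nominal_stress",
    "electric_displacement",
    "sigma_zz_plane",
    "dissipation_rate",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Kinematics1D:
    """Diagonal deformation state: F = diag(F_rr, F_tt, F_zz)."""

    F_rr: Any
    F_tt: Any
    F_zz: Any
    J: Any = None
    J_a: Any = None
    Cinv_rr: Any = None

    def __post_init__(self):
        if np.any(value(self.F_rr) <= 0) or np.any(value(self.F_tt) <= 0) \
                or np.any(value(self.F_zz) <= 0):
            raise ValueError("stretches must be positive")
        if self.J is None:
            self.J = self.F_rr * self.F_tt * self.F_zz
        if self.J_a is None:
            self.J_a = self.F_rr * self.F_tt
        if self.Cinv_rr is None:
            self.Cinv_rr = 1.0 / (self.F_rr * self.F_rr)


def kinematics(F_rr, F_tt, F_zz) -> Kinematics1D:
    return Kinematics1D(F_rr, F_tt, F_zz)


@dataclass
class PointState:
    """Primary fields and their radial reference gradients at one point.

    Ion entries are mappings keyed by species name (mobile species only;
    fixed species are constant and live in the :class:`ParameterSet`).
    """

    Cw_ic: Any
    Cw_ec: Any
    Ci_ic: Mapping[str, Any]
    Ci_ec: Mapping[str, Any]
    psi_ic: Any = 0.0
    psi_ec: Any = 0.0
    pw: Any = 0.0
    grad_Cw_ic: Any = 0.0
    grad_Cw_ec: Any = 0.0
    grad_Ci_ic: Mapping[str, Any] = field(default_factory=dict)
    grad_Ci_ec: Mapping[str, Any] = field(default_factory=dict)
    grad_psi_ic: Any = 0.0
    grad_psi_ec: Any = 0.0
    grad_pw: Any = 0.0


@dataclass
class StressDecomposition:
    """Diagonal nominal/Cauchy stress split and the pressure contributions."""

    P_mec: tuple
    P_w: tuple
    P_pol_ic: tuple
    P_pol_ec: tuple
    sigma: tuple
    p_mec: Any
    p_w: Any
    p_pol: Any
    p_pol_e: Any
    p_total: Any

    @property
    def P(self) -> tuple:
        return tuple(self.P_mec[k] + self.P_w[k] + self.P_pol_ic[k] + self.P_pol_ec[k]
                     for k in range(3))


@dataclass
class FluxSet:
    Jw_ic: Any
    Jw_ec: Any
    Ji_ic: Mapping[str, Any]
    Ji_ec: Mapping[str, Any]


# ---------------------------------------------------------------------------
# Volumetric constraint
# ---------------------------------------------------------------------------

def water_from_constraint(J, Cw_ec, ps: ParameterSet):
    """IC water concentration eliminated through the volume-ratio constraint.

    Inverts ``J = 1 + Phi0*(v_w*C_w - 1) + Phi0e*(v_w*C_w^e - 1)`` (dilute
    incompressible mixture) for C_w.  Raises if the result is nonpositive,
    which signals nonphysical collapse of the IC space.
    """
    if np.any(value(J) <= 0):
        raise ValueError("volume ratio must be positive")
    Cw = 1.0 / ps.v_w + (J - 1.0 - ps.Phi0_ec * (ps.v_w * Cw_ec - 1.0)) \
        / (ps.Phi0_ic * ps.v_w)
    if np.any(value(Cw) <= 0):
        raise ValueError("IC water concentration nonpositive: IC space collapse")
    return Cw


def volume_from_water(Cw_ic, Cw_ec, ps: ParameterSet):
    """Volume ratio from the water contents (forward form of the constraint)."""
    return 1.0 + ps.Phi0_ic * (ps.v_w * Cw_ic - 1.0) \
        + ps.Phi0_ec * (ps.v_w * Cw_ec - 1.0)


# ---------------------------------------------------------------------------
# Chemical / electrochemical potentials
# ---------------------------------------------------------------------------

def chemical_potential_water(C_osm, Cw, pw, ps: ParameterSet):
    """mu_w = -R T C_osm / C_w + v_w p_w  [J/mol].

    ``C_osm`` is the osmotic concentration summing mobile and fixed species.
    """
    if np.any(value(Cw) <= 0):
        raise ValueError("water concentration must be positive")
    return -ps.R_gas * ps.T * C_osm / Cw + ps.v_w * pw


def electrochemical_potential_ion(Ci, Cw, z, psi, ps: ParameterSet):
    """mu~_i = R T ln(C_i / C_w) + F z_i psi  [J/mol]."""
    if np.any(value(Ci) <= 0) or np.any(value(Cw) <= 0):
        raise ValueError("concentrations must be positive")
    return ps.R_gas * ps.T * jlog(Ci / Cw) + ps.F * z * psi


# ---------------------------------------------------------------------------
# Mobility matrices (Onsager form)
# ---------------------------------------------------------------------------

def _mobility(Dw, Cw, Ds, Cs, Cinv_rr, RT):
    n = 1 + len(Cs)
    M = np.zeros((n, n))
    pref = Cinv_rr / RT
    M[0, 0] = Dw * Cw
    for i, (Di, Ci) in enumerate(zip(Ds, Cs), start=1):
        M[0, i] = M[i, 0] = Dw * Ci
        M[i, i] = (Dw * Ci / Cw + Di) * Ci
        for k in range(i + 1, len(Cs) + 1):
            M[i, k] = M[k, i] = Dw * Ci * Cs[k - 1] / Cw
    return pref * M


def mobility_matrices(state: PointState, kin: Kinematics1D, ps: ParameterSet):
    """The (1+n)x(1+n) symmetric IC and EC mobility matrices.

    Ordering: water first, then mobile species in registry order.  The scalar
    radial component of C^{-1} replaces the tensor factor in 1-D.  Both
    matrices are symmetric and positive definite for positive diffusivities
    and concentrations.
    """
    RT = ps.R_gas * ps.T
    names = [s.name for s in ps.mobile]
    Cinv = float(value(kin.Cinv_rr))
    M_ic = _mobility(ps.D_w_ic, float(value(state.Cw_ic)),
                     [s.D_ic for s in ps.mobile],
                     [float(value(state.Ci_ic[n])) for n in names], Cinv, RT)
    M_ec = _mobility(ps.D_w_ec, float(value(state.Cw_ec)),
                     [s.D_ec for s in ps.mobile],
                     [float(value(state.Ci_ec[n])) for n in names], Cinv, RT)
    return M_ic, M_ec


# ---------------------------------------------------------------------------
# Bulk fluxes — explicit (primal-variable) form
# ---------------------------------------------------------------------------

def _space_fluxes(Dw, Cw, gCw, species, Ds, Ci, gCi, psi_grad, pw_grad,
                  C_fix, Cinv, ps):
    RT = ps.R_gas * ps.T
    if np.any(value(Cw) <= 0):
        raise ValueError("water concentration must be positive")
    migr = 0.0
    for s, c in zip(species, Ci.values()):
        migr = migr + s.z * c
    Jw = -Dw * Cinv * (ps.v_w * Cw / RT * pw_grad
                       + ps.F / RT * migr * psi_grad
                       + (C_fix / Cw) * gCw)
    Ji = {}
    for s, Di in zip(species, Ds):
        c, gc = Ci[s.name], gCi[s.name]
        Ji[s.name] = (c / Cw) * Jw - Di * Cinv * (
            gc - (c / Cw) * gCw + ps.F / RT * s.z * c * psi_grad)
    return Jw, Ji


def ic_fluxes(state: PointState, kin: Kinematics1D, ps: ParameterSet):
    """IC (through-gap-junction) nominal water and ion fluxes.

    Water is driven by its pressure gradient, electro-osmosis with the mobile
    ions, and the fixed-ion osmotic term; ions ride on the water flux
    (convection) and electro-diffuse.  With closed gap junctions all IC
    diffusivities are zero and the fluxes vanish.
    """
    C_fix = sum(s.C0_ic for s in ps.fixed)
    return _space_fluxes(ps.D_w_ic, state.Cw_ic, state.grad_Cw_ic, ps.mobile,
                         [s.D_ic for s in ps.mobile], state.Ci_ic,
                         state.grad_Ci_ic, state.grad_psi_ic, state.grad_pw,
                         C_fix, kin.Cinv_rr, ps)


def ec_fluxes(state: PointState, kin: Kinematics1D, ps: ParameterSet):
    """EC (intercellular-cleft) nominal water and ion fluxes."""
    C_fix = sum(s.C0_ec for s in ps.fixed)
    return _space_fluxes(ps.D_w_ec, state.Cw_ec, state.grad_Cw_ec, ps.mobile,
                         [s.D_ec for s in ps.mobile], state.Ci_ec,
                         state.grad_Ci_ec, state.grad_psi_ec, state.grad_pw,
                         C_fix, kin.Cinv_rr, ps)


# ---------------------------------------------------------------------------
# Bulk fluxes — potential-gradient (Onsager) route, used as a cross-check
# ---------------------------------------------------------------------------

def _space_fluxes_mobility(Dw, Cw, gCw, species, Ds, Ci, gCi, psi, gpsi,
                           pw_grad, C_fix, Cinv, ps):
    RT = ps.R_gas * ps.T
    # grad mu_w with C_osm = C_mobile + C_fix, fixed part constant
    gC_mob = 0.0
    C_osm = C_fix
    for c in Ci.values():
        C_osm = C_osm + c
    for g in gCi.values():
        gC_mob = gC_mob + g
    gmu_w = -RT * (gC_mob / Cw - C_osm * gCw / (Cw * Cw)) + ps.v_w * pw_grad
    gmut = {}
    for s in species:
        c, gc = Ci[s.name], gCi[s.name]
        gmut[s.name] = RT * (gc / c - gCw / Cw) + ps.F * s.z * gpsi
    acc = Cw * gmu_w
    for s in species:
        acc = acc + Ci[s.name] * gmut[s.name]
    Jw = -(Dw / RT) * Cinv * acc
    Ji = {}
    for s, Di in zip(species, Ds):
        c = Ci[s.name]
        Ji[s.name] = (c / Cw) * Jw - (Di / RT) * Cinv * c * gmut[s.name]
    return Jw, Ji, gmu_w, gmut


def fluxes_via_mobility(state: PointState, kin: Kinematics1D, ps: ParameterSet,
                        space: str = "ic"):
    """Fluxes computed from chemical/electrochemical potential gradients.

    Independent route through the Onsager mobility structure; algebraically
    equivalent to :func:`ic_fluxes` / :func:`ec_fluxes` and used in tests to
    cross-validate the explicit forms.
    """
    if space == "ic":
        C_fix = sum(s.C0_ic for s in ps.fixed)
        Jw, Ji, *_ = _space_fluxes_mobility(
            ps.D_w_ic, state.Cw_ic, state.grad_Cw_ic, ps.mobile,
            [s.D_ic for s in ps.mobile], state.Ci_ic, state.grad_Ci_ic,
            state.psi_ic, state.grad_psi_ic, state.grad_pw, C_fix,
            kin.Cinv_rr, ps)
    else:
        C_fix = sum(s.C0_ec for s in ps.fixed)
        Jw, Ji, *_ = _space_fluxes_mobility(
            ps.D_w_ec, state.Cw_ec, state.grad_Cw_ec, ps.mobile,
            [s.D_ec for s in ps.mobile], state.Ci_ec, state.grad_Ci_ec,
            state.psi_ec, state.grad_psi_ec, state.grad_pw, C_fix,
            kin.Cinv_rr, ps)
    return Jw, Ji


# ---------------------------------------------------------------------------
# Stress, electric displacement, plane stress
# ---------------------------------------------------------------------------

def _pol_P(Fk, D, J, eps, comp):
    """Diagonal components of the polarization nominal stress for radial D.

    Specializes (1/(2 eps J)) [2 F (D x D) - (C : (D x D)) F^{-T}] to
    F = diag, D radial: rr component F_rr D^2/(2 eps J); tt and zz components
    -F_rr^2 D^2 / (2 eps J F_kk).
    """
    F_rr = Fk[0]
    if comp == 0:
        return F_rr * D * D / (2.0 * eps * J)
    return -(F_rr * F_rr) * D * D / (2.0 * eps * J * Fk[comp])


def nominal_stress(kin: Kinematics1D, D_ic, D_ec, pw, ps: ParameterSet,
                   dc: DerivedConstants) -> StressDecomposition:
    """Additive nominal stress split, its Cauchy map, and the pressure split.

    Components are ordered (rr, tt, zz).  The compressible neo-Hookean
    network stress is G(F - F^{-T}) + lambda ln J F^{-T}; the water pressure
    acts as an eigenstress -p_w J F^{-T}; the polarization (Maxwell) stresses
    follow from the ideal-dielectric energy with the radial nominal electric
    displacements D_ic, D_ec of each space.
    """
    G, lam = dc.lame_G, dc.lame_lambda
    eps = ps.eps0 * ps.eps_r * ps.permittivity_scale
    F = (kin.F_rr, kin.F_tt, kin.F_zz)
    J = kin.J
    lnJ = jlog(J)
    P_mec = tuple(G * (F[k] - 1.0 / F[k]) + lam * lnJ / F[k] for k in range(3))
    P_w = tuple(-pw * J / F[k] for k in range(3))
    if ps.include_polarization:
        P_pi = tuple(_pol_P(F, D_ic, J, eps, k) for k in range(3))
        P_pe = tuple(_pol_P(F, D_ec, J, eps, k) for k in range(3))
    else:
        P_pi = P_pe = (0.0, 0.0, 0.0)
    sigma = tuple((P_mec[k] + P_w[k] + P_pi[k] + P_pe[k]) * F[k] / J
                  for k in range(3))
    # pressure split (positive if compressive)
    trb = F[0] * F[0] + F[1] * F[1] + F[2] * F[2]
    p_mec = -(G * (trb / 3.0 - 1.0) + lam * lnJ) / J
    d_ic = D_ic * kin.F_rr / J
    d_ec = D_ec * kin.F_rr / J
    if ps.include_polarization:
        p_pol = d_ic * d_ic / (6.0 * eps)
        p_pol_e = d_ec * d_ec / (6.0 * eps)
    else:
        p_pol = p_pol_e = 0.0
    p_total = p_mec + pw + p_pol + p_pol_e
    return StressDecomposition(P_mec, P_w, P_pi, P_pe, sigma,
                               p_mec, pw, p_pol, p_pol_e, p_total)


def electric_displacement(kin: Kinematics1D, grad_psi, ps: ParameterSet,
                          scaled: bool = True):
    """Radial nominal electric displacement D = -eps0 eps_r J C^{-1} grad psi.

    ``scaled`` applies the bulk permittivity regularization factor used by
    the Gauss-law rows of the solver; pass False for the physical value.
    """
    eps = ps.eps0 * ps.eps_r * (ps.permittivity_scale if scaled else 1.0)
    return -eps * kin.J * kin.Cinv_rr * grad_psi


def sigma_zz_plane(F_rr, F_tt, F_zz, pw, d_ic, d_ec, ps: ParameterSet,
                   dc: DerivedConstants, include_polarization=None):
    """Out-of-plane total Cauchy stress, zeroed by the plane-stress condition.

    ``d_ic``/``d_ec`` are *current* radial electric displacements; for a
    radial field their Maxwell stress is compressive along z.
    """
    G, lam = dc.lame_G, dc.lame_lambda
    J = F_rr * F_tt * F_zz
    s = (G * (F_zz * F_zz - 1.0) + lam * jlog(J)) / J - pw
    if include_polarization is None:
        include_polarization = ps.include_polarization
    if include_polarization:
        eps = ps.eps0 * ps.eps_r * ps.permittivity_scale
        s = s - (d_ic * d_ic + d_ec * d_ec) / (2.0 * eps)
    return s


def plane_stress_condense(F_rr, F_tt, pw, ps: ParameterSet,
                          dc: DerivedConstants, d_ic=0.0, d_ec=0.0,
                          tol_factor: float = 1e-10, F_zz_max: float = 50.0):
    """Solve sigma_zz(F_zz) = 0 for the out-of-plane stretch.

    Safeguarded scalar Newton (bisection fallback) on (0, F_zz_max);
    converges to |sigma_zz| <= tol_factor * E.  Raises if no root is
    bracketed, signalling step rejection.
    """
    from scipy.optimize import brentq

    if value(F_rr) <= 0 or value(F_tt) <= 0:
        raise ValueError("in-plane stretches must be positive")

    def f(x):
        return float(value(sigma_zz_plane(F_rr, F_tt, x, pw, d_ic, d_ec, ps, dc)))

    lo, hi = 1e-6, F_zz_max
    if f(lo) * f(hi) > 0:
        raise ValueError("plane-stress condensation: no root bracketed")
    root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    if abs(f(root)) > tol_factor * ps.E:
        raise ValueError("plane-stress condensation did not converge")
    return root


# ---------------------------------------------------------------------------
# Dissipation rate (runtime second-law diagnostic)
# ---------------------------------------------------------------------------

def dissipation_rate(state: PointState, kin: Kinematics1D, fluxes: FluxSet,
                     membrane_fluxes, ps: ParameterSet,
                     dc: DerivedConstants):
    """Local dissipation rate [W/m^3 reference], must be >= 0.

    Bulk part: -J_w.grad mu_w - sum_i J_i.grad mu~_i in each space; membrane
    part: -(A^c/V^c)[J_w^m (mu_w^e - mu_w) + sum_i J_i^m (mu~_i^e - mu~_i)].
    Evaluated from the supplied fluxes and the potential gradients recomputed
    from the state, so it is a genuine diagnostic of whichever fluxes are
    passed in.
    """
    RT = ps.R_gas * ps.T
    C_fix_ic = sum(s.C0_ic for s in ps.fixed)
    C_fix_ec = sum(s.C0_ec for s in ps.fixed)
    *_, gmu_w_ic, gmut_ic = _space_fluxes_mobility(
        ps.D_w_ic, state.Cw_ic, state.grad_Cw_ic, ps.mobile,
        [s.D_ic for s in ps.mobile], state.Ci_ic, state.grad_Ci_ic,
        state.psi_ic, state.grad_psi_ic, state.grad_pw, C_fix_ic,
        kin.Cinv_rr, ps)
    *_, gmu_w_ec, gmut_ec = _space_fluxes_mobility(
        ps.D_w_ec, state.Cw_ec, state.grad_Cw_ec, ps.mobile,
        [s.D_ec for s in ps.mobile], state.Ci_ec, state.grad_Ci_ec,
        state.psi_ec, state.grad_psi_ec, state.grad_pw, C_fix_ec,
        kin.Cinv_rr, ps)
    out = -(fluxes.Jw_ic * gmu_w_ic + fluxes.Jw_ec * gmu_w_ec)
    for s in ps.mobile:
        out = out - fluxes.Ji_ic[s.name] * gmut_ic[s.name] \
            - fluxes.Ji_ec[s.name] * gmut_ec[s.name]
    if membrane_fluxes is not None:
        C_osm_ic = C_fix_ic
        C_osm_ec = C_fix_ec
        for n in state.Ci_ic:
            C_osm_ic = C_osm_ic + state.Ci_ic[n]
            C_osm_ec = C_osm_ec + state.Ci_ec[n]
        dmu_w = chemical_potential_water(C_osm_ec, state.Cw_ec, state.pw, ps) \
            - chemical_potential_water(C_osm_ic, state.Cw_ic, state.pw, ps)
        acc = membrane_fluxes.Jw_m * dmu_w
        for s in ps.mobile:
            dmut = electrochemical_potential_ion(
                state.Ci_ec[s.name], state.Cw_ec, s.z, state.psi_ec, ps) \
                - electrochemical_potential_ion(
                    state.Ci_ic[s.name], state.Cw_ic, s.z, state.psi_ic, ps)
            acc = acc + membrane_fluxes.Ji_m[s.name] * dmut
        out = out - dc.area_per_volume * acc
    return out
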