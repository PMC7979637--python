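"""Closed-form steady-state and equilibrium calculators.

These serve as the primary analytic oracle for the PDE solver: the
open-boundary (no tight junction) steady state follows from bath equilibrium
plus intracellular electroneutrality with the fixed anion, and the sealed
(tight-junction) steady state follows from species/water conservation with
equal current concentrations across the membrane.  Both are independent of
the finite-element path and are compared against it in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .parameters import DerivedConstants, ParameterSet, derive_constants

__all__ = ["SteadyState", "open_boundary_steady", "sealed_steady",
           "nernst_potential", "donnan_state"]


@dataclass
class SteadyState:
    """Uniform steady state of the cluster.

    Current-volume concentrations c (mol per m^3 of current fluid volume)
    relate to reference ones through c_i = C_i / (v_w C_w).
    """

    c_ic: dict  # current IC concentrations, incl. fixed species
    c_ec: dict
    C_ic: dict  # reference IC concentrations
    C_ec: dict
    Cw_ic: float
    Cw_ec: float
    J: float
    lambda_s: float  # isotropic in-plane/out-of-plane stretch
    p_w: float  # Pa
    osmotic_ratio_ic: float  # C / C0 (reference osmotic concentrations)
    osmotic_ratio_ec: float  # C^e / C^{e,0}
    water_ratio_ic: float  # C_w / C_w^0
    water_ratio_ec: float
    boundary_displacement_fraction: float  # u(R_cl) / R_cl
    details: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _fixed_charge(ps: ParameterSet, space: str) -> float:
    return sum(s.z * (s.C0_ic if space == "ic" else s.C0_ec) for s in ps.fixed)


def open_boundary_steady(ps: ParameterSet,
                         dc: DerivedConstants | None = None) -> SteadyState:
    """Steady state with a permeable boundary (tight junctions absent).

    Without pumps and in the compliant limit (water pressure negligible
    against the osmotic pressures), every mobile species equilibrates with
    the bath: current concentrations c_i = c_i^e = C_i^{e,0} and potentials
    vanish.  The impermeant intracellular anion then fixes the IC water
    content through electroneutrality, the volumetric constraint gives J
    (the EC space stays undeformed), and the traction-free plane-stress
    equilibrium of the isotropically swollen cluster yields the stretch
    lambda_s = J^{1/3}, a linear-in-R displacement, and the uniform water
    pressure balancing the network stress.
    """
    if ps.tj_sealed:
        raise ValueError("open-boundary steady state requires tj_sealed=False")
    dc = dc or derive_constants(ps)
    c_mob = {s.name: s.C0_ec for s in ps.mobile}
    mobile_charge = sum(s.z * c_mob[s.name] for s in ps.mobile)
    fixed_ic = _fixed_charge(ps, "ic")
    if fixed_ic == 0.0 and mobile_charge == 0.0:
        w = 1.0  # no driving force: undeformed reference state
    else:
        if mobile_charge == 0.0 or -fixed_ic / mobile_charge <= 0:
            raise ValueError(
                "IC electroneutrality insoluble: fixed and mobile charges "
                "have incompatible signs")
        w = -fixed_ic / mobile_charge  # v_w * C_w
    Cw = w / ps.v_w
    Cwe = 1.0 / ps.v_w  # EC space undeformed
    J = 1.0 + ps.Phi0_ic * (w - 1.0)
    lam_s = J ** (1.0 / 3.0)
    p_w = (dc.lame_G * (lam_s * lam_s - 1.0)
           + dc.lame_lambda * math.log(J)) / J

    c_ic = dict(c_mob)
    c_ec = dict(c_mob)
    C_ic = {n: c * w for n, c in c_mob.items()}
    C_ec = {n: c for n, c in c_mob.items()}  # w_e = 1
    for s in ps.fixed:
        C_ic[s.name] = s.C0_ic
        C_ec[s.name] = s.C0_ec
        c_ic[s.name] = s.C0_ic / w
        c_ec[s.name] = s.C0_ec
    C_osm_ic = sum(C_ic.values())
    C_osm_ec = sum(C_ec.values())
    return SteadyState(
        c_ic=c_ic, c_ec=c_ec, C_ic=C_ic, C_ec=C_ec, Cw_ic=Cw, Cw_ec=Cwe,
        J=J, lambda_s=lam_s, p_w=p_w,
        osmotic_ratio_ic=C_osm_ic / max(dc.C0_osm_ic, 1e-300),
        osmotic_ratio_ec=C_osm_ec / max(dc.C0_osm_ec, 1e-300),
        water_ratio_ic=w, water_ratio_ec=1.0,
        boundary_displacement_fraction=lam_s - 1.0,
        details={"v_w_Cw": w, "mobile_charge_current": mobile_charge},
    )


def sealed_steady(ps: ParameterSet,
                  dc: DerivedConstants | None = None) -> SteadyState:
    """Steady state with a sealed boundary (tight junctions present).

    Reference totals Phi0 C_i + Phi0^e C_i^e and the water total are
    conserved; at steady state the current concentrations equalize across
    the membrane (c_i = c_i^e) and each space is electroneutral with its own
    fixed anion content.  In the limit reported for the benchmark the
    cluster is globally undeformed (J = 1 pointwise), which closes the
    system: the mobile current concentrations follow from the totals, and
    the fixed-anion electroneutrality fixes each space's water content.
    """
    dc = dc or derive_constants(ps)
    S = ps.Phi0_ic + ps.Phi0_ec
    c_mob = {s.name: (ps.Phi0_ic * s.C0_ic + ps.Phi0_ec * s.C0_ec) / S
             for s in ps.mobile}
    mobile_charge = sum(s.z * c_mob[s.name] for s in ps.mobile)

    def water_content(fixed_charge, phi, init):
        if fixed_charge == 0.0:
            return init  # no Donnan constraint: water split unchanged
        w = -fixed_charge / mobile_charge if mobile_charge else math.nan
        if not (w > 0):
            raise ValueError("sealed steady state: electroneutrality insoluble")
        return w

    w_ic = water_content(_fixed_charge(ps, "ic"), ps.Phi0_ic, 1.0)
    w_ec = water_content(_fixed_charge(ps, "ec"), ps.Phi0_ec, 1.0)
    # conservation of water (equivalently of total charge) must close
    drift = ps.Phi0_ic * w_ic + ps.Phi0_ec * w_ec - S
    if abs(drift) > 1e-9 * S:
        raise ValueError(
            f"sealed steady state inconsistent: water total drift {drift:g}")

    c_ic = dict(c_mob)
    c_ec = dict(c_mob)
    C_ic = {n: c * w_ic for n, c in c_mob.items()}
    C_ec = {n: c * w_ec for n, c in c_mob.items()}
    for s in ps.fixed:
        C_ic[s.name] = s.C0_ic
        C_ec[s.name] = s.C0_ec
        c_ic[s.name] = s.C0_ic / w_ic
        c_ec[s.name] = s.C0_ec / w_ec
    C_osm_ic = sum(C_ic.values())
    C_osm_ec = sum(C_ec.values())
    return SteadyState(
        c_ic=c_ic, c_ec=c_ec, C_ic=C_ic, C_ec=C_ec,
        Cw_ic=w_ic / ps.v_w, Cw_ec=w_ec / ps.v_w,
        J=1.0, lambda_s=1.0, p_w=0.0,
        osmotic_ratio_ic=C_osm_ic / max(dc.C0_osm_ic, 1e-300),
        osmotic_ratio_ec=C_osm_ec / max(dc.C0_osm_ec, 1e-300),
        water_ratio_ic=w_ic, water_ratio_ec=w_ec,
        boundary_displacement_fraction=0.0,
        details={"water_total_drift": drift,
                 "c_mobile": c_mob},
    )


def nernst_potential(species, Ci_ic, Cw_ic, Ci_ec, Cw_ec, ps: ParameterSet):
    """Equilibrium potential psi - psi^e of one species [V].

    psi_N = (R T / (z F)) ln[(C_i^e / C_w^e) / (C_i / C_w)].
    """
    if species.z == 0:
        raise ValueError("Nernst potential undefined for a neutral species")
    for q in (Ci_ic, Cw_ic, Ci_ec, Cw_ec):
        if q <= 0:
            raise ValueError("concentrations must be positive")
    return ps.R_gas * ps.T / (species.z * ps.F) \
        * math.log((Ci_ec / Cw_ec) / (Ci_ic / Cw_ic))


def donnan_state(fixed_charge: float, bath: dict, ps: ParameterSet):
    """Gibbs-Donnan equilibrium against a monovalent bath.

    ``bath`` maps species name -> (z, current bath concentration); all
    |z| must be 1.  Solves equal electrochemical potentials plus local
    electroneutrality with the (signed) fixed charge; returns the internal
    current concentrations and the potential relative to the bath.  A
    negative fixed charge yields a negative potential and cation
    accumulation — the polarity seen in the cluster's early transient.
    """
    Cp = sum(c for z, c in bath.values() if z == 1)
    Cm = sum(c for z, c in bath.values() if z == -1)
    for name, (z, c) in bath.items():
        if abs(z) != 1:
            raise ValueError(f"{name}: Donnan helper is monovalent-only")
        if c < 0:
            raise ValueError(f"{name}: negative bath concentration")
    q = fixed_charge
    if Cp <= 0 or Cm <= 0:
        raise ValueError("bath must contain both a cation and an anion")
    # x = exp(-F psi / (R T));  Cp x - Cm / x + q = 0
    x = (-q + math.sqrt(q * q + 4.0 * Cp * Cm)) / (2.0 * Cp)
    psi = -ps.R_gas * ps.T / ps.F * math.log(x)
    inside = {name: c * (x if z == 1 else 1.0 / x)
              for name, (z, c) in bath.items()}
    return {"psi": psi, "concentrations": inside,
            "net_charge": sum((1 if bath[n][0] == 1 else -1) * c
                              for n, c in inside.items()) + q}
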