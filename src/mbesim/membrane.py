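"""Transmembrane exchange through aquaporins and ion channels.

Fluxes are positive from the intracellular (IC) to the extracellular (EC)
space and vanish at transmembrane chemical/electrochemical equilibrium.
Aquaporins and ion channels are species-specific, so each flux depends only
on its own potential jump; membrane properties are taken deformation-
independent.  A single water pressure field is shared by the two spaces, so
the transmembrane water driving force is purely osmotic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from . import jet
from .jet import log as jlog
from .jet import value
from .parameters import ParameterSet, SpeciesSpec

__all__ = [
    "MembraneFluxes",
    "transmembrane_water_flux",
    "transmembrane_ion_flux",
    "membrane_fluxes",
    "membrane_capacitor_displacement",
    "ghk_resting_potential",
]


@dataclass
class MembraneFluxes:
    Jw_m: Any  # mol m^-2 s^-1, positive IC -> EC
    Ji_m: Mapping[str, Any]
    psi_m: Any  # membrane potential psi - psi^e [V]


def transmembrane_water_flux(state, ps: ParameterSet):
    """Osmotic water flux through aquaporins.

    J_w^m = -D_w^m (C_w + C_w^e)/(2 T^m) * (C_w^e C - C_w C^e)/(C_w C_w^e),
    with C, C^e the full osmotic concentrations (mobile + fixed).  Zero when
    the osmotic-to-water ratios of the two spaces coincide; negative (EC to
    IC inflow) for an IC osmotic excess.
    """
    Cw, Cwe = state.Cw_ic, state.Cw_ec
    if np.any(value(Cw) <= 0) or np.any(value(Cwe) <= 0):
        raise ValueError("water concentrations must be positive")
    C = sum(s.C0_ic for s in ps.fixed)
    Ce = sum(s.C0_ec for s in ps.fixed)
    for n in state.Ci_ic:
        C = C + state.Ci_ic[n]
        Ce = Ce + state.Ci_ec[n]
    return -ps.D_w_m * (Cw + Cwe) / (2.0 * ps.T_m) \
        * (Cwe * C - Cw * Ce) / (Cw * Cwe)


def transmembrane_ion_flux(species: SpeciesSpec, state, ps: ParameterSet,
                           in_core=False):
    """Electro-diffusive ion flux through channels (GHK-type kinetics).

    J_i^m = -D_i^m (C_i + C_i^e)/(2 T^m)
            * [ln((C_i^e/C_i)(C_w/C_w^e)) - F z_i psi^m / (R T)].
    ``in_core`` selects the channel-overexpressing region's transmembrane
    diffusivity (sodium in the benchmark).
    """
    Ci, Cie = state.Ci_ic[species.name], state.Ci_ec[species.name]
    Cw, Cwe = state.Cw_ic, state.Cw_ec
    for q in (Ci, Cie, Cw, Cwe):
        if np.any(value(q) <= 0):
            raise ValueError("concentrations must be positive")
    D_in = species.D_m if species.D_m_in is None else species.D_m_in
    Dm = np.where(in_core, D_in, species.D_m) if np.ndim(in_core) \
        else species.D_m_at(bool(in_core))
    psi_m = state.psi_ic - state.psi_ec
    arg = jlog((Cie / Ci) * (Cw / Cwe)) \
        - ps.F * species.z / (ps.R_gas * ps.T) * psi_m
    return -Dm * (Ci + Cie) / (2.0 * ps.T_m) * arg


def membrane_fluxes(state, ps: ParameterSet, in_core=False) -> MembraneFluxes:
    Ji = {s.name: transmembrane_ion_flux(s, state, ps, in_core)
          for s in ps.mobile}
    return MembraneFluxes(transmembrane_water_flux(state, ps), Ji,
                          state.psi_ic - state.psi_ec)


def membrane_capacitor_displacement(psi_boundary, ps: ParameterSet,
                                    which: str = "membrane"):
    """Thin-capacitor electric displacement at the cluster boundary.

    The cell membranes facing the bath (and, when sealed, the tight-junction
    belt) act as planar capacitors against the grounded bath (psi_bar = 0):
    D_bar = eps0 eps_r^m psi / T^m  or  eps0 eps_r^tj psi^e / T^tj.
    """
    if which == "membrane":
        return ps.eps0 * ps.eps_r_m * psi_boundary / ps.T_m
    if which == "tj":
        return ps.eps0 * ps.eps_r_tj * psi_boundary / ps.T_tj
    raise ValueError(f"unknown capacitor {which!r}")


def ghk_resting_potential(ps: ParameterSet, region: str = "out") -> float:
    """Goldman-Hodgkin-Katz resting membrane potential [V].

    Uses the transmembrane diffusivities of the requested region as relative
    permeabilities and the initial concentrations.  Monovalent mobile species
    only; a validation helper, never used inside the dynamics.
    """
    in_core = region == "in"
    num = den = 0.0
    permeant = False
    for s in ps.mobile:
        P = s.D_m_at(in_core)
        if P > 0:
            permeant = True
        if abs(s.z) != 1:
            raise ValueError(
                f"{s.name}: GHK voltage equation implemented for monovalent "
                "ions only")
        if s.z == 1:
            num += P * s.C0_ec
            den += P * s.C0_ic
        else:
            num += P * s.C0_ic
            den += P * s.C0_ec
    if not permeant:
        raise ValueError("GHK potential needs at least one permeant species")
    return ps.R_gas * ps.T / ps.F * float(np.log(num / den))
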