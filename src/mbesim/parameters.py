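"""Model parameters for the cell-cluster mechanobioelectricity benchmark.

The cluster is modeled as a mixture of a hyperelastic solid network and two
interpenetrating fluid compartments: the intracellular (IC) space — cytoplasm
connected cell-to-cell by gap junctions (GJs) — and the extracellular (EC)
space of intercellular clefts, possibly sealed at the cluster boundary by
tight junctions (TJs).  Everything is SI internally; configuration files may
carry the customary mixed units (um, kPa, cm^3/mol) through explicit unit
tags, converted on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

from .constants import EPS0, FARADAY, R_GAS

__all__ = [
    "SpeciesSpec",
    "ParameterSet",
    "DerivedConstants",
    "load_parameters",
    "derive_constants",
    "validate_initial_state",
    "reference_parameters",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One ionic species of the IC/EC electrolyte.

    ``mobile=False`` marks a fixed species (e.g. impermeant cytosolic
    macro-anions): its reference concentration never changes and all its
    diffusivities are zero, but it still enters the osmotic and charge sums.
    ``D_m_in`` allows a different transmembrane diffusivity inside the
    channel-overexpressing core region (sodium in the benchmark).
    """

    name: str
    z: int
    mobile: bool
    C0_ic: float  # mol/m^3 (per reference IC volume)
    C0_ec: float  # mol/m^3 (per reference EC volume)
    D_ic: float = 0.0  # m^2/s
    D_ec: float = 0.0  # m^2/s
    D_m: float = 0.0  # m^2/s, transmembrane (outer region)
    D_m_in: float | None = None  # transmembrane in the core region, if different

    def __post_init__(self):
        if self.C0_ic < 0 or self.C0_ec < 0:
            raise ValueError(f"{self.name}: negative initial concentration")
        if not self.mobile and (self.D_ic or self.D_ec or self.D_m or self.D_m_in):
            raise ValueError(f"{self.name}: fixed species must have zero diffusivities")
        for d in (self.D_ic, self.D_ec, self.D_m):
            if d < 0:
                raise ValueError(f"{self.name}: negative diffusivity")

    def D_m_at(self, in_core: bool) -> float:
        if in_core and self.D_m_in is not None:
            return self.D_m_in
        return self.D_m


@dataclass(frozen=True)
class ParameterSet:
    """Geometry, material, transport and scenario parameters (SI units)."""

    R_c: float  # reference cell radius [m]
    T_m: float  # membrane thickness [m]
    R_cl: float  # reference cluster radius [m]
    Phi0_ic: float  # initial IC porosity [-]
    Phi0_ec: float  # initial EC porosity [-]
    T: float  # absolute temperature [K]
    eps_r: float  # relative permittivity of the IC/EC solutions [-]
    eps_r_m: float  # membrane relative permittivity [-]
    eps_r_tj: float  # TJ relative permittivity [-]
    T_tj: float  # TJ thickness [m]
    v_w: float  # water molar volume [m^3/mol]
    E: float  # Young modulus [Pa]
    nu: float  # Poisson ratio [-]
    D_w_ic: float  # IC water diffusivity (through GJs) [m^2/s]
    D_w_ec: float  # EC water diffusivity [m^2/s]
    D_w_m: float  # transmembrane water diffusivity [m^2/s]
    species: tuple[SpeciesSpec, ...]
    region_boundary: float  # radius separating the core from the annulus [m]
    gj_open: bool
    tj_sealed: bool
    permittivity_scale: float = 1.0  # bulk Gauss-law regularization factor
    include_polarization: bool = True
    F: float = FARADAY
    R_gas: float = R_GAS
    eps0: float = EPS0

    def __post_init__(self):
        if not (0 < self.Phi0_ec < self.Phi0_ic and self.Phi0_ic + self.Phi0_ec < 1):
            raise ValueError("porosities must satisfy 0 < Phi0_ec < Phi0_ic, sum < 1")
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.E <= 0:
            raise ValueError("Young modulus must be positive")
        for name in ("R_c", "T_m", "R_cl", "T", "eps_r", "eps_r_m", "eps_r_tj",
                     "T_tj", "v_w", "permittivity_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("D_w_ic", "D_w_ec", "D_w_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.region_boundary < self.R_cl:
            raise ValueError("region boundary must lie inside (0, R_cl)")
        if not self.gj_open:
            if self.D_w_ic != 0 or any(s.D_ic != 0 for s in self.species):
                raise ValueError("closed gap junctions require zero IC diffusivities")

    # -- convenience views -------------------------------------------------
    @property
    def mobile(self) -> tuple[SpeciesSpec, ...]:
        return tuple(s for s in self.species if s.mobile)

    @property
    def fixed(self) -> tuple[SpeciesSpec, ...]:
        return tuple(s for s in self.species if not s.mobile)

    def with_overrides(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedConstants:
    lame_lambda: float  # Pa
    lame_G: float  # Pa
    Cw0: float  # initial water concentration 1/v_w [mol/m^3]
    area_per_volume: float  # membrane area per cell volume, 2/R_c [1/m]
    C0_osm_ic: float  # initial IC osmotic concentration (all species) [mol/m^3]
    C0_osm_ec: float  # initial EC osmotic concentration [mol/m^3]

    def __post_init__(self):
        for name in ("lame_lambda", "lame_G", "Cw0", "area_per_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def derive_constants(ps: ParameterSet) -> DerivedConstants:
    """Lame moduli, initial water concentration, A^c/V^c, osmotic sums."""
    lam = ps.E * ps.nu / ((1 + ps.nu) * (1 - 2 * ps.nu))
    G = ps.E / (2 * (1 + ps.nu))
    return DerivedConstants(
        lame_lambda=lam,
        lame_G=G,
        Cw0=1.0 / ps.v_w,
        area_per_volume=2.0 / ps.R_c,
        C0_osm_ic=sum(s.C0_ic for s in ps.species),
        C0_osm_ec=sum(s.C0_ec for s in ps.species),
    )


# ---------------------------------------------------------------------------
# Reference (benchmark) configuration
# ---------------------------------------------------------------------------

def _reference_species() -> tuple[SpeciesSpec, ...]:
    return (
        SpeciesSpec("Na+", +1, True, 10.0, 145.0, 1e-12, 1e-9, 1e-18, 1e-17),
        SpeciesSpec("K+", +1, True, 140.0, 5.0, 1e-12, 1e-9, 5e-18),
        SpeciesSpec("Cl-", -1, True, 10.0, 110.0, 1e-12, 1e-9, 5e-17),
        SpeciesSpec("A-", -1, False, 140.0, 40.0),
    )


def reference_parameters(**overrides) -> ParameterSet:
    """The benchmark parameter set: an average animal-cell cluster.

    Gap junctions open, tight junctions absent by default; the innermost
    region of radius R_cl/2 overexpresses sodium channels (10x transmembrane
    sodium diffusivity).
    """
    base = dict(
        R_c=5e-6,
        T_m=5e-9,
        R_cl=500e-6,
        Phi0_ic=0.695,
        Phi0_ec=0.005,
        T=310.0,
        eps_r=80.0,
        eps_r_m=3.0,
        eps_r_tj=30.0,
        T_tj=500e-9,
        v_w=18e-6,
        E=400.0,
        nu=0.3,
        D_w_ic=1e-9,
        D_w_ec=1e-7,
        D_w_m=1e-8,
        species=_reference_species(),
        region_boundary=250e-6,
        gj_open=True,
        tj_sealed=False,
    )
    base.update(overrides)
    if not base["gj_open"]:
        base["D_w_ic"] = 0.0
        base["species"] = tuple(
            replace(s, D_ic=0.0) if s.mobile else s for s in base["species"]
        )
    return ParameterSet(**base)


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {
    "m": 1.0, "um": 1e-6, "nm": 1e-9, "mm": 1e-3,
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6,
    "K": 1.0, "-": 1.0, "1": 1.0,
    "m^3/mol": 1.0, "cm^3/mol": 1e-6,
    "m^2/s": 1.0,
    "mol/m^3": 1.0, "mM": 1.0,
    "V": 1.0, "mV": 1e-3, "s": 1.0, "h": 3600.0, "min": 60.0,
}

_SCALARS = {
    "R_c", "T_m", "R_cl", "Phi0_ic", "Phi0_ec", "T", "eps_r", "eps_r_m",
    "eps_r_tj", "T_tj", "v_w", "E", "nu", "D_w_ic", "D_w_ec", "D_w_m",
    "region_boundary", "permittivity_scale",
}
_FLAGS = {"gj_open", "tj_sealed", "include_polarization"}


def _to_si(value) -> float:
    if isinstance(value, dict):
        try:
            num, unit = value["value"], value["unit"]
        except KeyError as exc:
            raise ValueError(f"unit-tagged value needs 'value' and 'unit': {value}") from exc
        try:
            return float(num) * _UNIT_FACTORS[unit]
        except KeyError as exc:
            raise ValueError(f"unknown unit {unit!r}") from exc
    return float(value)


def load_parameters(config) -> ParameterSet:
    """Build a :class:`ParameterSet` from a key-value document.

    ``config`` may be a mapping, a YAML string, or a path to a YAML file.
    ``preset: reference`` pulls in the benchmark values of Table-style
    defaults; any other key overrides the preset field by field.  Scalar
    entries may be plain SI numbers or ``{value: ..., unit: ...}`` pairs.
    Species are overridden by name under a ``species:`` mapping.
    """
    if isinstance(config, str):
        if "\n" not in config and config.endswith((".yml", ".yaml", ".json")):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        else:
            config = yaml.safe_load(config)
    if config is None:
        config = {}
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")

    cfg = dict(config)
    preset = cfg.pop("preset", None)
    if preset is None and not cfg:
        raise ValueError("empty configuration: supply fields or 'preset: reference'")
    if preset not in (None, "reference"):
        raise ValueError(f"unknown preset {preset!r}")

    overrides: dict = {}
    for key, raw in cfg.items():
        if key in _FLAGS:
            overrides[key] = bool(raw)
        elif key in _SCALARS:
            val = _to_si(raw)
            overrides[key] = val
        elif key == "species":
            pass  # handled below
        else:
            raise ValueError(f"unknown configuration key {key!r}")

    if preset == "reference" or preset is None:
        species = list(_reference_species())
    if "species" in cfg:
        by_name = {s.name: s for s in species}
        for name, fields in cfg["species"].items():
            if name not in by_name:
                raise ValueError(f"unknown species name {name!r}")
            upd = {k: (_to_si(v) if k not in ("mobile", "name", "z") else v)
                   for k, v in fields.items()}
            by_name[name] = replace(by_name[name], **upd)
        species = [by_name[s.name] for s in species]
    overrides["species"] = tuple(species)

    if preset == "reference":
        return reference_parameters(**overrides)
    # fully explicit configuration: every mandatory field must be present
    missing = (_SCALARS - {"permittivity_scale"}) - set(overrides)
    if missing:
        raise ValueError(f"missing mandatory fields: {sorted(missing)}")
    for flag in ("gj_open", "tj_sealed"):
        if flag not in overrides:
            raise ValueError(f"missing mandatory flag {flag!r}")
    return ParameterSet(**overrides)


# ---------------------------------------------------------------------------
# Initial-state validation
# ---------------------------------------------------------------------------

def validate_initial_state(ps: ParameterSet, diluteness_threshold: float = 0.02) -> dict:
    """Consistency report for the initial condition.

    The zero initial potentials are only admissible if both spaces start
    electroneutral; the initial transmembrane water flux vanishes only if the
    initial IC and EC osmotic concentrations agree; and the ideal-dilute
    mixing free energy presumes ion/water mole ratios well below one.
    Raises on violated electroneutrality, reports the rest.
    """
    q_ic = sum(s.z * s.C0_ic for s in ps.species)
    q_ec = sum(s.z * s.C0_ec for s in ps.species)
    dc = derive_constants(ps)
    report = {
        "charge_ic": q_ic,
        "charge_ec": q_ec,
        "electroneutral": math.isclose(q_ic, 0.0, abs_tol=1e-9)
        and math.isclose(q_ec, 0.0, abs_tol=1e-9),
        "C0_osm_ic": dc.C0_osm_ic,
        "C0_osm_ec": dc.C0_osm_ec,
        "osmotic_balanced": math.isclose(dc.C0_osm_ic, dc.C0_osm_ec, rel_tol=1e-12,
                                         abs_tol=1e-9),
        "diluteness_ic": dc.C0_osm_ic / dc.Cw0,
        "diluteness_ec": dc.C0_osm_ec / dc.Cw0,
    }
    report["dilute"] = (report["diluteness_ic"] < diluteness_threshold
                        and report["diluteness_ec"] < diluteness_threshold)
    if not report["electroneutral"]:
        raise ValueError(
            f"initial electroneutrality violated: IC charge {q_ic:g}, "
            f"EC charge {q_ec:g} mol/m^3 (zero initial potentials inconsistent)"
        )
    return report
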