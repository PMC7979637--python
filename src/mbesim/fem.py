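"""Galerkin assembly of the coupled cluster equations on the radial mesh.

Thirteen equal-order P1 nodal fields are carried:

=========  =============================================================
``u``      radial displacement of the solid network [m]
``pw``     water pressure (volumetric Lagrange multiplier) [Pa]
``psi``    IC electric potential [V]
``psie``   EC electric potential [V]
``Cwe``    EC water concentration per reference EC volume [mol/m^3]
``C_*``    mobile IC ion concentrations (one field per species)
``Ce_*``   mobile EC ion concentrations
``lz``     out-of-plane stretch (plane-stress condition, weak form)
``Jf``     volume ratio (weak projection of F_rr F_tt lambda_z)
=========  =============================================================

The IC water concentration is *not* an unknown: it is eliminated through the
volumetric constraint in favor of ``pw``, whose residual row is the IC water
balance.  Carrying ``lz`` and ``Jf`` as fields (rather than condensing them
per quadrature point) keeps every Jacobian entry an explicit analytic
derivative and gives a consistent first-order gradient of the IC water
concentration, needed by the convective flux terms.

Weak forms use the axisymmetric measure R dR with 2-point Gauss quadrature;
time derivatives are backward differences between the supplied states.  The
residual is written once over forward-mode jets, so the sparse Jacobian is
exact chain-rule differentiation of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Callable

import numpy as np
import scipy.sparse as sp

from . import constitutive as con
from . import jet
from . import membrane as mem
from .jet import Jet, partial, value
from .mesh import Mesh1D, SHAPE_N
from .parameters import DerivedConstants, ParameterSet, derive_constants

__all__ = ["DofLayout", "AssembledSystem", "initial_state", "assemble",
           "apply_boundary_conditions", "kinematics_at", "diagnostics",
           "nodal_outputs", "field_scales"]


# ---------------------------------------------------------------------------
# Degrees of freedom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DofLayout:
    """Interleaved nodal unknowns: dof = node * n_fields + field index."""

    fields: tuple
    n_nodes: int

    @classmethod
    def for_parameters(cls, ps: ParameterSet, mesh: Mesh1D) -> "DofLayout":
        names = ["u", "pw", "psi", "psie", "Cwe"]
        names += [f"C_{s.name}" for s in ps.mobile]
        names += [f"Ce_{s.name}" for s in ps.mobile]
        names += ["lz", "Jf"]
        return cls(tuple(names), mesh.n_nodes)

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def n_dof(self) -> int:
        return self.n_fields * self.n_nodes

    def fidx(self, name: str) -> int:
        return self.fields.index(name)

    def index(self, node: int, name: str) -> int:
        return node * self.n_fields + self.fidx(name)

    def view(self, x: np.ndarray, name: str) -> np.ndarray:
        """Nodal values of one field (a strided view into the state vector)."""
        return x.reshape(self.n_nodes, self.n_fields)[:, self.fidx(name)]


def field_scales(ps: ParameterSet, layout: DofLayout) -> np.ndarray:
    """Characteristic magnitude of each unknown, for norms and line search."""
    dc = derive_constants(ps)
    C_char = max(dc.C0_osm_ic, dc.C0_osm_ec, 1.0)
    base = {"u": 0.1 * ps.R_cl, "pw": ps.E,
            "psi": ps.R_gas * ps.T / ps.F, "psie": ps.R_gas * ps.T / ps.F,
            "Cwe": dc.Cw0, "lz": 1.0, "Jf": 1.0}
    out = np.empty(layout.n_fields)
    for i, f in enumerate(layout.fields):
        out[i] = base.get(f, C_char)
    return np.tile(out, layout.n_nodes)


def initial_state(mesh: Mesh1D, ps: ParameterSet,
                  layout: DofLayout | None = None) -> np.ndarray:
    """Reference initial condition: undeformed, unpressurized, unpolarized."""
    layout = layout or DofLayout.for_parameters(ps, mesh)
    x = np.zeros(layout.n_dof)
    xm = x.reshape(layout.n_nodes, layout.n_fields)
    xm[:, layout.fidx("Cwe")] = 1.0 / ps.v_w
    for s in ps.mobile:
        xm[:, layout.fidx(f"C_{s.name}")] = s.C0_ic
        xm[:, layout.fidx(f"Ce_{s.name}")] = s.C0_ec
    xm[:, layout.fidx("lz")] = 1.0
    xm[:, layout.fidx("Jf")] = 1.0
    return x


# ---------------------------------------------------------------------------
# Pointwise integrands
# ---------------------------------------------------------------------------

def _interp(x, layout, mesh, want_jets):
    """Field values and reference gradients at the quadrature points.

    Returns dicts q, g keyed by field name with (nel*2,) arrays, seeded as
    jets when a Jacobian is requested.
    """
    nel = mesh.n_elements
    xm = x.reshape(layout.n_nodes, layout.n_fields)
    x1 = xm[:-1, :]  # left node of each element
    x2 = xm[1:, :]
    h = mesh.h[:, None]
    q, g = {}, {}
    for i, f in enumerate(layout.fields):
        qv = (np.outer(x1[:, i], SHAPE_N[0]) + np.outer(x2[:, i], SHAPE_N[1]))
        gv = ((x2[:, i] - x1[:, i])[:, None] / h) * np.ones((1, 2))
        qv, gv = qv.ravel(), gv.ravel()
        if want_jets:
            q[f] = Jet(qv, {f"q_{f}": np.ones_like(qv)})
            g[f] = Jet(gv, {f"g_{f}": np.ones_like(gv)})
        else:
            q[f], g[f] = qv, gv
    return q, g


def _point_state(q, g, Cw, gCw, ps):
    names = [s.name for s in ps.mobile]
    return con.PointState(
        Cw_ic=Cw, Cw_ec=q["Cwe"],
        Ci_ic={n: q[f"C_{n}"] for n in names},
        Ci_ec={n: q[f"Ce_{n}"] for n in names},
        psi_ic=q["psi"], psi_ec=q["psie"], pw=q["pw"],
        grad_Cw_ic=gCw, grad_Cw_ec=g["Cwe"],
        grad_Ci_ic={n: g[f"C_{n}"] for n in names},
        grad_Ci_ec={n: g[f"Ce_{n}"] for n in names},
        grad_psi_ic=g["psi"], grad_psi_ec=g["psie"], grad_pw=g["pw"],
    )


def _integrands(q, g, R, in_core, prev, idt, ps, dc, extra_sources=None):
    """Source (s, tested by N) and flux (f, tested by N') of every row."""
    names = [s.name for s in ps.mobile]
    F_rr = 1.0 + g["u"]
    F_tt = 1.0 + q["u"] / R
    kin = con.Kinematics1D(F_rr, F_tt, q["lz"])
    Jf = q["Jf"]
    Cw = con.water_from_constraint(Jf, q["Cwe"], ps)
    gCw = (g["Jf"] - ps.Phi0_ec * ps.v_w * g["Cwe"]) / (ps.Phi0_ic * ps.v_w)
    D_ic = con.electric_displacement(kin, g["psi"], ps)
    D_ec = con.electric_displacement(kin, g["psie"], ps)

    state = _point_state(q, g, Cw, gCw, ps)
    Jw_ic, Ji_ic = con.ic_fluxes(state, kin, ps)
    Jw_ec, Ji_ec = con.ec_fluxes(state, kin, ps)
    mf = mem.membrane_fluxes(state, ps, in_core=in_core)
    sd = con.nominal_stress(kin, D_ic, D_ec, q["pw"], ps, dc)
    P = sd.P

    AV = dc.area_per_volume
    rho_ic = sum(s.z * s.C0_ic for s in ps.fixed)
    rho_ec = sum(s.z * s.C0_ec for s in ps.fixed)
    for s in ps.mobile:
        rho_ic = rho_ic + s.z * q[f"C_{s.name}"]
        rho_ec = rho_ec + s.z * q[f"Ce_{s.name}"]

    rows = {
        "u": (P[1] / R, P[0]),
        "pw": (ps.Phi0_ic * (Cw - prev["Cw"]) * idt + AV * mf.Jw_m, -Jw_ic),
        "Cwe": (ps.Phi0_ec * (q["Cwe"] - prev["Cwe"]) * idt - AV * mf.Jw_m,
                -Jw_ec),
        "psi": (-ps.Phi0_ic * ps.F * rho_ic, -D_ic),
        "psie": (-ps.Phi0_ec * ps.F * rho_ec, -D_ec),
        "lz": (sd.sigma[2], 0.0),
        "Jf": (Jf - kin.J, 0.0),
    }
    for n in names:
        rows[f"C_{n}"] = (
            ps.Phi0_ic * (q[f"C_{n}"] - prev[f"C_{n}"]) * idt
            + AV * mf.Ji_m[n], -Ji_ic[n])
        rows[f"Ce_{n}"] = (
            ps.Phi0_ec * (q[f"Ce_{n}"] - prev[f"Ce_{n}"]) * idt
            - AV * mf.Ji_m[n], -Ji_ec[n])
    if extra_sources:
        for name, fn in extra_sources.items():
            s0, f0 = rows[name]
            rows[name] = (s0 + fn(R if not isinstance(R, Jet) else value(R)),
                          f0)
    return rows


def _prev_values(x_prev, layout, mesh, ps):
    q, _ = _interp(x_prev, layout, mesh, want_jets=False)
    prev = {"Cwe": q["Cwe"],
            "Cw": value(con.water_from_constraint(q["Jf"], q["Cwe"], ps))}
    for s in ps.mobile:
        prev[f"C_{s.name}"] = q[f"C_{s.name}"]
        prev[f"Ce_{s.name}"] = q[f"Ce_{s.name}"]
    return prev


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class AssembledSystem:
    residual: np.ndarray
    jacobian: sp.csr_matrix | None
    layout: DofLayout
    diagnostics: dict = dfield(default_factory=dict)


def assemble(x, x_prev, dt, mesh: Mesh1D, ps: ParameterSet,
             dc: DerivedConstants | None = None, with_jacobian: bool = True,
             apply_bcs: bool = True, extra_sources=None) -> AssembledSystem:
    """Residual (and analytic Jacobian) of the fully coupled time step.

    ``dt = inf`` drops the mass terms (steady assembly).  Raises ValueError
    on nonphysical states (nonpositive stretches or concentrations), which
    the time stepper treats as step rejection.
    """
    dc = dc or derive_constants(ps)
    layout = DofLayout.for_parameters(ps, mesh)
    idt = 0.0 if np.isinf(dt) else 1.0 / dt
    nel = mesh.n_elements
    q, g = _interp(x, layout, mesh, want_jets=with_jacobian)
    prev = _prev_values(x_prev if x_prev is not None else x, layout, mesh, ps)
    R = mesh.qp_radius.ravel()
    wR = mesh.qp_weight.ravel()
    in_core = mesh.qp_in_core.ravel()
    rows = _integrands(q, g, R, in_core, prev, idt, ps, dc, extra_sources)

    nf = layout.n_fields
    Ginv = 1.0 / mesh.h  # |N'| per element
    Gsign = np.array([-1.0, 1.0])
    r = np.zeros(layout.n_dof)
    coo_i, coo_j, coo_v = [], [], []
    el_nodes = np.arange(nel)
    wR2 = wR.reshape(nel, 2)

    for name, (s_term, f_term) in rows.items():
        fr = layout.fidx(name)
        sv = np.broadcast_to(value(s_term), R.shape).reshape(nel, 2)
        fv = np.broadcast_to(value(f_term), R.shape).reshape(nel, 2)
        if not (np.all(np.isfinite(sv)) and np.all(np.isfinite(fv))):
            bad = np.argwhere(~np.isfinite(sv + fv))
            raise FloatingPointError(
                f"non-finite residual in row {name!r} at element "
                f"{bad[0][0] if len(bad) else '?'}")
        for a in (0, 1):
            Na = SHAPE_N[a]  # (2,) values at the two qps
            Ga = Gsign[a] * Ginv  # (nel,)
            contrib = (wR2 * (Na[None, :] * sv + Ga[:, None] * fv)).sum(axis=1)
            np.add.at(r, (el_nodes + a) * nf + fr, contrib)
        if not with_jacobian:
            continue
        # collect partials of s and f w.r.t. every seeded local input
        deps = {}
        for term, kind in ((s_term, "s"), (f_term, "f")):
            if isinstance(term, Jet):
                for key, darr in term.d.items():
                    deps.setdefault(key, {})[kind] = \
                        np.broadcast_to(darr, R.shape).reshape(nel, 2)
        for key, parts in deps.items():
            mode, fc_name = key.split("_", 1)
            fc = layout.fidx(fc_name)
            ds = parts.get("s")
            df = parts.get("f")
            for a in (0, 1):
                Na = SHAPE_N[a]
                Ga = Gsign[a] * Ginv
                for b in (0, 1):
                    Nb = SHAPE_N[b]
                    Gb = Gsign[b] * Ginv
                    colfac = Nb[None, :] if mode == "q" else Gb[:, None]
                    k = 0.0
                    if ds is not None:
                        k = k + (wR2 * (Na[None, :] * ds * colfac)).sum(axis=1)
                    if df is not None:
                        k = k + (wR2 * ((Ga[:, None]) * df * colfac)).sum(axis=1)
                    coo_i.append((el_nodes + a) * nf + fr)
                    coo_j.append((el_nodes + b) * nf + fc)
                    coo_v.append(k)

    if with_jacobian:
        J = sp.coo_matrix(
            (np.concatenate(coo_v),
             (np.concatenate(coo_i), np.concatenate(coo_j))),
            shape=(layout.n_dof, layout.n_dof)).tocsr()
    else:
        J = None
    system = AssembledSystem(r, J, layout)
    if apply_bcs:
        system = apply_boundary_conditions(system, x, mesh, ps, dc)
    return system


def apply_boundary_conditions(system: AssembledSystem, x, mesh: Mesh1D,
                              ps: ParameterSet,
                              dc: DerivedConstants | None = None
                              ) -> AssembledSystem:
    """Natural capacitor couplings and essential constraints at R=0, R=R_cl.

    Axis: u = 0 (all other rows carry natural zero-flux conditions).  Outer
    boundary: the IC Gauss row always receives the membrane-capacitor
    displacement; with tight junctions absent, the EC potential is grounded
    and the EC water/ion concentrations follow bath chemical equilibrium;
    with tight junctions sealed, the EC Gauss row receives the TJ capacitor
    and all EC transport rows keep their natural zero-flux form.
    """
    dc = dc or derive_constants(ps)
    layout = system.layout
    r = system.residual
    J = system.jacobian
    last = layout.n_nodes - 1
    RT = ps.R_gas * ps.T
    Rcl = mesh.nodes[-1]
    add_i, add_j, add_v = [], [], []

    # membrane capacitor on the IC Gauss row (natural condition, Eq. D.N)
    i_psi = layout.index(last, "psi")
    cap_m = ps.eps0 * ps.eps_r_m / ps.T_m
    r[i_psi] += cap_m * x[i_psi] * Rcl
    add_i.append(i_psi); add_j.append(i_psi); add_v.append(cap_m * Rcl)

    replaced = []

    def constrain(row, res, cols):
        replaced.append(row)
        r[row] = res
        for c, v in cols:
            add_i.append(row); add_j.append(c); add_v.append(v)

    # axis: clamp the displacement
    i_u0 = layout.index(0, "u")
    constrain(i_u0, x[i_u0], [(i_u0, 1.0)])

    if ps.tj_sealed:
        i_pe = layout.index(last, "psie")
        cap_tj = ps.eps0 * ps.eps_r_tj / ps.T_tj
        r[i_pe] += cap_tj * x[i_pe] * Rcl
        add_i.append(i_pe); add_j.append(i_pe); add_v.append(cap_tj * Rcl)
    else:
        # grounded bath
        i_pe = layout.index(last, "psie")
        constrain(i_pe, x[i_pe], [(i_pe, 1.0)])
        # bath chemical equilibrium for EC water (scaled to O(concentration))
        i_cwe = layout.index(last, "Cwe")
        i_pw = layout.index(last, "pw")
        C0e = dc.C0_osm_ec
        cwe, pw = x[i_cwe], x[i_pw]
        fixed_ec = sum(s.C0_ec for s in ps.fixed)
        ce_idx = [layout.index(last, f"Ce_{s.name}") for s in ps.mobile]
        C_osm = fixed_ec + sum(x[i] for i in ce_idx)
        res = (cwe * ps.v_w * (RT * C0e + pw) - RT * C_osm) / (RT * ps.v_w)
        cols = [(i_cwe, (RT * C0e + pw) / RT), (i_pw, cwe / RT)]
        cols += [(i, -1.0 / ps.v_w) for i in ce_idx]
        constrain(i_cwe, res, cols)
        # bath chemical equilibrium per mobile species
        for s, i_ce in zip(ps.mobile, ce_idx):
            res = x[i_ce] - ps.v_w * s.C0_ec * cwe
            constrain(i_ce, res,
                      [(i_ce, 1.0), (i_cwe, -ps.v_w * s.C0_ec)])

    if J is not None:
        mask = np.ones(layout.n_dof)
        mask[replaced] = 0.0
        J = sp.diags(mask) @ J
        J = (J + sp.coo_matrix((add_v, (add_i, add_j)),
                               shape=J.shape)).tocsr()
    system.jacobian = J
    system.residual = r
    return system


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def kinematics_at(x, mesh: Mesh1D, ps: ParameterSet, nodal: bool = True):
    """Nodal (or quadrature-point) kinematics of the current state.

    Nodal radial stretches are recovered by area-weighted averaging of the
    element gradients; the hoop stretch uses 1 + u/R with the axis limit
    1 + du/dR, so axisymmetric states with u ~ alpha R stay regular at R=0.
    """
    layout = DofLayout.for_parameters(ps, mesh)
    u = layout.view(x, "u")
    lz = layout.view(x, "lz")
    du = np.diff(u) / mesh.h
    if nodal:
        F_rr = np.empty_like(u)
        F_rr[0] = 1.0 + du[0]
        F_rr[-1] = 1.0 + du[-1]
        w = mesh.h
        F_rr[1:-1] = 1.0 + (du[:-1] * w[:-1] + du[1:] * w[1:]) \
            / (w[:-1] + w[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            F_tt = np.where(mesh.nodes > 0, 1.0 + u / np.where(
                mesh.nodes > 0, mesh.nodes, 1.0), F_rr)
        return con.Kinematics1D(F_rr, F_tt, lz)
    R = mesh.qp_radius.ravel()
    qv = np.repeat(du, 2)
    uq = (np.outer(u[:-1], SHAPE_N[0]) + np.outer(u[1:], SHAPE_N[1])).ravel()
    return con.Kinematics1D(1.0 + qv, 1.0 + uq / R,
                            np.repeat(0.5 * (lz[:-1] + lz[1:]), 2))


def nodal_outputs(x, mesh: Mesh1D, ps: ParameterSet) -> dict:
    """Primary and derived nodal profiles for reporting."""
    layout = DofLayout.for_parameters(ps, mesh)
    dc = derive_constants(ps)
    out = {"R": mesh.nodes.copy()}
    for f in ("u", "pw", "psi", "psie", "Cwe", "lz", "Jf"):
        out[f] = layout.view(x, f).copy()
    out["psi_m"] = out["psi"] - out["psie"]
    out["Cw"] = value(con.water_from_constraint(out["Jf"], out["Cwe"], ps))
    for s in ps.mobile:
        out[f"C_{s.name}"] = layout.view(x, f"C_{s.name}").copy()
        out[f"Ce_{s.name}"] = layout.view(x, f"Ce_{s.name}").copy()
    C_osm = sum(s.C0_ic for s in ps.fixed) \
        + sum(out[f"C_{s.name}"] for s in ps.mobile)
    Ce_osm = sum(s.C0_ec for s in ps.fixed) \
        + sum(out[f"Ce_{s.name}"] for s in ps.mobile)
    out["C_osm"] = C_osm
    out["Ce_osm"] = Ce_osm
    out["osmotic_ratio_ic"] = C_osm / dc.C0_osm_ic
    out["osmotic_ratio_ec"] = Ce_osm / dc.C0_osm_ec
    out["water_ratio_ic"] = out["Cw"] * ps.v_w
    out["water_ratio_ec"] = out["Cwe"] * ps.v_w
    out["J"] = out["Jf"]
    out["J_a"] = out["Jf"] / out["lz"]
    return out


def diagnostics(x, mesh: Mesh1D, ps: ParameterSet) -> dict:
    """Conserved totals and the dissipation-rate integral of a state."""
    layout = DofLayout.for_parameters(ps, mesh)
    dc = derive_constants(ps)
    q, g = _interp(x, layout, mesh, want_jets=False)
    R = mesh.qp_radius.ravel()
    wR = mesh.qp_weight.ravel()
    in_core = mesh.qp_in_core.ravel()
    F_rr = 1.0 + g["u"]
    F_tt = 1.0 + q["u"] / R
    kin = con.Kinematics1D(F_rr, F_tt, q["lz"])
    Cw = con.water_from_constraint(q["Jf"], q["Cwe"], ps)
    gCw = (g["Jf"] - ps.Phi0_ec * ps.v_w * g["Cwe"]) / (ps.Phi0_ic * ps.v_w)
    state = _point_state(q, g, Cw, gCw, ps)
    Jw_ic, Ji_ic = con.ic_fluxes(state, kin, ps)
    Jw_ec, Ji_ec = con.ec_fluxes(state, kin, ps)
    fx = con.FluxSet(Jw_ic, Jw_ec, Ji_ic, Ji_ec)
    mf = mem.membrane_fluxes(state, ps, in_core=in_core)
    diss = con.dissipation_rate(state, kin, fx, mf, ps, dc)
    totals = {"water": float(np.sum(wR * (ps.Phi0_ic * Cw
                                          + ps.Phi0_ec * q["Cwe"])))}
    for s in ps.mobile:
        totals[s.name] = float(np.sum(wR * (
            ps.Phi0_ic * q[f"C_{s.name}"] + ps.Phi0_ec * q[f"Ce_{s.name}"])))
    return {"totals": totals,
            "dissipation_integral": float(np.sum(wR * diss))}
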