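"""Manufactured-solution machinery for verifying the Galerkin assembler.

Smooth analytic fields (axis-regular, geometrically consistent) are pushed
through the same pointwise integrands the assembler uses, but with *exact*
gradients; the strong-form residual obtained by numerically differentiating
the resulting flux profiles then serves as a source term.  The discrete weak
residual of the interpolated manufactured solution, corrected by that
source, must converge to zero at the element order under mesh refinement.
"""

import numpy as np
import scipy.sparse as sp

from mbesim import fem
from mbesim.fem import _integrands
from mbesim.mesh import build_mesh
from mbesim.parameters import derive_constants


def manufactured_fields(ps):
    Rcl = ps.R_cl

    def fields(R):
        R = np.asarray(R, dtype=float)
        s = R / Rcl
        c = np.cos(np.pi * s)
        out = {
            "u": 0.02 * Rcl * (s + 0.3 * s ** 2),
            "pw": 50.0 * (1 + 0.5 * c),
            "psi": 0.01 * (0.2 + 0.3 * c),
            "psie": 0.005 * (0.1 + 0.2 * c),
            "Cwe": (1 + 0.05 * c) / ps.v_w,
            "lz": 1 + 0.05 * c,
        }
        for sp_ in ps.mobile:
            out[f"C_{sp_.name}"] = sp_.C0_ic * (1 + 0.1 * c)
            out[f"Ce_{sp_.name}"] = sp_.C0_ec * (1 + 0.08 * c)
        du = 0.02 * (1 + 0.6 * s)
        u_over_R = np.where(R > 0, out["u"] / np.where(R > 0, R, 1.0), 0.02)
        out["Jf"] = (1 + du) * (1 + u_over_R) * out["lz"]
        return out

    return fields


def strong_sources(ps, dc=None):
    """Per-row strong-form residual of the manufactured fields, as fn(R)."""
    dc = dc or derive_constants(ps)
    fields = manufactured_fields(ps)
    names = [s.name for s in ps.mobile]
    eps = 1e-5 * ps.R_cl

    def grads(R):
        fp, fm = fields(R + eps), fields(R - eps)
        return {k: (fp[k] - fm[k]) / (2 * eps) for k in fp}

    def rowvals(R):
        q, g = fields(R), grads(R)
        prev = {"Cwe": q["Cwe"], "Cw": 0.0}
        for n in names:
            prev[f"C_{n}"] = q[f"C_{n}"]
            prev[f"Ce_{n}"] = q[f"Ce_{n}"]
        return _integrands(q, g, R, R < ps.region_boundary, prev, 0.0, ps, dc)

    def make(row):
        def fn(R):
            R = np.asarray(R, dtype=float)
            s_val = np.broadcast_to(
                np.asarray(rowvals(R)[row][0], float), R.shape)

            def Rf(RR):
                return RR * np.broadcast_to(
                    np.asarray(rowvals(RR)[row][1], float), RR.shape)

            dRf = (Rf(R + eps) - Rf(R - eps)) / (2 * eps)
            # weak flux term int N' f R dR corresponds to -(1/R)(R f)'
            return s_val - dRf / R

        return fn

    probe = rowvals(np.array([0.37 * ps.R_cl]))
    return {row: make(row) for row in probe}


def mms_error(ps, n_elements, sources=None):
    """Scaled interior residual of the interpolated manufactured solution."""
    dc = derive_constants(ps)
    sources = sources or strong_sources(ps, dc)
    mesh = build_mesh(ps, n_elements, grading_ratio=1.0)
    layout = fem.DofLayout.for_parameters(ps, mesh)
    fields = manufactured_fields(ps)
    x = np.zeros(layout.n_dof)
    f = fields(mesh.nodes)
    for name in layout.fields:
        layout.view(x, name)[:] = f[name]
    neg = {row: (lambda fn: (lambda R: -fn(R)))(fn)
           for row, fn in sources.items()}
    sys_ = fem.assemble(x, x, np.inf, mesh, ps, with_jacobian=True,
                        apply_bcs=False, extra_sources=neg)
    xs = fem.field_scales(ps, layout)
    rown = np.abs(sys_.jacobian @ sp.diags(xs)).max(axis=1).toarray().ravel()
    r = np.abs(sys_.residual) / np.maximum(rown, 1e-300)
    nf = layout.n_fields
    interior = np.ones(layout.n_dof, bool)
    for nd in (0, 1, layout.n_nodes - 2, layout.n_nodes - 1):
        interior[nd * nf:(nd + 1) * nf] = False
    idx = np.arange(layout.n_dof)
    return {fl: float(np.max(r[interior & (idx % nf == k)]))
            for k, fl in enumerate(layout.fields)}
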