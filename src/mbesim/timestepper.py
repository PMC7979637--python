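"""Monolithic implicit time integration of the coupled cluster equations.

Backward-Euler steps are solved by a damped Newton method with an exact
sparse Jacobian, a positivity-preserving line search (concentrations and
stretches must stay in the feasible set — there is no clamping anywhere in
the constitutive laws), adaptive step control, and a relative-rate
steady-state criterion.  The solve path contains no randomness: identical
inputs give bit-identical trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .mesh import Mesh1D, build_mesh
from .parameters import ParameterSet, derive_constants

__all__ = ["SolverSettings", "NewtonResult", "RunHistory", "SolverAbort",
           "newton_solve", "advance", "run_to_steady"]


class SolverAbort(RuntimeError):
    """Raised when the step size collapses; carries the partial trajectory."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history

log = logging.getLogger("mbesim")


@dataclass(frozen=True)
class SolverSettings:
    newton_tol: float = 1e-9  # on the scaled residual inf-norm
    max_newton: int = 20
    dt_init: float = 1e-2  # s
    dt_min: float = 1e-9  # s
    dt_max: float = 3600.0  # s
    growth: float = 1.5
    shrink: float = 0.25
    steady_tol: float = 1e-8  # 1/s, relative field change rate
    dissipation_tol: float = 1e-8  # scaled lower bound on the dissipation
    seed: int = 0  # only used by randomized test-state generators

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("need dt_min <= dt_init <= dt_max, all positive")
        for nm in ("newton_tol", "steady_tol"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass
class NewtonResult:
    x: np.ndarray
    converged: bool
    iterations: int
    residual_norm: float
    history: list


def _positive_dof_mask(layout) -> np.ndarray:
    mask = np.zeros(layout.n_fields, dtype=bool)
    for i, f in enumerate(layout.fields):
        if f.startswith(("C", "Ce_")) or f in ("lz", "Jf", "Cwe"):
            mask[i] = True
    return np.tile(mask, layout.n_nodes)


def newton_solve(assembler: Callable, x0: np.ndarray,
                 settings: SolverSettings, x_scales: np.ndarray,
                 pos_mask: np.ndarray | None = None) -> NewtonResult:
    """Damped Newton with positivity line search and residual backtracking.

    ``assembler(x, with_jacobian)`` returns an :class:`fem.AssembledSystem`
    and may raise ``ValueError``/``FloatingPointError`` for infeasible
    states; a guess that violates positivity is rejected before iterating.
    Residuals are measured in scaled units: each row is normalized by the
    inf-norm of the corresponding row of J.diag(x_scales), so the norm is an
    estimate of the scaled Newton update it still drives.
    """
    x = x0.copy()
    if pos_mask is not None and np.any(x[pos_mask] <= 0):
        raise ValueError("initial guess violates positivity preconditions")
    history = []
    d_r = None
    for it in range(settings.max_newton + 1):
        sys_ = assembler(x, True)
        Jx = sys_.jacobian @ sp.diags(x_scales)
        rown = np.maximum(np.abs(Jx).max(axis=1).toarray().ravel(), 1e-300)
        if d_r is None:
            d_r = 1.0 / rown
        rnorm = float(np.max(np.abs(d_r * sys_.residual)))
        history.append(rnorm)
        if rnorm <= settings.newton_tol:
            return NewtonResult(x, True, it, rnorm, history)
        if it == settings.max_newton:
            break
        Js = sp.diags(d_r) @ Jx
        try:
            dy = spla.spsolve(Js.tocsc(), -(d_r * sys_.residual))
        except RuntimeError:
            return NewtonResult(x, False, it, rnorm, history)
        if not np.all(np.isfinite(dy)):
            return NewtonResult(x, False, it, rnorm, history)
        dx = x_scales * dy
        alpha = 1.0
        if pos_mask is not None:
            shrinking = pos_mask & (dx < 0)
            if np.any(shrinking):
                amax = np.min(-0.9 * x[shrinking] / dx[shrinking])
                alpha = min(alpha, float(amax))
        accepted = False
        for _ in range(8):
            try:
                trial = x + alpha * dx
                rtrial = assembler(trial, False).residual
                tnorm = float(np.max(np.abs(d_r * rtrial)))
            except (ValueError, FloatingPointError):
                alpha *= 0.5
                continue
            if np.isfinite(tnorm) and tnorm <= (1.0 - 1e-4 * alpha) * rnorm:
                x = trial
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            return NewtonResult(x, False, it + 1, rnorm, history)
    return NewtonResult(x, False, settings.max_newton, history[-1], history)


# ---------------------------------------------------------------------------
# Time marching
# ---------------------------------------------------------------------------

@dataclass
class RunHistory:
    """Accepted trajectory of one simulation."""

    times: list
    states: list  # state vector per accepted time
    mesh: Mesh1D
    ps: ParameterSet
    log: list = field(default_factory=list)  # per-step machine-readable dicts
    steady: bool = False

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        return self.states[i]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def advance(x, t, dt, mesh, ps, settings: SolverSettings, dc=None,
            x_scales=None, pos_mask=None):
    """One accepted backward-Euler step with automatic dt reduction.

    Returns (x_new, t_new, dt_taken, dt_next, newton_result).  Newton
    failures halve dt down to ``dt_min``; easy convergence grows the next
    step up to ``dt_max``.
    """
    dc = dc or derive_constants(ps)
    layout = fem.DofLayout.for_parameters(ps, mesh)
    if x_scales is None:
        x_scales = fem.field_scales(ps, layout)
    if pos_mask is None:
        pos_mask = _positive_dof_mask(layout)

    while True:
        def assembler(xt, with_jac, _dt=dt):
            return fem.assemble(xt, x, _dt, mesh, ps, dc,
                                with_jacobian=with_jac)

        try:
            res = newton_solve(assembler, x, settings, x_scales, pos_mask)
        except (ValueError, FloatingPointError):
            res = NewtonResult(x, False, 0, np.inf, [])
        if res.converged:
            grow = settings.growth if res.iterations <= max(
                3, settings.max_newton // 2) else 1.0
            dt_next = min(dt * grow, settings.dt_max)
            return res.x, t + dt, dt, dt_next, res
        if dt <= settings.dt_min * (1 + 1e-12):
            raise RuntimeError(
                f"time step collapsed below dt_min={settings.dt_min:g} s at "
                f"t={t:g} s (residual {res.residual_norm:g})")
        dt = max(dt * settings.shrink, settings.dt_min)
        log.debug("newton failed, retrying with dt=%g", dt)


def run_to_steady(ps: ParameterSet, mesh: Mesh1D | None = None,
                  settings: SolverSettings | None = None,
                  t_max: float = 48 * 3600.0,
                  output_times=(), n_elements: int = 64) -> RunHistory:
    """Integrate from the reference initial state until steadiness.

    Steadiness: the largest scaled nodal rate max |dX/dt|/X_char drops below
    ``settings.steady_tol``.  The step size is clipped so requested output
    times are hit exactly.  If ``t_max`` is reached first the result is
    flagged non-steady.
    """
    settings = settings or SolverSettings()
    mesh = mesh if mesh is not None else build_mesh(ps, n_elements)
    dc = derive_constants(ps)
    layout = fem.DofLayout.for_parameters(ps, mesh)
    x = fem.initial_state(mesh, ps, layout)
    x_scales = fem.field_scales(ps, layout)
    pos_mask = _positive_dof_mask(layout)
    targets = sorted(set(float(t) for t in output_times if 0 < t <= t_max))
    hist = RunHistory([0.0], [x.copy()], mesh, ps)
    t, dt_cand = 0.0, settings.dt_init
    while t < t_max * (1 - 1e-12):
        upcoming = [tt for tt in targets if tt > t * (1 + 1e-12)]
        dt_clip = min(dt_cand, t_max - t, *(tt - t for tt in upcoming[:1]))
        try:
            x_new, t_new, dt_taken, dt_next, res = advance(
                x, t, dt_clip, mesh, ps, settings, dc, x_scales, pos_mask)
        except RuntimeError as exc:
            raise SolverAbort(str(exc), history=hist) from exc
        if dt_taken >= dt_clip * (1 - 1e-12):
            # step was only clipped to hit an output time; keep growing
            dt_cand = min(max(dt_cand, dt_next), settings.dt_max)
        else:
            dt_cand = dt_next
        rate = float(np.max(np.abs(x_new - x) / x_scales)) / dt_taken
        diag = fem.diagnostics(x_new, mesh, ps)
        entry = {"t": t_new, "dt": dt_taken, "newton_iterations":
                 res.iterations, "residual_norm": res.residual_norm,
                 "rate": rate, **diag}
        hist.log.append(entry)
        hist.times.append(t_new)
        hist.states.append(x_new.copy())
        x, t = x_new, t_new
        if rate < settings.steady_tol:
            hist.steady = True
            break
    return hist
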