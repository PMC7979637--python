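"""Named scenarios, sweep driver, and result export.

Three benchmark scenarios mirror the junction configurations of the study:
``noGJ_noTJ`` (closed gap junctions, permeable boundary), ``GJ_noTJ``
(gap junctions open), and ``GJ_TJ`` (gap junctions open, boundary sealed by
tight junctions).  Results carry full provenance: the resolved configuration
stored next to the profiles is sufficient to re-run the scenario
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, fem
from .mesh import build_mesh
from .parameters import ParameterSet, load_parameters, reference_parameters
from .timestepper import RunHistory, SolverAbort, SolverSettings, run_to_steady

__all__ = ["ScenarioSpec", "ScenarioResult", "SCENARIOS", "run_scenario",
           "run_sweep", "export_profiles"]

log = logging.getLogger("mbesim")

#: ParameterSet flag overrides of the named junction configurations
SCENARIOS = {
    "noGJ_noTJ": {"gj_open": False, "tj_sealed": False},
    "GJ_noTJ": {"gj_open": True, "tj_sealed": False},
    "GJ_TJ": {"gj_open": True, "tj_sealed": True},
}

#: default snapshot times [s]: the short-transient figures plus long-run marks
DEFAULT_OUTPUT_TIMES = (30.0, 60.0, 120.0, 300.0, 600.0, 3600.0, 86400.0)


@dataclass
class ScenarioSpec:
    name: str = "GJ_noTJ"
    overrides: dict = field(default_factory=dict)  # ParameterSet overrides
    output_times: tuple = DEFAULT_OUTPUT_TIMES
    t_max: float = 48 * 3600.0
    n_elements: int = 64
    grading_ratio: float = 1.15
    settings: SolverSettings = field(default_factory=SolverSettings)
    sweep_param: str | None = None
    sweep_values: tuple = ()

    def parameter_set(self) -> ParameterSet:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; "
                             f"choose from {sorted(SCENARIOS)}")
        base = dict(SCENARIOS[self.name])
        base.update(self.overrides)
        return reference_parameters(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["settings"] = dataclasses.asdict(self.settings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        if "settings" in d and isinstance(d["settings"], dict):
            d["settings"] = SolverSettings(**d["settings"])
        if "output_times" in d:
            d["output_times"] = tuple(d["output_times"])
        if "sweep_values" in d:
            d["sweep_values"] = tuple(d["sweep_values"])
        return cls(**d)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    times: list
    profiles: list  # dict of nodal arrays per stored time
    diagnostics: list  # per-step log entries
    steady: bool
    status: str  # "ok" | "aborted"
    provenance: dict

    @property
    def final(self) -> dict:
        return self.profiles[-1]

    def profile_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: columns (time, R, field, value)."""
        recs = []
        for t, prof in zip(self.times, self.profiles):
            R = prof["R"]
            for name, arr in prof.items():
                if name == "R":
                    continue
                recs.append(pd.DataFrame(
                    {"time": t, "R": R, "field": name, "value": arr}))
        return pd.concat(recs, ignore_index=True)

    def save(self, outdir) -> pathlib.Path:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profile_frame().to_csv(outdir / "profiles.csv", index=False)
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump({"status": self.status, "steady": self.steady,
                       "steps": self.diagnostics}, fh, indent=1)
        with open(outdir / "resolved_config.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1)
        return outdir


def _snapshot_times(hist: RunHistory, requested) -> list:
    want = [0.0] + [t for t in requested if t <= hist.times[-1] * (1 + 1e-12)]
    if hist.times[-1] not in want:
        want.append(hist.times[-1])
    return sorted(set(want))


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Run one scenario: parameters -> mesh -> time integration -> profiles."""
    ps = spec.parameter_set()
    mesh = build_mesh(ps, spec.n_elements, spec.grading_ratio)
    provenance = {"mbesim_version": __version__, "scenario": spec.to_dict()}
    status, steady = "ok", False
    try:
        hist = run_to_steady(ps, mesh=mesh, settings=spec.settings,
                             t_max=spec.t_max, output_times=spec.output_times)
        steady = hist.steady
    except SolverAbort as exc:
        log.error("scenario %s aborted: %s", spec.name, exc)
        if exc.history is None:
            raise
        hist, status = exc.history, "aborted"
    times = _snapshot_times(hist, spec.output_times)
    profiles = [fem.nodal_outputs(hist.state_at(t), mesh, ps) for t in times]
    return ScenarioResult(spec, times, profiles, hist.log, steady, status,
                          provenance)


def run_sweep(spec: ScenarioSpec):
    """One run per sweep value, plus a summary table of key outputs.

    Per-point failures are recorded and the sweep continues.  The summary
    holds, per value: the displacement at the half radius at t = 600 s, the
    membrane-potential extrema, and the osmotic-ratio extrema.
    """
    if not spec.sweep_param or not spec.sweep_values:
        raise ValueError("sweep requires sweep_param and sweep_values")
    results, rows = {}, []
    for v in spec.sweep_values:
        sub = dataclasses.replace(
            spec, overrides={**spec.overrides, spec.sweep_param: v},
            sweep_param=None, sweep_values=())
        try:
            res = run_scenario(sub)
        except (RuntimeError, ValueError) as exc:
            results[v] = None
            rows.append({"value": v, "status": f"failed: {exc}"})
            continue
        results[v] = res
        it600 = int(np.argmin(np.abs(np.asarray(res.times) - 600.0)))
        prof = res.profiles[it600]
        ps = sub.parameter_set()
        rows.append({
            "value": v, "status": "ok", "t_snapshot": res.times[it600],
            "u_half_radius": float(np.interp(ps.region_boundary,
                                             prof["R"], prof["u"])),
            "u_boundary": float(prof["u"][-1]),
            "psi_m_min": float(prof["psi_m"].min()),
            "psi_m_max": float(prof["psi_m"].max()),
            "pw_max": float(prof["pw"].max()),
            "osmotic_ratio_ic_max": float(prof["osmotic_ratio_ic"].max()),
            "osmotic_ratio_ec_min": float(prof["osmotic_ratio_ec"].min()),
        })
    return results, pd.DataFrame(rows)


def export_profiles(result: ScenarioResult, fmt: str = "csv", outdir="."):
    """Write result profiles as tidy CSV or as per-field plot panels."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        path = outdir / "profiles.csv"
        result.profile_frame().to_csv(path, index=False)
        return [path]
    if fmt == "plot":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        ps = result.spec.parameter_set()
        paths = []
        for name in ("osmotic_ratio_ic", "osmotic_ratio_ec", "psi", "psie",
                     "psi_m", "water_ratio_ic", "water_ratio_ec", "pw", "J",
                     "J_a", "u"):
            fig, ax = plt.subplots(figsize=(4, 3))
            for t, prof in zip(result.times, result.profiles):
                ax.plot(prof["R"] / ps.R_cl, prof[name], label=f"t={t:g}s")
            ax.set_xlabel("R / R_cl")
            ax.set_ylabel(name)
            ax.legend(fontsize=6)
            fig.tight_layout()
            p = outdir / f"{name}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
        return paths
    raise ValueError(f"unknown export format {fmt!r}")
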