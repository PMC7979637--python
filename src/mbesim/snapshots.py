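"""Optional self-describing binary snapshots of simulation states (HDF5)."""

from __future__ import annotations

import json

import numpy as np

from . import __version__
from .mesh import Mesh1D


def save_history(path, history, spec_dict=None) -> None:
    """Write a trajectory (times, states, mesh, config) to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["mbesim_version"] = __version__
        fh.create_dataset("times", data=np.asarray(history.times))
        fh.create_dataset("states", data=np.asarray(history.states))
        fh.create_dataset("mesh_nodes", data=history.mesh.nodes)
        fh.attrs["region_boundary"] = history.mesh.region_boundary
        fh.attrs["steady"] = bool(history.steady)
        if spec_dict is not None:
            fh.attrs["scenario_json"] = json.dumps(spec_dict)


def load_history(path):
    """Read back (times, states, mesh, scenario dict or None)."""
    import h5py

    with h5py.File(path, "r") as fh:
        times = fh["times"][...]
        states = fh["states"][...]
        mesh = Mesh1D(fh["mesh_nodes"][...], float(fh.attrs["region_boundary"]))
        spec = json.loads(fh.attrs["scenario_json"]) \
            if "scenario_json" in fh.attrs else None
    return times, states, mesh, spec
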