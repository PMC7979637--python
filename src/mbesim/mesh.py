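"""Graded 1-D radial reference mesh for the axisymmetric cluster."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet

__all__ = ["Mesh1D", "build_mesh"]

# 2-point Gauss rule on the reference element, local coordinate in [0, 1]
_XI = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
# linear shape functions evaluated at the two quadrature points: N[a, qp]
SHAPE_N = np.array([1.0 - _XI, _XI])


@dataclass
class Mesh1D:
    """Nodes on [0, R_cl] with an element edge at the region interface."""

    nodes: np.ndarray
    region_boundary: float

    def __post_init__(self):
        d = np.diff(self.nodes)
        if np.any(d <= 0):
            raise ValueError("mesh nodes must be strictly increasing")
        if self.nodes[0] != 0.0:
            raise ValueError("mesh must start at the axis R = 0")
        if not np.any(np.isclose(self.nodes, self.region_boundary,
                                 rtol=1e-12, atol=0.0)):
            raise ValueError("mesh must contain a node at the region boundary")

    # -- derived element data ---------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def n_elements(self) -> int:
        return self.nodes.size - 1

    @property
    def h(self) -> np.ndarray:
        return np.diff(self.nodes)

    @property
    def qp_radius(self) -> np.ndarray:
        """Quadrature-point radii, shape (n_elements, 2)."""
        return self.nodes[:-1, None] + np.outer(self.h, _XI)

    @property
    def qp_weight(self) -> np.ndarray:
        """Axisymmetric quadrature weights w * R, shape (n_elements, 2)."""
        return 0.5 * self.h[:, None] * self.qp_radius

    @property
    def qp_in_core(self) -> np.ndarray:
        """Core-region mask per quadrature point (jump on a mesh edge)."""
        return self.qp_radius < self.region_boundary

    def to_csv(self, path) -> None:
        np.savetxt(path, self.nodes, header="node_radius_m", comments="")


def _graded_sizes(n: int, ratio: float) -> np.ndarray:
    """Symmetric two-sided geometric element-size profile (finer at ends)."""
    k = np.arange(n)
    expo = np.minimum(k, n - 1 - k)
    return ratio ** expo.astype(float)


def build_mesh(ps: ParameterSet, n_elements: int = 64,
               grading_ratio: float = 1.15) -> Mesh1D:
    """Graded mesh on [0, R_cl] with a node exactly at the region interface.

    Each of the two subdomains (core and annulus) receives half the
    elements, refined geometrically toward its ends so that the axis
    neighborhood, the channel-overexpression interface, and the cluster
    boundary layer are all resolved.
    """
    if n_elements < 4:
        raise ValueError("need at least 4 elements")
    if grading_ratio < 1.0:
        raise ValueError("grading ratio must be >= 1")
    n_in = n_elements // 2
    n_out = n_elements - n_in
    nodes = [np.array([0.0])]
    for (a, b, m) in ((0.0, ps.region_boundary, n_in),
                      (ps.region_boundary, ps.R_cl, n_out)):
        sizes = _graded_sizes(m, grading_ratio)
        sizes *= (b - a) / sizes.sum()
        pts = a + np.cumsum(sizes)
        pts[-1] = b  # exact endpoints
        nodes.append(pts)
    allnodes = np.concatenate(nodes)
    return Mesh1D(allnodes, ps.region_boundary)
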