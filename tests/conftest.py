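import numpy as np
import pytest

from mbesim import constitutive as con
from mbesim.parameters import derive_constants, reference_parameters


@pytest.fixture(scope="session")
def ps():
    """Benchmark parameters: gap junctions open, boundary permeable."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ps_nogj():
    return reference_parameters(gj_open=False)


@pytest.fixture(scope="session")
def ps_tj():
    return reference_parameters(tj_sealed=True)


@pytest.fixture(scope="session")
def dc(ps):
    return derive_constants(ps)


def random_point_state(ps, rng, with_gradients=True, dilute=True):
    """A physically admissible random state for constitutive-law tests.

    Concentrations stay positive and (optionally) dilute; gradients are
    O(field/R_cl) so flux magnitudes are realistic.
    """
    names = [s.name for s in ps.mobile]
    Cw = (1.0 / ps.v_w) * rng.uniform(0.5, 3.0)
    Cwe = (1.0 / ps.v_w) * rng.uniform(0.5, 3.0)
    cmax = 0.005 * Cw if dilute else 0.2 * Cw
    gscale = (1.0 / ps.R_cl) if with_gradients else 0.0
    Ci = {n: rng.uniform(0.05, 1.0) * cmax for n in names}
    Cie = {n: rng.uniform(0.05, 1.0) * cmax for n in names}
    return con.PointState(
        Cw_ic=Cw, Cw_ec=Cwe, Ci_ic=Ci, Ci_ec=Cie,
        psi_ic=rng.uniform(-0.1, 0.1), psi_ec=rng.uniform(-0.1, 0.1),
        pw=rng.uniform(-200.0, 200.0),
        grad_Cw_ic=gscale * Cw * rng.uniform(-1, 1),
        grad_Cw_ec=gscale * Cwe * rng.uniform(-1, 1),
        grad_Ci_ic={n: gscale * Ci[n] * rng.uniform(-1, 1) for n in names},
        grad_Ci_ec={n: gscale * Cie[n] * rng.uniform(-1, 1) for n in names},
        grad_psi_ic=gscale * 0.05 * rng.uniform(-1, 1),
        grad_psi_ec=gscale * 0.05 * rng.uniform(-1, 1),
        grad_pw=gscale * 100.0 * rng.uniform(-1, 1),
    )


def random_kinematics(rng):
    F_rr = rng.uniform(0.7, 1.6)
    F_tt = rng.uniform(0.7, 1.6)
    F_zz = rng.uniform(0.7, 1.6)
    return con.Kinematics1D(F_rr, F_tt, F_zz)
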