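"""Pointwise constitutive laws: potentials, fluxes, stresses, dissipation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbesim import constitutive as con
from mbesim import jet
from mbesim.jet import Jet, partial, seed, value
from mbesim.membrane import membrane_fluxes
from mbesim.parameters import derive_constants, reference_parameters

from conftest import random_kinematics, random_point_state


# ---------------------------------------------------------------------------
# Volumetric constraint
# ---------------------------------------------------------------------------

class TestWaterFromConstraint:
    def test_undeformed_reference(self, ps):
        assert con.water_from_constraint(1.0, 1 / ps.v_w, ps) \
            == pytest.approx(1 / ps.v_w)

    def test_benchmark_swollen_value(self, ps):
        # J chosen so that the IC space holds 3.5x its reference water
        cw = con.water_from_constraint(2.7375, 1 / ps.v_w, ps)
        assert cw * ps.v_w == pytest.approx(3.5, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(w=st.floats(0.2, 5.0), we=st.floats(0.2, 5.0))
    def test_roundtrip_is_exact_inverse(self, w, we):
        ps = reference_parameters()
        J = con.volume_from_water(w / ps.v_w, we / ps.v_w, ps)
        assert con.water_from_constraint(J, we / ps.v_w, ps) * ps.v_w \
            == pytest.approx(w, rel=1e-12)

    def test_collapse_raises(self, ps):
        with pytest.raises(ValueError):
            con.water_from_constraint(0.2, 1 / ps.v_w, ps)


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

class TestPotentials:
    def test_water_zero_without_solutes_or_pressure(self, ps):
        assert con.chemical_potential_water(0.0, 1 / ps.v_w, 0.0, ps) == 0.0

    def test_water_initial_value(self, ps):
        mu = con.chemical_potential_water(300.0, 1 / ps.v_w, 0.0, ps)
        assert mu == pytest.approx(-ps.R_gas * 310 * 300 * ps.v_w)
        assert mu == pytest.approx(-13.9, abs=0.05)

    def test_water_equal_ratio_symmetry(self, ps):
        a = con.chemical_potential_water(300.0, 1 / ps.v_w, 50.0, ps)
        b = con.chemical_potential_water(600.0, 2 / ps.v_w, 50.0, ps)
        assert a == pytest.approx(b)

    def test_ion_zero_at_unit_ratio(self, ps):
        assert con.electrochemical_potential_ion(5.0, 5.0, 2, 0.0, ps) == 0.0

    def test_ion_nernst_equilibrium(self, ps):
        # equal mu~ across the membrane at the Nernst potential
        RT, F = ps.R_gas * ps.T, ps.F
        ratio_ic, ratio_ec, z = 140 / 5.5e4, 5 / 5.5e4, 1
        psi_m = -(RT / (z * F)) * math.log(ratio_ic / ratio_ec)
        mu_ic = con.electrochemical_potential_ion(140.0, 5.5e4, z, psi_m, ps)
        mu_ec = con.electrochemical_potential_ion(5.0, 5.5e4, z, 0.0, ps)
        assert mu_ic == pytest.approx(mu_ec)

    def test_potassium_nernst_is_minus_89_mV(self, ps):
        RT, F = ps.R_gas * ps.T, ps.F
        psi = RT / F * math.log(5 / 140)
        assert psi * 1e3 == pytest.approx(-89.0, abs=0.1)

    def test_nonpositive_concentration_raises(self, ps):
        with pytest.raises(ValueError):
            con.electrochemical_potential_ion(-1.0, 5.5e4, 1, 0.0, ps)
        with pytest.raises(ValueError):
            con.chemical_potential_water(300.0, 0.0, 0.0, ps)


# ---------------------------------------------------------------------------
# Mobility matrices
# ---------------------------------------------------------------------------

class TestMobilityMatrices:
    def test_zero_diffusivities_give_zero(self, ps):
        psz = ps.with_overrides(
            D_w_ic=0.0, D_w_ec=0.0,
            species=tuple(
                s.__class__(**{**s.__dict__, "D_ic": 0.0, "D_ec": 0.0})
                for s in ps.species))
        rng = np.random.default_rng(1)
        state = random_point_state(psz, rng)
        M_ic, M_ec = con.mobility_matrices(state, random_kinematics(rng), psz)
        assert not M_ic.any() and not M_ec.any()

    def test_leading_entry_and_symmetry(self, ps):
        rng = np.random.default_rng(2)
        state = random_point_state(ps, rng)
        kin = random_kinematics(rng)
        M_ic, M_ec = con.mobility_matrices(state, kin, ps)
        lead = ps.D_w_ec * state.Cw_ec / (ps.R_gas * ps.T) * kin.Cinv_rr
        assert M_ec[0, 0] == pytest.approx(lead)
        np.testing.assert_array_equal(M_ic, M_ic.T)  # Onsager: exact
        np.testing.assert_array_equal(M_ec, M_ec.T)

    def test_positive_definite_on_random_states(self, ps):
        rng = np.random.default_rng(3)
        for _ in range(100):
            state = random_point_state(ps, rng, dilute=False)
            M_ic, M_ec = con.mobility_matrices(
                state, random_kinematics(rng), ps)
            np.linalg.cholesky(M_ic)  # raises if not PD
            np.linalg.cholesky(M_ec)


# ---------------------------------------------------------------------------
# Bulk fluxes
# ---------------------------------------------------------------------------

class TestFluxes:
    def test_zero_gradients_zero_fluxes(self, ps):
        rng = np.random.default_rng(4)
        state = random_point_state(ps, rng, with_gradients=False)
        kin = random_kinematics(rng)
        for fn in (con.ic_fluxes, con.ec_fluxes):
            Jw, Ji = fn(state, kin, ps)
            assert Jw == 0.0
            assert all(v == 0.0 for v in Ji.values())

    def test_immobile_water_reduces_to_nernst_planck(self, ps):
        """With D_w = 0 the convective ion-flux term must vanish."""
        psz = ps.with_overrides(D_w_ic=0.0)
        rng = np.random.default_rng(5)
        state = random_point_state(psz, rng)
        kin = random_kinematics(rng)
        Jw, Ji = con.ic_fluxes(state, kin, psz)
        assert Jw == 0.0
        RT = ps.R_gas * ps.T
        for s in psz.mobile:
            c, gc = state.Ci_ic[s.name], state.grad_Ci_ic[s.name]
            np_flux = -s.D_ic * kin.Cinv_rr * (
                gc - c / state.Cw_ic * state.grad_Cw_ic
                + ps.F / RT * s.z * c * state.grad_psi_ic)
            assert Ji[s.name] == pytest.approx(np_flux, rel=1e-14)

    def test_darcy_limit_without_ions(self, ps):
        """Zero ion content: water flux is proportional to -grad p_w."""
        names = [s.name for s in ps.mobile]
        state = con.PointState(
            Cw_ic=1 / ps.v_w, Cw_ec=1 / ps.v_w,
            Ci_ic={n: 0.0 for n in names}, Ci_ec={n: 0.0 for n in names},
            grad_Ci_ic={n: 0.0 for n in names},
            grad_Ci_ec={n: 0.0 for n in names},
            grad_pw=500.0 / ps.R_cl, grad_psi_ic=1.0, grad_psi_ec=1.0,
            grad_Cw_ic=10.0, grad_Cw_ec=10.0)
        ps0 = ps.with_overrides(species=ps.mobile)  # no fixed anions either
        kin = con.Kinematics1D(1.2, 1.1, 0.9)
        RT = ps.R_gas * ps.T
        for fn, Dw, Cw in ((con.ic_fluxes, ps.D_w_ic, state.Cw_ic),
                           (con.ec_fluxes, ps.D_w_ec, state.Cw_ec)):
            Jw, Ji = fn(state, kin, ps0)
            darcy = -Dw * kin.Cinv_rr * ps.v_w * Cw / RT * state.grad_pw
            assert Jw == pytest.approx(darcy, rel=1e-14)
            assert all(v == 0.0 for v in Ji.values())

    @pytest.mark.parametrize("space", ["ic", "ec"])
    def test_route_equivalence_explicit_vs_onsager(self, ps, space):
        """The primal-variable flux form equals the potential-gradient form.

        Checked on 50 random dilute states including fixed ions, to 1e-10
        relative — the two routes are algebraically identical.
        """
        rng = np.random.default_rng(6)
        for _ in range(50):
            state = random_point_state(ps, rng)
            kin = random_kinematics(rng)
            direct = con.ic_fluxes if space == "ic" else con.ec_fluxes
            Jw_a, Ji_a = direct(state, kin, ps)
            Jw_b, Ji_b = con.fluxes_via_mobility(state, kin, ps, space)
            scale = abs(Jw_a) + 1e-30
            assert abs(Jw_a - Jw_b) / scale < 1e-10
            for n in Ji_a:
                scale = abs(Ji_a[n]) + abs(Jw_a) * 1e-3 + 1e-30
                assert abs(Ji_a[n] - Ji_b[n]) / scale < 1e-10


# ---------------------------------------------------------------------------
# Stress and electric displacement
# ---------------------------------------------------------------------------

class TestStress:
    def test_reference_state_is_stress_free(self, ps, dc):
        kin = con.Kinematics1D(1.0, 1.0, 1.0)
        sd = con.nominal_stress(kin, 0.0, 0.0, 0.0, ps, dc)
        assert all(p == pytest.approx(0.0, abs=1e-12) for p in sd.P)
        assert sd.p_total == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_swelling_with_matching_pressure_is_stress_free(
            self, ps, dc):
        lam_s = 1.4
        J = lam_s ** 3
        pw = (dc.lame_G * (lam_s ** 2 - 1)
              + dc.lame_lambda * math.log(J)) / J
        kin = con.Kinematics1D(lam_s, lam_s, lam_s)
        sd = con.nominal_stress(kin, 0.0, 0.0, pw, ps, dc)
        for k in range(3):
            assert sd.sigma[k] == pytest.approx(0.0, abs=1e-12 * ps.E)

    def test_cauchy_map_identity(self, ps, dc):
        """sigma = J^-1 P F^T on random diagonal states (componentwise)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            kin = random_kinematics(rng)
            D_ic, D_ec = rng.uniform(-1e-6, 1e-6, size=2)
            pw = rng.uniform(-200, 200)
            sd = con.nominal_stress(kin, D_ic, D_ec, pw, ps, dc)
            F = (kin.F_rr, kin.F_tt, kin.F_zz)
            for k in range(3):
                assert sd.sigma[k] == pytest.approx(
                    sd.P[k] * F[k] / kin.J, rel=1e-12, abs=1e-20)

    def test_pressure_split_sums(self, ps, dc):
        rng = np.random.default_rng(8)
        kin = random_kinematics(rng)
        sd = con.nominal_stress(kin, 1e-7, -2e-7, 77.0, ps, dc)
        assert sd.p_total == pytest.approx(
            sd.p_mec + sd.p_w + sd.p_pol + sd.p_pol_e)
        assert sd.p_total == pytest.approx(-sum(sd.sigma) / 3.0)


class TestElectricDisplacement:
    def test_zero_gradient(self, ps):
        kin = con.Kinematics1D(1.3, 1.2, 0.8)
        assert con.electric_displacement(kin, 0.0, ps) == 0.0

    def test_identity_kinematics_linear_dielectric(self, ps):
        kin = con.Kinematics1D(1.0, 1.0, 1.0)
        g = 100.0
        D = con.electric_displacement(kin, g, ps, scaled=False)
        assert D == pytest.approx(-ps.eps0 * ps.eps_r * g)

    def test_deformation_factor(self, ps):
        """J=2 with F_rr=2 halves the J C^-1_rr geometric factor."""
        kin = con.Kinematics1D(2.0, 2.0, 0.5)  # J = 2, J/F_rr^2 = 0.5
        ref = con.electric_displacement(con.Kinematics1D(1, 1, 1), 1.0, ps)
        assert con.electric_displacement(kin, 1.0, ps) \
            == pytest.approx(0.5 * ref)


class TestPlaneStress:
    def test_reference_state(self, ps, dc):
        assert con.plane_stress_condense(1.0, 1.0, 0.0, ps, dc) \
            == pytest.approx(1.0)

    def test_equibiaxial_stretch_contracts_laterally(self, ps, dc):
        fzz = con.plane_stress_condense(1.2, 1.2, 0.0, ps, dc)
        assert fzz < 1.0
        # bisection oracle on the same scalar equation
        from scipy.optimize import bisect
        oracle = bisect(
            lambda z: value(con.sigma_zz_plane(1.2, 1.2, z, 0.0, 0, 0, ps, dc)),
            0.1, 2.0, xtol=1e-12)
        assert fzz == pytest.approx(oracle, abs=1e-10)

    def test_isotropic_steady_state_is_condensed_solution(self, ps, dc):
        lam_s = 1.3989
        J = lam_s ** 3
        pw = (dc.lame_G * (lam_s ** 2 - 1)
              + dc.lame_lambda * math.log(J)) / J
        assert con.plane_stress_condense(lam_s, lam_s, pw, ps, dc) \
            == pytest.approx(lam_s, rel=1e-10)

    def test_residual_below_tolerance(self, ps, dc):
        fzz = con.plane_stress_condense(1.1, 0.9, 30.0, ps, dc)
        r = value(con.sigma_zz_plane(1.1, 0.9, fzz, 30.0, 0, 0, ps, dc))
        assert abs(r) <= 1e-10 * ps.E


# ---------------------------------------------------------------------------
# Dissipation
# ---------------------------------------------------------------------------

class TestDissipation:
    def test_zero_fluxes_zero_dissipation(self, ps, dc):
        rng = np.random.default_rng(9)
        state = random_point_state(ps, rng)
        kin = random_kinematics(rng)
        names = list(state.Ci_ic)
        fx = con.FluxSet(0.0, 0.0, dict.fromkeys(names, 0.0),
                         dict.fromkeys(names, 0.0))
        assert con.dissipation_rate(state, kin, fx, None, ps, dc) == 0.0

    def test_constitutive_fluxes_dissipate_nonnegatively(self, ps, dc):
        """200 random states: the second law holds for the modeled fluxes."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            state = random_point_state(ps, rng, dilute=False)
            kin = random_kinematics(rng)
            Jw_ic, Ji_ic = con.ic_fluxes(state, kin, ps)
            Jw_ec, Ji_ec = con.ec_fluxes(state, kin, ps)
            fx = con.FluxSet(Jw_ic, Jw_ec, Ji_ic, Ji_ec)
            mf = membrane_fluxes(state, ps)
            d = con.dissipation_rate(state, kin, fx, mf, ps, dc)
            assert d >= -1e-20

    def test_flipped_membrane_flux_can_violate_second_law(self, ps, dc):
        rng = np.random.default_rng(11)
        found_negative = False
        for _ in range(50):
            state = random_point_state(ps, rng, with_gradients=False)
            kin = random_kinematics(rng)
            names = list(state.Ci_ic)
            fx = con.FluxSet(0.0, 0.0, dict.fromkeys(names, 0.0),
                             dict.fromkeys(names, 0.0))
            mf = membrane_fluxes(state, ps)
            mf.Jw_m = -mf.Jw_m  # constructed violation
            if con.dissipation_rate(state, kin, fx, mf, ps, dc) < 0:
                found_negative = True
                break
        assert found_negative


# ---------------------------------------------------------------------------
# Analytic derivative contract
# ---------------------------------------------------------------------------

def _fd(fn, x0, h):
    return (fn(x0 + h) - fn(x0 - h)) / (2 * h)


@pytest.mark.parametrize("name", ["water_constraint", "mu_water", "mu_ion",
                                  "sigma_zz", "flux_water"])
def test_jet_partials_match_finite_differences(ps, dc, name):
    """Every constitutive operation exposes exact analytic partials.

    Forward-mode jet derivatives must match central finite differences to
    1e-6 relative on representative states.
    """
    rng = np.random.default_rng(12)
    if name == "water_constraint":
        fn = lambda J: con.water_from_constraint(J, 1.1 / ps.v_w, ps)
        x0, h = 1.4, 1e-6
    elif name == "mu_water":
        fn = lambda Cw: con.chemical_potential_water(310.0, Cw, 40.0, ps)
        x0, h = 1.3 / ps.v_w, 20.0
    elif name == "mu_ion":
        fn = lambda C: con.electrochemical_potential_ion(C, 5.5e4, -1, 0.02, ps)
        x0, h = 12.0, 1e-4
    elif name == "sigma_zz":
        fn = lambda z: con.sigma_zz_plane(1.2, 1.1, z, 25.0, 1e-7, 0, ps, dc)
        x0, h = 0.95, 1e-7
    else:
        state = random_point_state(ps, rng)
        kin = random_kinematics(rng)

        def fn(gpw):
            s2 = con.PointState(**{**state.__dict__, "grad_pw": gpw})
            return con.ic_fluxes(s2, kin, ps)[0]

        x0, h = state.grad_pw, abs(state.grad_pw) * 1e-3 + 1e-6
    j = fn(seed(x0, "x"))
    analytic = partial(j, "x")
    numeric = value(_fd(fn, x0, h))
    assert analytic == pytest.approx(numeric, rel=1e-6)
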