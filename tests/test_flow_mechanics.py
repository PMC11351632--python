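"""Wall mechanics, rheology and the peristalsis-ciliary flow field."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oviductsim.flow_mechanics import (CiliaField, FlowField, MucusProperties,
                                       PeristalsisWave, StrainState,
                                       WallMaterial, cilia_radial_profile,
                                       default_waves, lame_parameters,
                                       strain_energy, wall_displacement)
from oviductsim.tube_geometry import build_tube


class TestLameParameters:
    def test_mu_hand_arithmetic(self):
        mu, _ = lame_parameters(13.0, 95.0, 20.0, 0.49)
        assert mu == pytest.approx(95.0 * 13.0 / (2.0 * 20.0 * 1.49), rel=1e-12)
        assert mu == pytest.approx(20.7215, abs=1e-3)

    def test_lambda_hand_arithmetic(self):
        _, lam = lame_parameters(13.0, 95.0, 20.0, 0.49)
        assert lam == pytest.approx(0.49 * 95.0 * 13.0 / (1.49 * 0.02 * 20.0),
                                    rel=1e-12)
        assert lam == pytest.approx(1015.352, abs=1e-2)

    def test_lambda_vanishes_with_nu(self):
        _, lam = lame_parameters(13.0, 20.0, 20.0, 1e-9)
        assert lam == pytest.approx(0.0, abs=1e-7)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            lame_parameters(13.0, 95.0, 20.0, 0.5)
        with pytest.raises(ValueError):
            lame_parameters(-1.0, 95.0, 20.0, 0.4)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(12.0, 14.0), st.floats(85.0, 105.0), st.floats(5.0, 40.0),
           st.floats(0.01, 0.49))
    def test_both_parameters_positive(self, kappa, L, A, nu):
        mu, lam = lame_parameters(kappa, L, A, nu)
        assert mu > 0 and lam > 0


class TestStrainEnergy:
    def test_zero_at_reference_state(self):
        assert strain_energy(StrainState(I1=3.0, J=1.0), 7.0, 11.0) == 0.0
        assert WallMaterial().strain_energy(StrainState(3.0, 1.0)) == 0.0

    def test_hand_evaluation(self):
        assert strain_energy(StrainState(I1=4.0, J=1.0), 2.0, 5.0) == \
            pytest.approx(1.0)

    def test_increasing_in_first_invariant(self):
        w = [strain_energy(StrainState(I1=i1, J=1.0), 2.0, 5.0)
             for i1 in (3.0, 3.5, 4.0, 5.0)]
        assert all(b > a for a, b in zip(w, w[1:]))

    def test_nonnegative_near_reference(self):
        mat = WallMaterial()
        for i1, j in [(3.0, 1.0), (3.01, 1.0), (3.001, 1.001), (3.002, 0.999)]:
            assert mat.strain_energy(StrainState(i1, j)) >= -1e-9

    def test_invalid_j(self):
        with pytest.raises(ValueError):
            StrainState(I1=3.0, J=0.0)


class TestViscosity:
    @pytest.mark.parametrize("gamma,eta", [(0.0, 0.98), (1.0, 1.00), (50.0, 1.98)])
    def test_printed_affine_law(self, gamma, eta):
        assert MucusProperties().viscosity(gamma) == pytest.approx(eta)

    def test_affine_in_shear(self):
        m = MucusProperties()
        g = np.linspace(0.0, 100.0, 7)
        np.testing.assert_allclose(m.viscosity(g), 0.98 + 0.02 * g, rtol=1e-15)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            MucusProperties().viscosity(-1.0)


class TestWallDisplacement:
    def test_zero_forcing_zero_displacement(self, tube20):
        mat = WallMaterial()
        waves = [PeristalsisWave(amplitude_p=0.0),
                 PeristalsisWave(amplitude_p=0.0, direction="pro_uterus")]
        s = np.linspace(0.0, tube20.total_length_L, 30)
        for t in (0.0, 13.0, 27.5):
            np.testing.assert_allclose(
                wall_displacement(tube20, mat, waves, s, t), 0.0)

    def test_periodic_with_contraction_period(self, tube20):
        mat = WallMaterial()
        waves = default_waves(tube20)
        period = 60.0 / waves[0].frequency
        assert period == pytest.approx(40.0)
        s = np.linspace(0.0, tube20.total_length_L, 17)
        np.testing.assert_allclose(
            wall_displacement(tube20, mat, waves, s, 3.0),
            wall_displacement(tube20, mat, waves, s, 3.0 + period), atol=1e-12)

    def test_amplitude_halves_when_stiffness_doubles(self, tube20):
        soft = WallMaterial(kappa=13.0, A_ref=20.0)
        # doubling mu via halving the reference area (mu = L*kappa/(2A(1+nu)))
        stiff = WallMaterial(kappa=13.0, A_ref=10.0)
        assert stiff.mu_lame == pytest.approx(2.0 * soft.mu_lame)
        wave = PeristalsisWave()
        s = np.linspace(5.0, 90.0, 9)
        d_soft = wall_displacement(tube20, soft, wave, s, 11.0)
        d_stiff = wall_displacement(tube20, stiff, wave, s, 11.0)
        np.testing.assert_allclose(d_stiff, 0.5 * d_soft, rtol=1e-9)

    def test_never_exceeds_90pct_of_resting_radius(self, tube20):
        mat = WallMaterial()
        wave = PeristalsisWave(amplitude_p=20000.0)   # absurd forcing
        s = np.linspace(0.0, tube20.total_length_L, 50)
        d = wall_displacement(tube20, mat, wave, s, 0.0)
        r0 = np.sqrt(tube20.luminal_area(s) / math.pi)
        assert np.all(d <= 0.9 * r0 + 1e-12)


class TestFlowField:
    def test_no_drive_no_flow(self, tube20):
        waves = [PeristalsisWave(amplitude_p=0.0)]
        cilia = CiliaField(density=0.0)
        ff = FlowField(tube20, waves=waves, cilia=cilia)
        s = np.linspace(0.0, tube20.total_length_L, 23)
        for t in (0.0, 17.0):
            np.testing.assert_allclose(ff.velocity(s, np.full_like(s, 0.4), t),
                                       0.0, atol=1e-14)

    def test_cilia_only_flow_is_pro_uterus_at_wall(self, tube20):
        ff = FlowField(tube20, waves=[PeristalsisWave(amplitude_p=0.0)])
        s = np.linspace(1.0, tube20.total_length_L - 1.0, 31)
        u = ff.velocity(s, np.full_like(s, 1.0), 5.0)
        assert np.all(u < 0.0)

    def test_mass_conservation_discrete(self, flow20):
        """dQ/ds + dA/dt = 0 with the matched discrete operators."""
        Q, A = flow20._Q, flow20._A
        ds = flow20.s_grid[1] - flow20.s_grid[0]
        dt = flow20.period / len(flow20.t_grid)
        dQds = np.diff(Q, axis=0) / ds
        dAdt = (np.roll(A, -1, axis=1) - np.roll(A, 1, axis=1)) / (2.0 * dt)
        dAdt_mid = 0.5 * (dAdt[1:] + dAdt[:-1])
        assert np.max(np.abs(dQds + dAdt_mid)) < 1e-9

    def test_flux_continuous_in_s(self, flow20):
        s = np.linspace(1.0, 100.0, 400)
        q = flow20.flux(s, 13.0)
        assert np.max(np.abs(np.diff(q))) < 0.05 * (np.abs(q).max() + 1e-9)

    def test_velocity_periodic_in_time(self, flow20):
        s = np.array([20.0, 50.0, 80.0])
        r = np.array([0.2, 0.5, 0.9])
        np.testing.assert_allclose(flow20.velocity(s, r, 7.0),
                                   flow20.velocity(s, r, 47.0), atol=1e-12)

    def test_r_frac_domain_enforced(self, flow20):
        with pytest.raises(ValueError):
            flow20.velocity(10.0, 1.5, 0.0)

    def test_age_monotone_cilia_slip(self):
        slips = [FlowField(build_tube(a)).cilia.slip_speed()
                 for a in ("20s", "30s", "40s")]
        assert slips[0] > slips[1] > slips[2]

    def test_viscosity_at_wall_shear(self, flow20):
        eta = flow20.viscosity_at(50.0, 10.0)
        gamma = flow20.wall_shear_rate(50.0, 10.0)
        assert eta == pytest.approx(0.98 + 0.02 * gamma)

    def test_poiseuille_profile_shape(self, flow20):
        s, t = 60.0, 9.0
        u_mean = flow20.mean_velocity(s, t)
        u_axis = flow20.velocity(s, 0.0, t)
        assert u_axis == pytest.approx(2.0 * u_mean, rel=1e-9)


def test_cilia_radial_profile_bounds():
    r = np.linspace(0.0, 1.0, 21)
    g = cilia_radial_profile(r)
    assert g[r <= 0.6].max() == 0.0
    assert g[-1] == pytest.approx(1.0)
    assert np.all(np.diff(g) >= 0)


def test_cilia_slip_law_scalings():
    base = CiliaField(density=2000.0).slip_speed()
    assert CiliaField(density=1000.0).slip_speed() == pytest.approx(base / 2)
    assert CiliaField(density=2000.0, beat_frequency=10.8).slip_speed() == \
        pytest.approx(2 * base)
    assert CiliaField(density=2000.0, cilium_length=14.0).slip_speed() == \
        pytest.approx(4 * base)


def test_wave_validation():
    with pytest.raises(ValueError):
        PeristalsisWave(direction="sideways")
    with pytest.raises(ValueError):
        PeristalsisWave(frequency=0.0)
    with pytest.raises(ValueError):
        WallMaterial(kappa=20.0)
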