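"""Forward physics: complex permittivities, Clausius-Mossotti factor,
shell reductions, torque and angular velocity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotospec import (DEFAULT_MEDIUM, DielectricMaterial, DoubleShellCell,
                      EPSILON_0, FieldConfig, Medium, SingleShellCell,
                      angular_velocity, clausius_mossotti,
                      complex_permittivity, double_shell_permittivity,
                      erot_torque, predict_spectrum,
                      single_shell_permittivity)
from conftest import draw_double_shell, draw_single_shell


class TestComplexPermittivity:
    def test_lossless_material_is_purely_real(self):
        eps = complex_permittivity(DielectricMaterial(80.0, 0.0), 12345.0)
        assert eps == pytest.approx(80.0 * EPSILON_0)
        assert eps.imag == 0.0

    def test_hand_evaluated_value_at_1mhz(self):
        eps = complex_permittivity(DielectricMaterial(80.0, 0.01), 1e6)
        assert eps.real == pytest.approx(7.083e-10, rel=1e-3)
        assert eps.imag == pytest.approx(-1.5915e-9, rel=1e-3)

    def test_loss_term_vanishes_at_high_frequency(self):
        m = DielectricMaterial(80.0, 0.01)
        assert abs(complex_permittivity(m, 1e15).imag) < 1e-5 * abs(
            complex_permittivity(m, 1e3).imag)

    @pytest.mark.parametrize("f", [0.0, -1.0, np.nan])
    def test_nonpositive_frequency_rejected(self, f):
        with pytest.raises(ValueError):
            complex_permittivity(DielectricMaterial(80.0, 0.01), f)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            DielectricMaterial(-1.0, 0.0)
        with pytest.raises(ValueError):
            DielectricMaterial(80.0, -0.5)


class TestClausiusMossotti:
    def test_matched_particle_vanishes(self):
        assert clausius_mossotti(80 * EPSILON_0 + 0j, 80 * EPSILON_0 + 0j) == 0

    def test_lossless_double_contrast(self):
        k = clausius_mossotti(160 * EPSILON_0 + 0j, 80 * EPSILON_0 + 0j)
        assert k == pytest.approx(0.25)

    def test_insulating_particle_low_frequency_limit(self):
        f = 0.01
        eps_p = complex_permittivity(DielectricMaterial(80.0, 0.0), f)
        eps_m = complex_permittivity(DielectricMaterial(80.0, 0.01), f)
        assert clausius_mossotti(eps_p, eps_m).real == pytest.approx(-0.5,
                                                                     abs=1e-6)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError, match="Clausius-Mossotti"):
            clausius_mossotti(-2.0 + 0j, 1.0 + 0j)


class TestSingleShell:
    def test_thin_membrane_approaches_cytoplasm(self):
        """With moderate material contrast the shell becomes transparent."""
        cy = DielectricMaterial(60.0, 0.5)
        mb = DielectricMaterial(20.0, 0.1)
        eps_cy = complex_permittivity(cy, 1e5)
        errs = []
        for t_frac in (1e-6, 1e-9, 1e-12):
            cell = SingleShellCell(6e-6, 6e-6 * t_frac, mb, cy)
            errs.append(abs(single_shell_permittivity(cell, 1e5) - eps_cy)
                        / abs(eps_cy))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-9

    def test_membrane_matching_cytoplasm_is_homogeneous(self):
        m = DielectricMaterial(70.0, 0.8)
        for t in (4e-9, 40e-9, 1e-6):
            cell = SingleShellCell(6e-6, t, m, m)
            got = single_shell_permittivity(cell, 2e5)
            want = complex_permittivity(m, 2e5)
            assert abs(got - want) / abs(want) < 1e-12

    def test_against_independent_volume_fraction_form(self, mose_e_cell):
        """Cross-check with the algebraically distinct v1-form expression."""
        f = 1e5
        eps_mb = complex_permittivity(mose_e_cell.membrane, f)
        eps_cp = complex_permittivity(mose_e_cell.cytoplasm, f)
        v1 = 1.0 / mose_e_cell.v0
        e = eps_cp / eps_mb
        oracle = eps_mb * (2 * (1 - v1) + (1 + 2 * v1) * e) / (
            (2 + v1) + (1 - v1) * e)
        got = single_shell_permittivity(mose_e_cell, f)
        assert abs(got - oracle) / abs(oracle) < 1e-12


def _inside_out_oracle(cell: DoubleShellCell, f: float) -> complex:
    """Independent two-step Maxwell mixing applied inside out.

    Each step replaces (core of permittivity e_c, volume fraction v, in a
    shell of permittivity e_s) by the equivalent homogeneous sphere using
    the Clausius-Mossotti form e_s*(1+2vX)/(1-vX), X = (e_c-e_s)/(e_c+2e_s).
    """
    def mix(e_core, e_shell, v):
        x = (e_core - e_shell) / (e_core + 2 * e_shell)
        return e_shell * (1 + 2 * v * x) / (1 - v * x)

    e_np = complex_permittivity(cell.nucleoplasm, f)
    e_nb = complex_permittivity(cell.nuclear_envelope, f)
    e_cp = complex_permittivity(cell.cytoplasm, f)
    e_mb = complex_permittivity(cell.membrane, f)
    nucleus = mix(e_np, e_nb, cell.v3)
    interior = mix(nucleus, e_cp, cell.v2)
    return mix(interior, e_mb, cell.v1)


class TestDoubleShell:
    def test_degenerate_nucleus_reduces_to_single_shell(self, mose_e_cell):
        cy = mose_e_cell.cytoplasm
        rng = np.random.default_rng(7)
        f = np.geomspace(3e3, 10e6, 7)
        for _ in range(20):
            r_n = rng.uniform(0.2, 0.9) * (mose_e_cell.radius
                                           - mose_e_cell.membrane_thickness)
            t_n = rng.uniform(0.05, 0.5) * r_n
            dcell = DoubleShellCell(
                radius=mose_e_cell.radius,
                membrane_thickness=mose_e_cell.membrane_thickness,
                membrane=mose_e_cell.membrane, cytoplasm=cy,
                nucleus_radius=r_n, nuclear_envelope_thickness=t_n,
                nuclear_envelope=cy, nucleoplasm=cy)
            got = double_shell_permittivity(dcell, f)
            want = single_shell_permittivity(mose_e_cell, f)
            assert np.max(np.abs(got - want) / np.abs(want)) < 1e-10

    def test_fully_homogeneous_limit(self):
        m = DielectricMaterial(60.0, 0.7)
        cell = DoubleShellCell(radius=6e-6, membrane_thickness=6e-15,
                               membrane=m, cytoplasm=m, nucleus_radius=3e-6,
                               nuclear_envelope_thickness=40e-9,
                               nuclear_envelope=m, nucleoplasm=m)
        got = double_shell_permittivity(cell, 5e4)
        want = complex_permittivity(m, 5e4)
        assert abs(got - want) / abs(want) < 1e-10

    def test_matches_inside_out_mixing_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            cell = draw_double_shell(rng)
            f = 10 ** rng.uniform(np.log10(3e3), 7)
            got = double_shell_permittivity(cell, f)
            want = _inside_out_oracle(cell, f)
            assert abs(got - want) / abs(want) < 1e-11

    def test_geometry_validation(self):
        m = DielectricMaterial(50.0, 0.1)
        with pytest.raises(ValueError, match="fit inside"):
            DoubleShellCell(radius=6e-6, membrane_thickness=4e-9,
                            membrane=m, cytoplasm=m, nucleus_radius=6e-6,
                            nuclear_envelope_thickness=40e-9,
                            nuclear_envelope=m, nucleoplasm=m)


class TestTorqueAndVelocity:
    def test_real_contrast_gives_zero_torque(self, medium):
        t = erot_torque(70 * EPSILON_0 + 0j,
                        Medium(DielectricMaterial(80.0, 0.0), 0.89e-3),
                        6e-6, 14e3, 1e5)
        assert t == 0.0

    def test_cofield_sign_and_cubic_scaling(self, medium, mose_e_cell):
        f = 1e6  # co-field branch: Im(K) < 0 there for this cell
        eps_p = single_shell_permittivity(mose_e_cell, f)
        t1 = erot_torque(eps_p, medium, 6e-6, 14e3, f)
        t2 = erot_torque(eps_p, medium, 12e-6, 14e3, f)
        assert t1 > 0
        assert t2 == pytest.approx(8 * t1)

    def test_prefactor_velocity_78_rad_s(self):
        """u = 78.0 rad/s for Im(K)=-1 at the reference constants."""
        u = (80 * EPSILON_0) / (2 * 0.89e-3) * 1.0 * 14e3 ** 2
        assert u == pytest.approx(78.0, abs=0.05)

    def test_velocity_consistent_with_torque_balance(self, medium):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cell = draw_single_shell(rng)
            f = 10 ** rng.uniform(np.log10(3e3), 7)
            u = angular_velocity(cell, medium, 14e3, f)
            torque = erot_torque(single_shell_permittivity(cell, f), medium,
                                 cell.radius, 14e3, f)
            u_from_torque = torque / (8 * np.pi * medium.viscosity
                                      * cell.radius ** 3)
            assert u == pytest.approx(u_from_torque, rel=1e-12)

    def test_velocity_vanishes_at_frequency_extremes(self, medium,
                                                     mose_e_cell):
        u_band = np.abs(angular_velocity(mose_e_cell, medium, 14e3,
                                         np.geomspace(3e3, 10e6, 50)))
        for f in (1e-3, 1e14):
            assert abs(angular_velocity(mose_e_cell, medium, 14e3, f)) < \
                1e-4 * u_band.max()

    def test_conductivity_frequency_scaling_invariance(self):
        """In the conductivity-dominated regime, scaling all conductivities
        and the frequency together leaves the velocity unchanged."""
        lam = 7.0
        f = 3e3

        def make(scale):
            cell = SingleShellCell(
                6e-6, 4e-9, DielectricMaterial(30.0, 5e-4 * scale),
                DielectricMaterial(45.0, 1.5 * scale))
            med = Medium(DielectricMaterial(80.0, 0.01 * scale), 0.89e-3)
            return angular_velocity(cell, med, 14e3, f * scale)

        u1, u2 = make(1.0), make(lam)
        assert u2 == pytest.approx(u1, rel=0.01)


class TestPredictSpectrum:
    def test_single_frequency(self, mose_e_cell, medium):
        s = predict_spectrum(mose_e_cell, medium,
                             FieldConfig(frequencies=(1e5,)))
        assert len(s) == 1

    def test_field_squared_scaling(self, mose_e_cell, medium):
        f = tuple(np.geomspace(3e3, 10e6, 10))
        s1 = predict_spectrum(mose_e_cell, medium,
                              FieldConfig(e_rms=14e3, frequencies=f))
        s2 = predict_spectrum(mose_e_cell, medium,
                              FieldConfig(e_rms=28e3, frequencies=f))
        np.testing.assert_allclose(s2.velocities, 4 * s1.velocities,
                                   rtol=1e-12)

    def test_antifield_to_cofield_transition(self, mose_e_cell, medium,
                                             field):
        s = predict_spectrum(mose_e_cell, medium, field)
        assert np.sum(np.diff(np.sign(s.velocities)) != 0) >= 1

    def test_field_config_validation(self):
        with pytest.raises(ValueError):
            FieldConfig(frequencies=(1e5, 1e4))  # not increasing
        with pytest.raises(ValueError):
            FieldConfig(e_rms=-1.0, frequencies=(1e5,))


class TestPropertyBased:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(eps_mb=st.floats(1.0, 30.0), log_sigma_mb=st.floats(-12, -3),
           eps_cp=st.floats(45.0, 125.0), sigma_cp=st.floats(0.01, 2.0),
           t_nm=st.floats(4.0, 40.0), log_f=st.floats(3.48, 7.0))
    def test_torque_balance_holds_everywhere(self, eps_mb, log_sigma_mb,
                                             eps_cp, sigma_cp, t_nm, log_f):
        """u and T_E/(8 pi eta R^3) are the same quantity by construction."""
        cell = SingleShellCell(6e-6, t_nm * 1e-9,
                               DielectricMaterial(eps_mb, 10 ** log_sigma_mb),
                               DielectricMaterial(eps_cp, sigma_cp))
        f = 10 ** log_f
        u = angular_velocity(cell, DEFAULT_MEDIUM, 14e3, f)
        torque = erot_torque(single_shell_permittivity(cell, f),
                             DEFAULT_MEDIUM, cell.radius, 14e3, f)
        balance = torque / (8 * np.pi * DEFAULT_MEDIUM.viscosity
                            * cell.radius ** 3)
        assert u == pytest.approx(balance, rel=1e-10, abs=1e-30)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(eps_mb=st.floats(1.0, 30.0), log_sigma_mb=st.floats(-12, -3),
           eps_cp=st.floats(45.0, 125.0), sigma_cp=st.floats(0.01, 2.0),
           log_f=st.floats(3.48, 7.0))
    def test_cm_factor_bounded(self, eps_mb, log_sigma_mb, eps_cp, sigma_cp,
                               log_f):
        cell = SingleShellCell(6e-6, 7e-9,
                               DielectricMaterial(eps_mb, 10 ** log_sigma_mb),
                               DielectricMaterial(eps_cp, sigma_cp))
        f = 10 ** log_f
        eps_m = complex_permittivity(DEFAULT_MEDIUM.material, f)
        k = clausius_mossotti(single_shell_permittivity(cell, f), eps_m)
        assert -0.5 - 1e-9 <= k.real <= 1.0 + 1e-9
        assert abs(k.imag) <= 0.75 + 1e-9


class TestPassivityBounds:
    def test_cm_factor_stays_in_physical_box(self, medium):
        rng = np.random.default_rng(19)
        for _ in range(2000):
            cell = draw_single_shell(rng)
            f = 10 ** rng.uniform(np.log10(3e3), 7)
            eps_p = single_shell_permittivity(cell, f)
            eps_m = complex_permittivity(medium.material, f)
            k = clausius_mossotti(eps_p, eps_m)
            assert -0.5 - 1e-9 <= k.real <= 1.0 + 1e-9
            assert abs(k.imag) <= 0.75 + 1e-9
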