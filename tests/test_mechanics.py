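"""Stress/strain conversion, moduli recovery, Poisson, dose, scheduling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from situtomo.io_core import LoadingRecord, Volume3D
from situtomo.mechanics import (
    ProtocolSpec,
    absorbed_dose_cylinder,
    aggregate_modulus,
    build_scan_schedule,
    instantaneous_modulus,
    lateral_strain_from_volumes,
    poisson_ratio,
    quasi_equilibrium_modulus,
    relaxation_ratio,
    sls_ramp_stress,
    summarize_mechanics,
    to_stress_strain,
)
from situtomo.synthetic import SLSParams, gen_loading_curve


def make_record(time, force, disp, height=2.0):
    rec = LoadingRecord(np.asarray(time), np.asarray(force), np.asarray(disp),
                        sample_height_mm=height)
    return to_stress_strain(rec)


class TestStressStrain:
    def test_area_arithmetic(self):
        rec = make_record([0, 1], [0.0, 12.566], [0.0, 0.1])
        assert rec.stress_MPa[1] == pytest.approx(1.000, abs=1e-3)
        assert rec.stress_MPa[0] == 0.0

    def test_strain_from_height(self):
        rec = make_record([0, 1], [0, 1], [0.0, 0.3], height=2.0)
        assert rec.strain_frac[1] == pytest.approx(0.15)

    def test_compression_reported_positive(self):
        rec = make_record([0, 1], [0, -5.0], [0.0, -0.2])
        assert rec.stress_MPa[1] > 0 and rec.strain_frac[1] > 0

    def test_missing_height_rejected(self):
        rec = LoadingRecord(np.arange(3.0), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="height"):
            to_stress_strain(rec)


class TestInstantaneousModulus:
    def test_linear_elastic_recovered_exactly(self):
        params = SLSParams(E0_MPa=1.5, Einf_MPa=1.5, tau_s=10.0)  # purely elastic
        rec = gen_loading_curve(ProtocolSpec.continuous_loading(), params, dt_s=1.0)
        to_stress_strain(rec)
        e_i = instantaneous_modulus(rec)
        assert e_i == pytest.approx([1.5], abs=1e-9)

    def test_sls_ramp_matches_analytic_secant(self):
        """Fit window deep in the saturated ramp: least-squares slope equals
        the closed-form secant of the SLS ramp response to 1e-6 MPa."""
        params = SLSParams(E0_MPa=2.0, Einf_MPa=1.0, tau_s=2.0)
        protocol = ProtocolSpec.continuous_loading(15.0, 0.03)
        rec = gen_loading_curve(protocol, params, dt_s=0.5)
        to_stress_strain(rec)
        e_i = instantaneous_modulus(rec, step_window_strain_pct=2.0)[0]
        rate = 3e-4
        t2, t1 = 500.0, 500.0 - 0.02 / rate
        s = sls_ramp_stress(np.array([t1, t2]), rate, 2.0, 1.0, 2.0)
        secant = (s[1] - s[0]) / (rate * (t2 - t1))
        assert abs(e_i - secant) < 1e-6

    def test_too_few_window_samples_rejected(self):
        rec = make_record([0, 1, 2], [0, 1, 2], [0.0, 0.15, 0.3])
        with pytest.raises(ValueError, match="window"):
            instantaneous_modulus(rec, step_window_strain_pct=0.1)


class TestQuasiEquilibrium:
    def test_sls_equilibrium_modulus_recovered(self):
        params = SLSParams(E0_MPa=2.0, Einf_MPa=1.0, tau_s=20.0)
        rec = gen_loading_curve(ProtocolSpec.stress_relaxation(), params, dt_s=0.25)
        to_stress_strain(rec)
        _, e_qeq = quasi_equilibrium_modulus(rec)
        assert e_qeq == pytest.approx(1.000, rel=1e-3)

    def test_slope_arithmetic(self):
        # two holds relaxing to 0.15 and 0.30 MPa at 15% and 30% strain
        t = np.arange(0, 400.0)
        strain = np.clip(t, 0, 15) / 100 + np.clip(t - 200, 0, 15) / 100
        area = np.pi * 4.0
        stress = np.where(t < 200, np.clip(t, 0, 15) / 100, 0.15)
        stress = np.where(t >= 215, 0.30, stress)
        rec = LoadingRecord(t, stress * area, strain * 2.0, sample_height_mm=2.0)
        to_stress_strain(rec)
        eq, e_qeq = quasi_equilibrium_modulus(rec)
        assert e_qeq == pytest.approx(1.0, rel=1e-6)

    def test_continuous_loading_record_rejected(self):
        params = SLSParams(1.5, 1.0, 10.0)
        rec = gen_loading_curve(ProtocolSpec.continuous_loading(), params, dt_s=1.0)
        to_stress_strain(rec)
        with pytest.raises(ValueError, match="relaxation steps"):
            quasi_equilibrium_modulus(rec)


class TestRelaxationRatio:
    def test_arithmetic_and_elastic_limit(self):
        assert relaxation_ratio(2.0, 1.0) == 0.5
        assert relaxation_ratio(1.3, 1.3) == 1.0

    def test_sls_step_ratio_is_einf_over_e0(self):
        protocol = ProtocolSpec.stress_relaxation(ramp_rate_pct_per_s=400.0,
                                                  relaxation_s=(80.0, 80.0))
        params = SLSParams(E0_MPa=2.0, Einf_MPa=1.0, tau_s=8.0)
        rec = gen_loading_curve(protocol, params, dt_s=0.0125)
        to_stress_strain(rec)
        summary = summarize_mechanics(rec)
        assert summary.relax_ratio[0] == pytest.approx(0.5, rel=0.02)


class TestPoisson:
    def test_ratio_arithmetic(self):
        assert poisson_ratio(0.05, 0.15) == pytest.approx(1 / 3, rel=1e-6)
        assert poisson_ratio(0.0, 0.15) == 0.0

    def test_barrel_phantom_widening(self):
        """4% lateral widening at 10% axial compression -> nu = 0.40."""

        def cylinder(radius, n=160, nz=8):
            yy, xx = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2,
                                 indexing="ij")
            r = np.sqrt(yy ** 2 + xx ** 2)
            sl = np.clip(radius + 0.5 - r, 0.0, 1.0)
            return Volume3D(np.broadcast_to(sl, (nz, n, n)).astype(np.float32))

        lat = lateral_strain_from_volumes(cylinder(60.0), cylinder(62.4))
        nu = poisson_ratio(lat, 0.10)
        assert nu == pytest.approx(0.40, abs=0.02)

    def test_non_positive_axial_rejected(self):
        with pytest.raises(ValueError):
            poisson_ratio(0.1, 0.0)


class TestAggregateModulus:
    def test_zero_poisson_reduces_to_young(self):
        assert aggregate_modulus(1.0, 0.0) == 1.0

    def test_direct_evaluation(self):
        assert aggregate_modulus(1.0, 0.3) == pytest.approx(0.7 / (1.3 * 0.4), rel=1e-9)

    def test_divergence_near_incompressible(self):
        assert aggregate_modulus(1.0, 0.4999) > 1e3
        with pytest.raises(ValueError):
            aggregate_modulus(1.0, 0.5)

    @given(st.floats(0.1, 10.0), st.floats(0.0, 0.45), st.floats(0.01, 0.04))
    def test_strictly_increasing_in_poisson(self, E, nu, dnu):
        assert aggregate_modulus(E, nu + dnu) > aggregate_modulus(E, nu)


class TestDose:
    def test_optically_thin_limit(self):
        psi = 3.0
        dose = absorbed_dose_cylinder(psi, radius_mm=1e-3)
        assert dose == pytest.approx(psi * 0.7786 * 0.1, rel=1e-3)  # Psi * mu/rho (m^2/kg)

    def test_opaque_limit(self):
        psi, rho, R = 2.0, 1.06, 2.0
        dose = absorbed_dose_cylinder(psi, mu_over_rho_cm2_per_g=100.0, radius_mm=R)
        expected = 2 * psi / (rho * 1e3 * np.pi * R * 1e-3)
        assert dose == pytest.approx(expected, rel=5e-3)

    def test_linear_in_fluence_and_bounded(self):
        d1 = absorbed_dose_cylinder(1.0)
        d5 = absorbed_dose_cylinder(5.0)
        assert d5 == pytest.approx(5 * d1, rel=1e-9)
        # self-shielding only removes energy: both limits are upper bounds
        thin = 1.0 * 0.7786 * 0.1
        opaque = 2 * 1.0 / (1.06e3 * np.pi * 2e-3)
        assert 0 < d1 < min(thin, opaque)

    def test_monte_carlo_chord_oracle(self):
        rng = np.random.default_rng(0)
        R = 2e-3
        mu = 0.7786 * 1.06 * 1e2
        x = rng.uniform(-R, R, 4_000_000)
        absorbed = 1.0 - np.exp(-mu * 2 * np.sqrt(R * R - x * x))
        mc = absorbed.mean() * 2 * R / (1.06e3 * np.pi * R * R)
        assert absorbed_dose_cylinder(1.0) == pytest.approx(mc, rel=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            absorbed_dose_cylinder(-1.0)


class TestScanSchedule:
    def test_continuous_loading_ends_at_500_s(self):
        sched = build_scan_schedule(ProtocolSpec.continuous_loading(15.0, 0.03))
        assert len(sched) == 7
        assert sched[-1] == pytest.approx(500.0)
        np.testing.assert_allclose(np.diff(sched), 500.0 / 7)

    def test_stress_relaxation_trigger_counts(self):
        prot = ProtocolSpec.stress_relaxation()
        assert len(build_scan_schedule(prot)) == 14
        assert len(build_scan_schedule(prot, include_end_of_relaxation=True)) == 16

    def test_first_peak_trigger_time(self):
        sched = build_scan_schedule(ProtocolSpec.stress_relaxation())
        assert sched[0] == pytest.approx(15.0)  # 15% at 1%/s

    def test_offset_beyond_hold_rejected(self):
        prot = ProtocolSpec.stress_relaxation(relaxation_s=(100.0, 100.0))
        with pytest.raises(ValueError, match="duration"):
            build_scan_schedule(prot)
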