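"""Sonophore mechanics: geometry, pressures, equilibrium gap, limit cycles."""

import math

import numpy as np
import pytest

from sonaxon import (
    BLSConstants,
    cavitation_cycle,
    effective_cycle_averages,
    equilibrium_gap,
    leaflet_geometry,
    membrane_capacitance,
    molecular_pressure,
    pressure_components,
)
from sonaxon.bls import (
    CycleProfile,
    SonophoreState,
    cavitation_cycle_reference,
    elastic_pressure,
    electric_pressure,
    molecular_pressure_flat,
    resting_gas_content,
)

A_SONO = 32e-9


class TestGeometry:
    @pytest.mark.parametrize(
        "Z, a, inv_R, S",
        [
            (0.0, 32e-9, 0.0, math.pi * (32e-9) ** 2),  # flat leaflet
            (32e-9, 32e-9, 1.0 / 32e-9, 2 * math.pi * (32e-9) ** 2),  # hemisphere
            (16e-9, 32e-9, 1.0 / 40e-9, 4021e-18),  # R = (a^2+Z^2)/(2Z) = 40 nm
        ],
    )
    def test_closed_forms(self, Z, a, inv_R, S):
        r, s = leaflet_geometry(Z, a)
        assert r == pytest.approx(inv_R, rel=1e-12, abs=1e-3)
        assert s == pytest.approx(S, rel=1e-3)

    def test_sign_and_area_bound(self):
        Z = np.linspace(-0.6e-9, 20e-9, 50)
        inv_R, S = leaflet_geometry(Z, A_SONO)
        assert np.all(np.sign(inv_R) == np.sign(Z))
        assert np.all(S >= math.pi * A_SONO**2 - 1e-30)


class TestCapacitance:
    def test_flat_limit(self):
        assert membrane_capacitance(0.0, A_SONO, 1.4e-9, 1e-2) == pytest.approx(1e-2)
        # continuity when approaching the flat configuration
        assert membrane_capacitance(1e-15, A_SONO, 1.4e-9, 1e-2) == pytest.approx(1e-2, rel=1e-5)

    @pytest.mark.parametrize(
        "Z, ratio", [(1e-9, 0.621), (-0.5e-9, 1.754)]
    )
    def test_deflected_values(self, Z, ratio):
        assert membrane_capacitance(Z, A_SONO, 1.4e-9, 1.0) == pytest.approx(ratio, rel=1e-3)

    def test_interpenetration_rejected(self):
        with pytest.raises(ValueError):
            membrane_capacitance(-0.71e-9, A_SONO, 1.4e-9, 1e-2)

    def test_strictly_decreasing_in_deflection(self):
        Delta = 1.4e-9
        Z = np.linspace(-Delta / 4, A_SONO / 4, 200)
        Cm = membrane_capacitance(Z, A_SONO, Delta, 1e-2)
        assert np.all(np.diff(Cm) < 0)


class TestPressures:
    def test_electric_pressure_example(self, consts):
        # |Qm| = 140 nC/cm^2 -> Qm^2/(2 eps0) ~ 110.7 kPa attraction
        p = electric_pressure(0.0, -1.4e-3, A_SONO, consts)
        assert p == pytest.approx(-110.7e3, rel=1e-3)

    def test_electric_pressure_never_positive(self, consts):
        Z = np.linspace(-0.5e-9, 10e-9, 30)
        for q in (-2e-3, -5e-4, 0.0, 1e-3):
            assert np.all(electric_pressure(Z, q, A_SONO, consts) <= 0)

    def test_flat_molecular_zero_crossing(self, consts):
        assert molecular_pressure_flat(consts.delta_star, consts) == pytest.approx(0.0, abs=1e-9)

    def test_molecular_matches_flat_at_zero_deflection(self, consts):
        gap = 1.1e-9
        pm = molecular_pressure(0.0, A_SONO, gap, consts)
        assert pm == pytest.approx(float(molecular_pressure_flat(gap, consts)), rel=1e-12)

    def test_breakdown_and_static_balance(self, consts):
        Qm0 = -1.4e-3
        Delta = equilibrium_gap(Qm0, consts)
        ng = resting_gas_content(A_SONO, Delta, consts)
        st = SonophoreState(a=A_SONO, Z=0.0, dZdt=0.0, n_g=ng, Qm=Qm0, Delta=Delta)
        pb = pressure_components(st, consts, P_A=0.0)
        # resting static balance: P_S + P_M + P_G + P_Q - P_0 = 0
        residual = pb.P_S + pb.P_M + pb.P_G + pb.P_Q - consts.P_0
        assert abs(residual) < 1e-6 * consts.P_0
        assert pb.P_VS == 0.0 and pb.P_VL == 0.0

    def test_viscous_terms_oppose_motion(self, consts):
        for U in (1e-3, -1e-3):
            st = SonophoreState(a=A_SONO, Z=0.3e-9, dZdt=U, n_g=1e-22, Qm=0.0, Delta=1.4e-9)
            pb = pressure_components(st, consts)
            assert np.sign(pb.P_VS) == -np.sign(U)
            assert np.sign(pb.P_VL) == -np.sign(U)

    def test_elastic_pressure_restoring(self, consts):
        assert elastic_pressure(1e-9, A_SONO, consts.k_s) < 0
        assert elastic_pressure(-0.4e-9, A_SONO, consts.k_s) > 0


class TestEquilibriumGap:
    def test_uncharged_gap_is_delta_star(self, consts):
        assert equilibrium_gap(0.0, consts) == pytest.approx(consts.delta_star)

    @pytest.mark.parametrize(
        "Qm0_nC_cm2, gap_nm", [(-140.0, 1.1), (-60.0, 1.3)]
    )
    def test_published_gaps(self, consts, Qm0_nC_cm2, gap_nm):
        gap = equilibrium_gap(Qm0_nC_cm2 * 1e-5, consts)
        assert gap * 1e9 == pytest.approx(gap_nm, abs=0.05)

    def test_monotone_decreasing_in_charge_magnitude(self, consts):
        qs = np.linspace(0.0, 2e-3, 15)
        gaps = [equilibrium_gap(-q, consts) for q in qs]
        assert np.all(np.diff(gaps) < 1e-18)
        # sign-independence
        assert equilibrium_gap(1e-3, consts) == equilibrium_gap(-1e-3, consts)


class TestCavitationCycle:
    def test_no_drive_is_flat(self, consts):
        p = cavitation_cycle(A_SONO, 500e3, 0.0, -1.4e-3, consts, Cm0=2e-2)
        assert np.all(p.Z_t == 0.0)
        assert np.all(p.Cm_t == 2e-2)

    def test_limit_cycle_reproducible(self, consts):
        kw = dict(Qm0=-1.4e-3, Cm0=2e-2)
        p1 = cavitation_cycle(A_SONO, 500e3, 80e3, -1.3e-3, consts, **kw)
        p2 = cavitation_cycle(A_SONO, 500e3, 80e3, -1.3e-3, consts, **kw)
        rms = np.sqrt(np.mean((p1.Z_t - p2.Z_t) ** 2)) / np.max(np.abs(p1.Z_t))
        assert rms < 1e-6

    def test_threshold_scale_deflections_stay_small(self, consts):
        # near-threshold drives produce sub-nanometer deflections
        p = cavitation_cycle(A_SONO, 500e3, 91e3, -1.3e-3, consts, Qm0=-1.4e-3, Cm0=2e-2)
        assert np.max(np.abs(p.Z_t)) < 0.5e-9

    def test_matches_stiff_reference_solver(self, consts):
        """Fixed-step kernel vs adaptive LSODA oracle on one condition."""
        kw = dict(Delta=equilibrium_gap(-1.4e-3, consts), Cm0=2e-2)
        pk = cavitation_cycle(A_SONO, 500e3, 100e3, -1.3e-3, consts, **kw)
        pr = cavitation_cycle_reference(A_SONO, 500e3, 100e3, -1.3e-3, consts, **kw)
        cs_k = 1.0 / np.mean(1.0 / pk.Cm_t)
        cs_r = 1.0 / np.mean(1.0 / pr.Cm_t)
        assert cs_k == pytest.approx(cs_r, rel=5e-3)

    def test_quasistatic_oracle_at_low_amplitude(self, consts):
        """At sub-resonance drive and fast gas exchange, the deflection tracks
        the instantaneous pressure balance; check the effective capacitance
        against a solver-free quasi-static phase sweep."""
        from scipy.optimize import brentq
        from sonaxon.bls import gas_pressure

        A, Qm, f = 40e3, -1.3e-3, 500e3
        Delta = equilibrium_gap(-1.4e-3, consts)
        prof = cavitation_cycle(A_SONO, f, A, Qm, consts, Delta=Delta, Cm0=1.0)
        phases = np.linspace(0, 2 * math.pi, 100, endpoint=False)
        Zqs = np.empty_like(phases)
        for i, ph in enumerate(phases):
            PA = -A * math.sin(ph)

            def bal(Z):
                return (
                    PA
                    + elastic_pressure(Z, A_SONO, consts.k_s)
                    + molecular_pressure(Z, A_SONO, Delta, consts)
                    + consts.P_0  # gas pinned at hydrostatic by fast exchange
                    + float(electric_pressure(Z, Qm, A_SONO, consts))
                    - consts.P_0
                )

            Zqs[i] = brentq(bal, -0.49 * Delta, 0.5 * A_SONO)
        cm_qs = membrane_capacitance(Zqs, A_SONO, Delta, 1.0)
        cs_qs = 1.0 / np.mean(1.0 / cm_qs)
        cs_dyn = 1.0 / np.mean(1.0 / prof.Cm_t)
        assert cs_dyn == pytest.approx(cs_qs, rel=0.02)


class _TwoGateMembrane:
    """Minimal membrane stub for averaging tests."""

    Cm0 = 1e-2
    gates = ("x",)

    def rates(self, gate, Vm):
        Vm = np.asarray(Vm, dtype=float)
        return 100.0 + 1e4 * Vm, 200.0 - 1e4 * Vm


class TestEffectiveAverages:
    def test_constant_profile_is_resting(self):
        mem = _TwoGateMembrane()
        t = np.linspace(0, 2e-6, 100, endpoint=False)
        prof = CycleProfile(t=t, Z_t=np.zeros_like(t), Cm_t=np.full_like(t, mem.Cm0), n_cycles_to_converge=1)
        eff = effective_cycle_averages(prof, -6e-4, 1.0, mem)
        assert eff.Vm_star == pytest.approx(-60e-3)
        assert eff.Cm_star == pytest.approx(mem.Cm0)
        al, be = mem.rates("x", -60e-3)
        assert eff.alpha_star["x"] == pytest.approx(float(al))
        assert eff.beta_star["x"] == pytest.approx(float(be))

    def test_square_wave_harmonic_mean(self):
        mem = _TwoGateMembrane()
        t = np.linspace(0, 2e-6, 100, endpoint=False)
        Cm = np.where(np.arange(100) < 50, 1e-2, 2e-2)
        prof = CycleProfile(t=t, Z_t=np.zeros_like(t), Cm_t=Cm, n_cycles_to_converge=1)
        eff = effective_cycle_averages(prof, -6e-4, 1.0, mem)
        assert eff.Cm_star == pytest.approx(4.0 / 3.0 * 1e-2)

    def test_zero_coverage_recovers_resting(self, consts):
        mem = _TwoGateMembrane()
        t = np.linspace(0, 2e-6, 64, endpoint=False)
        rng = np.random.default_rng(0)
        Cm = 1e-2 * (0.5 + rng.uniform(size=64))
        prof = CycleProfile(t=t, Z_t=np.zeros_like(t), Cm_t=Cm, n_cycles_to_converge=1)
        eff = effective_cycle_averages(prof, -6e-4, 0.0, mem)
        assert eff.Vm_star == pytest.approx(-60e-3)
        assert eff.Cm_star == pytest.approx(mem.Cm0)

    def test_harmonic_below_arithmetic_mean(self, consts):
        prof = cavitation_cycle(A_SONO, 500e3, 100e3, -1.3e-3, consts, Qm0=-1.4e-3, Cm0=2e-2)
        mem = _TwoGateMembrane()
        for fs in (0.3, 0.8, 1.0):
            Cm_fs = fs * prof.Cm_t + (1 - fs) * 2e-2
            eff_cm = 1.0 / np.mean(1.0 / Cm_fs)
            assert eff_cm <= np.mean(Cm_fs) + 1e-18
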