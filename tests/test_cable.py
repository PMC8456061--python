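"""Hybrid cable system: assembly, equivalence, integration, bookkeeping."""

import numpy as np
import pytest

from sonaxon import (
    CableTopology,
    FixedSource,
    PassiveMembrane,
    assemble_system,
    extracellular_drive_currents,
    integrate_hybrid,
    integrate_nice_detailed,
    single_compartment,
)
from sonaxon.lookup import ProjectedTables
from sonaxon.protocols import PulseProtocol


def _passive_topo(n=2, Cm0=1e-2, gLeak=1.0, ELeak=-70e-3, Ga=1e-9, Am=1e-10, double=False):
    mem = PassiveMembrane(Cm0=Cm0, gLeak=gLeak, ELeak=ELeak)
    kw = {}
    if double:
        kw = dict(Cx=np.full(n, 1e-3), gx=np.full(n, 5.0), Gp=np.full(n - 1, Ga), phi_e=np.zeros(n))
    return CableTopology(
        membrane=mem,
        Am=np.full(n, Am),
        edges=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
        Ga=np.full(n - 1, Ga),
        **kw,
    )


def _const_tables(mem, Cm_values, n_Q=50):
    """Per-compartment tables with fixed effective capacitances."""
    n = len(Cm_values)
    Q = np.linspace(mem.Cm0 * -0.15, mem.Cm0 * 0.05, n_Q)
    V = np.vstack([Q / c for c in Cm_values])
    tabs = {"V": V, "Cm": np.tile(np.asarray(Cm_values)[:, None], (1, n_Q))}
    return ProjectedTables(Q_grid=Q, tables=tabs, amplitudes=np.zeros(n))


class TestAssembly:
    def test_single_compartment_reduces_to_point_ode(self, fh):
        topo = single_compartment(fh)
        sm = assemble_system(topo)
        G = sm.G_matrix(np.array([fh.Cm0]))
        assert np.all(G[:1, :1] == 0.0)  # no axial terms

    def test_equilibrium_residual_zero(self):
        topo = _passive_topo()
        sm = assemble_system(topo)
        mem = topo.membrane
        y = np.array([mem.Qm0, mem.Qm0, 0.0, 0.0])
        G = sm.G_matrix(np.full(2, mem.Cm0))
        np.testing.assert_allclose(G @ y, 0.0, atol=1e-18)

    def test_axial_antisymmetry(self):
        topo = _passive_topo()
        rng = np.random.default_rng(3)
        Cm = np.array([0.8e-2, 1.3e-2])
        Q = rng.uniform(-1e-3, 1e-3, 2)
        Vm = Q / Cm
        I12 = topo.Ga[0] * (Vm[0] - Vm[1])
        I21 = topo.Ga[0] * (Vm[1] - Vm[0])
        assert I12 == -I21

    def test_axial_block_interior_row_sums(self):
        topo = _passive_topo(n=4)
        M = topo.axial_matrix(topo.Ga)
        np.testing.assert_allclose(M.sum(axis=1), 0.0, atol=1e-24)

    def test_alternative_formulation_equivalence(self):
        """The substituted lower-block form has residual r2' = r1 + r2."""
        rng = np.random.default_rng(11)
        topo = _passive_topo(n=3, double=True)
        topo.phi_e = rng.uniform(-1e-3, 1e-3, 3)
        sm = assemble_system(topo)
        Cm = rng.uniform(0.5e-2, 1.5e-2, 3)
        y = rng.uniform(-1e-3, 1e-3, 6)
        dy = rng.uniform(-1.0, 1.0, 6)
        Is = rng.uniform(-1, 1, 3)
        Iion = rng.uniform(-1, 1, 3)
        r = sm.C_matrix() @ dy + sm.G_matrix(Cm) @ y - sm.I_vector(Is, Iion)
        r_alt = sm.C_matrix_alt() @ dy + sm.G_matrix_alt(Cm) @ y - sm.I_vector_alt(Is, Iion)
        # the substituted extracellular rows equal the sum of the two
        # Kirchhoff balances, eliminating the membrane-current identity terms
        np.testing.assert_allclose(r_alt[3:], r[:3] + r[3:], rtol=1e-9, atol=1e-12)


class TestExtracellularDrive:
    def test_uniform_field_silent(self):
        topo = _passive_topo(n=5)
        np.testing.assert_allclose(extracellular_drive_currents(topo, np.full(5, 3e-3)), 0.0)

    def test_linearity(self):
        topo = _passive_topo(n=5)
        rng = np.random.default_rng(5)
        phi = rng.uniform(-1e-3, 1e-3, 5)
        I1 = extracellular_drive_currents(topo, phi)
        I2 = extracellular_drive_currents(topo, 2 * phi)
        np.testing.assert_allclose(I2, 2 * I1, rtol=1e-12)

    def test_central_node_stencil(self):
        """Point source over the middle of 3 nodes: central drive equals the
        negative of the summed flanking drives (difference-stencil identity)."""
        topo = _passive_topo(n=3)
        phi = np.array([1e-3, 5e-3, 1e-3])
        Is = extracellular_drive_currents(topo, phi)
        assert Is[1] == pytest.approx(-(Is[0] + Is[2]), rel=1e-12)
        assert Is[1] < 0  # cathodic surround of a positive peak


class TestEffectiveIntegration:
    def test_rest_stays_at_rest(self):
        topo = _passive_topo()
        src = FixedSource(*[_const_tables(topo.membrane, [1e-2, 1e-2])] * 2)
        tr = integrate_hybrid(topo, src, None, t_end=10e-3, dt_out=1e-4)
        drift = np.abs(tr.Qm[-1] - tr.Qm[0]).max() * 1e5
        assert drift < 0.1  # nC/cm^2

    def test_two_compartment_steady_state_matches_linear_circuit(self):
        """Constant distinct effective capacitances: the steady state solves
        the 2x2 linear circuit  g(Q_k/C*_k - EL) = Ga/Am (Q_j/C*_j - Q_k/C*_k)."""
        topo = _passive_topo(Ga=2e-9)
        mem = topo.membrane
        Cs = [0.8e-2, 0.95e-2]
        tabs = _const_tables(mem, Cs)
        src = FixedSource(tabs, tabs)
        tr = integrate_hybrid(topo, src, PulseProtocol(PD=1.0, amplitude=1.0), t_end=0.6, dt_out=5e-3, rtol=1e-12, atol_Q=1e-14)
        # closed-form: voltages equalize to ELeak (no external drive), so
        # Q_k = C*_k * V with V solving  g(V - EL) = 0  ->  V = EL exactly
        g = mem.gLeak
        G = topo.Ga[0] / topo.Am[0]
        A = np.array([[g + G, -G], [-G, g + G]])
        b = np.array([g * mem.ELeak, g * mem.ELeak])
        V = np.linalg.solve(A, b)
        Q_expected = np.array(Cs) * V
        np.testing.assert_allclose(tr.Qm[-1], Q_expected, rtol=1e-9)

    def test_global_charge_bookkeeping(self, fh, fh_lookup):
        """Sum_k Am_k dQ_k equals the integral of applied minus ionic currents
        (axial terms cancel)."""
        from sonaxon import LookupSource
        from sonaxon.fibers import build_senn_fiber

        fiber = build_senn_fiber(10e-6, n_nodes=5)
        prof = np.array([1.0, 0.9, 0.8, 0.9, 1.0])
        src = LookupSource(fh_lookup, prof)
        tr = integrate_hybrid(
            fiber.topology, src, PulseProtocol(PD=0.3e-3, amplitude=100e3), t_end=0.6e-3, dt_out=2e-6
        )
        Am = fiber.topology.Am
        dQ = (tr.Qm[-1] - tr.Qm[0]) @ Am
        # recompute ionic currents along the trace
        I = np.empty_like(tr.Qm)
        for i in range(len(tr.t)):
            I[i] = fh.i_total(tr.Vm[i], tr.gates[i])
        integral = -np.trapezoid(I @ Am, tr.t)
        # compare against the gross charge moved (the net change nearly
        # cancels between hyperpolarization and recovery phases)
        gross = np.trapezoid(np.abs(I @ Am), tr.t)
        assert abs(dQ - integral) < 2e-2 * gross

    def test_double_cable_uniform_drive_is_silent(self):
        topo = _passive_topo(n=3, double=True)
        tabs = _const_tables(topo.membrane, [1e-2] * 3)
        src = FixedSource(tabs, tabs)
        tr = integrate_hybrid(topo, src, None, t_end=5e-3, dt_out=1e-4)
        assert np.abs(tr.Qm - tr.Qm[0]).max() * 1e5 < 0.1
        assert np.abs(tr.Vx).max() < 1e-7

    def test_double_cable_relaxes_to_imposed_field(self):
        topo = _passive_topo(n=2, double=True)
        topo.phi_e = np.array([2e-3, 2e-3])
        tabs = _const_tables(topo.membrane, [1e-2, 1e-2])
        src = FixedSource(tabs, tabs)
        tr = integrate_hybrid(topo, src, None, t_end=50e-3, dt_out=1e-3)
        # extracellular nodes settle at the imposed potential
        np.testing.assert_allclose(tr.Vx[-1], topo.phi_e, rtol=1e-3)

    def test_solver_tolerance_robustness(self, fh, fh_lookup):
        """Halving the absolute tolerance moves the spike peak time < 1%."""
        from sonaxon import LookupSource
        from sonaxon.protocols import spike_times

        topo = single_compartment(fh)
        src = LookupSource(fh_lookup, [1.0])
        times = []
        for atol in (1e-8, 5e-9):
            tr = integrate_hybrid(
                topo, src, PulseProtocol(PD=30e-3, amplitude=150e3), t_end=32e-3, dt_out=1e-5, atol_Q=atol
            )
            st = spike_times(tr.t, tr.normalized_charge(0))
            assert len(st) >= 1
            times.append(st[0])
        assert times[0] == pytest.approx(times[1], rel=0.01)


class TestDetailedIntegration:
    def test_no_drive_stays_at_rest(self):
        topo = _passive_topo(Ga=1e-9)
        tr = integrate_nice_detailed(topo, A_amp=[0.0, 0.0], t_end=40e-6, f_US=500e3)
        assert np.abs(tr.Qm - tr.Qm[0]).max() * 1e5 < 0.01

    def test_reference_condition_charge_buildup(self):
        """Asymmetric drive produces a depolarizing charge build-up that
        converges toward a plateau."""
        from sonaxon.benchmarks import PassiveBenchmarkSpec, run_passive_benchmark

        spec = PassiveBenchmarkSpec(tau_m=30e-6, tau_ax=30e-6, A1=100e3, A2=50e3)
        res = run_passive_benchmark(spec)
        dq = res.Q_nice[-1] - res.Q_nice[0]
        assert dq[0] > 0  # depolarization (charge moves up from rest)
        # late-time slope much smaller than early slope (plateau convergence)
        tc, qc = res.t_nice, res.Q_nice[:, 0]
        early = (qc[len(qc) // 8] - qc[0]) / (tc[len(qc) // 8] - tc[0])
        late = abs(qc[-1] - qc[-len(qc) // 8]) / (tc[-1] - tc[-len(qc) // 8])
        assert late < 0.2 * abs(early)

    def test_cycle_average_idempotent(self):
        topo = _passive_topo(Ga=1e-9)
        tr = integrate_nice_detailed(topo, A_amp=[60e3, 30e3], t_end=40e-6, f_US=500e3)
        tc, qc = tr.cycle_averaged()
        assert len(tc) == 20
        # averaging an already cycle-averaged (slowly varying) series changes little
        assert np.abs(np.diff(qc, axis=0)).max() < 0.02 * (np.abs(qc).max())
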