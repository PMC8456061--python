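"""Pulsing schemes, titration, SD analysis, spike metrics, deviations."""

import numpy as np
import pytest

from sonaxon import (
    GammaSpec,
    MuxProtocol,
    PulseProtocol,
    deviation_gamma,
    deviation_passive,
    passive_buildup_estimate,
    population_rate_comparison,
    strength_duration_curve,
    titrate_threshold,
)
from sonaxon.cable import CableTrace
from sonaxon.protocols import (
    SpikeFeatures,
    buildup_time,
    detect_spikes_and_rate,
    measure_spike_features,
    spike_times,
)


def _trace_from(t, qn_per_comp, Cm0=1e-2):
    """Wrap normalized-charge columns (V) into a CableTrace."""
    from sonaxon import PassiveMembrane, CableTopology

    qn = np.atleast_2d(np.asarray(qn_per_comp).T).T
    mem = PassiveMembrane(Cm0=Cm0, ELeak=float(qn[0, 0]))
    n = qn.shape[1]
    topo = CableTopology(
        membrane=mem,
        Am=np.full(n, 1e-10),
        edges=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
        Ga=np.full(max(n - 1, 0), 1e-9),
    )
    return CableTrace(
        t=t,
        Qm=qn * Cm0,
        gates=np.zeros((len(t), n, 0)),
        level=np.zeros(len(t)),
        topology=topo,
    )


class TestProtocols:
    def test_duty_cycle_invariants(self):
        p = PulseProtocol(PD=1e-3, PRF=100.0)
        assert p.duty_cycle == pytest.approx(0.1)
        with pytest.raises(ValueError):
            PulseProtocol(PD=20e-3, PRF=100.0)
        cont = PulseProtocol.from_duty_cycle(1.0, 100.0)
        assert cont.duty_cycle == pytest.approx(1.0)

    def test_single_pulse_segments(self):
        p = PulseProtocol(PD=2e-3, amplitude=5.0)
        segs = p.segments(10e-3)
        assert segs == [(0.0, 2e-3, 5.0), (2e-3, 10e-3, 0.0)]

    def test_train_segments_count(self):
        p = PulseProtocol(PD=1e-3, amplitude=1.0, PRF=100.0, n_pulses=3)
        segs = p.segments(30e-3)
        on = [s for s in segs if s[2] > 0]
        assert len(on) == 3
        assert on[1][0] == pytest.approx(10e-3)

    def test_mux_overlap_takes_maximum(self):
        long = PulseProtocol(PD=10e-3, amplitude=40e3, PRF=50.0, n_pulses=2)
        short = PulseProtocol(PD=1e-3, amplitude=144e3, PRF=200.0, n_pulses=8)
        segs = MuxProtocol(long, short).segments(40e-3)
        # during the first ms both schemes are on: the larger amplitude wins
        assert segs[0][2] == pytest.approx(144e3)
        # between short pulses within the long pulse, the long amplitude holds
        lev_at = lambda t: next(lv for (a, b, lv) in segs if a <= t < b)
        assert lev_at(2e-3) == pytest.approx(40e3)
        assert lev_at(5.5e-3) == pytest.approx(144e3)
        assert lev_at(12e-3) == pytest.approx(0.0)

    def test_envelope_covers_window(self):
        p = PulseProtocol(PD=1e-3, PRF=100.0, n_pulses=5)
        segs = p.segments(60e-3)
        assert segs[0][0] == 0.0 and segs[-1][1] == pytest.approx(60e-3)
        for (a, b, _), (c, _, _) in zip(segs[:-1], segs[1:]):
            assert b == pytest.approx(c)


class TestTitration:
    def test_synthetic_oracle(self):
        thr = titrate_threshold(lambda A: A >= 100.0, (10.0, 1000.0), rtol=0.01)
        assert thr == pytest.approx(100.0, rel=0.01)

    def test_bad_bounds_raise(self):
        from sonaxon.protocols import TitrationError

        with pytest.raises(TitrationError):
            titrate_threshold(lambda A: True, (10.0, 1000.0))
        with pytest.raises(TitrationError):
            titrate_threshold(lambda A: False, (10.0, 1000.0))

    def test_bracket_endpoints_consistent(self):
        calls = []

        def probe(A):
            calls.append(A)
            return A >= 100.0

        thr = titrate_threshold(probe, (10.0, 1000.0), rtol=0.01)
        subs = [a for a in calls if a < 100.0]
        supras = [a for a in calls if a >= 100.0]
        assert max(subs) <= thr <= min(supras)


class TestStrengthDuration:
    def test_weiss_law_chronaxie(self):
        b, c = 7.0, 2e-3  # rheobase and chronaxie of the hyperbolic law

        def threshold_at(pd):
            return b * (1 + c / pd)

        pds = [0.1e-3, 0.5e-3, c, 5e-3, 20e-3, 200e-3]
        sd = strength_duration_curve(threshold_at, pds, bounds=None)
        assert sd.rheobase == pytest.approx(b, rel=0.02)
        assert sd.chronaxie == pytest.approx(c, rel=0.02)
        assert np.all(np.diff(sd.threshold) <= 0)

    def test_non_monotone_warns(self):
        vals = {1e-3: 10.0, 2e-3: 12.0, 4e-3: 5.0, 8e-3: 4.0}
        with pytest.warns(UserWarning, match="non-monotone"):
            strength_duration_curve(lambda pd: vals[pd], list(vals), bounds=None)


class TestSpikesAndRates:
    def test_gaussian_bump_train_rate(self):
        t = np.linspace(0, 0.12, 6000)
        qn = np.full_like(t, -60e-3)
        for k in range(10):
            qn += 0.1 * np.exp(-((t - (5e-3 + k / 100.0)) ** 2) / (2 * (0.5e-3) ** 2))
        tr = _trace_from(t, np.column_stack([qn, qn]))
        an = detect_spikes_and_rate(tr)
        assert an.fr_defined
        assert an.firing_rate == pytest.approx(100.0, rel=1e-3)
        assert an.n_propagated == 10

    def test_subthreshold_trace_silent(self):
        t = np.linspace(0, 0.1, 1000)
        qn = -60e-3 + 2e-3 * np.sin(2 * np.pi * 10 * t)
        an = detect_spikes_and_rate(_trace_from(t, qn))
        assert an.n_propagated == 0 and not an.fr_defined and an.firing_rate == 0.0

    def test_spike_feature_measurement(self):
        t = np.linspace(0, 20e-3, 4000)
        qn = -60e-3 + 0.08 * np.exp(-((t - 10e-3) ** 2) / (2 * (1e-3) ** 2))
        f = measure_spike_features(t, qn)
        assert f.prominence == pytest.approx(0.08, rel=1e-2)
        assert f.half_width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 1e-3, rel=2e-2)


class TestBuildup:
    def test_linear_ramp(self):
        t = np.linspace(0, 10e-3, 1001)
        qn = -70e-3 + 1.0 * t  # 1 mV/ms
        tb, ok = buildup_time(_trace_from(t, qn), 0)
        assert ok and tb == pytest.approx(5e-3, rel=1e-6)

    def test_never_reached_flag(self):
        t = np.linspace(0, 10e-3, 100)
        tb, ok = buildup_time(_trace_from(t, np.full_like(t, -70e-3)), 0)
        assert not ok and tb is None

    def test_passive_estimate(self):
        assert passive_buildup_estimate(1e-2, 1e-2, -70e-3) == 0.0
        # 0.95 vs 1 uF/cm^2 at EL = -70 mV -> +3.5 nC/cm^2
        dq = passive_buildup_estimate(0.95e-2, 1e-2, -70e-3)
        assert dq * 1e5 == pytest.approx(3.5, rel=1e-9)


class TestCurrentDecomposition:
    def test_single_passive_compartment_all_leak(self):
        from sonaxon import PassiveMembrane, single_compartment, integrate_hybrid
        from sonaxon.cable import FixedSource
        from sonaxon.lookup import ProjectedTables
        from sonaxon.protocols import decompose_currents

        mem = PassiveMembrane(Cm0=1e-2, gLeak=1.0, ELeak=-70e-3)
        Q = np.linspace(-1.2e-3, 0.2e-3, 40)
        tabs = ProjectedTables(
            Q_grid=Q,
            tables={"V": (Q / 0.95e-2)[None, :], "Cm": np.full((1, 40), 0.95e-2)},
            amplitudes=np.zeros(1),
        )
        src = FixedSource(tabs, tabs)
        topo = single_compartment(mem)
        tr = integrate_hybrid(topo, src, None, t_end=50e-3, dt_out=2e-4)
        out = decompose_currents(tr, src.tables_on, 0, (0.0, 50e-3))
        assert set(out) == {"leak", "total"}
        assert out["total"] == pytest.approx(out["leak"], rel=1e-12)
        # the decomposition integral reproduces the actual charge change
        assert out["total"] == pytest.approx(tr.Qm[-1, 0] - tr.Qm[0, 0], rel=1e-3)


class TestDeviationMetrics:
    def test_identical_traces_zero(self):
        t = np.linspace(0, 10e-3, 500)
        q = -70e-3 * 1e-2 + 5e-5 * (1 - np.exp(-t / 2e-3))
        eps_inf, eps_tau, ok = deviation_passive(t, q, t, q)
        assert eps_inf == 0.0 and eps_tau == 0.0 and ok

    def test_constant_offset_steady_state(self):
        t = np.linspace(0, 10e-3, 500)
        q = -7e-4 + 5e-5 * (1 - np.exp(-t / 1e-3))
        eps_inf, _, _ = deviation_passive(t, q, t, q + 2e-5)
        assert eps_inf == pytest.approx(2e-5, rel=1e-9)  # 2 nC/cm^2

    def test_small_range_excluded(self):
        t = np.linspace(0, 10e-3, 500)
        q = -7e-4 + 5e-6 * (1 - np.exp(-t / 1e-3))  # 0.5 nC/cm^2 range
        _, eps_tau, ok = deviation_passive(t, q, t, q * 1.01)
        assert not ok and eps_tau == 0.0

    def test_exponential_pair_against_quadrature_oracle(self):
        """tau vs 2 tau exponentials with a shared asymptote: compare against
        a dense independent quadrature of the defining integrals."""
        tau = 1e-3
        t = np.linspace(0, 20e-3, 4000)
        q_ref = 1e-4 * (1 - np.exp(-t / tau))
        q_test = 1e-4 * (1 - np.exp(-t / (2 * tau)))
        _, eps_tau, ok = deviation_passive(t, q_ref, t, q_test)
        assert ok
        # oracle: explicit integrals of |z_test - z_ref| and (1 - z_ref)
        zr = q_ref / q_ref.max()
        zt = (q_test - q_ref.min()) / (q_ref.max() - q_ref.min())
        i_thr = np.argmax(np.abs(zr - zr[-1]) <= 0.001 * np.ones_like(zr))
        num = np.trapezoid(np.abs(zt[: i_thr + 1] - zr[: i_thr + 1]), t[: i_thr + 1])
        den = np.trapezoid(1 - zr[: i_thr + 1], t[: i_thr + 1])
        assert eps_tau == pytest.approx(num / den, rel=1e-6)


class TestGamma:
    SPEC = GammaSpec(dQm_tol=1e-5, dt_tol=1e-3)

    def test_identical_zero(self):
        t = np.linspace(0, 10e-3, 300)
        q = 1e-4 * np.sin(2 * np.pi * 100 * t)
        assert deviation_gamma(t, q, t, q, self.SPEC) == 0.0

    def test_pure_offset_on_constant_trace(self):
        t = np.linspace(0, 10e-3, 300)
        q = np.full_like(t, -7e-4)
        dq = 2e-5
        eps = deviation_gamma(t, q, t, q + dq, self.SPEC)
        assert eps == pytest.approx(dq / self.SPEC.dQm_tol, rel=1e-9)

    def test_time_shift_of_step(self):
        """A small time shift of a sharp step costs ~ shift/dt_tol."""
        t = np.linspace(0, 10e-3, 2001)
        delta = 0.2e-3
        q_ref = np.where(t > 5e-3, 1e-4, 0.0)
        q_test = np.where(t > 5e-3 + delta, 1e-4, 0.0)
        eps = deviation_gamma(t, q_ref, t, q_test, self.SPEC, max_points=4000)
        assert eps == pytest.approx(delta / self.SPEC.dt_tol, rel=0.05)

    def test_matches_brute_force_minimization(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5e-3, 400)
        q_ref = 1e-4 * np.cumsum(rng.normal(size=len(t))) / 50
        q_test = q_ref + 1e-5 * np.sin(2 * np.pi * 300 * t)
        eps = deviation_gamma(t, q_ref, t, q_test, self.SPEC, max_points=1000)
        brute = 0.0
        for i in range(len(t)):
            g = np.sqrt(((t[i] - t) / self.SPEC.dt_tol) ** 2 + ((q_test - q_ref[i]) / self.SPEC.dQm_tol) ** 2)
            brute = max(brute, float(g.min()))
        assert eps == pytest.approx(brute, rel=1e-6)

    def test_tolerance_scaling_premetric(self):
        t = np.linspace(0, 5e-3, 300)
        q_ref = 1e-4 * (1 - np.exp(-t / 1e-3))
        q_test = q_ref * 0.9
        e1 = deviation_gamma(t, q_ref, t, q_test, GammaSpec(1e-5, 1e-3))
        e2 = deviation_gamma(t, q_ref, t, q_test, GammaSpec(2e-5, 2e-3))
        assert e2 == pytest.approx(e1 / 2, rel=1e-9)

    def test_from_spike_features(self):
        spec = GammaSpec.from_spike_features(SpikeFeatures(prominence=0.1, half_width=1e-3), Cm0=1e-2)
        assert spec.dQm_tol == pytest.approx(0.3 * 0.1 * 1e-2)
        assert spec.dt_tol == pytest.approx(0.3e-3)


class TestPopulationComparison:
    def test_identical_groups_not_significant(self):
        H, p = population_rate_comparison([50.0, 50.1, 49.9, 50.0], [50.0, 50.1, 49.9, 50.0])
        assert p > 0.9

    def test_disjoint_groups_highly_significant(self):
        rng = np.random.default_rng(1)
        g1 = 200.02 + 0.01 * rng.normal(size=56)
        g2 = 49.75 + 0.26 * rng.normal(size=221)
        H, p = population_rate_comparison(g1, g2)
        assert p < 1e-3

    def test_within_group_order_invariance(self):
        rng = np.random.default_rng(2)
        g1 = rng.uniform(10, 20, 10)
        g2 = rng.uniform(15, 25, 12)
        H1, _ = population_rate_comparison(g1, g2)
        H2, _ = population_rate_comparison(rng.permutation(g1), g2[::-1])
        assert H1 == pytest.approx(H2, rel=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            population_rate_comparison([1.0, 2.0], [1.0, 2.0, 3.0])
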