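"""Two-compartment accuracy benchmarks: detailed vs cycle-averaged paradigms.

A pair of acoustically driven compartments — passive membranes with
prescribed membrane and axial time constants, or one-node axon-specific
membranes — is integrated both with the temporally detailed model
(mechanics fully resolved at 0.001 acoustic periods) and with the
cycle-averaged effective paradigm.  Deviation metrics quantify where the
effective approximation holds: steady-state charge deviation, normalized
transient deviation, and the spike-tolerance gamma distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bls import BLSConstants
from .cable import (
    CableTopology,
    LookupSource,
    integrate_hybrid,
    integrate_nice_detailed,
)
from .fibers import build_node_model
from .lookup import build_lookup
from .membranes import PassiveMembrane, get_membrane
from .protocols import (
    GammaSpec,
    deviation_gamma,
    deviation_passive,
)


@dataclass
class PassiveBenchmarkSpec:
    """Two passive compartments parameterized by their time constants.

    The membrane conductance and axial coupling are reverse-engineered
    from the requested time constants (tau_m = Cm0/gLeak,
    tau_ax = Cm0 Am / Ga), so measured-back constants equal the request
    exactly.
    """

    tau_m: float  # s
    tau_ax: float  # s
    Cm0: float = 1e-2  # F/m^2
    ELeak: float = -70e-3  # V
    f_US: float = 500e3
    A1: float = 100e3  # Pa
    A2: float = 50e3  # Pa
    dphi: float = 0.0  # inter-compartment drive phase shift (rad)
    a: float = 32e-9
    fs: float = 0.8
    Am: float = 1e-10  # m^2 (arbitrary; cancels in the dynamics)

    @property
    def gLeak(self):
        return self.Cm0 / self.tau_m

    @property
    def Ga(self):
        return self.Cm0 * self.Am / self.tau_ax

    @property
    def duration(self):
        """Five times the longest time constant, at least 10 acoustic periods."""
        return max(5.0 * max(self.tau_m, self.tau_ax), 10.0 / self.f_US)


def build_passive_benchmark(spec: PassiveBenchmarkSpec) -> CableTopology:
    """Two-compartment passive topology realizing the requested time constants."""
    if spec.tau_m <= 0 or spec.tau_ax <= 0:
        raise ValueError("time constants must be positive")
    mem = PassiveMembrane(Cm0=spec.Cm0, gLeak=spec.gLeak, ELeak=spec.ELeak)
    return CableTopology(
        membrane=mem,
        Am=np.array([spec.Am, spec.Am]),
        edges=np.array([[0, 1]]),
        Ga=np.array([spec.Ga]),
    )


def measured_time_constants(topology: CableTopology):
    """(tau_m, tau_ax) read back from an assembled passive topology."""
    mem = topology.membrane
    return mem.Cm0 / mem.gLeak, mem.Cm0 * topology.Am[0] / topology.Ga[0]


@dataclass
class BenchmarkResult:
    eps_inf: float  # C/m^2
    eps_tau: float  # fraction
    tau_defined: bool
    t_nice: np.ndarray = field(repr=False, default=None)
    Q_nice: np.ndarray = field(repr=False, default=None)
    t_sonic: np.ndarray = field(repr=False, default=None)
    Q_sonic: np.ndarray = field(repr=False, default=None)


class _ConstantProtocol:
    """Continuous stimulation at a fixed envelope level."""

    def __init__(self, level=1.0):
        self.level = level

    def segments(self, t_end):
        return [(0.0, t_end, self.level)]


def run_passive_benchmark(spec: PassiveBenchmarkSpec, consts: BLSConstants = None, n_Q: int = 25) -> BenchmarkResult:
    """Detailed vs effective integration of one passive benchmark cell."""
    consts = consts or BLSConstants()
    topo = build_passive_benchmark(spec)
    mem = topo.membrane
    t_end = spec.duration
    nice = integrate_nice_detailed(
        topo,
        A_amp=[spec.A1, spec.A2],
        t_end=t_end,
        f_US=spec.f_US,
        a=spec.a,
        fs=spec.fs,
        phase=[0.0, spec.dphi],
        consts=consts,
    )
    tc, qc = nice.cycle_averaged()
    # effective run with exact-amplitude lookup columns
    Qg = np.linspace(mem.Cm0 * -0.12, mem.Cm0 * 0.0, n_Q)
    amps = sorted({0.0, spec.A1, spec.A2})
    lkp = build_lookup(mem, a=spec.a, f_US=spec.f_US, A_grid=np.asarray(amps), Q_grid=Qg, fs=spec.fs, consts=consts)
    src = LookupSource(lkp, np.array([spec.A1, spec.A2]))
    dt_out = max(t_end / 2000.0, 1.0 / spec.f_US)
    sonic = integrate_hybrid(topo, src, _ConstantProtocol(), t_end=t_end, dt_out=dt_out)
    eps_inf, eps_tau, ok = deviation_passive(tc, qc, sonic.t, sonic.Qm)
    return BenchmarkResult(eps_inf, eps_tau, ok, tc, qc, sonic.t, sonic.Qm)


def sweep_deviation_map(tau_m_grid, tau_ax_grid, stimulus: dict = None, consts: BLSConstants = None):
    """Deviation metrics over a (tau_m, tau_ax) grid at a fixed stimulus.

    Returns dict with 2D arrays ``eps_inf`` (C/m^2), ``eps_tau``
    (fraction; NaN where excluded) indexed [i_tau_m, i_tau_ax]; per-cell
    failures are recorded as NaN and the sweep continues.
    """
    stimulus = stimulus or {}
    nm, na = len(tau_m_grid), len(tau_ax_grid)
    eps_inf = np.full((nm, na), np.nan)
    eps_tau = np.full((nm, na), np.nan)
    failures = []
    for i, tm in enumerate(tau_m_grid):
        for j, ta in enumerate(tau_ax_grid):
            spec = PassiveBenchmarkSpec(tau_m=tm, tau_ax=ta, **stimulus)
            try:
                res = run_passive_benchmark(spec, consts=consts)
            except Exception as e:  # pragma: no cover - defensive
                failures.append((tm, ta, repr(e)))
                continue
            eps_inf[i, j] = res.eps_inf
            eps_tau[i, j] = res.eps_tau if res.tau_defined else np.nan
    return {"tau_m": np.asarray(tau_m_grid), "tau_ax": np.asarray(tau_ax_grid), "eps_inf": eps_inf, "eps_tau": eps_tau, "failures": failures}


def axon_benchmark_compare(
    kind: str,
    A1: float,
    A2: float,
    duration: float = None,
    gamma_spec: GammaSpec = None,
    f_US: float = 500e3,
    a: float = 32e-9,
    fs: float = 0.8,
    consts: BLSConstants = None,
    n_Q: int = 30,
) -> float:
    """Gamma deviation of the effective paradigm on a two-compartment axon.

    Two identical compartments with the morphology and full membrane
    dynamics of one node of the given fiber type (``senn_node`` or
    ``sundt``), stimulated at per-compartment amplitudes for a
    type-specific duration (1 ms myelinated, 10 ms unmyelinated).
    """
    consts = consts or BLSConstants()
    node = build_node_model(kind)
    mem = node.topology.membrane
    if duration is None:
        duration = 1e-3 if kind == "senn_node" else 10e-3
    Am = node.topology.Am[0]
    # axial conductance of one internode / inter-segment connection
    if kind == "senn_node":
        from .fibers import SENN_AXON_DIAMETER_RATIO, SENN_RHO_AXIAL

        D = node.D
        Ga = math.pi * (SENN_AXON_DIAMETER_RATIO * D / 2.0) ** 2 / (SENN_RHO_AXIAL * 100.0 * D)
    else:
        from .fibers import SUNDT_RHO_AXIAL, optimal_segment_length

        D = node.D
        seg = optimal_segment_length(D)
        Ga = math.pi * (D / 2.0) ** 2 / (SUNDT_RHO_AXIAL * seg)
    topo = CableTopology(
        membrane=mem,
        Am=np.array([Am, Am]),
        edges=np.array([[0, 1]]),
        Ga=np.array([Ga]),
    )
    nice = integrate_nice_detailed(topo, A_amp=[A1, A2], t_end=duration, f_US=f_US, a=a, fs=fs, consts=consts)
    tc, qc = nice.cycle_averaged()
    Qg = np.linspace(mem.Cm0 * -0.1, mem.Cm0 * 0.05, n_Q)
    amps = sorted({0.0, A1, A2})
    lkp = build_lookup(mem, a=a, f_US=f_US, A_grid=np.asarray(amps), Q_grid=Qg, fs=fs, consts=consts)
    src = LookupSource(lkp, np.array([A1, A2]))
    sonic = integrate_hybrid(topo, src, _ConstantProtocol(), t_end=duration, dt_out=max(duration / 5000.0, 1.0 / f_US))
    if gamma_spec is None:
        gamma_spec = GammaSpec(dQm_tol=0.3 * 0.1 * mem.Cm0, dt_tol=0.3 * 0.5e-3)
    return deviation_gamma(tc, qc, sonic.t, sonic.Qm, gamma_spec)
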