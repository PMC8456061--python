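"""Worked-example reproduction workflows.

End-to-end computations of the framework's headline quantities: the
rheobase ultrasonic excitation thresholds of the two node models and the
mechanistic quantities tied to them (threshold charge build-ups,
effective-capacitance drops, intra-cycle oscillation ranges, equilibrium
gaps, electric-pressure and threshold-charge ratios), and the
charge-build-up latencies of the full fiber models under the standard
Gaussian exposure.  Every quantity is computed from scratch by running
the simulators; nothing is tabulated.
"""

from __future__ import annotations

import numpy as np

from . import run as runners
from .bls import BLSConstants, cavitation_cycle, coverage_weighted_capacitance, equilibrium_gap
from .cable import DirectSource, LookupSource
from .fields import gaussian_profile
from .lookup import build_lookup
from .protocols import PulseProtocol, buildup_time, run_sonication


def node_worked_example(kind, PD=100e-3, rtol=0.01, n_Q=40, tail=60e-3, consts=None):
    """Titrate one node model at rheobase and derive its threshold mechanics.

    Returns a dict with ``threshold_Pa``, ``buildup_V`` (maximal
    sub-threshold normalized charge build-up), ``Q_thr`` (C/m^2, charge at
    spike threshold), ``cm_drop`` (relative effective-capacitance change at
    the threshold drive and threshold charge), and ``osc_range``
    (normalized intra-cycle oscillation range of the coverage-weighted
    capacitance at threshold).
    """
    consts = consts or BLSConstants()
    res = runners.node_threshold(kind, PD=PD, rtol=rtol, tail=tail, n_Q=n_Q, consts=consts)
    buildup = threshold_buildup(res.supra_trace)
    mem = res.sub_trace.topology.membrane
    Q_thr = mem.Cm0 * (mem.Vm0 + buildup)
    Delta = equilibrium_gap(mem.Qm0, consts)
    prof = cavitation_cycle(
        runners.DEFAULT_A, runners.DEFAULT_F_US, res.threshold, Q_thr, consts, Delta=Delta, Cm0=mem.Cm0
    )
    Cm_fs = coverage_weighted_capacitance(prof.Cm_t, runners.DEFAULT_FS, mem.Cm0)
    cm_star = 1.0 / float(np.mean(1.0 / Cm_fs))
    return {
        "kind": kind,
        "threshold_Pa": res.threshold,
        "buildup_V": buildup,
        "Q_thr": Q_thr,
        "cm_drop": cm_star / mem.Cm0 - 1.0,
        "osc_range": float((Cm_fs.max() - Cm_fs.min()) / mem.Cm0),
        "membrane": mem,
    }


def threshold_buildup(supra_trace):
    """Normalized charge build-up at spike initiation (V).

    On the barely supra-threshold trace, the slow passage through the
    ghost of the sub-threshold equilibrium ends where the charge rate is
    minimal before the regenerative escape; the build-up at that
    bottleneck is the spiking threshold in charge space.
    """
    qn = supra_trace.normalized_charge(0)
    t = supra_trace.t
    i_spk = int(np.argmax(qn))
    if i_spk < 3:
        raise RuntimeError("no regenerative escape found on the supra-threshold trace")
    dq = np.gradient(qn[: i_spk + 1], t[: i_spk + 1])
    risen = np.where(qn[: i_spk + 1] - qn[0] > 1e-3)[0]
    i0 = risen[0] if len(risen) else 1
    i_bot = i0 + int(np.argmin(dq[i0 : i_spk + 1]))
    return float(qn[i_bot] - qn[0])


def threshold_pressure_ratios(fh_example, sundt_example):
    """Electric-pressure and charge ratios at the two threshold conditions.

    The electric pressure scales with Qm^2 at any common deflection, so the
    magnitude ratio is evaluated at the flat configuration.
    """
    from .bls import electric_pressure

    consts = BLSConstants()
    a = runners.DEFAULT_A
    pq_f = float(electric_pressure(0.0, fh_example["Q_thr"], a, consts))
    pq_s = float(electric_pressure(0.0, sundt_example["Q_thr"], a, consts))
    return {
        "PQ_ratio": abs(pq_f) / abs(pq_s),
        "Q_ratio": abs(fh_example["Q_thr"]) / abs(sundt_example["Q_thr"]),
    }


def senn_fiber_latency(peak=120e3, PD=1e-3, width=5e-3, n_Q=40, consts=None):
    """Time for the central Ranvier node to build up 5 mV under the standard
    Gaussian exposure (s).  Uses exact-amplitude charge-space projections
    (one fresh limit cycle per node), free of amplitude-interpolation bias.
    """
    fiber = runners.make_fiber("senn", length=10e-3)
    mem = fiber.topology.membrane
    prof = gaussian_profile(1.0, width, fiber.x)
    src = DirectSource(mem, prof.A, Q_grid=runners.charge_grid(mem, n_Q), fs=runners.DEFAULT_FS, consts=consts)
    tr = run_sonication(fiber.topology, src, PulseProtocol(PD=PD, amplitude=peak), tail=5e-3, dt_out=1e-6)
    tb, ok = buildup_time(tr, fiber.n_comp // 2)
    if not ok:
        raise RuntimeError("central node never reached the 5 mV build-up level")
    return tb, tr


def sundt_fiber_latency(peak=120e3, PD=10e-3, width=5e-3, n_A=30, n_Q=30, consts=None):
    """Time for the central compartment of the unmyelinated fiber to build up
    5 mV under the standard Gaussian exposure (s)."""
    fiber = runners.make_fiber("sundt", length=10e-3)
    mem = fiber.topology.membrane
    A_grid = np.concatenate(([0.0], np.geomspace(2e3, 1.1 * peak, n_A)))
    lkp = build_lookup(mem, A_grid=A_grid, Q_grid=runners.charge_grid(mem, n_Q), fs=runners.DEFAULT_FS, consts=consts)
    prof = gaussian_profile(1.0, width, fiber.x)
    src = LookupSource(lkp, prof.A)
    tr = run_sonication(fiber.topology, src, PulseProtocol(PD=PD, amplitude=peak), tail=15e-3, dt_out=2e-5)
    tb, ok = buildup_time(tr, fiber.n_comp // 2)
    if not ok:
        raise RuntimeError("central compartment never reached the 5 mV build-up level")
    return tb, tr
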