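"""High-level experiment runners combining fields, fibers, lookups, protocols.

These are the workflows behind the command-line interface and the
reproduction scripts: node-model threshold titrations, full-fiber
responses to Gaussian acoustic exposures, strength-duration curves,
firing-rate maps and multiplexed two-fiber stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bls import BLSConstants
from .cable import DirectSource, LookupSource, integrate_hybrid
from .fibers import FiberModel, build_node_model, build_senn_fiber, build_sundt_fiber
from .fields import gaussian_profile
from .lookup import build_lookup, default_amplitude_grid
from .membranes import get_membrane
from .protocols import (
    MuxProtocol,
    PulseProtocol,
    SpikeAnalysis,
    detect_spikes_and_rate,
    node_spike_detector,
    run_sonication,
    titrate_threshold,
)

#: Default sonophore/stimulus conditions used across the worked examples.
DEFAULT_A = 32e-9  # sonophore radius (m)
DEFAULT_FS = 0.8  # coverage fraction
DEFAULT_F_US = 500e3  # carrier frequency (Hz)


def charge_grid(membrane, n=30):
    return np.linspace(membrane.Cm0 * -0.1, membrane.Cm0 * 0.05, n)


# ----------------------------------------------------------------------------
# Node-model workflows
# ----------------------------------------------------------------------------

@dataclass
class NodeTitration:
    threshold: float  # Pa
    sub_trace: object  # CableTrace at the highest non-spiking amplitude
    supra_trace: object  # CableTrace at the lowest spiking amplitude
    sub_amplitude: float
    supra_amplitude: float


def node_sonication_trace(
    kind,
    A,
    PD,
    f_US=DEFAULT_F_US,
    a=DEFAULT_A,
    fs=DEFAULT_FS,
    tail=40e-3,
    n_Q=30,
    consts: BLSConstants = None,
    dt_out=5e-5,
):
    """Single-pulse response of an isolated node model at amplitude ``A``."""
    node = build_node_model(kind)
    mem = node.topology.membrane
    src = DirectSource(mem, [1.0], a=a, f_US=f_US, Q_grid=charge_grid(mem, n_Q), fs=fs, consts=consts)
    # DirectSource scales the profile by the segment level; profile 1.0 -> level = A
    proto = PulseProtocol(PD=PD, amplitude=A)
    return run_sonication(node.topology, src, proto, tail=tail, dt_out=dt_out)


def node_threshold(
    kind,
    PD=100e-3,
    f_US=DEFAULT_F_US,
    a=DEFAULT_A,
    fs=DEFAULT_FS,
    bounds=None,
    rtol=0.01,
    tail=40e-3,
    n_Q=30,
    consts: BLSConstants = None,
) -> NodeTitration:
    """Binary-search excitation threshold of an isolated node model (Pa).

    The spike criterion is a prominent charge-density peak anywhere in the
    pulse-plus-tail window (offset responses included).
    """
    if bounds is None:
        bounds = (50e3, 200e3) if kind == "senn_node" else (10e3, 80e3)
    node = build_node_model(kind)
    mem = node.topology.membrane
    src = DirectSource(mem, [1.0], a=a, f_US=f_US, Q_grid=charge_grid(mem, n_Q), fs=fs, consts=consts)
    traces = {}

    def spikes_at(A):
        proto = PulseProtocol(PD=PD, amplitude=A)
        tr = run_sonication(node.topology, src, proto, tail=tail, dt_out=5e-5)
        spiked = node_spike_detector(tr)
        traces[A] = (spiked, tr)
        return spiked

    thr = titrate_threshold(spikes_at, bounds, rtol=rtol)
    subs = [(A, tr) for A, (s, tr) in traces.items() if not s]
    supras = [(A, tr) for A, (s, tr) in traces.items() if s]
    sub_A, sub_tr = max(subs, key=lambda x: x[0])
    supra_A, supra_tr = min(supras, key=lambda x: x[0])
    return NodeTitration(thr, sub_tr, supra_tr, sub_A, supra_A)


# ----------------------------------------------------------------------------
# Fiber workflows
# ----------------------------------------------------------------------------

def make_fiber(kind, D=None, length=10e-3) -> FiberModel:
    if kind in ("senn", "senn_node"):
        return build_senn_fiber(D or 10e-6, length=length)
    if kind == "sundt":
        return build_sundt_fiber(D or 0.8e-6, length=length)
    raise ValueError(f"unknown fiber kind {kind!r}")


def fiber_lookup(
    membrane,
    f_US=DEFAULT_F_US,
    a=DEFAULT_A,
    fs=DEFAULT_FS,
    n_A=15,
    n_Q=30,
    A_max=600e3,
    consts: BLSConstants = None,
):
    """Amplitude/charge lookup sized for fiber simulations."""
    if isinstance(membrane, str):
        membrane = get_membrane(membrane)
    return build_lookup(
        membrane,
        a=a,
        f_US=f_US,
        A_grid=default_amplitude_grid(n=n_A, A_max=A_max),
        Q_grid=charge_grid(membrane, n_Q),
        fs=fs,
        consts=consts,
    )


def fiber_gaussian_source(fiber: FiberModel, lookup, width=5e-3):
    """Lookup-backed effective source for a Gaussian beam centered on the fiber.

    The per-compartment profile is the normalized Gaussian; protocol levels
    carry the peak amplitude in Pa.
    """
    prof = gaussian_profile(1.0, width, fiber.x)
    return LookupSource(lookup, prof.A)


def fiber_gaussian_trace(
    fiber: FiberModel,
    lookup,
    peak,
    PD,
    width=5e-3,
    PRF=None,
    n_pulses=1,
    tail=10e-3,
    dt_out=2e-5,
):
    """Response of a fiber to a pulsed Gaussian acoustic exposure."""
    src = fiber_gaussian_source(fiber, lookup, width)
    proto = PulseProtocol(PD=PD, amplitude=peak, PRF=PRF, n_pulses=n_pulses)
    return run_sonication(fiber.topology, src, proto, tail=tail, dt_out=dt_out)


def fiber_threshold(
    fiber: FiberModel,
    lookup,
    PD,
    width=5e-3,
    bounds=(5e3, 500e3),
    rtol=0.01,
    tail=15e-3,
    prominence=0.03,
):
    """Titrated peak amplitude eliciting a propagated spike (Pa)."""
    src = fiber_gaussian_source(fiber, lookup, width)

    def spikes_at(peak):
        proto = PulseProtocol(PD=PD, amplitude=peak)
        tr = run_sonication(fiber.topology, src, proto, tail=tail, dt_out=5e-5)
        return detect_spikes_and_rate(tr, prominence=prominence).n_propagated > 0

    return titrate_threshold(spikes_at, bounds, rtol=rtol)


def mux_two_fiber(
    PRF_long=50.0,
    PRF_short=200.0,
    A_long=None,
    A_short=None,
    PD_long=10e-3,
    PD_short=100e-6,
    width=2e-3,
    length=10e-3,
    n_pulses_long=6,
    lookups=None,
    margin=1.1,
    thresholds=None,
    dt_out=5e-5,
) -> dict:
    """Multiplexed two-fiber stimulation: firing rate of each fiber type.

    A short-pulse scheme (repetition rate ``PRF_short``) targets the
    myelinated fiber and a long-pulse scheme (``PRF_long``) the
    unmyelinated fiber; amplitudes default to 10% above each fiber's
    titrated threshold at its pulse duration.
    """
    fibers = {
        "senn": make_fiber("senn", length=length),
        "sundt": make_fiber("sundt", length=length),
    }
    if lookups is None:
        lookups = {k: fiber_lookup(f.topology.membrane) for k, f in fibers.items()}
    if thresholds is None:
        thresholds = {
            "senn": fiber_threshold(fibers["senn"], lookups["senn"], PD_short, width=width),
            "sundt": fiber_threshold(fibers["sundt"], lookups["sundt"], PD_long, width=width),
        }
    A_short = margin * thresholds["senn"] if A_short is None else A_short
    A_long = margin * thresholds["sundt"] if A_long is None else A_long
    t_end = n_pulses_long / PRF_long + 30e-3
    n_short = int(t_end * PRF_short)
    proto = MuxProtocol(
        PulseProtocol(PD=PD_long, amplitude=A_long, PRF=PRF_long, n_pulses=n_pulses_long),
        PulseProtocol(PD=PD_short, amplitude=A_short, PRF=PRF_short, n_pulses=n_short),
    )
    out = {"A_long": A_long, "A_short": A_short, "thresholds": thresholds, "rates": {}}
    for kind, fiber in fibers.items():
        src = fiber_gaussian_source(fiber, lookups[kind], width)
        tr = integrate_hybrid(fiber.topology, src, proto, t_end=t_end, dt_out=dt_out)
        out["rates"][kind] = detect_spikes_and_rate(tr)
    return out


def firing_rate_map(fiber, lookup, PD_list, PRF_list, peak=300e3, width=None, n_pulses=10):
    """Mean firing rate over a (pulse duration, repetition rate) grid (Hz)."""
    width = width or fiber.length / 5.0
    src = fiber_gaussian_source(fiber, lookup, width)
    fr = np.full((len(PD_list), len(PRF_list)), np.nan)
    for i, pd in enumerate(PD_list):
        for j, prf in enumerate(PRF_list):
            if pd * prf > 1.0:
                continue
            proto = PulseProtocol(PD=pd, amplitude=peak, PRF=prf, n_pulses=n_pulses)
            t_end = n_pulses / prf + 20e-3
            tr = integrate_hybrid(fiber.topology, src, proto, t_end=t_end, dt_out=5e-5)
            fr[i, j] = detect_spikes_and_rate(tr).firing_rate
    return fr


def fiber_electric_trace(
    fiber: FiberModel,
    I_electrode,
    PD,
    z0=1e-3,
    x0=0.0,
    PRF=None,
    n_pulses=1,
    tail=10e-3,
    dt_out=2e-5,
):
    """Response to a pulsed extracellular point-electrode stimulus.

    The electrode current sets the extracellular potential along the
    fiber (anisotropic endoneurium), which is applied as equivalent
    intracellular activating currents scaled by the pulse envelope.
    """
    from .cable import extracellular_drive_currents
    from .fields import electrode_potential
    from .lookup import ProjectedTables

    phi = electrode_potential(1.0, x0, z0, fiber.x)  # V per A of electrode current
    Is_unit = extracellular_drive_currents(fiber.topology, phi)  # A/m^2 per A
    mem = fiber.topology.membrane
    # resting-membrane tables (no acoustic drive)
    from .lookup import build_lookup

    lkp = build_lookup(mem, A_grid=np.array([0.0, 1.0]), Q_grid=charge_grid(mem, 40), fs=0.0)
    src = LookupSource(lkp, np.zeros(fiber.n_comp))
    proto = PulseProtocol(PD=PD, amplitude=I_electrode, PRF=PRF, n_pulses=n_pulses)
    return run_sonication(fiber.topology, src, proto, tail=tail, dt_out=dt_out, Is_profile=Is_unit)
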