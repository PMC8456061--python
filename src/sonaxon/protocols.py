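"""Stimulation protocols, titration, excitability and accuracy metrics.

Temporal pulsing schemes (single pulses, trains, duty-cycle sweeps and
multiplexed dual-scheme stimuli), binary-search threshold titration,
strength-duration analysis (rheobase, chronaxie), spike detection and
firing rates, charge build-up quantification, per-current decomposition,
and the deviation metrics used to benchmark the cycle-averaged paradigm
against temporally detailed solutions (steady-state and transient
deviations, and the tolerance-normalized gamma distance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .cable import CableTrace, integrate_hybrid, single_compartment


# ----------------------------------------------------------------------------
# Pulsing schemes
# ----------------------------------------------------------------------------

@dataclass
class PulseProtocol:
    """Rectangular pulse train.

    ``amplitude`` is the stimulus envelope level during pulses (peak Pa for
    acoustic drives, scale factor for injected/extracellular currents).
    Continuous stimulation is the DC = 1 limit (PRF * PD = 1).
    """

    PD: float  # pulse duration (s)
    amplitude: float = 1.0
    PRF: float = None  # pulse repetition frequency (Hz); None = single pulse
    n_pulses: int = 1
    start: float = 0.0

    def __post_init__(self):
        if self.PD <= 0:
            raise ValueError("pulse duration must be positive")
        if self.PRF is not None and self.PD * self.PRF > 1.0 + 1e-9:
            raise ValueError("duty cycle PD*PRF exceeds 1")

    @classmethod
    def from_duty_cycle(cls, DC, PRF, amplitude=1.0, n_pulses=1, start=0.0):
        if not 0 < DC <= 1:
            raise ValueError("duty cycle must lie in (0, 1]")
        return cls(PD=DC / PRF, amplitude=amplitude, PRF=PRF, n_pulses=n_pulses, start=start)

    @property
    def duty_cycle(self):
        return 1.0 if self.PRF is None else self.PD * self.PRF

    @property
    def period(self):
        return None if self.PRF is None else 1.0 / self.PRF

    def edges(self, t_end):
        """Sorted (t_on, t_off) pairs within [0, t_end]."""
        out = []
        for i in range(self.n_pulses if self.PRF is not None else 1):
            t0 = self.start + (i / self.PRF if self.PRF is not None else 0.0)
            t1 = min(t0 + self.PD, t_end)
            if t0 >= t_end:
                break
            out.append((t0, t1))
        return out

    def segments(self, t_end):
        """Piecewise-constant envelope [(t0, t1, level), ...] covering [0, t_end]."""
        return _merge_envelopes([self], t_end)


@dataclass
class MuxProtocol:
    """Multiplexed stimulus: superposition of two independent pulse trains.

    Where constituent pulses overlap, the applied amplitude is the
    per-time maximum of the two envelopes (amplitude-coded interleaving).
    """

    scheme1: PulseProtocol
    scheme2: PulseProtocol

    def segments(self, t_end):
        return _merge_envelopes([self.scheme1, self.scheme2], t_end)


def _merge_envelopes(protocols, t_end):
    times = {0.0, t_end}
    for p in protocols:
        for (t0, t1) in p.edges(t_end):
            times.add(t0)
            times.add(t1)
    times = sorted(t for t in times if 0.0 <= t <= t_end)
    segs = []
    for t0, t1 in zip(times[:-1], times[1:]):
        if t1 <= t0:
            continue
        tm = 0.5 * (t0 + t1)
        level = 0.0
        for p in protocols:
            for (a, b) in p.edges(t_end):
                if a <= tm < b and abs(p.amplitude) > abs(level):
                    level = p.amplitude
        # merge with previous segment when the level is unchanged
        if segs and segs[-1][2] == level:
            segs[-1] = (segs[-1][0], t1, level)
        else:
            segs.append((t0, t1, level))
    return segs


# ----------------------------------------------------------------------------
# Spike detection and firing rate
# ----------------------------------------------------------------------------

@dataclass
class SpikeFeatures:
    """Reference spike shape of one membrane model."""

    prominence: float  # normalized charge prominence (V)
    half_width: float  # s


def spike_times(t, qn, prominence=0.03):
    """Peak times of a normalized-charge trace with a minimum prominence (V)."""
    idx, _ = signal.find_peaks(qn, prominence=prominence)
    return t[idx]


def measure_spike_features(t, qn, prominence=0.03) -> SpikeFeatures:
    """Prominence and half-width of the largest detected spike."""
    idx, props = signal.find_peaks(qn, prominence=prominence)
    if len(idx) == 0:
        raise ValueError("no spike found in trace")
    best = int(np.argmax(props["prominences"]))
    widths, _, _, _ = signal.peak_widths(qn, idx[best : best + 1], rel_height=0.5)
    dt = float(np.median(np.diff(t)))
    return SpikeFeatures(prominence=float(props["prominences"][best]), half_width=float(widths[0] * dt))


@dataclass
class SpikeAnalysis:
    times_start: np.ndarray  # spike times at the first extremity (s)
    times_end: np.ndarray  # spike times at the last extremity (s)
    firing_rate: float  # Hz (0 with defined=False when < 2 propagated spikes)
    fr_defined: bool
    n_propagated: int


def detect_spikes_and_rate(trace: CableTrace, prominence=0.03, max_delay=None) -> SpikeAnalysis:
    """Propagated spikes and firing rate from the extremity compartments.

    A spike counts as propagated when detected at both fiber extremities
    (within ``max_delay`` of each other when given).  The firing rate is
    the reciprocal of the mean inter-spike interval at the extremities.
    """
    qn = trace.normalized_charge()
    t = trace.t
    t_a = spike_times(t, qn[:, 0], prominence)
    t_b = spike_times(t, qn[:, -1], prominence)
    if trace.n_comp == 1:
        prop = t_a
    else:
        prop = []
        for ta in t_a:
            d = np.abs(t_b - ta)
            if len(d) and (max_delay is None or d.min() <= max_delay):
                prop.append(ta)
        prop = np.asarray(prop)
    if len(prop) >= 2:
        fr = 1.0 / float(np.mean(np.diff(prop)))
        return SpikeAnalysis(t_a, t_b, fr, True, len(prop))
    return SpikeAnalysis(t_a, t_b, 0.0, False, len(prop))


# ----------------------------------------------------------------------------
# Titration and strength-duration analysis
# ----------------------------------------------------------------------------

class TitrationError(RuntimeError):
    pass


def titrate_threshold(spikes_at, bounds, rtol=0.01, check_bounds=True):
    """Binary-search threshold of a monotone spike response.

    Parameters
    ----------
    spikes_at : callable(amplitude) -> bool
    bounds : (lo, hi)
        Bracketing amplitudes; ``lo`` must not spike and ``hi`` must.
    rtol : float
        Terminates when the bracket's relative width falls below this.

    Returns the geometric midpoint of the final bracket.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("invalid bounds")
    if check_bounds:
        if spikes_at(lo):
            raise TitrationError(f"lower bound {lo!r} already elicits a spike")
        if not spikes_at(hi):
            raise TitrationError(f"upper bound {hi!r} does not elicit a spike")
    while (hi - lo) / hi > rtol:
        mid = math.sqrt(lo * hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


@dataclass
class SDCurve:
    PD: np.ndarray  # s
    threshold: np.ndarray  # stimulus units
    rheobase: float
    chronaxie: float


def strength_duration_curve(threshold_at, PD_list, bounds) -> SDCurve:
    """Thresholds across pulse durations, with rheobase and chronaxie.

    ``threshold_at(PD)`` titrates one duration.  The rheobase is the
    threshold at the longest duration; the chronaxie is found by
    log-interpolating the curve at twice the rheobase (first crossing,
    with a warning, if the curve is not monotone).
    """
    PD = np.asarray(sorted(PD_list), dtype=float)
    thr = np.array([threshold_at(pd) for pd in PD])
    rheo = float(thr[-1])
    if np.any(np.diff(thr) > 1e-9 * rheo):
        warnings.warn("non-monotone strength-duration curve; chronaxie from first crossing")
    target = 2.0 * rheo
    chron = None
    for i in range(len(PD) - 1):
        y0, y1 = thr[i], thr[i + 1]
        if (y0 - target) * (y1 - target) <= 0 and y0 != y1:
            w = (math.log(target) - math.log(y0)) / (math.log(y1) - math.log(y0))
            chron = math.exp(math.log(PD[i]) + w * (math.log(PD[i + 1]) - math.log(PD[i])))
            break
    if chron is None:
        chron = float(PD[0]) if thr[0] < target else float("nan")
    return SDCurve(PD=PD, threshold=thr, rheobase=rheo, chronaxie=float(chron))


# ----------------------------------------------------------------------------
# Charge build-up analyses
# ----------------------------------------------------------------------------

def buildup_time(trace: CableTrace, compartment: int, dV: float = 5e-3, t_onset: float = 0.0):
    """First time the normalized charge rises ``dV`` above rest (s).

    Returns ``(time, True)`` or ``(None, False)`` when the build-up level
    is never reached.
    """
    qn = trace.normalized_charge(compartment)
    above = np.where((qn - qn[0]) >= dV)[0]
    if len(above) == 0:
        return None, False
    i = above[0]
    if i == 0:
        return 0.0, True
    # linear refinement between samples
    f = (dV - (qn[i - 1] - qn[0])) / (qn[i] - qn[i - 1])
    return float(trace.t[i - 1] + f * (trace.t[i] - trace.t[i - 1]) - t_onset), True


def passive_buildup_estimate(Cm_star: float, Cm0: float, ELeak: float) -> float:
    """Leak-circuit steady-state charge build-up (C/m^2).

    (dQm)_inf ~= (Cm* - Cm0) * ELeak: the build-up expected from the drop
    in effective capacitance alone, for a membrane dominated by leakage.
    """
    return (Cm_star - Cm0) * ELeak


def decompose_currents(trace: CableTrace, source, compartment: int, window) -> dict:
    """Charge contribution of each current over a time window (C/m^2).

    Re-evaluates the per-current densities (and the net axial current)
    along the saved trace and integrates them over ``window = (t0, t1)``.
    The contributions sum to the total charge change computed from the
    same integrand, an algebraic identity of the charge-casted balance.
    """
    t0, t1 = window
    mask = (trace.t >= t0) & (trace.t <= t1)
    t = trace.t[mask]
    topo = trace.topology
    mem = topo.membrane
    k = compartment
    Vm = trace.Vm[mask]
    gates_k = trace.gates[mask, k, :]
    out = {}
    for name, dens in mem.currents(Vm[:, k], gates_k).items():
        out[name] = -float(np.trapezoid(dens, t))
    if len(topo.edges):
        ax = np.zeros(len(t))
        Vx = trace.Vx[mask] if trace.Vx is not None else None
        Vi = Vm + (Vx if Vx is not None else 0.0)
        for (i, j), g in zip(topo.edges, topo.Ga):
            if i == k:
                ax += g * (Vi[:, j] - Vi[:, k])
            elif j == k:
                ax += g * (Vi[:, i] - Vi[:, k])
        out["axial"] = float(np.trapezoid(ax / topo.Am[k], t))
    total = sum(out.values())
    out["total"] = total
    return out


# ----------------------------------------------------------------------------
# Accuracy (deviation) metrics
# ----------------------------------------------------------------------------

#: Charge-variation floor below which the transient metric is not meaningful.
TRANSIENT_EXCLUSION_RANGE = 1e-5  # C/m^2 (1 nC/cm^2)


def _unit_normalize(x):
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x), 0.0
    return (x - lo) / (hi - lo), hi - lo


def deviation_passive(t_ref, Q_ref, t_test, Q_test, steady_frac=0.001):
    """Steady-state and transient deviations between two charge solutions.

    Parameters are per-compartment arrays (nt, n).  Returns
    ``(eps_inf, eps_tau, tau_defined)`` where ``eps_inf`` (C/m^2) is the
    maximal across-compartment steady-state difference and ``eps_tau``
    (fraction) the maximal normalized transient deviation; compartments
    whose reference charge range is below 1 nC/cm^2 are excluded from the
    transient metric (``tau_defined`` is False when all are).
    """
    Q_ref = np.atleast_2d(np.asarray(Q_ref, dtype=float).T).T
    Q_test = np.atleast_2d(np.asarray(Q_test, dtype=float).T).T
    n = Q_ref.shape[1]
    eps_inf = 0.0
    eps_tau = 0.0
    tau_defined = False
    for k in range(n):
        qr = Q_ref[:, k]
        qt = np.interp(t_ref, t_test, Q_test[:, k])
        eps_inf = max(eps_inf, abs(qr[-1] - qt[-1]))
        zr, rng = _unit_normalize(qr)
        if rng < TRANSIENT_EXCLUSION_RANGE:
            continue
        zt = (qt - np.min(qr)) / rng
        zss = zr[-1]
        conv = np.where(np.abs(zr - zss) <= steady_frac)[0]
        # first index after which the reference stays converged
        i_thr = len(zr) - 1
        for i in conv:
            if np.all(np.abs(zr[i:] - zss) <= steady_frac):
                i_thr = i
                break
        if i_thr < 2:
            continue
        num = np.trapezoid(np.abs(zt[: i_thr + 1] - zr[: i_thr + 1]), t_ref[: i_thr + 1])
        den = np.trapezoid(1.0 - zr[: i_thr + 1], t_ref[: i_thr + 1])
        if den > 0:
            eps_tau = max(eps_tau, num / den)
            tau_defined = True
    return float(eps_inf), float(eps_tau), tau_defined


@dataclass
class GammaSpec:
    """Value/time tolerances of the gamma distance."""

    dQm_tol: float  # C/m^2
    dt_tol: float  # s

    @classmethod
    def from_spike_features(cls, features: SpikeFeatures, Cm0: float, fraction: float = 0.3):
        """Tolerances as 30% of the model's spike prominence and half-width."""
        return cls(dQm_tol=fraction * features.prominence * Cm0, dt_tol=fraction * features.half_width)


def deviation_gamma(t_ref, Q_ref, t_test, Q_test, spec: GammaSpec, max_points: int = 2000):
    """Maximal tolerance-normalized gamma distance between two solutions.

    For each reference sample (t1, Qref(t1)), the distance to the nearest
    test sample in the (time/dt_tol, charge/dQm_tol) plane is minimized
    over t2; the metric is the maximum of these minima across time and
    compartments.  Values below 1 mean agreement within tolerances.
    """
    Q_ref = np.atleast_2d(np.asarray(Q_ref, dtype=float).T).T
    Q_test = np.atleast_2d(np.asarray(Q_test, dtype=float).T).T
    sr = max(1, len(t_ref) // max_points)
    st = max(1, len(t_test) // max_points)
    tr = t_ref[::sr]
    tt = t_test[::st]
    eps = 0.0
    for k in range(Q_ref.shape[1]):
        qr = Q_ref[::sr, k]
        qt = Q_test[::st, k]
        dt2 = ((tr[:, None] - tt[None, :]) / spec.dt_tol) ** 2
        dq2 = ((qr[:, None] - qt[None, :]) / spec.dQm_tol) ** 2
        gamma = np.sqrt(np.min(dt2 + dq2, axis=1))
        eps = max(eps, float(np.max(gamma)))
    return eps


def population_rate_comparison(rates_group1, rates_group2):
    """Kruskal-Wallis comparison of two firing-rate distributions.

    Returns (H statistic, p value); ties are handled by midranks.
    """
    r1 = np.asarray(rates_group1, dtype=float)
    r2 = np.asarray(rates_group2, dtype=float)
    if len(r1) < 3 or len(r2) < 3:
        raise ValueError("need at least 3 firing rates per group")
    H, p = stats.kruskal(r1, r2)
    return float(H), float(p)


# ----------------------------------------------------------------------------
# High-level runners
# ----------------------------------------------------------------------------

def run_sonication(topology, source, protocol, t_end=None, tail=10e-3, dt_out=2e-5, **kw) -> CableTrace:
    """Integrate a cable under a pulsed acoustic drive (effective paradigm).

    ``t_end`` defaults to the end of the last pulse plus a ``tail`` to
    capture offset responses and propagation.
    """
    if t_end is None:
        segs = protocol.segments(1e9)
        t_last = max(t1 for (_, t1, lev) in segs if lev != 0)
        t_end = t_last + tail
    return integrate_hybrid(topology, source, protocol, t_end=t_end, dt_out=dt_out, **kw)


def node_spike_detector(trace: CableTrace, prominence=0.03, runaway_buildup=0.03) -> bool:
    """Spike criterion for point models.

    Either a prominent charge-density peak, or a charge build-up far beyond
    the sub-threshold range (strong drives produce a depolarization-block
    plateau whose regenerative escape has no discrete peak).
    """
    qn = trace.normalized_charge(0)
    if len(spike_times(trace.t, qn, prominence)) > 0:
        return True
    return float(qn.max() - qn[0]) > runaway_buildup
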