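"""Hybrid charge/voltage multi-compartment cable system.

Each longitudinal compartment carries a charge-casted membrane node
(state: charge density Qm) and, optionally, an extracellular voltage node
(state: Vx) connected to an extracellular driving potential through a
transverse RC layer.  Kirchhoff balances at both nodes yield a hybrid
system

    C dy/dt + G(t) y = I(t),      y = [Qm_1..n ; Vx_1..n]

with constant capacitance/identity blocks in C and time-varying
conductance-over-capacitance blocks in G.  Both axon models used here are
single-cable (no extracellular layer), in which case only the first n
equations evolve; the double-cable form is kept for generality and is
exercised on toy fixtures.

Two integration paradigms are provided:

* :func:`integrate_hybrid` — effective (cycle-averaged) integration where
  membrane voltage, capacitance and gating rates are interpolated from
  charge-space projections of precomputed lookups; adaptive implicit
  (BDF) stepping with pure absolute tolerance on charge.
* :func:`integrate_nice_detailed` — temporally detailed integration of
  the fully coupled mechanical + electrical system for one- or
  two-compartment benchmarks, at a fixed step of 0.001 acoustic periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .bls import _consts_tuple, _GL_NODES, _GL_WEIGHTS, _mech_rhs_terms, njit
from .bls import BLSConstants, equilibrium_gap, quasistatic_deflection, resting_gas_content
from .lookup import ProjectedTables, runtime_projection, direct_projection
from .membranes import FrankenhaeuserHuxleyNode, Membrane, PassiveMembrane, SundtSegment


class SolverFailure(RuntimeError):
    pass


# ----------------------------------------------------------------------------
# Topology
# ----------------------------------------------------------------------------

@dataclass
class CableTopology:
    """Compartments, areas and axial/extracellular coupling of one cable."""

    membrane: Membrane
    Am: np.ndarray  # membrane area per compartment (m^2)
    edges: np.ndarray  # (n_edges, 2) int compartment indices
    Ga: np.ndarray  # intracellular axial conductance per edge (S)
    x: np.ndarray = None  # compartment center coordinates (m)
    # extracellular layer (double-cable mode); None in single-cable mode
    Cx: np.ndarray = None  # transverse extracellular capacitance (F/m^2)
    gx: np.ndarray = None  # transverse extracellular conductance (S/m^2)
    Gp: np.ndarray = None  # extracellular axial conductance per edge (S)
    phi_e: np.ndarray = None  # extracellular driving potential (V)

    def __post_init__(self):
        self.Am = np.atleast_1d(np.asarray(self.Am, dtype=float))
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.Ga = np.atleast_1d(np.asarray(self.Ga, dtype=float))
        if np.any(self.Am <= 0):
            raise ValueError("compartment areas must be positive")
        if self.x is None:
            self.x = np.arange(self.n, dtype=float)
        if self.n > 1 and not self._connected():
            raise ValueError("cable topology is not connected")

    @property
    def n(self):
        return len(self.Am)

    @property
    def double_cable(self):
        return self.Cx is not None

    def _connected(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return nx.is_connected(g)

    def axial_matrix(self, G_edges, row_scale=None, col_scale=None):
        """Graph-Laplacian-style axial block, optionally row/column scaled."""
        n = self.n
        M = np.zeros((n, n))
        for (k, j), g in zip(self.edges, G_edges):
            M[k, k] += g
            M[j, j] += g
            M[k, j] -= g
            M[j, k] -= g
        if row_scale is not None:
            M = M / row_scale[:, None]
        if col_scale is not None:
            M = M / col_scale[None, :]
        return M


def single_compartment(membrane: Membrane, Am=1e-10) -> CableTopology:
    """Point ('node') model: one compartment, no axial coupling."""
    return CableTopology(membrane=membrane, Am=[Am], edges=np.empty((0, 2), int), Ga=[])


# ----------------------------------------------------------------------------
# System matrices (block form)
# ----------------------------------------------------------------------------

@dataclass
class SystemMatrices:
    """Block matrices of the hybrid system C dy/dt + G(t) y = I(t)."""

    topology: CableTopology

    def C_matrix(self):
        n = self.topology.n
        top = np.hstack([np.eye(n), np.zeros((n, n))])
        Cx = np.diag(self.topology.Cx) if self.topology.double_cable else np.zeros((n, n))
        bot = np.hstack([-np.eye(n), Cx])
        return np.vstack([top, bot])

    def G_matrix(self, Cm):
        """Time-varying matrix for given per-compartment capacitances (F/m^2)."""
        t = self.topology
        Cm = np.asarray(Cm, dtype=float)
        A_qq = t.axial_matrix(t.Ga, row_scale=t.Am, col_scale=Cm)
        A_qv = t.axial_matrix(t.Ga, row_scale=t.Am)
        n = t.n
        if t.double_cable:
            lower = np.diag(t.gx) + t.axial_matrix(t.Gp, row_scale=t.Am)
        else:
            lower = np.zeros((n, n))
        top = np.hstack([A_qq, A_qv])
        bot = np.hstack([np.zeros((n, n)), lower])
        return np.vstack([top, bot])

    def I_vector(self, Is, Iion):
        t = self.topology
        Ie = t.gx * t.phi_e if t.double_cable else np.zeros(t.n)
        return np.concatenate([Is - Iion, Iion + Ie])

    # Alternative formulation in which the lower block rows are replaced by
    # the sum of the two Kirchhoff balances (removing the membrane-current
    # identity terms); algebraically equivalent to the primary form.
    def C_matrix_alt(self):
        n = self.topology.n
        C = np.zeros((2 * n, 2 * n))
        if self.topology.double_cable:
            C[n:, n:] = np.diag(self.topology.Cx)
        return C

    def G_matrix_alt(self, Cm):
        t = self.topology
        G = self.G_matrix(Cm)
        n = t.n
        G[n:, :] += G[:n, :]
        return G

    def I_vector_alt(self, Is, Iion):
        t = self.topology
        Ie = t.gx * t.phi_e if t.double_cable else np.zeros(t.n)
        return np.concatenate([np.zeros(t.n), Is + Ie])


def assemble_system(topology: CableTopology) -> SystemMatrices:
    """Build the block-matrix description of a cable topology."""
    return SystemMatrices(topology=topology)


def extracellular_drive_currents(topology: CableTopology, phi_e) -> np.ndarray:
    """Equivalent intracellular currents for an imposed extracellular field.

    Activating-function form: I_s,k = (1/Am_k) sum_j Ga_kj (phi_j - phi_k),
    in A/m^2; zero for a uniform field.
    """
    phi_e = np.asarray(phi_e, dtype=float)
    if len(phi_e) != topology.n:
        raise ValueError("phi_e must be defined on every compartment")
    out = np.zeros(topology.n)
    for (k, j), g in zip(topology.edges, topology.Ga):
        out[k] += g * (phi_e[j] - phi_e[k])
        out[j] += g * (phi_e[k] - phi_e[j])
    return out / topology.Am


# ----------------------------------------------------------------------------
# Effective-variable sources
# ----------------------------------------------------------------------------

class EffectiveSource:
    """Maps a stimulus envelope level to per-compartment charge-space tables."""

    def tables_for(self, level: float) -> ProjectedTables:
        raise NotImplementedError


class LookupSource(EffectiveSource):
    """Projection from a precomputed lookup at per-compartment amplitudes."""

    def __init__(self, lookup, A_profile):
        self.lookup = lookup
        self.A_profile = np.atleast_1d(np.asarray(A_profile, dtype=float))
        self._cache = {}

    def tables_for(self, level):
        key = float(level)
        if key not in self._cache:
            self._cache[key] = runtime_projection(self.lookup, key * self.A_profile)
        return self._cache[key]


class DirectSource(EffectiveSource):
    """Projection computed from fresh limit cycles at the exact amplitudes."""

    def __init__(self, membrane, A_profile, a=32e-9, f_US=500e3, Q_grid=None, fs=0.8, consts=None, settings=None):
        self.membrane = membrane
        self.A_profile = np.atleast_1d(np.asarray(A_profile, dtype=float))
        self.kw = dict(a=a, f_US=f_US, Q_grid=Q_grid, fs=fs, consts=consts, settings=settings)
        self._cache = {}

    def tables_for(self, level):
        key = float(level)
        if key not in self._cache:
            self._cache[key] = direct_projection(self.membrane, key * self.A_profile, **self.kw)
        return self._cache[key]


class FixedSource(EffectiveSource):
    """Constant tables (synthetic fixtures and closed-form oracles)."""

    def __init__(self, tables_on: ProjectedTables, tables_off: ProjectedTables):
        self.tables_on = tables_on
        self.tables_off = tables_off

    def tables_for(self, level):
        return self.tables_on if level else self.tables_off


# ----------------------------------------------------------------------------
# Effective (SONIC) integration
# ----------------------------------------------------------------------------

@dataclass
class CableTrace:
    """Time-resolved result of a cable integration."""

    t: np.ndarray  # (nt,) s
    Qm: np.ndarray  # (nt, n) C/m^2
    gates: np.ndarray  # (nt, n, n_gates)
    level: np.ndarray  # (nt,) stimulus envelope level at each sample
    Vm: np.ndarray = None  # (nt, n) effective membrane potential (V)
    Cm_star: np.ndarray = None  # (nt, n) effective capacitance (F/m^2)
    Vx: np.ndarray = None  # (nt, n) extracellular voltage (V), double-cable only
    topology: CableTopology = None
    events: list = field(default_factory=list)  # (time, label) pulse edges

    @property
    def n_comp(self):
        return self.Qm.shape[1]

    def normalized_charge(self, k=None):
        """Normalized charge density Qm / Cm0 (V)."""
        q = self.Qm if k is None else self.Qm[:, k]
        return q / self.topology.membrane.Cm0

    def to_frame(self):
        import pandas as pd

        cols = {"t_s": self.t, "level": self.level}
        for k in range(self.n_comp):
            cols[f"Qm{k}_C_per_m2"] = self.Qm[:, k]
        return pd.DataFrame(cols)


def _gate_layout(membrane, n):
    ng = len(membrane.gates)
    return 1 + ng  # per-compartment state count in the single-cable vector


def _jac_sparsity(topology, ng):
    n = topology.n
    nx = n if topology.double_cable else 0
    size = n * (1 + ng) + nx
    rows, cols = [], []

    def add(r, c):
        rows.append(r)
        cols.append(c)

    for k in range(n):
        add(k, k)
        for g in range(ng):
            xg = n + g * n + k
            add(k, xg)
            add(xg, xg)
            add(xg, k)
    for (k, j) in topology.edges:
        add(k, j)
        add(j, k)
    if nx:
        base = n * (1 + ng)
        for k in range(n):
            add(base + k, base + k)
            add(base + k, k)
            add(k, base + k)
            for g in range(ng):
                add(base + k, n + g * n + k)
        for (k, j) in topology.edges:
            add(base + k, base + j)
            add(base + j, base + k)
            add(base + k, j)
            add(base + j, k)
            add(k, base + j)
            add(j, base + k)
    data = np.ones(len(rows))
    return sparse.coo_matrix((data, (rows, cols)), shape=(size, size))


def integrate_hybrid(
    topology: CableTopology,
    source: EffectiveSource,
    protocol=None,
    t_end: float = 10e-3,
    Is_profile=None,
    dt_out: float = 1e-5,
    atol_Q: float = 1e-8,
    rtol: float = 1e-6,
    y0=None,
    method: str = "BDF",
) -> CableTrace:
    """Integrate the hybrid system under the effective (cycle-averaged) paradigm.

    Parameters
    ----------
    source : EffectiveSource
        Charge-space effective-variable tables per stimulus level (for
        acoustic drives) — level 0 tables are the resting membrane.
    protocol : object with ``segments(t_end) -> [(t0, t1, level)]``
        Temporal envelope; ``None`` means unstimulated for the whole window.
    Is_profile : ndarray, optional
        Per-compartment injected current density (A/m^2) applied scaled by
        the segment level (electrical stimulation path).
    dt_out : float
        Dense-output sampling interval (s).
    atol_Q : float
        Absolute tolerance on charge states (C/m^2); 1e-8 C/m^2 is the
        paper-style 1e-3 nC/cm^2 criterion.
    """
    mem = topology.membrane
    n = topology.n
    ng = len(mem.gates)
    nxs = n if topology.double_cable else 0
    if protocol is None:
        segments = [(0.0, t_end, 0.0)]
    else:
        segments = protocol.segments(t_end)
    if y0 is None:
        Q0, x0 = mem.resting_state()
        y0 = np.concatenate([np.full(n, Q0), np.tile(np.atleast_1d(x0), (n, 1)).T.ravel(), np.zeros(nxs)])
    Is_profile = np.zeros(n) if Is_profile is None else np.asarray(Is_profile, dtype=float)

    has_axial = len(topology.edges) > 0
    inv_Am = 1.0 / topology.Am
    edges = topology.edges
    Ga = topology.Ga

    def make_rhs(tables, Is_now):
        def rhs(t, y):
            Q = y[:n]
            gates = y[n : n + n * ng].reshape(ng, n)
            eff = tables.interp_all(Q)
            Vm = eff["V"]
            if nxs:
                Vx = y[n + n * ng :]
            dQ = Is_now - _total_current(mem, Vm, gates)
            if has_axial:
                ax = np.zeros(n)
                Vi = Vm + (Vx if nxs else 0.0)
                dv = Vi[edges[:, 0]] - Vi[edges[:, 1]]
                np.add.at(ax, edges[:, 1], Ga * dv)
                np.add.at(ax, edges[:, 0], -Ga * dv)
                dQ = dQ + ax * inv_Am
            out = [dQ]
            for g, gate in enumerate(mem.gates):
                al = eff[f"alpha_{gate}"]
                be = eff[f"beta_{gate}"]
                out.append(al * (1.0 - gates[g]) - be * gates[g])
            if nxs:
                Iion = _total_current(mem, Vm, gates)
                dVx = dQ + Iion - topology.gx * Vx + topology.gx * topology.phi_e
                if len(edges):
                    axp = np.zeros(n)
                    dvx = Vx[edges[:, 0]] - Vx[edges[:, 1]]
                    np.add.at(axp, edges[:, 1], topology.Gp * dvx)
                    np.add.at(axp, edges[:, 0], -topology.Gp * dvx)
                    dVx = dVx + axp * inv_Am
                out.append(dVx / topology.Cx)
            return np.concatenate(out)

        return rhs

    spar = _jac_sparsity(topology, ng) if method == "BDF" and n > 1 else None
    atol = np.concatenate([np.full(n, atol_Q), np.full(n * ng, 1e-6), np.full(nxs, 1e-6)])

    ts, Qs, Xs, Ls, VXs = [], [], [], [], []
    events = []
    y = np.asarray(y0, dtype=float)
    for (t0, t1, level) in segments:
        if t1 <= t0:
            continue
        tables = source.tables_for(level)
        rhs = make_rhs(tables, level * Is_profile)
        t_eval = t0 + np.arange(int((t1 - t0) / dt_out) + 1) * dt_out
        t_eval = t_eval[t_eval < t1 - 1e-12 * max(1.0, abs(t1))]
        t_eval = np.append(t_eval, t1)
        if ts:  # avoid duplicating the shared boundary sample
            t_eval = t_eval[1:] if len(t_eval) > 1 else t_eval
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac_sparsity=spar,
        )
        if not sol.success:
            raise SolverFailure(
                f"effective integration failed at t={sol.t[-1] if len(sol.t) else t0!r} s "
                f"(segment level {level!r}): {sol.message}; state snapshot: {y!r}"
            )
        y = sol.y[:, -1].copy()
        ts.append(sol.t)
        Qs.append(sol.y[:n].T)
        if ng:
            Xs.append(sol.y[n : n + n * ng].T.reshape(-1, ng, n).transpose(0, 2, 1))
        else:
            Xs.append(np.zeros((len(sol.t), n, 0)))
        VXs.append(sol.y[n + n * ng :].T if nxs else None)
        Ls.append(np.full(len(sol.t), level))
        events.append((t0, f"level={level}"))

    t = np.concatenate(ts)
    Qm = np.vstack(Qs)
    gates = np.concatenate(Xs, axis=0)
    level_t = np.concatenate(Ls)
    # effective voltage/capacitance along the trace
    Vm = np.empty_like(Qm)
    Cm_star = np.empty_like(Qm)
    for lev in np.unique(level_t):
        tabs = source.tables_for(lev)
        mask = level_t == lev
        for i in np.where(mask)[0]:
            eff = tabs.interp_all(Qm[i])
            Vm[i] = eff["V"]
            Cm_star[i] = eff["Cm"]
    return CableTrace(
        t=t,
        Qm=Qm,
        gates=gates,
        level=level_t,
        Vm=Vm,
        Cm_star=Cm_star,
        Vx=np.vstack(VXs) if nxs else None,
        topology=topology,
        events=events,
    )


def _total_current(mem, Vm, gates_gn):
    """Net ionic current with gates supplied as (n_gates, n) array."""
    if gates_gn.shape[0]:
        g = np.moveaxis(gates_gn, 0, -1)
    else:
        g = np.empty(Vm.shape + (0,))
    return mem.i_total(Vm, g)


# ----------------------------------------------------------------------------
# Detailed (NICE) integration for benchmark-scale models
# ----------------------------------------------------------------------------

# membrane kind codes for the compiled kernel
_KIND_PASSIVE, _KIND_FH, _KIND_SUNDT = 0, 1, 2


@njit(cache=True)
def _fh_rates_kernel(V, q10):
    """FH gate rates at absolute voltage V (V); returns 8-vector (1/s)."""
    v = (V + 70e-3) * 1e3
    out = np.empty(8)

    def trap(x, k):
        if abs(x) < 1e-7 * k:
            return k * (1.0 + x / (2.0 * k))
        ex = x / k
        if ex < -500.0:
            ex = -500.0
        return x / (1.0 - math.exp(-ex))

    out[0] = 0.36 * trap(v - 22.0, 3.0)
    out[1] = 0.4 * trap(13.0 - v, 20.0)
    out[2] = 0.1 * trap(-10.0 - v, 6.0)
    out[3] = 4.5 / (1.0 + math.exp((45.0 - v) / 10.0))
    out[4] = 0.02 * trap(v - 35.0, 10.0)
    out[5] = 0.05 * trap(10.0 - v, 10.0)
    out[6] = 0.006 * trap(v - 40.0, 10.0)
    out[7] = 0.09 * trap(-25.0 - v, 20.0)
    for i in range(8):
        out[i] *= 1e3 * q10
    return out


@njit(cache=True)
def _ghk_kernel(P, c_in, c_out, V):
    u = 96485.0 * V / (8.314 * 309.15)
    if u > 500.0:
        u = 500.0
    if u < -500.0:
        u = -500.0
    eu = math.exp(-u)
    if abs(u) < 1e-9:
        frac = 1.0 + u / 2.0
    else:
        frac = u / (1.0 - eu)
    return P * 96485.0 * frac * (c_in - c_out * eu)


@njit(cache=True)
def _sundt_rates_kernel(V, q10_na, na_m_shift):
    """Sundt gate rates at absolute voltage V (V); returns 6-vector (1/s)."""
    u = (V - na_m_shift) * 1e3
    uh = V * 1e3 - 10.0  # inactivation shift (+10 mV absolute)
    v = V * 1e3
    out = np.empty(6)

    def trap(x, k):
        if abs(x) < 1e-7 * k:
            return k * (1.0 + x / (2.0 * k))
        ex = x / k
        if ex < -500.0:
            ex = -500.0
        return x / (1.0 - math.exp(-ex))

    kna = 1e3 * q10_na
    out[0] = 0.1 * trap(u + 40.0, 10.0) * kna
    e0 = (u + 65.0) / 18.0
    if e0 > 500.0:
        e0 = 500.0
    out[1] = 4.0 * math.exp(-e0) * kna
    kh = 1e3 * 3.0 ** ((36.0 - 24.0) / 10.0)
    e1 = (uh + 65.0) / 20.0
    if e1 > 500.0:
        e1 = 500.0
    out[2] = 0.07 * math.exp(-e1) * kh
    out[3] = 1.0 / (1.0 + math.exp(-(uh + 35.0) / 10.0)) * kh
    # Borg-Graham delayed rectifier (vhalf 13 mV, zeta -3, gamma 0.7, a0 0.02/ms)
    w = -3.0 * (v - 13.0) * 96485.0 / (8.314 * 309.15) * 1e-3
    if w > 500.0:
        w = 500.0
    elif w < -500.0:
        w = -500.0
    alp = math.exp(w)
    bet = math.exp(0.7 * w)
    ninf = 1.0 / (1.0 + alp)
    qt = 3.0 ** ((36.0 - 24.0) / 10.0)
    taun = bet / (0.1 * (1.0 + alp)) / qt  # ms
    if taun < 0.1:
        taun = 0.1
    out[4] = ninf / taun * 1e3
    out[5] = (1.0 - ninf) / taun * 1e3
    return out


@njit(cache=True)
def _iion_kernel(kind, V, gates, mp):
    """Net ionic current (A/m^2).  mp packs membrane parameters:

    passive: [gLeak, ELeak]
    fh:      [gLeak, ELeak, P_Na, P_K, P_P, Na_in, Na_out, K_in, K_out]
    sundt:   [gLeak, ELeak, gNa, gKd, ENa, EK]
    """
    i = mp[0] * (V - mp[1])
    if kind == _KIND_FH:
        m = gates[0]
        h = gates[1]
        nn = gates[2]
        p = gates[3]
        i += m * m * h * _ghk_kernel(mp[2], mp[5], mp[6], V)
        i += nn * nn * _ghk_kernel(mp[3], mp[7], mp[8], V)
        i += p * p * _ghk_kernel(mp[4], mp[5], mp[6], V)
    elif kind == _KIND_SUNDT:
        m = gates[0]
        h = gates[1]
        nn = gates[2]
        i += mp[2] * m * m * m * h * (V - mp[4])
        i += mp[3] * nn * (V - mp[5])
    return i


@njit(cache=True)
def _cm_kernel(Z, a, Delta, Cm0):
    if abs(Z) < 1e-16:
        return Cm0
    return Cm0 * (Delta / (a * a)) * (
        Z + (a * a - Z * Z - Z * Delta) / (2.0 * Z) * math.log((2.0 * Z + Delta) / Delta)
    )


@njit(cache=True)
def _nice_kernel(
    kind,
    ncomp,
    ngate,
    q10,
    VT,
    mp,
    a,
    Delta,
    Cm0,
    fs,
    A_amp,
    phase,
    f_US,
    c,
    gl_r,
    gl_w,
    Ga_over_Am,
    Z0,
    ng0,
    Q0,
    x0,
    t_on,
    t_end,
    nsteps_per_cycle,
    rec_stride,
):
    """Fixed-step IMEX integration of the coupled mechanical-electrical system.

    Mechanics per compartment: (Z, U, ng) as in the single-sonophore kernel;
    electrics: charge density Qm and gates following the instantaneous
    fs-weighted capacitance voltage; intracellular axial coupling between
    consecutive compartments via Ga_over_Am (S/m^2-style, current density
    per volt).  The drive is on for t < t_on and off afterwards.
    """
    T = 1.0 / f_US
    dt = T / nsteps_per_cycle
    nt = int(t_end / dt)
    nrec = nt // rec_stride + 1
    t_rec = np.empty(nrec)
    Q_rec = np.empty((nrec, ncomp))
    Z_rec = np.empty((nrec, ncomp))
    Cm_rec = np.empty((nrec, ncomp))

    Z = Z0.copy()
    U = np.zeros(ncomp)
    ng = ng0.copy()
    Q = Q0.copy()
    gates = x0.copy()  # (ncomp, ngate)
    half_floor = -0.495 * Delta

    Vm = np.empty(ncomp)
    irec = 0
    t = 0.0
    for it in range(nt + 1):
        if it % rec_stride == 0 and irec < nrec:
            t_rec[irec] = t
            for kkk in range(ncomp):
                Q_rec[irec, kkk] = Q[kkk]
                Z_rec[irec, kkk] = Z[kkk]
                Cm_rec[irec, kkk] = fs * _cm_kernel(Z[kkk], a, Delta, Cm0) + (1.0 - fs) * Cm0
            irec += 1
        if it == nt:
            break
        on = 1.0 if t < t_on else 0.0
        # --- half step (explicit predictors, implicit damping)
        Uh = np.empty(ncomp)
        Zh = np.empty(ncomp)
        ngh = np.empty(ncomp)
        Qh = np.empty(ncomp)
        gh = np.empty((ncomp, ngate))
        for k in range(ncomp):
            Cmk = fs * _cm_kernel(Z[k], a, Delta, Cm0) + (1.0 - fs) * Cm0
            Vm[k] = Q[k] / Cmk
        for k in range(ncomp):
            drive = on * A_amp[k]
            tt = t + phase[k] / (2.0 * math.pi * f_US)
            a1, lam1, g1 = _mech_rhs_terms(Z[k], U[k], ng[k], Q[k], tt, a, Delta, drive, f_US, c, gl_r, gl_w)
            Uh[k] = (U[k] + 0.5 * dt * a1) / (1.0 + 0.5 * dt * lam1)
            Zh[k] = Z[k] + 0.5 * dt * Uh[k]
            if Zh[k] < half_floor:
                Zh[k] = half_floor
            ngh[k] = ng[k] + 0.5 * dt * g1
            iion = _iion_kernel(kind, Vm[k], gates[k], mp)
            ax = 0.0
            if ncomp == 2:
                ax = Ga_over_Am * (Vm[1 - k] - Vm[k])
            Qh[k] = Q[k] + 0.5 * dt * (ax - iion)
            if ngate > 0:
                if kind == _KIND_FH:
                    r = _fh_rates_kernel(Vm[k], q10)
                else:
                    r = _sundt_rates_kernel(Vm[k], q10, VT)
                for g in range(ngate):
                    gh[k, g] = gates[k, g] + 0.5 * dt * (r[2 * g] * (1.0 - gates[k, g]) - r[2 * g + 1] * gates[k, g])
                    if gh[k, g] < 0.0:
                        gh[k, g] = 0.0
                    elif gh[k, g] > 1.0:
                        gh[k, g] = 1.0
        # --- full step (midpoint)
        Vmh = np.empty(ncomp)
        for k in range(ncomp):
            Cmk = fs * _cm_kernel(Zh[k], a, Delta, Cm0) + (1.0 - fs) * Cm0
            Vmh[k] = Qh[k] / Cmk
        th = t + 0.5 * dt
        on_h = 1.0 if th < t_on else 0.0
        for k in range(ncomp):
            drive = on_h * A_amp[k]
            tt = th + phase[k] / (2.0 * math.pi * f_US)
            a2, lam2, g2 = _mech_rhs_terms(Zh[k], Uh[k], ngh[k], Qh[k], tt, a, Delta, drive, f_US, c, gl_r, gl_w)
            Un = (U[k] * (1.0 - 0.5 * dt * lam2) + dt * a2) / (1.0 + 0.5 * dt * lam2)
            Z[k] = Z[k] + dt * 0.5 * (U[k] + Un)
            if Z[k] < half_floor:
                Z[k] = half_floor
                if Un < 0.0:
                    Un = 0.0
            U[k] = Un
            ng[k] = ng[k] + dt * g2
            iion = _iion_kernel(kind, Vmh[k], gh[k], mp)
            ax = 0.0
            if ncomp == 2:
                ax = Ga_over_Am * (Vmh[1 - k] - Vmh[k])
            Q[k] = Q[k] + dt * (ax - iion)
            if ngate > 0:
                if kind == _KIND_FH:
                    r = _fh_rates_kernel(Vmh[k], q10)
                else:
                    r = _sundt_rates_kernel(Vmh[k], q10, VT)
                for g in range(ngate):
                    gates[k, g] = gates[k, g] + dt * (r[2 * g] * (1.0 - gh[k, g]) - r[2 * g + 1] * gh[k, g])
                    if gates[k, g] < 0.0:
                        gates[k, g] = 0.0
                    elif gates[k, g] > 1.0:
                        gates[k, g] = 1.0
        t += dt
        for k in range(ncomp):
            if not (Q[k] == Q[k]) or not (Z[k] == Z[k]):
                return t_rec[:irec], Q_rec[:irec], Z_rec[:irec], Cm_rec[:irec], -1
    return t_rec[:irec], Q_rec[:irec], Z_rec[:irec], Cm_rec[:irec], 0


def _membrane_kernel_params(mem: Membrane):
    if isinstance(mem, PassiveMembrane):
        return _KIND_PASSIVE, np.array([mem.gLeak, mem.ELeak]), 0, 1.0, 0.0
    if isinstance(mem, FrankenhaeuserHuxleyNode):
        mp = np.array(
            [mem.gLeak, mem.ELeak, mem.P_Na, mem.P_K, mem.P_P, mem.Na_in, mem.Na_out, mem.K_in, mem.K_out]
        )
        return _KIND_FH, mp, 4, mem.q10_factor, 0.0
    if isinstance(mem, SundtSegment):
        mp = np.array([mem.gLeak, mem.ELeak, mem.gNa_bar, mem.gKd_bar, mem.ENa, mem.EK])
        return _KIND_SUNDT, mp, 3, mem.q10_factor, mem.na_m_shift
    raise TypeError(f"no detailed kernel for membrane {mem!r}")


@dataclass
class NiceTrace:
    """Cycle-resolved detailed trace plus its per-cycle average."""

    t: np.ndarray
    Qm: np.ndarray  # (nt, n)
    Z: np.ndarray
    Cm_fs: np.ndarray
    f_US: float

    def cycle_averaged(self):
        """Non-overlapping averages over exactly one acoustic period."""
        T = 1.0 / self.f_US
        dt = self.t[1] - self.t[0]
        per = max(1, int(round(T / dt)))
        nwin = len(self.t) // per
        tc = self.t[: nwin * per].reshape(nwin, per).mean(axis=1)
        qc = self.Qm[: nwin * per].reshape(nwin, per, -1).mean(axis=1)
        return tc, qc


def integrate_nice_detailed(
    topology: CableTopology,
    A_amp,
    t_end: float,
    f_US: float = 500e3,
    a: float = 32e-9,
    fs: float = 0.8,
    phase=None,
    t_on: float = None,
    consts: BLSConstants = None,
    nsteps_per_cycle: int = 1000,
    rec_stride: int = 25,
) -> NiceTrace:
    """Temporally detailed (cycle-resolved) integration of 1-2 compartments.

    Fully couples the sonophore mechanics of each compartment to its
    charge-casted membrane electrics at a fixed step of
    ``1/(f_US * nsteps_per_cycle)``; emits the raw charge trace (use
    :meth:`NiceTrace.cycle_averaged` for the per-cycle mean).
    """
    if topology.n > 2:
        raise ValueError("detailed integration supports at most 2 compartments")
    if topology.double_cable:
        raise ValueError("detailed integration supports single-cable benchmarks only")
    consts = consts or BLSConstants()
    mem = topology.membrane
    kind, mp, ngate, q10, VT = _membrane_kernel_params(mem)
    n = topology.n
    A_amp = np.broadcast_to(np.asarray(A_amp, dtype=float), (n,)).copy()
    phase = np.zeros(n) if phase is None else np.broadcast_to(np.asarray(phase, dtype=float), (n,)).copy()
    t_on = t_end if t_on is None else t_on
    Delta = equilibrium_gap(mem.Qm0, consts)
    ng0v = resting_gas_content(a, Delta, consts)
    Q0, x0 = mem.resting_state()
    x0 = np.tile(np.atleast_1d(np.asarray(x0, dtype=float)), (n, 1)) if ngate else np.zeros((n, 0))
    amax = float(np.max(A_amp))
    nspc = int(nsteps_per_cycle * min(8, max(1, math.ceil(amax / 1e5))))
    Z0 = np.empty(n)
    for k in range(n):
        if A_amp[k] == 0.0:
            Z0[k] = 0.0
        else:
            pa = -A_amp[k] * math.sin(2.0 * math.pi * f_US * (1.0 / (f_US * nspc)) + phase[k])
            Z0[k] = quasistatic_deflection(a, Delta, ng0v, Q0, pa, consts)
    Ga_over_Am = float(topology.Ga[0] / topology.Am[0]) if len(topology.Ga) else 0.0
    c = _consts_tuple(consts)
    gl_r = 0.5 * a * (_GL_NODES + 1.0)
    gl_w = 0.5 * a * _GL_WEIGHTS
    t_rec, Q_rec, Z_rec, Cm_rec, status = _nice_kernel(
        kind,
        n,
        ngate,
        q10,
        VT,
        mp,
        a,
        Delta,
        mem.Cm0,
        fs,
        A_amp,
        phase,
        f_US,
        c,
        gl_r,
        gl_w,
        Ga_over_Am,
        Z0,
        np.full(n, ng0v),
        np.full(n, Q0),
        x0,
        t_on,
        t_end,
        nspc,
        rec_stride,
    )
    if status != 0:
        raise SolverFailure(
            f"detailed integration diverged (NaN) near t={t_rec[-1] if len(t_rec) else 0.0!r} s "
            f"for A={A_amp!r}, f_US={f_US!r}"
        )
    return NiceTrace(t=t_rec, Qm=Q_rec, Z=Z_rec, Cm_fs=Cm_rec, f_US=f_US)
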