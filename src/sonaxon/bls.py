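"""Mechanics of a single bilayer sonophore.

This module implements the cavitating-bubble description of a bilayer
sonophore embedded in a neural membrane: a dome-shaped deflection of the
two leaflets (apex deflection ``Z``, gas content ``n_g``) driven by a
periodic acoustic pressure and restored by elastic, intermolecular,
gaseous and electric pressures.  The second-order deflection dynamics

    d2Z/dt2 = -3/(2 R(Z)) (dZ/dt)^2
              + 1/(rho_l |R(Z)|) * [P_A + P_S + P_VS - P_0 + P_VL + P_M + P_G + P_Q]

is integrated to a limit cycle, from which the intra-cycle capacitance
profile and its cycle-averaged ("effective") quantities are extracted.

Sign conventions: ``Z > 0`` is expansion (leaflets moving apart), the
acoustic drive is rarefaction-first, ``P_A(t) = -A sin(2 pi f t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import BLSConstants, EPS0, R_GAS

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


class ConvergenceError(RuntimeError):
    """Raised when a root search or limit-cycle integration fails."""


# 32-point Gauss-Legendre rule used for the radial surface integral of the
# intermolecular pressure (fixed order; the integrand is smooth on [0, a]).
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


# ----------------------------------------------------------------------------
# Geometry
# ----------------------------------------------------------------------------

def leaflet_geometry(Z, a):
    """Curvature and area of a spherical-cap leaflet.

    Parameters
    ----------
    Z : float or ndarray
        Apex deflection (m), signed.
    a : float
        In-plane sonophore radius (m).

    Returns
    -------
    inv_R : float or ndarray
        Signed curvature 1/R = 2 Z / (a^2 + Z^2) (1/m).
    S : float or ndarray
        Dome surface area pi (a^2 + Z^2) (m^2).
    """
    if a <= 0:
        raise ValueError("sonophore radius must be positive")
    Z = np.asarray(Z, dtype=float)
    inv_R = 2.0 * Z / (a * a + Z * Z)
    S = math.pi * (a * a + Z * Z)
    if Z.ndim == 0:
        return float(inv_R), float(S)
    return inv_R, S


def cavity_volume(Z, a, Delta):
    """Volume of the gas cavity between the two leaflets (m^3)."""
    return math.pi * a * a * Delta + (math.pi / 3.0) * Z * (3.0 * a * a + Z * Z)


def local_deflection(r, Z, a):
    """Deflection of the leaflet at in-plane radius ``r`` for apex deflection ``Z``.

    Spherical-cap profile: z(r) = sign(Z) (sqrt(R^2 - r^2) - |R| + |Z|),
    vanishing at the rim (r = a) and equal to Z at the apex.
    """
    r = np.asarray(r, dtype=float)
    if Z == 0.0:
        return np.zeros_like(r)
    R = (a * a + Z * Z) / (2.0 * abs(Z))
    return np.sign(Z) * (np.sqrt(R * R - r * r) - R + abs(Z))


# ----------------------------------------------------------------------------
# Capacitance
# ----------------------------------------------------------------------------

def membrane_capacitance(Z, a, Delta, Cm0):
    """Local membrane capacitance of a deflected sonophore (F/m^2).

    Planar-capacitor construction over the dome:

        Cm(Z) = Cm0 * Delta/a^2 * [ Z + (a^2 - Z^2 - Z Delta)/(2 Z)
                                      * ln((2 Z + Delta)/Delta) ]

    continuous at Z = 0 with limit Cm0.

    Raises
    ------
    ValueError
        If ``2 Z + Delta <= 0`` (leaflet interpenetration).
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(2.0 * Z + Delta <= 0.0):
        raise ValueError("leaflet interpenetration: 2Z + Delta <= 0")
    scalar = Z.ndim == 0
    Z = np.atleast_1d(Z)
    out = np.empty_like(Z)
    small = np.abs(Z) < 1e-16
    out[small] = Cm0
    Znz = Z[~small]
    out[~small] = (
        Cm0
        * (Delta / (a * a))
        * (Znz + (a * a - Znz * Znz - Znz * Delta) / (2.0 * Znz) * np.log((2.0 * Znz + Delta) / Delta))
    )
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------------------
# Pressure terms
# ----------------------------------------------------------------------------

@dataclass
class SonophoreState:
    """Instantaneous state of one sonophore."""

    a: float  # radius (m)
    Z: float  # apex deflection (m)
    dZdt: float  # apex velocity (m/s)
    n_g: float  # gas content (mol)
    Qm: float  # membrane charge density (C/m^2)
    Delta: float  # resting inter-leaflet gap at the membrane's resting charge (m)

    def __post_init__(self):
        if self.a <= 0 or self.n_g <= 0:
            raise ValueError("require a > 0 and n_g > 0")
        if self.Z <= -self.Delta / 2.0:
            raise ValueError("leaflet interpenetration: Z <= -Delta/2")


@dataclass
class PressureBreakdown:
    """All pressure terms acting on the leaflets (Pa)."""

    P_A: float
    P_S: float
    P_M: float
    P_G: float
    P_Q: float
    P_VS: float
    P_VL: float

    @property
    def total(self) -> float:
        return self.P_A + self.P_S + self.P_M + self.P_G + self.P_Q + self.P_VS + self.P_VL


def elastic_pressure(Z, a, k_s):
    """Leaflet tension pressure -4 k_s Z^3 / (a^2 (a^2 + Z^2)) (restoring)."""
    return -4.0 * k_s * Z ** 3 / (a * a * (a * a + Z * Z))


def electric_pressure(Z, Qm, a, consts: BLSConstants):
    """Electric (Maxwell) attraction pressure P_Q = -(S0/S) Qm^2 / (2 eps0 eps_r)."""
    S0_over_S = a * a / (a * a + np.asarray(Z, dtype=float) ** 2)
    return -S0_over_S * Qm * Qm / (2.0 * EPS0 * consts.eps_r)


def gas_pressure(Z, n_g, a, Delta, consts: BLSConstants):
    """Internal gas pressure n_g R T / V(Z)."""
    return n_g * R_GAS * consts.T_abs / cavity_volume(Z, a, Delta)


def molecular_pressure(Z, a, Delta, consts: BLSConstants):
    """Intermolecular (Lennard-Jones) pressure averaged over the dome surface.

    P_M(Z) = 1/S(Z) * int_0^a A_r [ (D*/d(r))^x - (D*/d(r))^y ] 2 pi r dr
    with local leaflet separation d(r) = 2 z(r) + Delta.
    """
    Z = float(Z)
    r = 0.5 * a * (_GL_NODES + 1.0)
    w = 0.5 * a * _GL_WEIGHTS
    z = local_deflection(r, Z, a)
    d = 2.0 * z + Delta
    if np.any(d <= 0.0):
        raise ValueError("leaflet interpenetration in molecular pressure integrand")
    g = consts.delta_star / d
    integrand = consts.A_r * (g ** consts.lj_x - g ** consts.lj_y) * 2.0 * math.pi * r
    _, S = leaflet_geometry(Z, a)
    return float(np.sum(w * integrand) / S)


def molecular_pressure_flat(gap, consts: BLSConstants):
    """Flat-configuration intermolecular pressure at uniform leaflet separation."""
    g = consts.delta_star / np.asarray(gap, dtype=float)
    return consts.A_r * (g ** consts.lj_x - g ** consts.lj_y)


def leaflet_viscous_pressure(Z, dZdt, a, consts: BLSConstants):
    """Viscous stress in the leaflets, -12 mu_s d_leaflet dZdt / R^2."""
    inv_R, _ = leaflet_geometry(Z, a)
    return -12.0 * consts.mu_s * consts.d_leaflet * dZdt * inv_R * inv_R


def liquid_viscous_pressure(Z, dZdt, a, consts: BLSConstants):
    """Viscous drag of the surrounding liquid, -4 mu_l dZdt / |R|."""
    inv_R, _ = leaflet_geometry(Z, a)
    return -4.0 * consts.mu_l * dZdt * abs(inv_R)


def pressure_components(state: SonophoreState, consts: BLSConstants, P_A: float = 0.0) -> PressureBreakdown:
    """Evaluate every pressure term for a given sonophore state."""
    return PressureBreakdown(
        P_A=P_A,
        P_S=elastic_pressure(state.Z, state.a, consts.k_s),
        P_M=molecular_pressure(state.Z, state.a, state.Delta, consts),
        P_G=gas_pressure(state.Z, state.n_g, state.a, state.Delta, consts),
        P_Q=float(electric_pressure(state.Z, state.Qm, state.a, consts)),
        P_VS=leaflet_viscous_pressure(state.Z, state.dZdt, state.a, consts),
        P_VL=liquid_viscous_pressure(state.Z, state.dZdt, state.a, consts),
    )


def resting_gas_content(a, Delta, consts: BLSConstants):
    """Gas content that equilibrates the cavity at P_G = P_0 with Z = 0 (mol)."""
    return consts.P_0 * cavity_volume(0.0, a, Delta) / (R_GAS * consts.T_abs)


# ----------------------------------------------------------------------------
# Equilibrium gap
# ----------------------------------------------------------------------------

def equilibrium_gap(Qm0: float, consts: BLSConstants) -> float:
    """Resting inter-leaflet gap Delta(Qm0) of a charged flat membrane (m).

    Solves the flat-configuration balance between the repulsive-attractive
    intermolecular pressure and the electric attraction pressure:

        A_r [ (D*/Delta)^x - (D*/Delta)^y ] = Qm0^2 / (2 eps0 eps_r)

    The root is unique on (0, D*]; it equals D* for an uncharged membrane
    and decreases with |Qm0|.
    """
    rhs = Qm0 * Qm0 / (2.0 * EPS0 * consts.eps_r)

    def f(u):  # u = delta_star / Delta >= 1
        return consts.A_r * (u ** consts.lj_x - u ** consts.lj_y) - rhs

    if rhs == 0.0:
        return consts.delta_star
    u_hi = 2.0
    while f(u_hi) < 0.0:
        u_hi *= 2.0
        if u_hi > 1e6:
            raise ConvergenceError(
                f"no equilibrium gap in bracket for Qm0={Qm0!r} C/m^2 "
                "(electric pressure exceeds the intermolecular repulsion range)"
            )
    u = brentq(f, 1.0, u_hi, xtol=1e-12, rtol=1e-14)
    return consts.delta_star / u


# ----------------------------------------------------------------------------
# Cavitation cycle integration
# ----------------------------------------------------------------------------

@dataclass
class MechSolverSettings:
    """Numerical settings of the limit-cycle integrator."""

    nsteps_per_cycle: int = 1000  # base temporal resolution (paper-style 1e-3/f)
    max_cycles: int = 10000
    cycle_rtol: float = 1e-5  # relative RMS change between consecutive cycles
    amp_refine_ref: float = 1.0e5  # Pa; step count scales with drive amplitude
    max_refine: int = 8


@dataclass
class CycleProfile:
    """Converged last-cycle profiles of one sonophore drive condition."""

    t: np.ndarray  # sample times within one acoustic period (s)
    Z_t: np.ndarray  # deflection samples (m)
    Cm_t: np.ndarray  # local capacitance samples (F/m^2)
    n_cycles_to_converge: int
    ng_t: np.ndarray = field(default=None, repr=False)
    U_t: np.ndarray = field(default=None, repr=False)
    converged: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.t, "Z_m": self.Z_t, "Cm_F_per_m2": self.Cm_t})


def _consts_tuple(consts: BLSConstants):
    return (
        consts.rho_l,
        consts.mu_l,
        consts.mu_s,
        consts.d_leaflet,
        consts.D_gl,
        consts.xi,
        consts.C_g,
        consts.k_H,
        consts.P_0,
        consts.k_s,
        consts.A_r,
        consts.lj_x,
        consts.lj_y,
        consts.delta_star,
        consts.eps_r,
        consts.T_abs,
    )


@njit(cache=True)
def _pm_avg_kernel(Z, a, Delta, A_r, lj_x, lj_y, delta_star, gl_r, gl_w):
    """Dome-averaged intermolecular pressure (numba-compiled inner loop)."""
    S = math.pi * (a * a + Z * Z)
    tot = 0.0
    if Z == 0.0:
        for i in range(gl_r.shape[0]):
            r = gl_r[i]
            g = delta_star / Delta
            tot += gl_w[i] * A_r * (g ** lj_x - g ** lj_y) * 2.0 * math.pi * r
    else:
        R = (a * a + Z * Z) / (2.0 * abs(Z))
        sgn = 1.0 if Z > 0.0 else -1.0
        for i in range(gl_r.shape[0]):
            r = gl_r[i]
            z = sgn * (math.sqrt(R * R - r * r) - R + abs(Z))
            d = 2.0 * z + Delta
            if d < 1e-12 * delta_star:
                d = 1e-12 * delta_star
            g = delta_star / d
            tot += gl_w[i] * A_r * (g ** lj_x - g ** lj_y) * 2.0 * math.pi * r
    return tot / S


@njit(cache=True)
def _mech_rhs_terms(Z, U, ng, Qm, t, a, Delta, A_drive, f_US, c, gl_r, gl_w):
    """Non-viscous acceleration, damping rate and gas flux at one state.

    Returns (accel_nv, lam, dng) where dU/dt = accel_nv - lam * U.
    """
    (rho_l, mu_l, mu_s, d_leaflet, D_gl, xi, C_g, k_H, P_0, k_s, A_r, lj_x, lj_y, delta_star, eps_r, T_abs) = c
    a2 = a * a
    inv_R = 2.0 * Z / (a2 + Z * Z)
    abs_inv_R = abs(inv_R)
    # pressures
    P_A = -A_drive * math.sin(2.0 * math.pi * f_US * t)
    P_S = -4.0 * k_s * Z * Z * Z / (a2 * (a2 + Z * Z))
    P_M = _pm_avg_kernel(Z, a, Delta, A_r, lj_x, lj_y, delta_star, gl_r, gl_w)
    V = math.pi * a2 * Delta + (math.pi / 3.0) * Z * (3.0 * a2 + Z * Z)
    P_G = ng * 8.314 * T_abs / V
    P_Q = -(a2 / (a2 + Z * Z)) * Qm * Qm / (2.0 * 8.854e-12 * eps_r)
    P_sum = P_A + P_S + P_M + P_G + P_Q - P_0
    accel_nv = -1.5 * inv_R * U * U + (abs_inv_R / rho_l) * P_sum
    lam = (12.0 * mu_s * d_leaflet * inv_R * inv_R + 4.0 * mu_l * abs_inv_R) * abs_inv_R / rho_l
    # gas flux
    S = math.pi * (a2 + Z * Z)
    dng = 2.0 * S * D_gl / xi * (C_g - P_G / k_H)
    return accel_nv, lam, dng


@njit(cache=True)
def _run_cycles(Z0, U0, ng0, Qm, a, Delta, A_drive, f_US, c, gl_r, gl_w, nsteps, max_cycles, rtol):
    """Integrate the sonophore ODE cycle-by-cycle to a limit cycle.

    Second-order IMEX midpoint scheme: the viscous damping (stiff, linear in
    the velocity) is treated with a trapezoidal implicit update, everything
    else explicitly at the midpoint.

    Returns (Z_samples, ng_samples, U_samples, n_cycles, converged).
    """
    T = 1.0 / f_US
    dt = T / nsteps
    half_floor = -0.495 * Delta
    Z = Z0
    U = U0
    ng = ng0
    Zs = np.empty(nsteps)
    ngs = np.empty(nsteps)
    Us = np.empty(nsteps)
    Zp = np.empty(nsteps)
    ngp = np.empty(nsteps)
    n_cycles = 0
    converged = False
    t = 0.0
    for cyc in range(max_cycles):
        for i in range(nsteps):
            Zs[i] = Z
            ngs[i] = ng
            Us[i] = U
            a1, lam1, g1 = _mech_rhs_terms(Z, U, ng, Qm, t, a, Delta, A_drive, f_US, c, gl_r, gl_w)
            Uh = (U + 0.5 * dt * a1) / (1.0 + 0.5 * dt * lam1)
            Zh = Z + 0.5 * dt * Uh
            if Zh < half_floor:
                Zh = half_floor
            ngh = ng + 0.5 * dt * g1
            a2_, lam2, g2 = _mech_rhs_terms(Zh, Uh, ngh, Qm, t + 0.5 * dt, a, Delta, A_drive, f_US, c, gl_r, gl_w)
            Un = (U * (1.0 - 0.5 * dt * lam2) + dt * a2_) / (1.0 + 0.5 * dt * lam2)
            Z = Z + dt * 0.5 * (U + Un)
            if Z < half_floor:
                Z = half_floor
                if Un < 0.0:
                    Un = 0.0
            ng = ng + dt * g2
            U = Un
            t += dt
        n_cycles = cyc + 1
        if cyc > 0:
            # relative RMS change of the sampled (Z, ng) trajectories
            sz = 0.0
            sn = 0.0
            zscale = 1e-12
            for i in range(nsteps):
                dz = Zs[i] - Zp[i]
                sz += dz * dz
                dn = ngs[i] - ngp[i]
                sn += dn * dn
                if abs(Zs[i]) > zscale:
                    zscale = abs(Zs[i])
            rms_z = math.sqrt(sz / nsteps) / zscale
            rms_n = math.sqrt(sn / nsteps) / ng0
            if rms_z < rtol and rms_n < rtol:
                converged = True
                break
        for i in range(nsteps):
            Zp[i] = Zs[i]
            ngp[i] = ngs[i]
    return Zs, ngs, Us, n_cycles, converged


def quasistatic_deflection(a, Delta, ng, Qm, P_A, consts: BLSConstants):
    """Static-balance deflection for a constant drive pressure (m)."""

    def f(Z):
        return (
            P_A
            + elastic_pressure(Z, a, consts.k_s)
            + molecular_pressure(Z, a, Delta, consts)
            + gas_pressure(Z, ng, a, Delta, consts)
            + float(electric_pressure(Z, Qm, a, consts))
            - consts.P_0
        )

    lo = -0.49 * Delta
    hi = a
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ConvergenceError("no quasi-static deflection root in bracket")
    return brentq(f, lo, hi, xtol=1e-16)


def cavitation_cycle(
    a: float,
    f_US: float,
    A: float,
    Qm: float,
    consts: BLSConstants,
    Delta: float = None,
    Cm0: float = 1e-2,
    Qm0: float = None,
    settings: MechSolverSettings = None,
) -> CycleProfile:
    """Drive one sonophore to its limit cycle and return last-cycle profiles.

    Parameters
    ----------
    a : float
        Sonophore radius (m).
    f_US : float
        Acoustic carrier frequency (Hz).
    A : float
        Acoustic pressure amplitude (Pa); drive is P_A(t) = -A sin(2 pi f t).
    Qm : float
        Membrane charge density held fixed over the cycle (C/m^2).
    consts : BLSConstants
    Delta : float, optional
        Resting inter-leaflet gap; computed from ``Qm0`` (or ``Qm``) via
        :func:`equilibrium_gap` when omitted.
    Cm0 : float
        Resting specific capacitance (F/m^2), scaling the Cm(Z) profile.
    Qm0 : float, optional
        Resting charge density defining the gap when ``Delta`` is omitted.
    """
    if f_US <= 0:
        raise ValueError("f_US must be positive")
    if A < 0:
        raise ValueError("amplitude must be non-negative")
    settings = settings or MechSolverSettings()
    if Delta is None:
        Delta = equilibrium_gap(Qm if Qm0 is None else Qm0, consts)
    nref = int(min(settings.max_refine, max(1, math.ceil(A / settings.amp_refine_ref))))
    nsteps = settings.nsteps_per_cycle * nref
    T = 1.0 / f_US
    t = np.arange(nsteps) * (T / nsteps)
    if A == 0.0:
        Z = np.zeros(nsteps)
        return CycleProfile(
            t=t,
            Z_t=Z,
            Cm_t=np.full(nsteps, Cm0),
            n_cycles_to_converge=0,
            ng_t=np.full(nsteps, resting_gas_content(a, Delta, consts)),
            U_t=np.zeros(nsteps),
        )
    ng0 = resting_gas_content(a, Delta, consts)
    # small quasi-static kick to leave the degenerate flat state
    P_A_first = -A * math.sin(2.0 * math.pi * f_US * (T / nsteps))
    Z0 = quasistatic_deflection(a, Delta, ng0, Qm, P_A_first, consts)
    c = _consts_tuple(consts)
    gl_r = 0.5 * a * (_GL_NODES + 1.0)
    gl_w = 0.5 * a * _GL_WEIGHTS
    Zs, ngs, Us, n_cycles, converged = _run_cycles(
        Z0, 0.0, ng0, Qm, a, Delta, A, f_US, c, gl_r, gl_w, nsteps, settings.max_cycles, settings.cycle_rtol
    )
    if not converged:
        raise ConvergenceError(
            f"no limit cycle within {settings.max_cycles} cycles "
            f"(a={a!r}, f_US={f_US!r}, A={A!r}, Qm={Qm!r})"
        )
    Cm_t = membrane_capacitance(Zs, a, Delta, Cm0)
    return CycleProfile(t=t, Z_t=Zs, Cm_t=Cm_t, n_cycles_to_converge=n_cycles, ng_t=ngs, U_t=Us)


# ----------------------------------------------------------------------------
# Cycle-averaged (effective) variables
# ----------------------------------------------------------------------------

@dataclass
class EffectiveVariables:
    """Cycle-averaged electrical variables for one (drive, charge) condition."""

    Vm_star: float  # effective transmembrane potential (V)
    Cm_star: float  # effective (harmonic-mean) capacitance (F/m^2)
    alpha_star: dict  # per-gate effective forward rates (1/s)
    beta_star: dict  # per-gate effective backward rates (1/s)


def coverage_weighted_capacitance(Cm_t, fs, Cm0):
    """fs-weighted macroscale capacitance fs*Cm(t) + (1 - fs)*Cm0."""
    if not 0.0 <= fs <= 1.0:
        raise ValueError("coverage fraction must lie in [0, 1]")
    return fs * np.asarray(Cm_t, dtype=float) + (1.0 - fs) * Cm0


def effective_cycle_averages(profile: CycleProfile, Qm: float, fs: float, membrane) -> EffectiveVariables:
    """Cycle averages of voltage, capacitance and gating rates.

    ``Vm*`` is the plain cycle mean of ``Qm / Cm_fs(t)``, ``Cm*`` the harmonic
    cycle mean of the fs-weighted capacitance (so that ``Vm* = Qm / Cm*``
    exactly for fixed charge), and the rate constants are cycle means of the
    membrane's voltage-dependent rates evaluated along the oscillating
    voltage profile.
    """
    Cm_fs = coverage_weighted_capacitance(profile.Cm_t, fs, membrane.Cm0)
    inv_mean = float(np.mean(1.0 / Cm_fs))
    Vm_t = Qm / Cm_fs
    alpha = {}
    beta = {}
    for gate in membrane.gates:
        al, be = membrane.rates(gate, Vm_t)
        alpha[gate] = float(np.mean(al))
        beta[gate] = float(np.mean(be))
    return EffectiveVariables(
        Vm_star=float(np.mean(Vm_t)),
        Cm_star=1.0 / inv_mean,
        alpha_star=alpha,
        beta_star=beta,
    )


# ----------------------------------------------------------------------------
# Reference (oracle-grade) integrator
# ----------------------------------------------------------------------------

def cavitation_cycle_reference(a, f_US, A, Qm, consts, Delta=None, Cm0=1e-2, Qm0=None, n_samples=1000, max_cycles=200, rtol=1e-4):
    """Adaptive stiff-solver version of :func:`cavitation_cycle`.

    Uses scipy's LSODA with tight tolerances; an order of magnitude slower
    than the fixed-step kernel, intended for cross-validation.
    """
    from scipy.integrate import solve_ivp

    if Delta is None:
        Delta = equilibrium_gap(Qm if Qm0 is None else Qm0, consts)
    ng0 = resting_gas_content(a, Delta, consts)
    T = 1.0 / f_US
    t_samp = np.linspace(0.0, T, n_samples, endpoint=False)
    if A == 0.0:
        return CycleProfile(t=t_samp, Z_t=np.zeros(n_samples), Cm_t=np.full(n_samples, Cm0), n_cycles_to_converge=0)

    def rhs(t, y):
        Z, U, ng = y
        Z = max(Z, -0.495 * Delta)
        inv_R, S = leaflet_geometry(Z, a)
        P = (
            -A * math.sin(2.0 * math.pi * f_US * t)
            + elastic_pressure(Z, a, consts.k_s)
            + molecular_pressure(Z, a, Delta, consts)
            + gas_pressure(Z, ng, a, Delta, consts)
            + float(electric_pressure(Z, Qm, a, consts))
            - consts.P_0
            + leaflet_viscous_pressure(Z, U, a, consts)
            + liquid_viscous_pressure(Z, U, a, consts)
        )
        dU = -1.5 * inv_R * U * U + abs(inv_R) / consts.rho_l * P
        dng = 2.0 * S * consts.D_gl / consts.xi * (consts.C_g - gas_pressure(Z, ng, a, Delta, consts) / consts.k_H)
        return [U, dU, dng]

    dt0 = T / n_samples
    Z0 = quasistatic_deflection(a, Delta, ng0, Qm, -A * math.sin(2 * math.pi * f_US * dt0), consts)
    y = [Z0, 0.0, ng0]
    prev = None
    for cyc in range(max_cycles):
        sol = solve_ivp(
            rhs,
            (cyc * T, (cyc + 1) * T),
            y,
            t_eval=cyc * T + t_samp,
            method="LSODA",
            rtol=1e-9,
            atol=[1e-16, 1e-8, 1e-28],
            max_step=T / 100,
        )
        if not sol.success:
            raise ConvergenceError(f"reference mechanical solver failed: {sol.message}")
        y = sol.y[:, -1].copy()
        Zc, ngc = sol.y[0], sol.y[2]
        if prev is not None:
            scale = max(np.max(np.abs(Zc)), 1e-12)
            if (
                np.sqrt(np.mean((Zc - prev[0]) ** 2)) / scale < rtol
                and np.sqrt(np.mean((ngc - prev[1]) ** 2)) / ng0 < rtol
            ):
                return CycleProfile(
                    t=t_samp,
                    Z_t=Zc,
                    Cm_t=membrane_capacitance(Zc, a, Delta, Cm0),
                    n_cycles_to_converge=cyc + 1,
                    ng_t=ngc,
                    U_t=sol.y[1],
                )
        prev = (Zc.copy(), ngc.copy())
    raise ConvergenceError("reference mechanical solver found no limit cycle")
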