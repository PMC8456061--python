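"""Charge-casted membrane models of peripheral axon compartments.

Three membranes are provided:

* ``senn_node`` — a Xenopus Ranvier node with the Frankenhaeuser-Huxley
  permeability (GHK-flux) formulation of the fast Na+, delayed-rectifier
  K+ and non-specific delayed (P) currents plus an ohmic leak, using the
  standard myelinated-fiber (SENN) parameter set.
* ``sundt`` — an unmyelinated C-fiber segment with Hodgkin-Huxley-style
  m3h Na+ and Borg-Graham delayed-rectifier K+ conductances and a
  high-resistance leak (Rm = 10 kOhm cm2).
* ``passive`` — a pure-leak RC membrane used by the two-compartment
  accuracy benchmarks.

All dynamics are charge-casted: the state is the membrane charge density
Qm (C/m^2) plus gating variables, and voltage is always derived as
Qm / Cm (instantaneous or effective).  Rate functions carry a Q10 = 3
temperature correction to 36 degC.  The leak reversal potential is solved
at initialization so that each model is exactly stationary at its nominal
resting potential.

Internal units are SI: V, C/m^2, F/m^2, S/m^2, A/m^2, 1/s.
"""

from __future__ import annotations

import numpy as np

from .constants import FARADAY, R_GAS

#: Simulation temperature (K); both axon models are adapted to 36 degC.
T_SIM = 309.15
T_SIM_DEGC = 36.0


def vtrap(x, k):
    """x / (1 - exp(-x/k)), with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-9 * k, k * (1.0 + x / (2.0 * k)), x / (1.0 - np.exp(-np.clip(x / k, -500, 500))))
    return out


def ghk_current(P, z, c_in, c_out, Vm):
    """Goldman-Hodgkin-Katz flux current density (A/m^2).

    Parameters: permeability P (m/s), valence z, intra/extracellular
    concentrations (mol/m^3), membrane potential Vm (V).
    """
    Vm = np.asarray(Vm, dtype=float)
    u = z * FARADAY * Vm / (R_GAS * T_SIM)  # dimensionless
    eu = np.exp(-np.clip(u, -500, 500))
    frac = np.where(np.abs(u) < 1e-9, 1.0 + u / 2.0, u / (1.0 - eu))
    return P * z * FARADAY * frac * (c_in - c_out * eu)


class Membrane:
    """Base class: fixed-capacitance membrane with gated ionic currents."""

    name: str = "membrane"
    Cm0: float = 1e-2  # F/m^2
    Vm0: float = -70e-3  # V
    gates: tuple = ()
    T_base_degC: float = 20.0
    q10: float = 3.0

    def __init__(self):
        self.ELeak = self._solve_leak_reversal()

    # -- kinetics ---------------------------------------------------------

    @property
    def q10_factor(self) -> float:
        return self.q10 ** ((T_SIM_DEGC - self.T_base_degC) / 10.0)

    def rates(self, gate, Vm):
        """Forward/backward rate constants of one gate at Vm (1/s)."""
        raise NotImplementedError

    def steady_states(self, Vm):
        """Gate steady-state values x_inf = alpha/(alpha+beta), shape (..., n_gates)."""
        Vm = np.asarray(Vm, dtype=float)
        out = np.empty(Vm.shape + (len(self.gates),))
        for i, g in enumerate(self.gates):
            al, be = self.rates(g, Vm)
            out[..., i] = al / (al + be)
        return out

    # -- currents ---------------------------------------------------------

    def gated_currents(self, Vm, gates):
        """Ionic currents other than leak, as a dict name -> A/m^2."""
        return {}

    def currents(self, Vm, gates):
        """All ionic current densities (A/m^2), leak included."""
        out = self.gated_currents(Vm, gates)
        out["leak"] = self.gLeak * (np.asarray(Vm, dtype=float) - self.ELeak)
        return out

    def i_total(self, Vm, gates):
        """Net ionic current density (A/m^2); the exact sum of the breakdown."""
        tot = 0.0
        for i in self.currents(Vm, gates).values():
            tot = tot + i
        return tot

    def _solve_leak_reversal(self):
        """Leak reversal that balances the gated currents at the resting state."""
        x0 = self.steady_states(self.Vm0)
        i_gated = 0.0
        for i in self.gated_currents(self.Vm0, x0).values():
            i_gated = i_gated + i
        return self.Vm0 + float(i_gated) / self.gLeak

    # -- resting state ----------------------------------------------------

    @property
    def Qm0(self) -> float:
        """Resting charge density Cm0 * Vm0 (C/m^2)."""
        return self.Cm0 * self.Vm0

    def resting_state(self):
        """(Qm0, gate steady-state vector) defining a stationary start."""
        return self.Qm0, self.steady_states(self.Vm0)

    def __repr__(self):
        return f"{type(self).__name__}(name={self.name!r})"


class FrankenhaeuserHuxleyNode(Membrane):
    """Amphibian Ranvier node (Frankenhaeuser-Huxley permeability model).

    Rate functions are the original 1964 set (membrane potential expressed
    relative to rest, rates in 1/ms), sped up by a Q10 of 3 from the 20 degC
    recording temperature to 36 degC.  Na+, K+ and P currents use GHK flux
    equations with the classic ionic concentrations; the leak is ohmic with
    gLeak = 30.3 mS/cm^2.
    """

    name = "senn_node"
    Cm0 = 2e-2  # F/m^2 (2 uF/cm^2)
    Vm0 = -70e-3
    gates = ("m", "h", "n", "p")
    T_base_degC = 20.0

    gLeak = 303.0  # S/m^2
    P_Na = 8e-5  # m/s
    P_K = 1.2e-5  # m/s
    P_P = 0.54e-5  # m/s
    Na_out = 114.5  # mol/m^3
    Na_in = 13.74
    K_out = 2.5
    K_in = 120.0

    def rates(self, gate, Vm):
        V = (np.asarray(Vm, dtype=float) - self.Vm0) * 1e3  # mV relative to rest
        if gate == "m":
            al = 0.36 * vtrap(V - 22.0, 3.0)
            be = 0.4 * vtrap(13.0 - V, 20.0)
        elif gate == "h":
            al = 0.1 * vtrap(-10.0 - V, 6.0)
            be = 4.5 / (1.0 + np.exp((45.0 - V) / 10.0))
        elif gate == "n":
            al = 0.02 * vtrap(V - 35.0, 10.0)
            be = 0.05 * vtrap(10.0 - V, 10.0)
        elif gate == "p":
            al = 0.006 * vtrap(V - 40.0, 10.0)
            be = 0.09 * vtrap(-25.0 - V, 20.0)
        else:
            raise KeyError(gate)
        k = 1e3 * self.q10_factor  # 1/ms -> 1/s plus temperature correction
        return al * k, be * k

    def gated_currents(self, Vm, gates):
        gates = np.asarray(gates, dtype=float)
        m, h, n, p = (gates[..., i] for i in range(4))
        return {
            "Na": m * m * h * ghk_current(self.P_Na, 1, self.Na_in, self.Na_out, Vm),
            "Kd": n * n * ghk_current(self.P_K, 1, self.K_in, self.K_out, Vm),
            "P": p * p * ghk_current(self.P_P, 1, self.Na_in, self.Na_out, Vm),
        }


class SundtSegment(Membrane):
    """Unmyelinated C-fiber segment (Sundt-type membrane).

    Hodgkin-Huxley-lineage m3h fast Na+ current with a depolarizing
    activation and inactivation shift, a Borg-Graham-form delayed-rectifier
    K+ current (half-activation at +13 mV), and a weak ohmic leak
    (Rm = 10 kOhm cm^2).  The Na+ shift is fixed so that the segment's
    regenerative spike onset sits a few millivolts above the -60 mV
    resting potential, matching the published spike-initiation behaviour
    of the source C-fiber model; the leak reversal then balances the
    residual resting window currents.  Na+ kinetics carry the classic
    Q10 = 3 correction from their 6.3 degC recording temperature, the
    delayed rectifier from 24 degC.
    """

    name = "sundt"
    Cm0 = 1e-2  # F/m^2 (1 uF/cm^2)
    Vm0 = -60e-3
    gates = ("m", "h", "n")
    T_base_degC = 6.3  # Na+ kinetics recording temperature

    gLeak = 1.0  # S/m^2 (0.1 mS/cm^2)
    gNa_bar = 400.0  # S/m^2
    gKd_bar = 100.0  # S/m^2
    ENa = 55e-3
    EK = -90e-3
    na_m_shift = 9.0e-3  # depolarizing shift of Na+ activation (V)
    na_h_shift = 10.0e-3  # depolarizing shift of Na+ inactivation (V)
    h_T_base_degC = 24.0  # slow inactivation: C-fiber-like tau_h of a few ms
    # delayed-rectifier (Borg-Graham form) parameters
    kdr_vhalf = 13.0  # mV
    kdr_zeta = -3.0
    kdr_gamma = 0.7
    kdr_a0 = 0.1  # 1/ms
    kdr_tau_floor = 0.1  # ms
    kdr_T_base_degC = 24.0

    def rates(self, gate, Vm):
        v = np.asarray(Vm, dtype=float) * 1e3  # absolute mV
        if gate == "m":
            u = v - self.na_m_shift * 1e3
            al = 0.1 * vtrap(u + 40.0, 10.0)
            be = 4.0 * np.exp(-np.clip((u + 65.0) / 18.0, -500, 500))
            k = 1e3 * self.q10_factor
            return al * k, be * k
        if gate == "h":
            u = v - self.na_h_shift * 1e3
            al = 0.07 * np.exp(-np.clip((u + 65.0) / 20.0, -500, 500))
            be = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
            k = 1e3 * self.q10 ** ((T_SIM_DEGC - self.h_T_base_degC) / 10.0)
            return al * k, be * k
        if gate == "n":
            w = 1e-3 * self.kdr_zeta * (v - self.kdr_vhalf) * FARADAY / (R_GAS * T_SIM)
            alp = np.exp(np.clip(w, -500, 500))
            bet = np.exp(np.clip(self.kdr_gamma * w, -500, 500))
            ninf = 1.0 / (1.0 + alp)
            qt = self.q10 ** ((T_SIM_DEGC - self.kdr_T_base_degC) / 10.0)
            # floor guards against rate blow-up at the extreme voltage
            # excursions explored during an acoustic cycle
            taun = np.maximum(bet / (self.kdr_a0 * (1.0 + alp)) / qt, self.kdr_tau_floor)  # ms
            k = 1e3
            return ninf / taun * k, (1.0 - ninf) / taun * k
        raise KeyError(gate)

    def gated_currents(self, Vm, gates):
        Vm = np.asarray(Vm, dtype=float)
        gates = np.asarray(gates, dtype=float)
        m, h, n = (gates[..., i] for i in range(3))
        return {
            "Na": self.gNa_bar * m * m * m * h * (Vm - self.ENa),
            "Kd": self.gKd_bar * n * (Vm - self.EK),
        }


class PassiveMembrane(Membrane):
    """Pure-leak RC membrane (benchmark model)."""

    name = "passive"
    gates = ()

    def __init__(self, Cm0=1e-2, gLeak=1.0, ELeak=-70e-3):
        self.Cm0 = Cm0
        self.gLeak = gLeak
        self.Vm0 = ELeak
        self.ELeak = ELeak

    def rates(self, gate, Vm):
        raise KeyError(gate)

    @property
    def tau_m(self):
        """Membrane time constant Cm0 / gLeak (s)."""
        return self.Cm0 / self.gLeak


_REGISTRY = {
    "senn_node": FrankenhaeuserHuxleyNode,
    "sundt": SundtSegment,
    "passive": PassiveMembrane,
}


def get_membrane(name: str, **kwargs) -> Membrane:
    """Instantiate a registered membrane model by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown membrane {name!r}; available: {sorted(_REGISTRY)}") from None
    return cls(**kwargs)


def membrane_names():
    return sorted(_REGISTRY)
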