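# sonaxon

Multiscale simulation of ultrasound neuromodulation of peripheral nerve
fibers by intramembrane cavitation.

## The scientific problem

Low-intensity focused ultrasound can excite neurons remotely. One candidate
mechanism is *intramembrane cavitation*: nanometric pockets between the two
leaflets of the plasma membrane ("bilayer sonophores") expand and contract
with the acoustic pressure, making the local membrane capacitance
`Cm(Z)` oscillate at the carrier frequency. Because the membrane charge
density `Qm` is a slow variable, these fast capacitance oscillations
translate into large oscillations of `Vm = Qm / Cm(t)` whose *cycle
averages* drive the slow electrical response.

This package implements the full modeling chain for myelinated and
unmyelinated peripheral axons:

* **Sonophore mechanics** — the cavitating-bubble deflection dynamics

  `d²Z/dt² = −3/(2R) (dZ/dt)² + 1/(ρ|R|) [P_A + P_S + P_VS − P_0 + P_VL + P_M + P_G + P_Q]`

  with elastic (`P_S`), dome-averaged intermolecular Lennard-Jones (`P_M`),
  gas (`P_G`), electric (`P_Q ∝ −Qm²`) and viscous (`P_VS`, `P_VL`)
  pressures, integrated to a limit cycle. The resting inter-leaflet gap is
  solved per membrane from the balance
  `A_r[(Δ*/Δ)^x − (Δ*/Δ)^y] = Qm0² / (2 ε₀ ε_r)`.
* **Effective (cycle-averaged) paradigm** — per (radius, frequency,
  amplitude, charge) condition the last-cycle capacitance profile is
  collapsed into `Vm* = ⟨Qm/Cm_fs(t)⟩`, the harmonic-mean effective
  capacitance `Cm* = ⟨1/Cm_fs⟩⁻¹` and cycle-averaged gating rates
  `α*, β*`, tabulated over an (amplitude, charge) grid, persisted to HDF5
  and interpolated bilinearly at run time (`fs` is the sonophore membrane
  coverage fraction, `Cm_fs = fs·Cm + (1−fs)·Cm0`).
* **Charge-casted membranes** — a Frankenhaeuser–Huxley Ranvier node
  (GHK-flux Na/K/P currents, `Cm0 = 2 µF/cm²`) and an unmyelinated C-fiber
  segment (`Cm0 = 1 µF/cm²`, HH-lineage m³h Na, delayed-rectifier K, weak
  leak), both adapted to 36 °C; state = `(Qm, gates)`, so time-varying
  capacitance never enters as a displacement current.
* **Hybrid cable solver** — the multi-compartment, multi-layer circuit
  `C dy/dt + G(t) y = I(t)` over `y = [Qm nodes; Vx nodes]`, integrated
  implicitly (BDF, pure absolute charge tolerance), with myelinated
  (nodes + resistive internodes, `L = 100 D`) and unmyelinated
  (uniform compartments of length `min(16.4 D + 9.1 µm, 22 µm)`) fibers,
  plus extracellular point-electrode drives via equivalent intracellular
  currents.
* **Exposure fields** — distributed-point-source transducer fields with a
  closed-form on-axis reference and natural focus `z_f = f r²/c − c/(4f)`,
  Gaussian beam profiles, and anisotropic endoneurium electrode potentials.
* **Protocols & metrics** — pulse trains, duty-cycle sweeps and multiplexed
  dual-scheme stimuli; binary-search titration; strength-duration curves
  (rheobase, chronaxie); spike detection and firing rates; charge build-up
  and per-current decompositions; and the accuracy metrics comparing the
  effective paradigm against temporally detailed two-compartment solutions
  (steady-state deviation ε∞, normalized transient deviation ε_τ, and the
  spike-tolerance gamma distance ε_γ).

It is intended for computational neuroscientists studying peripheral
ultrasound neuromodulation: fiber-type-specific excitability, pulsed
protocol design, and the validity domain of cycle-averaged simulation.

## Worked example

```python
import numpy as np
from sonaxon import (
    BLSConstants, cavitation_cycle, effective_cycle_averages,
    equilibrium_gap, get_membrane,
)

consts = BLSConstants()
node = get_membrane("senn_node")           # myelinated Ranvier node (Cm0 = 2 uF/cm2)

# resting inter-leaflet gap from the electric/intermolecular pressure balance
gap = equilibrium_gap(node.Qm0, consts)
print(f"equilibrium gap at Qm0 = {node.Qm0 * 1e5:.0f} nC/cm2: {gap * 1e9:.2f} nm")

# drive one sonophore to its limit cycle (500 kHz, 100 kPa) at fixed charge
prof = cavitation_cycle(32e-9, 500e3, 100e3, node.Qm0, consts,
                        Delta=gap, Cm0=node.Cm0)
print(f"limit cycle in {prof.n_cycles_to_converge} acoustic cycles, "
      f"peak deflection {prof.Z_t.max() * 1e9:.2f} nm")

# cycle-averaged (effective) variables at 80% sonophore coverage
eff = effective_cycle_averages(prof, node.Qm0, fs=0.8, membrane=node)
print(f"effective capacitance {eff.Cm_star * 1e2:.3f} uF/cm2 "
      f"({100 * (eff.Cm_star / node.Cm0 - 1):+.1f}% vs rest), "
      f"effective potential {eff.Vm_star * 1e3:.1f} mV")
```

prints

```
equilibrium gap at Qm0 = -140 nC/cm2: 1.10 nm
limit cycle in 3 acoustic cycles, peak deflection 0.34 nm
effective capacitance 1.939 uF/cm2 (-3.1% vs rest), effective potential -72.2 mV
```

The 1.10 nm gap is the charged-membrane equilibrium spacing of the two
leaflets; a 100 kPa, 500 kHz drive then cavitates the sonophore by a few
angstroms per cycle, which is already enough to depress the coverage-weighted
effective capacitance by ~3% and hyperpolarize the effective potential by
~2 mV — the seed of the leak-mediated charge build-up that ultimately
triggers ultrasonic excitation at higher amplitudes.

A command-line interface exposes the main workflows
(`sonaxon lookup|simulate|titrate|sdcurve|mux|bundle|benchmark`), e.g.

```sh
sonaxon titrate --kind sundt --pd 0.1
sonaxon benchmark passive --taum 1e-4 --tauax 1e-4
```

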