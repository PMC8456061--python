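# Methods

This note documents the models implemented in `sonaxon`, the parameter
choices that matter, the numerical machinery, and the package's known
limitations. Internal units are SI throughout; the I/O boundary uses the
field's conventions (kPa, mV, nC/cm², µF/cm², ms, µm).

## Sonophore mechanics

A bilayer sonophore of in-plane radius `a` (default 32 nm) is described by
the apex deflection `Z` (positive = leaflets moving apart), its velocity,
and the molar gas content `n_g` of the inter-leaflet cavity. The leaflets
deflect as spherical caps, giving curvature `1/R = 2Z/(a² + Z²)`, dome
area `S = π(a² + Z²)` and local deflection profile
`z(r) = sign(Z)(√(R² − r²) − |R| + |Z|)`. The acceleration balance sums:

| term | form | role |
|------|------|------|
| `P_A` | `−A sin(2π f t)` | acoustic drive, rarefaction-first |
| `P_S` | `−4 k_s Z³ / (a²(a² + Z²))` | leaflet elastic tension (areal modulus `k_s` = 0.24 N/m) |
| `P_M` | `S⁻¹ ∫ A_r[(Δ*/d)ˣ − (Δ*/d)ʸ] 2πr dr`, `d(r) = 2z(r) + Δ` | intermolecular repulsion/attraction (A_r = 100 kPa, x = 5, y = 3.3, Δ* = 1.4 nm) |
| `P_G` | `n_g R T / V(Z)` | internal gas |
| `P_Q` | `−(S0/S) Qm² / (2 ε₀ ε_r)` | electric attraction of the charged leaflets |
| `P_VS`, `P_VL` | `−12 µ_s δ (dZ/dt)/R²`, `−4 µ_l (dZ/dt)/|R|` | leaflet / liquid viscous stresses |

Gas exchanges across the leaflets with the dissolved pool,
`dn_g/dt = 2 S D_gl/ξ (C_g − P_G/k_H)`; with the default geometry the gas
relaxation time is a few nanoseconds, so the cavity is effectively
pressure-clamped at the hydrostatic value over a 2 µs acoustic period.
At 500 kHz the oscillation is strongly sub-resonant: the deflection
essentially tracks the instantaneous pressure balance (a solver-free
quasi-static phase sweep reproduces the dynamic effective capacitance to
~2% at moderate amplitudes, and is used as an independent oracle in the
tests), and the response is insensitive to the liquid density and the
viscosities.

The resting inter-leaflet gap is membrane-specific: it solves the flat
balance `A_r[(Δ*/Δ)ˣ − (Δ*/Δ)ʸ] = Qm0²/(2 ε₀ ε_r)` at the membrane's
resting charge density, giving 1.10 nm at −140 nC/cm² (myelinated node)
and 1.29 nm at −60 nC/cm² (unmyelinated segment). `Δ*` = 1.4 nm (the
charge-free gap), `A_r` and the Lennard-Jones exponents are fixed at the
values that make this balance reproduce those gaps; they are shipped, with
provenance comments, in a YAML constants block (`sonaxon constants`).
Temperature is fixed at 36 °C.

The local capacitance of the deflected sonophore is the planar-capacitor
average over the dome,

`Cm(Z) = Cm0 (Δ/a²) [Z + (a² − Z² − ZΔ)/(2Z) · ln((2Z + Δ)/Δ)]`,

continuous at `Z = 0` and strictly decreasing in `Z` over the physiological
deflection range.

## Effective (cycle-averaged) variables and lookups

Each `(a, f, A, Qm)` condition is integrated to a limit cycle (consecutive
cycles' sampled `(Z, n_g)` must agree to a relative RMS of 1e−5; typical
convergence is 3–10 cycles, hard cap 10⁴). The macroscale capacitance is
the coverage-weighted mixture `Cm_fs(t) = fs·Cm(Z(t)) + (1 − fs)·Cm0`
(`fs` = 0.8 throughout the worked examples), from which

* `Vm* = ⟨Qm / Cm_fs(t)⟩` (equal to `Qm/Cm*` exactly at fixed charge),
* `Cm* = ⟨1/Cm_fs(t)⟩⁻¹` (harmonic mean; always ≤ the arithmetic mean),
* `α*_x, β*_x = ⟨α_x(Vm(t))⟩, ⟨β_x(Vm(t))⟩` per gate.

Tables are built over an amplitude grid (log-spaced plus an exact zero row,
which is evaluated analytically as the resting membrane) and a charge grid
spanning `Cm0·[−100 mV, +50 mV]`; several coverage fractions can be
tabulated from one mechanical sweep since `fs` only rescales the stored
capacitance profile. Persistence is HDF5 with axes, units, membrane id and
a constants hash. Runtime queries interpolate bilinearly in `(A, Qm)`
(exact on nodes; out-of-hull queries are errors naming the offending axis);
per-compartment amplitude vectors are projected once per stimulus level
onto 1D charge-space functions used during ON and OFF integration phases.
During integration, charges transiently outside the tabulated hull (spike
peaks) are clamped to the edge of the charge grid.

For point-model titrations the package bypasses the amplitude grid
entirely: a `DirectSource` runs fresh limit cycles at the exact candidate
amplitude (one mechanical sweep per bisection step), removing
amplitude-interpolation bias from thresholds. The myelinated fiber latency
computation uses the same exact-amplitude path (11 nodes); the unmyelinated
fiber (455 compartments) uses a dense 30-point amplitude grid up to 10%
above the exposure peak.

## Membrane models

All membranes are charge-casted: state = `(Qm, gates)`, voltage derived as
`Qm/Cm` (instantaneous or effective), so the time-varying capacitance never
appears as a stiff displacement-current term. The leak reversal is solved
at initialization to balance the gated currents at the nominal resting
potential, making every model exactly stationary at rest.

**Myelinated node** (`senn_node`): the classic amphibian Ranvier-node
permeability formulation — GHK-flux Na (m²h, P_Na = 8e−3 cm/s),
delayed-rectifier K (n², P_K = 1.2e−3 cm/s), non-specific delayed P (p²,
P_P = 0.54e−3 cm/s, carried by Na) with the standard ionic concentrations,
plus an ohmic leak g_L = 30.3 mS/cm²; Cm0 = 2 µF/cm², Vm0 = −70 mV. Rates
carry a Q10 = 3 correction from 20 °C to 36 °C (factor 3^1.6 ≈ 5.80). In
the effective paradigm the GHK driving functions are evaluated at `Vm*`.

**Unmyelinated segment** (`sundt`): a C-fiber stand-in whose exact source
coefficients are not fully documented in the literature available here; it
was therefore *constructed* from the classic HH channel family and
calibrated against the published operating characteristics of C-fiber
segment models (this is the package's own design choice, recorded here):

* m³h Na (ḡ_Na = 400 S/m²) with the squid-era rate functions shifted
  depolarized by +9 mV (activation) and +10 mV (inactivation); the
  activation shift places the quasi-static current-voltage fold — the
  spike-initiation threshold under slow depolarization — at ≈ −54 mV,
  i.e. ~6 mV above the −60 mV resting potential.
* Na activation kinetics on the 6.3 °C Q10 = 3 base (×26 at 36 °C,
  effectively instantaneous); inactivation on a 24 °C base
  (τ_h ≈ 2 ms). The slow inactivation is essential: with near-instantaneous
  h the model either cannot spike or latches onto a depolarized
  fixed point created by the Na window; with τ_h of milliseconds the spike
  is a proper relaxation event that escapes that basin.
* Borg-Graham-form delayed rectifier (n¹, half-activation +13 mV,
  ζ = −3, γ = 0.7, a0 = 0.1 ms⁻¹, Q10 = 3 from 24 °C, time-constant floor
  0.1 ms to guard against rate blow-up at the extreme voltage excursions
  explored within an acoustic cycle), ḡ_Kd = 100 S/m². The rate scale and
  density were set so that spikes repolarize without a deep K undershoot —
  this is what lets a fiber follow a 50 Hz pulse train one-to-one at
  amplitudes just above threshold.
* Leak g_L = 0.1 mS/cm² (Rm = 10 kΩ·cm²), giving the ~300:1 leak-density
  ratio between the two membranes.

**Passive membrane**: pure leak RC, used by the accuracy benchmarks.

## Hybrid cable system

Each compartment carries a membrane charge node and optionally an
extracellular voltage node coupled through a transverse RC layer to an
imposed extracellular potential; Kirchhoff balances give
`C dy/dt + G(t) y = I(t)` with identity/capacitance blocks in `C` and
axial-conductance blocks in `G` whose columns are normalized by the
(time-varying) per-node capacitance. Both axon models are single-cable
(the extracellular layer is implemented for generality and exercised on
toy fixtures; an algebraically equivalent substituted block form is
covered by a unit test). Stimulus ON/OFF transitions restart the
integrator with the appropriate charge-space tables (instantaneous
capacitance reversion at offset). The solver is scipy's BDF on the sparse
system with a pure absolute charge tolerance of 1e−3 nC/cm² and dense
output (10–100 µs for effective runs, 1 µs where latencies are measured).

Fibers: myelinated fibers are chains of active nodes (length 2.5 µm,
axoplasm diameter 0.7 D, ρ_a = 110 Ω·cm) joined by purely resistive
internodes of length 100 D (no sonophores on internodes); unmyelinated
fibers are uniform compartments of the diameter-dependent optimal length
`min(16.4 D + 9.1 µm, 22 µm)` (ρ_a = 100 Ω·cm). Node ("point") models
reuse one compartment's geometry. Electrical stimulation enters as
equivalent intracellular currents `(1/Am) Σ G_a (φ_e,j − φ_e,k)` from the
anisotropic point-electrode potential.

The temporally detailed (cycle-resolved) integrator couples each
compartment's mechanics to its electrics at a fixed step of 0.001 acoustic
periods (refined up to 8× at strong drives) using a second-order IMEX
midpoint scheme: the viscous damping — the stiff part, linear in the
velocity — is treated with a trapezoidal implicit update, everything else
explicitly at the midpoint. The same kernel (validated against an adaptive
LSODA reference in the tests) drives the lookup precomputation. It is
restricted to one or two compartments (benchmark scale). Membrane kinetics
are duplicated inside the compiled kernel and pinned to the Python
implementations by exact cross-consistency tests.

## Protocols, titration and metrics

Pulse trains are piecewise-constant envelopes; multiplexed stimuli
superpose two trains, and where pulses overlap the applied amplitude is
the per-time maximum of the two (amplitude-coded interleaving). Titration
is a geometric binary search to 1% relative bracket width; the node-model
spike criterion accepts either a prominent charge-density peak (30 mV
prominence) or a charge excursion far beyond the sub-threshold range
(strong drives produce depolarization-block plateaus without discrete
peaks); fiber excitation requires detection at both extremities.
Rheobase titrations use 100 ms pulses with a 60 ms post-pulse window so
that marginal offset-mediated responses (capacitance reversion at stimulus
end maps the accumulated charge back onto the resting capacitance,
which can tip the membrane over threshold) are classified correctly.

The spike-threshold charge build-up is measured on the barely
supra-threshold trace as the normalized charge at the rate bottleneck —
the point of minimal dQm/dt between onset and the regenerative escape —
which marks the ghost of the disappeared sub-threshold equilibrium.

Strength-duration curves titrate a list of pulse durations; the rheobase
is the longest-duration threshold and the chronaxie is log-interpolated at
twice the rheobase. Firing rates are reciprocals of mean inter-spike
intervals at the fiber extremities. Charge build-up latency is the first
time `Qm/Cm0` rises 5 mV above rest. Current decompositions re-evaluate
per-current densities (and net axial current) along the saved trace, so
contributions sum to the trace's charge change by construction.

Accuracy metrics between an effective solution and the cycle-averaged
detailed solution: ε∞ is the maximal across-compartment steady-state
charge difference; ε_τ normalizes both solutions to the unit interval,
finds the first time the reference stays within 0.1% of its unit steady
state, and ratios the integrated discrepancy to the integrated remaining
transient (compartments whose reference range is below 1 nC/cm² are
excluded); ε_γ is the max-min tolerance-normalized distance in the
(time, charge) plane with tolerances set to 30% of a model's spike
prominence and half-width. Passive benchmark cells map requested time
constants exactly (`τ_m = Cm0/g_L`, `τ_ax = Cm0 A_m / G_a`) and run for
five times the longest time constant, at least 10 acoustic periods.
Population firing-rate comparisons use the Kruskal–Wallis rank test.

## Study-condition generators

The package generates all of its inputs programmatically; the defaults
*are* the study conditions: sonophore radius 32 nm, coverage 80%,
carrier 500 kHz, representative fiber diameters 10 µm (myelinated) and
0.8 µm (unmyelinated), 10 mm fibers, 5 mm-FWHM Gaussian beams at 120 kPa
for the typical responses (FWHM is the adopted width convention; a ±2σ
convention is also available), 2 mm beams for multiplexed protocols, and
100 ms pulses for rheobase titrations. Nerve bundles pack log-normal
diameter populations (modes 6 µm / 0.8 µm, truncated to 5–20 µm and
0.2–1.5 µm; the myelinated mode and the 0.2 µm packing clearance are set
by the geometric feasibility of placing 56 myelinated fibers in a 100 µm
cross-section) by random sequential addition, with longitudinal offsets
within ± one node spacing. These generators emulate idealized exposure
and morphology: homogeneous non-attenuating media, straight fibers,
uniform per-fiber diameter, no branching, no thermal or radiation-force
effects — so passing tests validate the simulation machinery under
idealized fields, not the variability of real nerves.

## Numerical choices and degenerate inputs

* Mechanical kernel: 1000 steps per acoustic cycle (scaled with amplitude
  up to 8×), IMEX midpoint; the flat state is degenerate (the effective
  inertia diverges as `Z → 0`), so integration starts from the
  quasi-static deflection under the first sub-step's drive pressure.
* Leaflet interpenetration (`2z + Δ ≤ 0`) is a domain error in the
  capacitance and pressure evaluations and is floored inside the kernel at
  `−0.495 Δ`.
* The intermolecular dome integral uses fixed 32-point Gauss–Legendre
  quadrature in radius.
* Zero-amplitude conditions short-circuit to the analytic resting row.
* Charge grids: 40–100 points; node worked examples report at the grid
  density where the threshold build-up is refinement-converged (±1%).
  Effective-voltage monotonicity in charge holds on sub-runaway amplitude
  rows; at strong drives the charge dependence of the capacitance drop
  (regenerative mechanical feedback) legitimately bends it.
* BDF tolerances: 1e−3 nC/cm² absolute on charges, 1e−6 on gates; halving
  tolerances moves spike times by well under 1%.
* Deterministic throughout; the only randomness (bundle sampling, packing)
  is seeded explicitly.

## Design choices where the design was open

* The acoustic drive is rarefaction-first (`P_A = −A sin`), so the first
  half-cycle expands the sonophore and the capacitance drops at onset.
* Coverage weighting applies to the capacitance profile before averaging
  (`Cm_fs` above); zero coverage reproduces the resting membrane exactly.
* `fs` is a per-run scalar, not a lookup axis.
* Titration uses geometric bisection (thresholds are log-distributed).
* In multiplexed overlaps the larger amplitude wins (no pressure summing).
* The latency computations report the first 5 mV build-up at the central
  compartment relative to stimulus onset, with linear sub-sample
  refinement.

## Known limitations

* The unmyelinated sonophore operates in a mechanically ultrasensitive
  regime: its resting gap (1.29 nm) sits close to the charge-free spacing,
  where the intermolecular stiffness is weak and the oscillation amplitude
  depends steeply on the charge state. Quantities downstream of that
  sensitivity (the unmyelinated threshold build-up, capacitance drop and
  intra-cycle oscillation range at threshold) carry correspondingly larger
  model uncertainty than their myelinated counterparts, and the full-fiber
  build-up latencies inherit part of it.
* The unmyelinated membrane is a calibrated stand-in, not a verbatim
  transcription of a published coefficient set; its resting stability,
  spike-initiation voltage, repetitive-firing capability and leak density
  are the calibrated properties.
* The detailed (cycle-resolved) integrator is limited to two compartments;
  full fibers run only under the effective paradigm.
* No extracellular cavitation, thermal or radiation-force effects; no
  double-cable myelinated morphology; homogeneous media only.
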