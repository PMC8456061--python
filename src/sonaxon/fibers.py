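"""Peripheral axon morphologies and heterogeneous nerve bundles.

Two single-cable fiber archetypes are constructed:

* **Myelinated (SENN-type)** — active Ranvier nodes (Frankenhaeuser-Huxley
  membrane) of fixed length connected by purely resistive myelinated
  internodes whose length scales with fiber diameter (L = 100 D); no
  sonophores (and no membrane dynamics) on the internodes.
* **Unmyelinated (Sundt-type)** — a continuous neurite discretized into
  uniform active compartments whose optimal length follows a
  diameter-dependent rule capped at 22 um.

Single-compartment "node" versions of both membranes support fast
excitability analyses, and a bundle builder packs fiber populations with
realistic diameter distributions into a cylindrical nerve cross-section.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cable import CableTopology, single_compartment
from .membranes import Membrane, get_membrane

# Geometry defaults (config-exposed through the builder signatures)
SENN_NODE_LENGTH = 2.5e-6  # m
SENN_AXON_DIAMETER_RATIO = 0.7  # axoplasm diameter / fiber outer diameter
SENN_RHO_AXIAL = 1.1  # Ohm*m (110 Ohm*cm)
SUNDT_RHO_AXIAL = 1.0  # Ohm*m (100 Ohm*cm)


def optimal_segment_length(D: float) -> float:
    """Optimal unmyelinated compartment length for fiber diameter ``D`` (m).

    Piecewise-linear convergence rule L_opt = min(16.4 D + 9.1 um, 22 um),
    fitted on 0.2-1.5 um fibers.
    """
    D_um = D * 1e6
    if not 0.2 < D_um < 1.5:
        warnings.warn(f"fiber diameter {D_um:.2f} um outside the fitted 0.2-1.5 um range")
    return min(16.4 * D_um + 9.1, 22.0) * 1e-6


@dataclass
class FiberModel:
    """Morphologically structured fiber: topology plus construction metadata."""

    kind: str  # 'senn' | 'sundt' | 'node'
    D: float  # fiber diameter (m)
    topology: CableTopology
    internode_length: float = None  # m (SENN only)
    segment_length: float = None  # m (Sundt only)

    @property
    def n_comp(self):
        return self.topology.n

    @property
    def x(self):
        """Compartment center coordinates (m), centered on 0."""
        return self.topology.x

    @property
    def length(self):
        return float(self.x[-1] - self.x[0])

    @property
    def node_spacing(self):
        """Node-to-node distance w (m)."""
        return self.internode_length if self.kind == "senn" else self.segment_length


def build_senn_fiber(D: float, n_nodes: int = None, length: float = None, membrane: Membrane = None) -> FiberModel:
    """Myelinated SENN fiber of diameter ``D``.

    Nodes of length 2.5 um carry the Ranvier-node membrane; internodes of
    length 100 D act as pure intracellular resistors.  Specify either an
    odd ``n_nodes`` or a total ``length`` (rounded to an odd node count).
    """
    if (n_nodes is None) == (length is None):
        raise ValueError("specify exactly one of n_nodes or length")
    L = 100.0 * D
    if n_nodes is None:
        n_nodes = int(round(length / L)) + 1
        if n_nodes % 2 == 0:
            n_nodes += 1
    if n_nodes < 3:
        raise ValueError("a SENN fiber needs at least 3 nodes")
    if n_nodes % 2 == 0:
        raise ValueError("n_nodes must be odd so a central node exists")
    membrane = membrane or get_membrane("senn_node")
    d_axon = SENN_AXON_DIAMETER_RATIO * D
    Am = math.pi * d_axon * SENN_NODE_LENGTH
    Ga = math.pi * (d_axon / 2.0) ** 2 / (SENN_RHO_AXIAL * L)
    edges = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    x = (np.arange(n_nodes) - (n_nodes - 1) / 2.0) * L
    topo = CableTopology(
        membrane=membrane,
        Am=np.full(n_nodes, Am),
        edges=edges,
        Ga=np.full(n_nodes - 1, Ga),
        x=x,
    )
    return FiberModel(kind="senn", D=D, topology=topo, internode_length=L)


def build_sundt_fiber(D: float, length: float, membrane: Membrane = None) -> FiberModel:
    """Unmyelinated Sundt fiber of diameter ``D`` and total ``length``.

    Uniform compartments of the diameter-dependent optimal length; odd
    compartment count so that a central compartment exists.
    """
    L = optimal_segment_length(D)
    if length < 10 * L:
        raise ValueError("fiber too short for a meaningful discretization (need >= 10 segments)")
    n = int(round(length / L))
    if n % 2 == 0:
        n += 1
    seg = length / n
    membrane = membrane or get_membrane("sundt")
    Am = math.pi * D * seg
    Ga = math.pi * (D / 2.0) ** 2 / (SUNDT_RHO_AXIAL * seg)
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    x = (np.arange(n) - (n - 1) / 2.0) * seg
    topo = CableTopology(
        membrane=membrane,
        Am=np.full(n, Am),
        edges=edges,
        Ga=np.full(n - 1, Ga),
        x=x,
    )
    return FiberModel(kind="sundt", D=D, topology=topo, segment_length=seg)


def build_node_model(kind: str, D: float = None) -> FiberModel:
    """Isolated point ('node') model of one axon compartment.

    ``kind`` is ``senn_node`` or ``sundt``; geometry follows the parent
    fiber's compartment for the given diameter (defaults: 10 um / 0.8 um).
    """
    if kind == "senn_node":
        D = 10e-6 if D is None else D
        Am = math.pi * (SENN_AXON_DIAMETER_RATIO * D) * SENN_NODE_LENGTH
        mem = get_membrane("senn_node")
    elif kind == "sundt":
        D = 0.8e-6 if D is None else D
        Am = math.pi * D * optimal_segment_length(D)
        mem = get_membrane("sundt")
    else:
        raise ValueError("kind must be 'senn_node' or 'sundt'")
    return FiberModel(kind="node", D=D, topology=single_compartment(mem, Am=Am))


# ----------------------------------------------------------------------------
# Bundles
# ----------------------------------------------------------------------------

@dataclass
class BundleFiber:
    kind: str  # 'senn' | 'sundt'
    D: float  # m
    y: float  # cross-section position (m)
    z: float  # cross-section position (m)
    offset: float  # longitudinal shift (m)


@dataclass
class Bundle:
    """Cylindrical nerve section populated with myelinated/unmyelinated fibers."""

    radius: float  # cross-section radius (m)
    length: float  # m
    fibers: list = field(default_factory=list)

    def counts(self):
        c = {"senn": 0, "sundt": 0}
        for f in self.fibers:
            c[f.kind] += 1
        return c

    def to_json(self, path=None):
        recs = [
            {
                "kind": f.kind,
                "D_um": f.D * 1e6,
                "y_um": f.y * 1e6,
                "z_um": f.z * 1e6,
                "offset_um": f.offset * 1e6,
            }
            for f in self.fibers
        ]
        payload = json.dumps({"radius_um": self.radius * 1e6, "length_mm": self.length * 1e3, "fibers": recs}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        b = cls(radius=d["radius_um"] * 1e-6, length=d["length_mm"] * 1e-3)
        b.fibers = [
            BundleFiber(
                kind=r["kind"],
                D=r["D_um"] * 1e-6,
                y=r["y_um"] * 1e-6,
                z=r["z_um"] * 1e-6,
                offset=r["offset_um"] * 1e-6,
            )
            for r in d["fibers"]
        ]
        return b


#: Physiological diameter ranges (m) and representative modes per population.
DIAMETER_RANGES = {"senn": (5e-6, 20e-6), "sundt": (0.2e-6, 1.5e-6)}
DIAMETER_MODES = {"senn": 6e-6, "sundt": 0.8e-6}
#: Log-normal spread of the truncated diameter samplers.
DIAMETER_SIGMA = {"senn": 0.25, "sundt": 0.35}


def sample_diameters(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated log-normal fiber diameters (m) for one population.

    Mode at the population's representative diameter, rejected outside the
    physiological range.
    """
    lo, hi = DIAMETER_RANGES[kind]
    mode = DIAMETER_MODES[kind]
    sigma = DIAMETER_SIGMA[kind]
    mu = math.log(mode) + sigma**2  # log-normal mode = exp(mu - sigma^2)
    out = np.empty(n)
    k = 0
    while k < n:
        d = float(np.exp(rng.normal(mu, sigma)))
        if lo <= d <= hi:
            out[k] = d
            k += 1
    return out


def build_bundle(
    n_myel: int = 56,
    n_unmyel: int = 221,
    radius: float = 50e-6,
    length: float = 10e-3,
    clearance: float = 0.2e-6,
    rng_seed: int = 0,
    max_attempts: int = 100000,
) -> Bundle:
    """Pack a mixed fiber population into a cylindrical bundle cross-section.

    Random sequential addition with per-fiber exclusion radius D/2 +
    ``clearance``; fibers receive random longitudinal offsets within plus
    or minus one node-to-node distance w to de-align their central nodes.
    """
    rng = np.random.default_rng(rng_seed)
    bundle = Bundle(radius=radius, length=length)
    specs = [("senn", d) for d in sample_diameters("senn", n_myel, rng)]
    specs += [("sundt", d) for d in sample_diameters("sundt", n_unmyel, rng)]
    placed = []  # (y, z, r_excl)
    attempts = 0
    for kind, D in specs:
        r_excl = D / 2.0 + clearance
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"bundle packing failed after {max_attempts} attempts "
                    f"({len(placed)}/{len(specs)} fibers placed); increase the radius"
                )
            rr = radius * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            y, z = rr * math.cos(th), rr * math.sin(th)
            if rr + D / 2.0 > radius:
                continue
            ok = True
            for (y2, z2, r2) in placed:
                if (y - y2) ** 2 + (z - z2) ** 2 < (r_excl + r2) ** 2:
                    ok = False
                    break
            if ok:
                break
        placed.append((y, z, r_excl))
        w = 100.0 * D if kind == "senn" else optimal_segment_length(D)
        offset = rng.uniform(-w, w)
        bundle.fibers.append(BundleFiber(kind=kind, D=D, y=y, z=z, offset=offset))
    return bundle


def build_fiber_for(bf: BundleFiber, length: float) -> FiberModel:
    """Instantiate the morphological model of one bundle fiber record."""
    if bf.kind == "senn":
        return build_senn_fiber(bf.D, length=length)
    return build_sundt_fiber(bf.D, length=length)


# ----------------------------------------------------------------------------
# Electrical validation harness
# ----------------------------------------------------------------------------

def conduction_velocity(fiber: FiberModel, trace, fracs=(0.6, 0.85)) -> float:
    """Conduction velocity (m/s) from spike arrival at two probe compartments.

    Uses the charge-density peak time at two compartments on the same side
    of the (centrally stimulated) fiber, away from the stimulation site and
    the sealed end.
    """
    n = fiber.n_comp
    i1, i2 = int(n * fracs[0]), int(n * fracs[1])
    Cm0 = fiber.topology.membrane.Cm0
    level = trace.Qm[0, i1] / Cm0 + 0.045  # upstroke crossing 45 mV above rest

    def first_crossing(k):
        qn = trace.Qm[:, k] / Cm0
        above = np.where(qn >= level)[0]
        if len(above) == 0:
            raise ValueError(f"no spike upstroke at probe compartment {k}")
        i = above[0]
        if i == 0:
            return trace.t[0]
        f = (level - qn[i - 1]) / (qn[i] - qn[i - 1])
        return trace.t[i - 1] + f * (trace.t[i] - trace.t[i - 1])

    t1, t2 = first_crossing(i1), first_crossing(i2)
    if t2 == t1:
        raise ValueError("no measurable conduction delay between probe compartments")
    return float(abs(fiber.x[i2] - fiber.x[i1]) / abs(t2 - t1))
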