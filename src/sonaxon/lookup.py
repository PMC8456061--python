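"""Precomputation, persistence and interpolation of cycle-averaged variables.

The multiscale (effective) integration paradigm separates microsecond
mechanical oscillations from millisecond electrical dynamics: for each
combination of sonophore radius, carrier frequency, pressure amplitude and
membrane charge density, the cavitation limit cycle is integrated once and
collapsed into cycle-averaged variables (Vm*, Cm*, per-gate rate
constants).  These are tabulated over a (A, Q) grid, persisted to HDF5,
and interpolated bilinearly at run time; per-compartment amplitudes are
then projected onto 1D charge-space functions used during stimulus-ON and
stimulus-OFF integration phases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .bls import (
    BLSConstants,
    MechSolverSettings,
    cavitation_cycle,
    coverage_weighted_capacitance,
    equilibrium_gap,
)
from .membranes import Membrane, get_membrane

LOOKUP_FORMAT_VERSION = "1"


class OutOfTableError(ValueError):
    """Raised when a query falls outside the tabulated hull."""


def _constants_sha(consts: BLSConstants) -> str:
    payload = json.dumps(consts.asdict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def default_amplitude_grid(n=30, A_max=600e3, A_min=1e3):
    """Log-spaced amplitude grid from A_min to A_max plus the zero row (Pa)."""
    return np.concatenate(([0.0], np.geomspace(A_min, A_max, n)))


def default_charge_grid(membrane: Membrane, n=50, V_lo=-100e-3, V_hi=50e-3):
    """Charge grid spanning the membrane's physiological voltage range (C/m^2)."""
    return np.linspace(membrane.Cm0 * V_lo, membrane.Cm0 * V_hi, n)


def _table_names(membrane: Membrane):
    names = ["V", "Cm"]
    for g in membrane.gates:
        names += [f"alpha_{g}", f"beta_{g}"]
    return names


@dataclass
class EffectiveLookup:
    """Tables of cycle-averaged variables over a (amplitude, charge) grid.

    ``tables['V']`` is the effective membrane potential (V), ``tables['Cm']``
    the effective (harmonic-mean, coverage-weighted) capacitance (F/m^2) and
    ``tables['alpha_x'] / tables['beta_x']`` the effective rate constants
    (1/s) of each gate ``x``; all have shape ``(len(A_grid), len(Q_grid))``.
    """

    membrane_name: str
    a: float  # sonophore radius (m)
    f_US: float  # carrier frequency (Hz)
    fs: float  # sonophore membrane coverage fraction
    A_grid: np.ndarray  # Pa, increasing, A_grid[0] == 0
    Q_grid: np.ndarray  # C/m^2, increasing
    tables: dict
    constants_sha: str = ""
    n_cycles: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.A_grid[0] != 0.0 or np.any(np.diff(self.A_grid) <= 0):
            raise ValueError("amplitude grid must be strictly increasing and start at 0")
        if np.any(np.diff(self.Q_grid) <= 0):
            raise ValueError("charge grid must be strictly increasing")
        for k, t in self.tables.items():
            if not np.all(np.isfinite(t)):
                raise ValueError(f"non-finite entries in lookup table {k!r}")

    @property
    def variable_names(self):
        return list(self.tables)

    # -- persistence ------------------------------------------------------

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            ax = f.create_group("axes")
            ax.create_dataset("A_Pa", data=self.A_grid)
            ax.create_dataset("Q_C_per_m2", data=self.Q_grid)
            tb = f.create_group("tables")
            for k, t in self.tables.items():
                tb.create_dataset(k, data=t)
            if self.n_cycles is not None:
                f.create_dataset("n_cycles", data=self.n_cycles)
            f.attrs["membrane"] = self.membrane_name
            f.attrs["a_m"] = self.a
            f.attrs["f_Hz"] = self.f_US
            f.attrs["fs"] = self.fs
            f.attrs["version"] = LOOKUP_FORMAT_VERSION
            f.attrs["constants_sha"] = self.constants_sha

    @classmethod
    def load(cls, path):
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                membrane_name=f.attrs["membrane"],
                a=float(f.attrs["a_m"]),
                f_US=float(f.attrs["f_Hz"]),
                fs=float(f.attrs["fs"]),
                A_grid=f["axes/A_Pa"][:],
                Q_grid=f["axes/Q_C_per_m2"][:],
                tables={k: f["tables"][k][:] for k in f["tables"]},
                constants_sha=str(f.attrs["constants_sha"]),
                n_cycles=f["n_cycles"][:] if "n_cycles" in f else None,
            )


def _effective_row(membrane, Qm, fs, Cm_profiles):
    """Cycle averages for one charge value from a stored Cm(t) profile."""
    Cm_fs = coverage_weighted_capacitance(Cm_profiles, fs, membrane.Cm0)
    Vm_t = Qm / Cm_fs
    out = {"V": float(np.mean(Vm_t)), "Cm": 1.0 / float(np.mean(1.0 / Cm_fs))}
    for g in membrane.gates:
        al, be = membrane.rates(g, Vm_t)
        out[f"alpha_{g}"] = float(np.mean(al))
        out[f"beta_{g}"] = float(np.mean(be))
    return out


def _resting_row(membrane, Q_grid):
    """Exact A = 0 row: resting-membrane evaluation at Vm = Q / Cm0."""
    Vm = Q_grid / membrane.Cm0
    row = {"V": Vm.copy(), "Cm": np.full_like(Q_grid, membrane.Cm0)}
    for g in membrane.gates:
        al, be = membrane.rates(g, Vm)
        row[f"alpha_{g}"] = np.asarray(al, dtype=float)
        row[f"beta_{g}"] = np.asarray(be, dtype=float)
    return row


def build_lookup(
    membrane,
    a: float = 32e-9,
    f_US: float = 500e3,
    A_grid=None,
    Q_grid=None,
    fs: float = 0.8,
    consts: BLSConstants = None,
    settings: MechSolverSettings = None,
    fs_list=None,
):
    """Precompute effective-variable tables for one membrane model.

    Each nonzero-amplitude cell runs one cavitation limit cycle at fixed
    charge; the stored capacitance profile is then rescaled by the coverage
    fraction, so several ``fs`` values can be tabulated without re-running
    the mechanics (pass ``fs_list`` to obtain a dict ``fs -> lookup``).
    """
    if isinstance(membrane, str):
        membrane = get_membrane(membrane)
    consts = consts or BLSConstants()
    A_grid = default_amplitude_grid() if A_grid is None else np.asarray(A_grid, dtype=float)
    Q_grid = default_charge_grid(membrane) if Q_grid is None else np.asarray(Q_grid, dtype=float)
    all_fs = list(fs_list) if fs_list is not None else [fs]
    Delta = equilibrium_gap(membrane.Qm0, consts)
    names = _table_names(membrane)
    tables = {f: {k: np.empty((len(A_grid), len(Q_grid))) for k in names} for f in all_fs}
    n_cycles = np.zeros((len(A_grid), len(Q_grid)), dtype=int)
    rest = _resting_row(membrane, Q_grid)
    for f in all_fs:
        for k in names:
            tables[f][k][0, :] = rest[k]
    for ia, A in enumerate(A_grid[1:], start=1):
        for iq, Q in enumerate(Q_grid):
            try:
                prof = cavitation_cycle(
                    a, f_US, A, Q, consts, Delta=Delta, Cm0=membrane.Cm0, settings=settings
                )
            except Exception as e:
                raise RuntimeError(f"mechanical solver failed at cell A={A!r} Pa, Q={Q!r} C/m^2") from e
            n_cycles[ia, iq] = prof.n_cycles_to_converge
            for f in all_fs:
                row = _effective_row(membrane, Q, f, prof.Cm_t)
                for k in names:
                    tables[f][k][ia, iq] = row[k]
    sha = _constants_sha(consts)
    out = {
        f: EffectiveLookup(
            membrane_name=membrane.name,
            a=a,
            f_US=f_US,
            fs=f,
            A_grid=A_grid,
            Q_grid=Q_grid,
            tables=tables[f],
            constants_sha=sha,
            n_cycles=n_cycles,
        )
        for f in all_fs
    }
    return out if fs_list is not None else out[all_fs[0]]


# ----------------------------------------------------------------------------
# Queries and runtime projection
# ----------------------------------------------------------------------------

def _check_axis(val, grid, name):
    if np.any(val < grid[0]) or np.any(val > grid[-1]):
        raise OutOfTableError(
            f"query outside table hull on axis {name!r}: value {val!r} not in "
            f"[{grid[0]!r}, {grid[-1]!r}]"
        )


def query_effective(lookup: EffectiveLookup, A: float, Qm: float) -> dict:
    """Bilinear interpolation of all effective variables at (A, Qm).

    Exact on grid nodes; raises :class:`OutOfTableError` outside the hull.
    """
    _check_axis(A, lookup.A_grid, "amplitude")
    _check_axis(Qm, lookup.Q_grid, "charge")
    ia = min(np.searchsorted(lookup.A_grid, A, side="right") - 1, len(lookup.A_grid) - 2)
    iq = min(np.searchsorted(lookup.Q_grid, Qm, side="right") - 1, len(lookup.Q_grid) - 2)
    ia = max(ia, 0)
    iq = max(iq, 0)
    wa = (A - lookup.A_grid[ia]) / (lookup.A_grid[ia + 1] - lookup.A_grid[ia])
    wq = (Qm - lookup.Q_grid[iq]) / (lookup.Q_grid[iq + 1] - lookup.Q_grid[iq])
    out = {}
    for k, t in lookup.tables.items():
        out[k] = float(
            t[ia, iq] * (1 - wa) * (1 - wq)
            + t[ia + 1, iq] * wa * (1 - wq)
            + t[ia, iq + 1] * (1 - wa) * wq
            + t[ia + 1, iq + 1] * wa * wq
        )
    return out


@dataclass
class ProjectedTables:
    """Per-compartment 1D charge-space functions of the effective variables.

    Produced by interpolating a lookup along the amplitude axis at each
    compartment's local amplitude; evaluation along the charge axis is
    vectorized over compartments (one shared charge grid).
    """

    Q_grid: np.ndarray  # (nQ,)
    tables: dict  # name -> (n_comp, nQ)
    amplitudes: np.ndarray  # (n_comp,) Pa

    @property
    def n_comp(self):
        return len(self.amplitudes)

    def interp_all(self, Qm):
        """Evaluate every variable at per-compartment charges (clipped to grid)."""
        Qm = np.asarray(Qm, dtype=float)
        Qg = self.Q_grid
        Qc = np.clip(Qm, Qg[0], Qg[-1])
        idx = np.clip(np.searchsorted(Qg, Qc, side="right") - 1, 0, len(Qg) - 2)
        w = (Qc - Qg[idx]) / (Qg[idx + 1] - Qg[idx])
        rows = np.arange(len(Qm))
        return {k: t[rows, idx] * (1.0 - w) + t[rows, idx + 1] * w for k, t in self.tables.items()}

    def interp(self, name, Qm):
        return self.interp_all(np.asarray(Qm, dtype=float))[name] if np.ndim(Qm) else float(
            np.interp(Qm, self.Q_grid, self.tables[name][0])
        )


def runtime_projection(lookup: EffectiveLookup, A_per_compartment) -> ProjectedTables:
    """Project the lookup onto per-compartment 1D functions of charge.

    Linear interpolation along the amplitude axis at each compartment's
    local amplitude (0 during stimulus-off phases).
    """
    A = np.atleast_1d(np.asarray(A_per_compartment, dtype=float))
    _check_axis(A, lookup.A_grid, "amplitude")
    ia = np.clip(np.searchsorted(lookup.A_grid, A, side="right") - 1, 0, len(lookup.A_grid) - 2)
    wa = (A - lookup.A_grid[ia]) / (lookup.A_grid[ia + 1] - lookup.A_grid[ia])
    tables = {}
    for k, t in lookup.tables.items():
        tables[k] = t[ia, :] * (1.0 - wa)[:, None] + t[ia + 1, :] * wa[:, None]
    return ProjectedTables(Q_grid=lookup.Q_grid.copy(), tables=tables, amplitudes=A)


def direct_projection(
    membrane,
    A_per_compartment,
    a: float = 32e-9,
    f_US: float = 500e3,
    Q_grid=None,
    fs: float = 0.8,
    consts: BLSConstants = None,
    settings: MechSolverSettings = None,
) -> ProjectedTables:
    """Charge-space projection computed by fresh mechanical runs at exact amplitudes.

    Equivalent to building a lookup whose amplitude grid contains each
    requested amplitude exactly; free of amplitude-interpolation bias, used
    for point-model titrations.
    """
    if isinstance(membrane, str):
        membrane = get_membrane(membrane)
    consts = consts or BLSConstants()
    A = np.atleast_1d(np.asarray(A_per_compartment, dtype=float))
    Q_grid = default_charge_grid(membrane) if Q_grid is None else np.asarray(Q_grid, dtype=float)
    Delta = equilibrium_gap(membrane.Qm0, consts)
    names = _table_names(membrane)
    tables = {k: np.empty((len(A), len(Q_grid))) for k in names}
    rest = _resting_row(membrane, Q_grid)
    cache = {}
    for ic, Ai in enumerate(A):
        if Ai == 0.0:
            for k in names:
                tables[k][ic, :] = rest[k]
            continue
        key = float(Ai)
        if key not in cache:
            rows = {k: np.empty(len(Q_grid)) for k in names}
            for iq, Q in enumerate(Q_grid):
                prof = cavitation_cycle(a, f_US, Ai, Q, consts, Delta=Delta, Cm0=membrane.Cm0, settings=settings)
                row = _effective_row(membrane, Q, fs, prof.Cm_t)
                for k in names:
                    rows[k][iq] = row[k]
            cache[key] = rows
        for k in names:
            tables[k][ic, :] = cache[key][k]
    return ProjectedTables(Q_grid=Q_grid.copy(), tables=tables, amplitudes=A)
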