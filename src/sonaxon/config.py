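"""Run configuration, constants provenance and result persistence."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .constants import BLSConstants

#: Default sonophore constants with provenance, shipped as YAML text so the
#: values can be inspected and overridden from a config file.  SI units with
#: explicit suffixes in the key names.
DEFAULT_BLS_YAML = """\
# Bilayer sonophore constants (SI units).
# Values follow the intramembrane-cavitation modeling literature
# (bilayer sonophore model and its cycle-averaged extension).
rho_l_kg_per_m3: 1075.0      # surrounding liquid density
mu_l_Pa_s: 7.0e-4            # liquid dynamic viscosity (water, 36 degC)
mu_s_Pa_s: 0.035             # leaflet dynamic viscosity
d_leaflet_m: 2.0e-9          # leaflet thickness
D_gl_m2_per_s: 3.68e-9       # gas diffusion coefficient in the liquid
xi_m: 0.5e-9                 # gas-transport boundary-layer thickness
C_g_mol_per_m3: 0.62         # dissolved gas concentration (air-saturated)
k_H_Pa_m3_per_mol: 1.613e5   # Henry constant (air)
P_0_Pa: 1.0e5                # hydrostatic pressure
k_s_N_per_m: 0.24            # leaflet areal compression modulus
A_r_Pa: 1.0e5                # intermolecular pressure amplitude
lj_x: 5.0                    # intermolecular repulsion exponent
lj_y: 3.3                    # intermolecular attraction exponent
delta_star_m: 1.4e-9         # charge-free inter-leaflet gap; reproduces the
                             # 1.1 / 1.3 nm charged equilibrium gaps
eps_r: 1.0                   # relative permittivity of the gap
T_abs_K: 309.15              # absolute temperature (36 degC)
"""

_YAML_KEYS = {
    "rho_l_kg_per_m3": "rho_l",
    "mu_l_Pa_s": "mu_l",
    "mu_s_Pa_s": "mu_s",
    "d_leaflet_m": "d_leaflet",
    "D_gl_m2_per_s": "D_gl",
    "xi_m": "xi",
    "C_g_mol_per_m3": "C_g",
    "k_H_Pa_m3_per_mol": "k_H",
    "P_0_Pa": "P_0",
    "k_s_N_per_m": "k_s",
    "A_r_Pa": "A_r",
    "lj_x": "lj_x",
    "lj_y": "lj_y",
    "delta_star_m": "delta_star",
    "eps_r": "eps_r",
    "T_abs_K": "T_abs",
}


def default_bls_yaml() -> str:
    return DEFAULT_BLS_YAML


def bls_constants_from_yaml(text: str = None) -> BLSConstants:
    """Parse sonophore constants from YAML (defaults when ``text`` is None)."""
    data = yaml.safe_load(text if text is not None else DEFAULT_BLS_YAML)
    kwargs = {}
    for yk, attr in _YAML_KEYS.items():
        if yk in data:
            kwargs[attr] = float(data[yk])
    unknown = set(data) - set(_YAML_KEYS)
    if unknown:
        raise ValueError(f"unknown constant keys in config: {sorted(unknown)}")
    return BLSConstants(**kwargs)


@dataclass
class RunConfig:
    """Serializable description of one simulation run."""

    membrane: str = "senn_node"
    fiber_kind: str = "node"  # node | senn | sundt
    fiber_D_um: float = 10.0
    fiber_length_mm: float = 10.0
    a_nm: float = 32.0
    fs: float = 0.8
    f_US_kHz: float = 500.0
    field_kind: str = "gaussian"  # gaussian | uniform
    field_width_mm: float = 5.0
    peak_amplitude_kPa: float = 120.0
    PD_ms: float = 1.0
    PRF_Hz: float = None
    n_pulses: int = 1
    tail_ms: float = 10.0
    lookup_nA: int = 15
    lookup_nQ: int = 30
    atol_Q_nC_per_cm2: float = 1e-3
    rng_seed: int = 0
    out_dir: str = "results"

    def validate(self):
        errors = []
        if self.fiber_kind not in ("node", "senn", "sundt"):
            errors.append("fiber_kind")
        if self.membrane not in ("senn_node", "sundt", "passive"):
            errors.append("membrane")
        if not 0 <= self.fs <= 1:
            errors.append("fs")
        for key in ("fiber_D_um", "a_nm", "f_US_kHz", "PD_ms", "peak_amplitude_kPa"):
            if getattr(self, key) is None or getattr(self, key) <= 0:
                errors.append(key)
        if errors:
            raise ValueError(f"invalid run config values for keys: {errors}")

    def sha(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None):
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text
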