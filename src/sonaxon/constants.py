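"""Physical constants and default bilayer-sonophore parameters.

All quantities are SI unless the name carries an explicit unit suffix.
The sonophore parameter values follow the intramembrane-cavitation
literature (bilayer sonophore model and its cycle-averaged extension);
they are also shipped as a YAML config with per-key provenance comments
(see :func:`sonaxon.config.default_bls_yaml`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

#: Universal gas constant (J/mol/K)
R_GAS = 8.314

#: Faraday constant (C/mol)
FARADAY = 96485.0

#: Vacuum permittivity (F/m)
EPS0 = 8.854e-12


@dataclass(frozen=True)
class BLSConstants:
    """Parameters of the bilayer-sonophore pressure system.

    Attributes
    ----------
    rho_l : float
        Density of the surrounding liquid (kg/m^3).
    mu_l : float
        Dynamic viscosity of the surrounding liquid (Pa*s).
    mu_s : float
        Dynamic viscosity of the leaflet (Pa*s).
    d_leaflet : float
        Thickness of one leaflet (m); enters the membrane viscous stress.
    D_gl : float
        Diffusion coefficient of gas in the surrounding liquid (m^2/s).
    xi : float
        Boundary-layer thickness for gas transport across the leaflet (m).
    C_g : float
        Dissolved gas concentration in the surrounding liquid (mol/m^3).
    k_H : float
        Henry constant for the dissolved gas (Pa*m^3/mol).
    P_0 : float
        Static (hydrostatic) pressure in the surrounding liquid (Pa).
    k_s : float
        Areal compression modulus of one leaflet (N/m).
    A_r : float
        Amplitude coefficient of the intermolecular (Lennard-Jones)
        pressure (Pa).
    lj_x, lj_y : float
        Repulsion and attraction exponents of the intermolecular
        pressure (dimensionless, lj_x > lj_y).
    delta_star : float
        Inter-leaflet gap of a charge-free membrane at equilibrium (m).
    eps_r : float
        Relative permittivity of the inter-leaflet space (dimensionless).
    T_abs : float
        Absolute temperature (K). Fixed at 36 degC.
    """

    rho_l: float = 1075.0
    mu_l: float = 7.0e-4
    mu_s: float = 0.035
    d_leaflet: float = 2.0e-9
    D_gl: float = 3.68e-9
    xi: float = 0.5e-9
    C_g: float = 0.62
    k_H: float = 1.613e5
    P_0: float = 1.0e5
    k_s: float = 0.24
    A_r: float = 1.0e5
    lj_x: float = 5.0
    lj_y: float = 3.3
    delta_star: float = 1.4e-9
    eps_r: float = 1.0
    T_abs: float = 309.15

    def __post_init__(self):
        for k, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"BLS constant {k!r} must be strictly positive, got {v}")
        if not self.lj_x > self.lj_y:
            raise ValueError("repulsion exponent lj_x must exceed attraction exponent lj_y")

    def replace(self, **kwargs) -> "BLSConstants":
        return replace(self, **kwargs)

    def asdict(self) -> dict:
        return asdict(self)
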