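"""Membrane-repulsion energetics and the resulting Boltzmann distance density.

Two short-range repulsions keep the SV from touching the PM: the steric
hydration force between hydrated lipid headgroups,

    E_hyd(d) = 2π λ² g P₀ e^(−d/λ),

and the screened electrostatic repulsion between the negatively charged
membranes,

    E_el(d) = g Z_mb e^(−d/λ_D),   Z_mb = 9.38·10⁻¹¹ · tanh²(φ₀ / 107),

with the geometric factor ``g`` equal to the SV radius (sphere–plane
geometry), φ₀ the membrane potential in millivolts, λ the hydration decay
length and λ_D the Debye screening length.  Energies are evaluated in joules
(all lengths converted to SI once, at evaluation).  The equilibrium gap
density in the absence of tethers is the Boltzmann weight
``P_hyd,el(d) ∝ exp(−(E_hyd + E_el)/k_B T)`` normalized to unit area on
``[0, d_max]``; the exponent reaches ≈ −7·10⁴ at contact, so the weight is
computed in the log domain and shifted before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistancePDF, normalized, uniform_pdf
from .errors import InvalidSpecError

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

_NM = 1e-9  # nm → m


@dataclass(frozen=True)
class EnergeticsConfig:
    """Membrane-repulsion parameters (defaults: phospholipid bilayers at 310 K).

    Parameters
    ----------
    P0
        Hydration force amplitude, Pa.
    lambda_hyd
        Hydration decay length, nm.
    lambda_debye
        Debye screening length, nm (0.8 nm ≈ 150 mM salt).
    phi0
        Membrane potential, mV.
    T
        Temperature, K.
    g_factor
        Geometric factor for sphere–plane geometry: the SV radius, nm.
    enabled
        When False, all repulsion energies are zero and the equilibrium
        density is uniform (the dehydrated, force-free limit).
    """

    P0: float = 6e10
    lambda_hyd: float = 0.2
    lambda_debye: float = 0.8
    phi0: float = -60.0
    T: float = 310.0
    g_factor: float = 20.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.lambda_hyd, self.lambda_debye, self.g_factor) <= 0:
            raise InvalidSpecError("lengths must be positive")
        if self.T <= 0:
            raise InvalidSpecError("temperature must be positive")


def hydration_energy(d, cfg: EnergeticsConfig):
    """Steric-hydration repulsion energy at gap ``d`` (nm), in joules."""
    d = _check_distance(d)
    if not cfg.enabled:
        return np.zeros_like(d) if isinstance(d, np.ndarray) else 0.0
    lam = cfg.lambda_hyd * _NM
    g = cfg.g_factor * _NM
    return 2.0 * np.pi * lam**2 * g * cfg.P0 * np.exp(-d / cfg.lambda_hyd)


def membrane_charge_factor(phi0_mV: float) -> float:
    """The Z_mb prefactor of the electrostatic repulsion (φ₀ in mV)."""
    return 9.38e-11 * np.tanh(phi0_mV / 107.0) ** 2


def electrostatic_energy(d, cfg: EnergeticsConfig):
    """Screened electrostatic repulsion energy at gap ``d`` (nm), in joules."""
    d = _check_distance(d)
    if not cfg.enabled:
        return np.zeros_like(d) if isinstance(d, np.ndarray) else 0.0
    g = cfg.g_factor * _NM
    return g * membrane_charge_factor(cfg.phi0) * np.exp(-d / cfg.lambda_debye)


def total_energy(d, cfg: EnergeticsConfig):
    """E_hyd + E_el at gap ``d`` (nm), joules."""
    return hydration_energy(d, cfg) + electrostatic_energy(d, cfg)


def log_boltzmann_weight(d_grid: np.ndarray, cfg: EnergeticsConfig) -> np.ndarray:
    """Unnormalized log Boltzmann weight −E(d)/k_B T on a distance grid."""
    d = np.asarray(d_grid, dtype=float)
    if not cfg.enabled:
        return np.zeros_like(d)
    return -total_energy(d, cfg) / (K_B * cfg.T)


def boltzmann_distance_pdf(cfg: EnergeticsConfig, d_grid: np.ndarray) -> DistancePDF:
    """Equilibrium gap density of an untethered SV on ``d_grid``.

    Log-domain evaluation: the weight is shifted by its maximum before
    exponentiation so that the huge contact-energy exponents underflow to an
    exact 0 rather than NaN.  With ``enabled=False`` the density is uniform.
    """
    d = np.asarray(d_grid, dtype=float)
    if not cfg.enabled:
        return uniform_pdf(d)
    logw = log_boltzmann_weight(d, cfg)
    w = np.exp(logw - logw.max())
    return normalized(d, w, occupancy_label=(0, 0, 0))


def _check_distance(d):
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise InvalidSpecError("distance must be non-negative")
    return arr if arr.ndim else float(arr)
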