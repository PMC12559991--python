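"""Composite steady-state SV–PM distance densities and movement probabilities.

A vesicle held by ``n_i`` tethers of species ``i`` at equilibrium samples the
gap density

    φ(d, n₁, n₂, n₃) ∝ P_hyd,el(d) · ∏ᵢ gᵢ(d)^{nᵢ},

where ``P_hyd,el`` is the membrane-repulsion Boltzmann density and ``gᵢ`` is
the species' assembly-rate profile renormalized to unit area (the density of
positions a single formed tether of that species holds the SV at).  Tethers
act as independent units, so multiple tethers multiply — and thereby sharpen
and shift — the density.  The product is re-normalized after every
combination.  Movement in the jump process is biased by the same density:
the probability of a downward step from ``d`` is
``m = φ(d−Δ)/(φ(d−Δ) + φ(d))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distributions import (DistancePDF, normalized, pdf_median,
                            pdf_quartile_width)
from .errors import (ContractError, DegenerateStateError,
                     DegenerateProfileError, InvalidSpecError,
                     UndefinedMoveError)
from .geometry import AssemblyRateProfile, HeightDistributionSpec

__all__ = [
    "TetherTypeSpec",
    "single_tether_distance_pdf",
    "composite_distance_pdf",
    "move_down_probability",
    "pdf_median",
    "pdf_quartile_width",
    "DistancePDF",
]

#: Log-density floor standing in for "outside the support" (exactly zero density).
LOG_ZERO = -1.0e6


@dataclass(frozen=True)
class TetherTypeSpec:
    """One tether species: height law, kinetic constants and copy number.

    ``kon_max`` is the maximal assembly rate (attained where g_on = 1) and
    ``koff`` the per-tether disassembly rate, both in s⁻¹; ``n_total`` is the
    number of copies available for tethering.
    """

    name: str
    height_spec: HeightDistributionSpec
    kon_max: float
    koff: float
    n_total: int

    def __post_init__(self) -> None:
        if self.kon_max < 0 or self.koff < 0:
            raise InvalidSpecError("rate constants must be non-negative")
        if int(self.n_total) != self.n_total or self.n_total < 0:
            raise InvalidSpecError("n_total must be a non-negative integer")


def single_tether_distance_pdf(profile: AssemblyRateProfile) -> DistancePDF:
    """Gap density of an SV held by exactly one tether of a species.

    This is the species' assembly-rate profile renormalized to unit area:
    the same geometry that sets where a tether can *form* sets where a formed
    tether *holds* the vesicle.
    """
    if profile.values.max() <= 0:
        raise DegenerateProfileError(
            f"profile for {profile.tether_type or 'tether'} is zero everywhere")
    return normalized(profile.d_grid, profile.values)


def _log_density(pdf: DistancePDF) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logp = np.log(pdf.density)
    return np.where(pdf.density > 0, logp, LOG_ZERO)


def composite_distance_pdf(single_pdfs: Sequence[DistancePDF],
                           counts: Sequence[int],
                           boltzmann: DistancePDF) -> DistancePDF:
    """Gap density of an SV held by ``counts[i]`` tethers of each species.

    Parameters
    ----------
    single_pdfs
        Per-species single-tether densities ``gᵢ(d)`` (unit area), all on the
        same grid as ``boltzmann``.
    counts
        Tether counts ``(n₁, n₂, n₃)``; with all counts zero the Boltzmann
        density is returned unchanged.
    boltzmann
        Membrane-repulsion equilibrium density (or the uniform density when
        repulsion is disabled).

    The product is evaluated in the log domain (a count of nine raised on a
    small density underflows otherwise) and re-normalized to unit area.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != len(single_pdfs):
        raise ContractError("need one count per tether species")
    if any(c < 0 for c in counts):
        raise ContractError("tether counts must be non-negative")
    if all(c == 0 for c in counts):
        return DistancePDF(boltzmann.d_grid, boltzmann.density, (0, 0, 0))

    logp = _log_density(boltzmann).copy()
    for pdf, n in zip(single_pdfs, counts):
        if n == 0:
            continue
        if pdf.d_grid.shape != boltzmann.d_grid.shape or not np.array_equal(
                pdf.d_grid, boltzmann.d_grid):
            raise ContractError("all PDFs in a composite must share one d_grid")
        logp = logp + n * _log_density(pdf)
    peak = logp.max()
    if peak <= LOG_ZERO / 2:
        raise DegenerateStateError(
            f"composite density for occupancy {counts} vanishes everywhere")
    dens = np.exp(np.maximum(logp - peak, LOG_ZERO))
    label = counts if len(counts) == 3 else None
    return normalized(boltzmann.d_grid, dens, label)


def move_down_probability(phi_down: float, phi_here: float) -> float:
    """Probability that the next spatial step is toward the PM.

    ``phi_down`` is the composite density one step closer to the PM and
    ``phi_here`` the density at the current gap; the step is taken downhill
    with probability φ(d−Δ)/(φ(d−Δ) + φ(d)).
    """
    if phi_down < 0 or phi_here < 0:
        raise ContractError("densities must be non-negative")
    total = phi_down + phi_here
    if total == 0:
        raise UndefinedMoveError("density vanishes at both candidate positions")
    return phi_down / total
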