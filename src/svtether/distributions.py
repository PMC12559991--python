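"""Probability densities over the SV–PM distance axis.

A :class:`DistancePDF` is a density over the gap ``d`` between the synaptic
vesicle (SV) surface and the plasma membrane (PM), tabulated on an ordered
grid in nanometres and normalized so that its trapezoidal integral is one.
All composite-state densities, the membrane-repulsion (Boltzmann) density
and the reweighted no-repulsion mixtures in this package share this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

#: Absolute tolerance on the trapezoidal area of any normalized density.
NORMALIZATION_ATOL = 1e-6


def trapezoid_area(d_grid: np.ndarray, density: np.ndarray) -> float:
    """Trapezoidal integral of ``density`` over ``d_grid``."""
    return float(np.trapezoid(density, d_grid))


@dataclass(frozen=True)
class DistancePDF:
    """A normalized probability density over SV–PM distance.

    Parameters
    ----------
    d_grid
        Ordered distances in nm.
    density
        Non-negative density values in nm⁻¹, trapezoid-normalized to 1.
    occupancy_label
        Optional tether-count triple ``(n_snare, n_munc13, n_syt)`` the
        density is conditioned on.
    """

    d_grid: np.ndarray
    density: np.ndarray
    occupancy_label: tuple[int, int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.d_grid, dtype=float)
        p = np.asarray(self.density, dtype=float)
        if d.ndim != 1 or d.shape != p.shape:
            raise ContractError("d_grid and density must be 1-D arrays of equal length")
        if np.any(np.diff(d) <= 0):
            raise ContractError("d_grid must be strictly increasing")
        if np.any(p < 0):
            raise ContractError("density must be non-negative")
        object.__setattr__(self, "d_grid", d)
        object.__setattr__(self, "density", p)

    @property
    def area(self) -> float:
        return trapezoid_area(self.d_grid, self.density)

    def require_normalized(self) -> None:
        area = self.area
        if abs(area - 1.0) > NORMALIZATION_ATOL:
            raise ContractError(f"density is not normalized (area={area!r})")

    def cdf(self) -> np.ndarray:
        """Trapezoidal cumulative distribution on the grid."""
        d, p = self.d_grid, self.density
        c = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(d))])
        return c

    def quantile(self, q: float) -> float:
        """Quantile by linear interpolation of the trapezoidal CDF."""
        self.require_normalized()
        c = self.cdf()
        c = c / c[-1]
        return float(np.interp(q, c, self.d_grid))

    def mode(self) -> float:
        """Grid location of the maximum density value."""
        return float(self.d_grid[int(np.argmax(self.density))])


def normalized(d_grid: np.ndarray, values: np.ndarray,
               occupancy_label: tuple[int, int, int] | None = None) -> DistancePDF:
    """Scale non-negative ``values`` to unit trapezoidal area and wrap them."""
    area = trapezoid_area(d_grid, values)
    if not np.isfinite(area) or area <= 0:
        raise ContractError("cannot normalize: non-positive or non-finite area")
    return DistancePDF(d_grid, np.asarray(values, dtype=float) / area, occupancy_label)


def uniform_pdf(d_grid: np.ndarray) -> DistancePDF:
    """The uniform density on the span of ``d_grid``."""
    d = np.asarray(d_grid, dtype=float)
    return DistancePDF(d, np.full_like(d, 1.0 / (d[-1] - d[0])))


def pdf_median(pdf: DistancePDF) -> float:
    """Median distance of a normalized :class:`DistancePDF` (nm)."""
    return pdf.quantile(0.5)


def pdf_quartile_width(pdf: DistancePDF) -> float:
    """Interquartile range (75% − 25% quantile) of the density (nm)."""
    return pdf.quantile(0.75) - pdf.quantile(0.25)
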