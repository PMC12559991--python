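"""Tether geometry: effective-height PDFs and distance-dependent assembly profiles.

Each tether species (SNARE complex, Munc13, synaptotagmin) is characterized by
the *effective height* ``h`` it can span between the plasma membrane (PM) and
its attachment point on the synaptic vesicle (SV).  Heights are random: uniform
between the minimum and maximum reach for SNARE and Syt, or — for the rod-like
Munc13 — the pushforward of a normal membrane angle α through ``h = l·sin α``.

Attachment points are restricted to the lower SV hemisphere.  For a spherical
SV of radius ``r``, a tether of height ``h`` formed while the SV sits at gap
``d`` attaches at lateral offset ``x = sqrt(r² − (r − h + d)²)`` from the SV
axis, and the density of attachment offsets grows linearly with circumference,
``f₁(x) = 2x/r²``.  Integrating ``f₁(x(h, d))·f₂(h)`` over the reachable
heights gives the (unnormalized) rate at which that tether species can form at
gap ``d``; dividing by the profile maximum yields the dimensionless
assembly-rate profile ``g_on(d) ∈ [0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProfileError, InvalidSpecError

__all__ = [
    "GeometryConfig",
    "HeightDistributionSpec",
    "HeightPDF",
    "AssemblyRateProfile",
    "build_height_pdf",
    "location_pdf",
    "assembly_rate_profile",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Geometric and quadrature settings.

    Parameters
    ----------
    r
        SV radius in nm (default 20, a typical small synaptic vesicle).
    d_max
        Largest tracked SV–PM gap in nm.
    h_quadrature_step
        Height-grid step (nm) used for building height PDFs and for the
        assembly-rate quadrature.
    d_fine_step
        Distance-grid step (nm) for static (steady-state) analyses.
    angle_step_deg
        Angle-grid step (degrees) for the Munc13 angle pushforward.
    """

    r: float = 20.0
    d_max: float = 100.0
    h_quadrature_step: float = 0.005
    d_fine_step: float = 0.01
    angle_step_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.r <= 0 or self.d_max <= 0:
            raise InvalidSpecError("r and d_max must be positive")
        if min(self.h_quadrature_step, self.d_fine_step, self.angle_step_deg) <= 0:
            raise InvalidSpecError("grid steps must be positive")

    def fine_d_grid(self) -> np.ndarray:
        n = int(round(self.d_max / self.d_fine_step))
        return np.linspace(0.0, self.d_max, n + 1)


@dataclass(frozen=True)
class HeightDistributionSpec:
    """Distribution of a tether's effective height.

    Two kinds are supported: ``"uniform"`` on ``[h_min, h_max]`` and
    ``"angle-normal"``, the distribution of ``l·sin α`` for a protein rod of
    length ``l`` whose PM angle α (degrees) is normal with the given mean and
    SD.  Angles beyond 90° fold back onto the same height automatically.
    """

    kind: str
    h_min: float | None = None
    h_max: float | None = None
    protein_length: float | None = None
    angle_mean: float | None = None
    angle_sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if self.h_min is None or self.h_max is None:
                raise InvalidSpecError("uniform spec needs h_min and h_max")
            if not (0 < self.h_min < self.h_max):
                raise InvalidSpecError("uniform spec requires 0 < h_min < h_max")
        elif self.kind == "angle-normal":
            if self.protein_length is None or self.angle_mean is None or self.angle_sd is None:
                raise InvalidSpecError("angle-normal spec needs length, angle mean and sd")
            if self.protein_length <= 0:
                raise InvalidSpecError("protein_length must be positive")
            if self.angle_sd <= 0:
                raise InvalidSpecError("angle_sd must be positive")
        else:
            raise InvalidSpecError(f"unknown height distribution kind {self.kind!r}")

    @classmethod
    def uniform(cls, h_min: float, h_max: float) -> "HeightDistributionSpec":
        return cls(kind="uniform", h_min=h_min, h_max=h_max)

    @classmethod
    def angle_normal(cls, protein_length: float, angle_mean: float,
                     angle_sd: float) -> "HeightDistributionSpec":
        return cls(kind="angle-normal", protein_length=protein_length,
                   angle_mean=angle_mean, angle_sd=angle_sd)


@dataclass(frozen=True)
class HeightPDF:
    """Effective-height density ``f₂(h)`` with its quadrature representation.

    ``h_grid``/``density`` tabulate the density itself (nm, nm⁻¹).
    ``quad_nodes``/``quad_weights`` represent the same distribution as a
    weighted point set (Σ w = 1) used to integrate functions of ``h``
    against f₂.  For angle-derived heights the nodes live on the angle grid
    pushed through ``h = l·sin α``, which integrates accurately through the
    inverse-square-root density singularity at ``h = l`` that a plain
    height-grid trapezoid rule cannot handle.
    """

    h_grid: np.ndarray
    density: np.ndarray
    quad_nodes: np.ndarray
    quad_weights: np.ndarray

    @property
    def h_min(self) -> float:
        return float(self.h_grid[0])

    @property
    def h_max(self) -> float:
        return float(self.h_grid[-1])

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.density, self.h_grid))


@dataclass(frozen=True)
class AssemblyRateProfile:
    """Normalized assembly-rate shape ``g_on(d)`` for one tether type.

    ``values`` are dimensionless in [0, 1] with maximum exactly 1; zero for
    gaps the tether cannot bridge.
    """

    d_grid: np.ndarray
    values: np.ndarray
    tether_type: str = ""


def build_height_pdf(spec: HeightDistributionSpec, cfg: GeometryConfig) -> HeightPDF:
    """Tabulate the normalized effective-height density for ``spec``.

    Uniform specs are tabulated directly on ``[h_min, h_max]``.  Angle-normal
    specs push a dense α grid on (0°, 180°) through ``h = l·sin α``, binning
    the normal weights onto a height grid of step ``h_quadrature_step``; the
    fold at α = 90° is handled by the binning itself.
    """
    step = cfg.h_quadrature_step
    if spec.kind == "uniform":
        n = max(int(np.ceil((spec.h_max - spec.h_min) / step)), 1)
        h = np.linspace(spec.h_min, spec.h_max, n + 1)
        f = np.full_like(h, 1.0 / (spec.h_max - spec.h_min))
        # trapezoid weights of the density itself
        w = np.full_like(h, (h[1] - h[0]) / (spec.h_max - spec.h_min))
        w[0] *= 0.5
        w[-1] *= 0.5
        return HeightPDF(h, f, h, w)

    # angle-normal: numeric pushforward of Normal(angle_mean, angle_sd)
    length = spec.protein_length
    alpha = np.arange(cfg.angle_step_deg / 2, 180.0, cfg.angle_step_deg)
    w = np.exp(-0.5 * ((alpha - spec.angle_mean) / spec.angle_sd) ** 2)
    w /= w.sum()
    h_of_alpha = length * np.sin(np.radians(alpha))
    keep = w > 1e-300
    nodes, w = h_of_alpha[keep], w[keep]
    edges = np.arange(0.0, length + step, step)
    idx = np.clip(np.digitize(nodes, edges) - 1, 0, len(edges) - 2)
    mass = np.bincount(idx, weights=w, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # trim leading/trailing zero mass so the support is tight
    nz = np.nonzero(mass)[0]
    lo, hi = nz[0], nz[-1] + 1
    centers, mass = centers[lo:hi], mass[lo:hi]
    area = np.trapezoid(mass, centers)
    return HeightPDF(centers, mass / area, nodes, w)


def location_pdf(x, r: float):
    """Density ``f₁(x) = 2x/r²`` of the lateral attachment offset on the SV.

    ``x`` is the distance from the SV axis of the attachment point projected
    onto the PM; valid on ``[0, r]`` and zero outside.  Accepts scalars or
    arrays; negative ``x`` raises.
    """
    if r <= 0:
        raise InvalidSpecError("r must be positive")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InvalidSpecError("attachment offset x must be non-negative")
    out = np.where(x_arr <= r, 2.0 * x_arr / r**2, 0.0)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _unnormalized_profile(hpdf: HeightPDF, cfg: GeometryConfig,
                          d_grid: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Quadrature of f₁(x(h, d))·f₂(h) over reachable heights, per distance."""
    r = cfg.r
    h = hpdf.quad_nodes
    w = hpdf.quad_weights
    out = np.empty_like(d_grid)
    for start in range(0, len(d_grid), chunk):
        d = d_grid[start:start + chunk, None]
        arg = r**2 - (r - h[None, :] + d) ** 2
        # lower-hemisphere contact only: h in [max(h_min, d), min(h_max, d + r)]
        mask = (h[None, :] >= d) & (h[None, :] <= d + r) & (arg > 0)
        x = np.sqrt(np.where(mask, arg, 0.0))
        out[start:start + chunk] = (
            np.where(mask, 2.0 * x / r**2 * w[None, :], 0.0).sum(axis=1))
    return out


def assembly_rate_profile(hpdf: HeightPDF, cfg: GeometryConfig, d_grid: np.ndarray,
                          tether_type: str = "") -> AssemblyRateProfile:
    """Build the normalized assembly-rate profile ``g_on(d)`` for one species.

    For each gap ``d`` the height density is integrated over
    ``[max(h_min, d), min(h_max, d + r)]`` against the attachment-offset
    density evaluated at ``x(h, d) = sqrt(r² − (r − h + d)²)``; the resulting
    curve is divided by its maximum.

    Raises
    ------
    DegenerateProfileError
        If the profile vanishes at every grid distance.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    raw = _unnormalized_profile(hpdf, cfg, d_grid)
    peak = raw.max()
    if peak <= 0:
        raise DegenerateProfileError(
            f"assembly profile for {tether_type or 'tether'} has empty support")
    return AssemblyRateProfile(d_grid, raw / peak, tether_type)
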