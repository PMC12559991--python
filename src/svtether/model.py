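"""The assembled docking model: three tether species + membrane repulsion.

:class:`DockingModel` ties together the geometry, energetics and steady-state
layers.  It precomputes, per tether species, the effective-height PDF, the
assembly-rate profile and the single-tether distance density on two grids:

* a *fine* grid (default step 0.01 nm) used for static analyses, where the
  published medians are quoted to 0.01 nm, and
* the *simulation* grid (0.5 nm step) that the jump process lives on.

The fine-grid artifacts are built lazily so simulation-only workflows skip
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

from .distributions import DistancePDF, uniform_pdf
from .energetics import EnergeticsConfig, boltzmann_distance_pdf, log_boltzmann_weight
from .errors import ContractError
from .geometry import (AssemblyRateProfile, GeometryConfig, HeightPDF,
                       assembly_rate_profile, build_height_pdf)
from .steady_state import (LOG_ZERO, TetherTypeSpec, composite_distance_pdf,
                           single_tether_distance_pdf)

#: Simulation distance resolution, nm.
SIM_STEP = 0.5


@dataclass(frozen=True)
class _GridTables:
    """Per-grid tabulations shared by static and dynamic code paths."""

    d_grid: np.ndarray
    profiles: tuple[AssemblyRateProfile, ...]
    single_pdfs: tuple[DistancePDF, ...]
    boltzmann: DistancePDF
    log_boltz: np.ndarray          # log of the *unnormalized* Boltzmann weight
    log_g: np.ndarray              # (n_types, n_d) log single-tether densities

    @classmethod
    def build(cls, specs, geometry: GeometryConfig, energetics: EnergeticsConfig,
              hpdfs: Sequence[HeightPDF], d_grid: np.ndarray) -> "_GridTables":
        profiles = tuple(
            assembly_rate_profile(hpdf, geometry, d_grid, spec.name)
            for spec, hpdf in zip(specs, hpdfs))
        singles = tuple(single_tether_distance_pdf(p) for p in profiles)
        boltz = boltzmann_distance_pdf(energetics, d_grid)
        log_boltz = log_boltzmann_weight(d_grid, energetics)
        log_g = np.full((len(specs), len(d_grid)), LOG_ZERO)
        for i, s in enumerate(singles):
            pos = s.density > 0
            log_g[i, pos] = np.log(s.density[pos])
        return cls(d_grid, profiles, singles, boltz, log_boltz, log_g)


class DockingModel:
    """Three tether species, membrane repulsion, and their tabulated densities.

    Parameters
    ----------
    specs
        The tether species, conventionally ordered (SNARE, Munc13, Syt).
    geometry
        SV radius, tracked range and quadrature steps.
    energetics
        Membrane-repulsion parameters; ``enabled=False`` yields the
        force-free model with a uniform untethered density.
    """

    def __init__(self, specs: Sequence[TetherTypeSpec],
                 geometry: GeometryConfig | None = None,
                 energetics: EnergeticsConfig | None = None) -> None:
        self.specs = tuple(specs)
        if len(self.specs) != 3:
            raise ContractError("DockingModel expects exactly three tether species")
        self.geometry = geometry or GeometryConfig()
        self.energetics = energetics or EnergeticsConfig()
        self.height_pdfs: tuple[HeightPDF, ...] = tuple(
            build_height_pdf(s.height_spec, self.geometry) for s in self.specs)

    # ---- grids ---------------------------------------------------------

    def sim_d_grid(self) -> np.ndarray:
        n = int(round(self.geometry.d_max / SIM_STEP))
        return np.linspace(0.0, self.geometry.d_max, n + 1)

    @cached_property
    def sim(self) -> _GridTables:
        """Tabulations on the 0.5 nm simulation grid."""
        return _GridTables.build(self.specs, self.geometry, self.energetics,
                                 self.height_pdfs, self.sim_d_grid())

    @cached_property
    def fine(self) -> _GridTables:
        """Tabulations on the fine static-analysis grid."""
        return _GridTables.build(self.specs, self.geometry, self.energetics,
                                 self.height_pdfs, self.geometry.fine_d_grid())

    def _tables(self, grid: str) -> _GridTables:
        if grid == "fine":
            return self.fine
        if grid == "sim":
            return self.sim
        raise ContractError(f"unknown grid {grid!r}")

    # ---- static densities ---------------------------------------------

    def composite_pdf(self, counts: Sequence[int], grid: str = "fine",
                      repulsion: bool | None = None) -> DistancePDF:
        """Composite gap density φ(d, n₁, n₂, n₃) for a tether occupancy.

        ``repulsion=False`` replaces the Boltzmann base density with the
        uniform density (the force-free evaluation used to mimic dehydrated
        EM preparations); the default follows the model's energetics flag.
        """
        t = self._tables(grid)
        if repulsion is None or repulsion == self.energetics.enabled:
            base = t.boltzmann
        else:
            base = (boltzmann_distance_pdf(self.energetics, t.d_grid)
                    if repulsion else uniform_pdf(t.d_grid))
        return composite_distance_pdf(t.single_pdfs, counts, base)

    def kon(self, type_index: int, d_grid_values: np.ndarray | None = None) -> np.ndarray:
        """Distance-dependent assembly rate k_on(d) = g_on(d)·k_on,max (sim grid)."""
        g = self.sim.profiles[type_index].values
        return g * self.specs[type_index].kon_max

    def with_energetics(self, enabled: bool) -> "DockingModel":
        """A copy of the model with membrane repulsion toggled."""
        cfg = EnergeticsConfig(**{**self.energetics.__dict__, "enabled": enabled})
        return DockingModel(self.specs, self.geometry, cfg)

    def describe(self) -> dict:
        """JSON-serializable snapshot of every model parameter."""
        return {
            "specs": [
                {"name": s.name, "kon_max": s.kon_max, "koff": s.koff,
                 "n_total": s.n_total,
                 "height_spec": {k: v for k, v in s.height_spec.__dict__.items()
                                 if v is not None}}
                for s in self.specs],
            "geometry": dict(self.geometry.__dict__),
            "energetics": dict(self.energetics.__dict__),
        }
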