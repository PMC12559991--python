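"""Reference parameter set for the three-tether docking model.

The default model tracks three tether species between a 20 nm-radius SV and
the PM:

* **SNARE** — the partially zippered complex, the shortest tether; effective
  height uniform on 2–8 nm; disassembly rate halved relative to the other
  species to compensate for the fact that its maximal assembly rate is not
  reachable at attainable gaps.
* **Munc13** — a ~20 nm rod standing at 80 ± 5° to the PM; height is
  20·sin α nm.
* **Syt** — synaptotagmin bridging to PM PI(4,5)P₂; the longest and most
  variable tether, uniform on 5–29 nm.

Copy numbers default to nine per species.  The *realistic-stoichiometry*
variant uses 35 SNAREs and 7 Syts (half of the biochemically counted copies,
i.e. those on the PM-facing hemisphere).
"""

from __future__ import annotations

from .energetics import EnergeticsConfig
from .geometry import GeometryConfig, HeightDistributionSpec
from .model import DockingModel
from .steady_state import TetherTypeSpec

#: Conventional species order used throughout the package.
TETHER_NAMES = ("SNARE", "Munc13", "Syt")

SNARE_HEIGHT = HeightDistributionSpec.uniform(2.0, 8.0)
MUNC13_HEIGHT = HeightDistributionSpec.angle_normal(20.0, 80.0, 5.0)
SYT_HEIGHT = HeightDistributionSpec.uniform(5.0, 29.0)

#: Vesicle mobility: rate of 0.5 nm spatial steps, s⁻¹.
MOBILITY_RATE = 16000.0


def default_specs(n_total: tuple[int, int, int] = (9, 9, 9),
                  kon_max: tuple[float, float, float] = (40.0, 40.0, 40.0),
                  koff: tuple[float, float, float] = (50.0, 100.0, 100.0),
                  snare_height: tuple[float, float] = (2.0, 8.0),
                  ) -> tuple[TetherTypeSpec, TetherTypeSpec, TetherTypeSpec]:
    """The reference (SNARE, Munc13, Syt) species with optional overrides."""
    snare_spec = (SNARE_HEIGHT if tuple(snare_height) == (2.0, 8.0)
                  else HeightDistributionSpec.uniform(*snare_height))
    return (
        TetherTypeSpec("SNARE", snare_spec, kon_max[0], koff[0], n_total[0]),
        TetherTypeSpec("Munc13", MUNC13_HEIGHT, kon_max[1], koff[1], n_total[1]),
        TetherTypeSpec("Syt", SYT_HEIGHT, kon_max[2], koff[2], n_total[2]),
    )


def control_model(geometry: GeometryConfig | None = None,
                  energetics: EnergeticsConfig | None = None) -> DockingModel:
    """The control model: nine copies of each species, repulsion on."""
    return DockingModel(default_specs(), geometry, energetics)
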