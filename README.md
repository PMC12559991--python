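# svtether

A stochastic tether model of synaptic-vesicle (SV) docking.

Before a synaptic vesicle can fuse with the presynaptic plasma membrane
(PM) it must be trafficked to, and held at, the membrane by protein
tethers of very different lengths: the SNARE complex (effective height
2–8 nm), Munc13 (a ~20 nm rod standing at 80 ± 5° to the PM) and
synaptotagmin (5–29 nm).  `svtether` implements a coarse-grained model of
this process for computational neuroscientists and synaptic biophysicists:
tether assembly rates that depend on the SV–PM gap through vesicle
geometry, hydration + electrostatic membrane repulsion, composite
steady-state distance distributions per tether occupancy, and exact
(Gillespie) stochastic simulation of vesicle movement coupled to tether
turnover — including knockout, tether-elongation and stoichiometry
scenarios.

## The model in brief

With `nᵢ` tethers of species `i` formed, the SV–PM gap `d` samples

    φ(d, n₁, n₂, n₃) ∝ P_hyd,el(d) · ∏ᵢ gᵢ(d)^{nᵢ}

where `P_hyd,el ∝ exp(−(E_hyd + E_el)/k_BT)` is the Boltzmann density under
membrane repulsion and `gᵢ` is the species' geometry-derived
assembly/holding density, `g_on(d) ∝ ∫ f₁(√(r² − (r − h + d)²)) f₂(h) dh`,
built from the tether-height density `f₂` and the attachment-offset density
`f₁(x) = 2x/r²` on a vesicle of radius `r = 20` nm.  Dynamics follow a
reaction-diffusion jump process: 0.5 nm vesicle steps at mobility
16 000 s⁻¹ biased by φ, binding at `g_onᵢ(d)·k_on,maxᵢ·(n_totalᵢ − nᵢ)`
and unbinding at `k_offᵢ·nᵢ`, simulated exactly with the Gillespie
algorithm.  See `docs/methods.md` for assumptions, parameters and
numerical choices.

## Worked example

```python
from svtether import control_model, pdf_median
from svtether.dynamics import SimConfig, run_replicates
from svtether.analysis import median_distance

model = control_model()              # nine copies per species, repulsion on

# steady state: one vs nine SNARE tethers
print(pdf_median(model.composite_pdf((1, 0, 0))))   # 4.89 nm
print(pdf_median(model.composite_pdf((9, 0, 0))))   # 3.27 nm

# dynamics: pooled dwell-time median over ten 50 s replicates
trajs = run_replicates(model, SimConfig(t_end=50.0, n_reps=10, base_seed=1))
print(median_distance(trajs))                       # ~5.5 nm
```

The first two numbers are medians of the equilibrium gap distribution: a
single SNARE holds the vesicle at 4.89 nm; nine cooperating SNAREs tighten
that to 3.27 nm.  The last is the median gap actually realized by the
simulated control vesicle over 50 s (started untethered at 100 nm) — about
5 nm, versus about 8 nm when SNAREs are removed
(`builtin_scenarios()["snare_ko"]`).

The `examples/` directory holds one short script per capability (geometry
profiles, static distributions, repulsion energetics, control simulation,
knockouts, stoichiometry rescaling, force-free reweighting); each prints
its numbers with a line on what they mean.  A thin CLI wraps the same
functions:

```bash
svtether list-scenarios
svtether static --out static_medians.csv
svtether simulate snare_ko --out-dir runs/snare_ko --seed 1
svtether rescale --kon 40 --koff 100 --alpha 0.7778
```

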