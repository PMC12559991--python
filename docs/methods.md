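# Methods

## The model

`svtether` models the docking of a synaptic vesicle (SV) — a sphere of
radius r = 20 nm — onto the flat plasma membrane (PM) as a one-dimensional
jump process in the gap `d` between the vesicle's closest point and the
membrane, coupled to the binding and unbinding of three species of protein
tether: the (partially zippered) SNARE complex, Munc13 and synaptotagmin
(Syt). The state is `(d, n₁, n₂, n₃)` with `d` on a 0.5 nm grid in
[0, 100] nm and `nᵢ` the number of formed tethers of species `i`.

**Tether geometry.** Each species spans a random *effective height* `h`
from the PM: uniform on 2–8 nm (SNARE) and 5–29 nm (Syt); for the rod-like
Munc13, `h = l·sin α` with `l = 20` nm and the PM angle α normal with mean
80° and SD 5° (angles beyond 90° fold back to the same height).  Tethers
attach anywhere on the PM-facing hemisphere; a tether of height `h` formed
at gap `d` attaches at lateral offset `x = √(r² − (r − h + d)²)`, and the
density of offsets grows with circumference, `f₁(x) = 2x/r²`.  Integrating
`f₁(x(h, d))·f₂(h)` over the reachable heights
`h ∈ [max(h_min, d), min(h_max, d + r)]` and dividing by the curve's
maximum gives the dimensionless assembly profile `g_on(d) ∈ [0, 1]` per
species.  The integral is used as written — no Jacobian of the h→x change
of variables is introduced — since the assembly rate is defined only up to
the species' maximal rate constant.

**Membrane repulsion.** Two short-range repulsions act between the bare
membranes: steric hydration, `E_hyd = 2πλ²gP₀·e^(−d/λ)` with λ = 0.2 nm,
P₀ = 6·10¹⁰ Pa and geometric factor g = r (sphere–plane), and screened
electrostatics, `E_el = g·Z_mb·e^(−d/λ_D)` with λ_D = 0.8 nm and
`Z_mb = 9.38·10⁻¹¹·tanh²(φ₀/107)` at φ₀ = −60 mV.  All lengths are
converted to SI before combining; energies are joules.  The equilibrium gap
density of an untethered SV is the normalized Boltzmann weight
`P_hyd,el(d) ∝ e^(−(E_hyd+E_el)/k_BT)` at T = 310 K.  The exponent reaches
≈ −7·10⁴ at contact, so the weight is evaluated in the log domain and
shifted by its maximum before exponentiation; the contact density
underflows to an exact 0, never NaN.

**Composite distance densities.** A formed tether holds the SV at the same
gaps at which it could form, so the single-tether density `gᵢ(d)` is the
assembly profile renormalized to unit area.  Tethers act independently:

    φ(d, n₁, n₂, n₃) ∝ P_hyd,el(d) · ∏ᵢ gᵢ(d)^{nᵢ},

renormalized after every product.  Repulsion is never overcome by adding
tethers — the model addresses docking, not fusion.

**Dynamics.** Eight reactions: a 0.5 nm step toward or away from the PM at
total mobility 16 000 s⁻¹ split by `m = φ(d−Δ)/(φ(d−Δ)+φ(d))`, binding at
`g_onᵢ(d)·k_on,maxᵢ·(n_totalᵢ−nᵢ)` and unbinding at `k_offᵢ·nᵢ`
(distance-independent).  Waiting times and reaction indices follow the
standard Gillespie scheme (τ = ln(1/q₁)/b₀; first index whose cumulative
rate reaches q₂·b₀).  Reference rate constants: k_on,max = 40 s⁻¹ for all
species; k_off = 100 s⁻¹ for Munc13 and Syt and 50 s⁻¹ for the SNARE
complex (halved because the SNARE's maximal assembly rate is unreachable at
attainable gaps).  Only rate *ratios* shape the stationary distribution, so
simulated times are model-time, not calibrated biological time.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| r | 20 | nm | SV radius |
| d_max | 100 | nm | tracked range; arbitrary, most activity is within 30 nm |
| n_total | (9, 9, 9) | — | copies per species; (35, 9, 7) in the realistic variant |
| k_on,max | (40, 40, 40) | s⁻¹ | maximal assembly rates |
| k_off | (50, 100, 100) | s⁻¹ | disassembly rates (SNARE, Munc13, Syt) |
| mobility | 16 000 | s⁻¹ | rate of 0.5 nm spatial steps |
| P₀, λ | 6e10 Pa, 0.2 nm | | hydration force amplitude and decay |
| λ_D, φ₀ | 0.8 nm, −60 mV | | Debye length, membrane potential |
| T | 310 | K | temperature |
| t_end, n_reps | 50 s, 100 | | published campaign size per condition |

Knockouts are pure copy-number removals (`n_total = 0`); the combined
"Munc13⁻, SNARE⁻" condition zeroes both, representing Munc13's role in
SNARE assembly with no extra mechanism.  SNARE-elongation variants shift
the SNARE height interval to 7–13 or 12–18 nm.

## Numerical choices

- **Grids.** Statics use a 0.01 nm distance grid (medians are quoted to
  0.01 nm); dynamics use the 0.5 nm simulation grid.  All densities on one
  grid share it exactly; mixing grids is an error, never an interpolation.
- **Height quadrature.** Densities are tabulated at 0.005 nm; the profile
  integral uses weighted quadrature nodes — trapezoid nodes for uniform
  heights, angle-grid nodes (step 0.05°) pushed through `l·sin α` for
  Munc13.  The pushforward density diverges like an inverse square root at
  `h = l`, where a plain height-grid trapezoid rule converges only
  ~O(√step); node quadrature integrates through the singularity, and
  halving both steps changes `g_on` by < 10⁻⁵ everywhere.
- **Boundaries.** At d = 0 the downward channel is closed (m treated as 0);
  at d_max the upward channel is closed.  Reflecting boundaries preserve
  normalization; with repulsion on, d = 0 is effectively never reached.
- **Zero-density regions.** One step up into a region where φ vanishes is
  legal (the up-rate never consults φ(d+Δ)); the next move is then forced
  downhill.  φ vanishing at the current position *and* one step below
  aborts the run with diagnostics — silent corruption is impossible.  Log
  densities use a −10⁶ floor for exact zeros, comfortably separated from
  the largest genuine exponent (≈ −7·10⁴ at contact).
- **Medians.** Static medians interpolate the trapezoidal CDF linearly.
  Trajectory medians are dwell-time weighted, interpolated within the
  0.5 nm median bin.  Threshold statistics use strict `d < threshold`.
- **Seeding.** Each replicate draws its stream from
  `SeedSequence([base_seed, rep_index])`; the same pair reproduces a
  trajectory bit for bit.  The event loop is numba-compiled with the
  MT19937 generator recorded in the trajectory metadata.
- **Undefined replicate metrics** (e.g. a vesicle that never reached 5 nm)
  are excluded from that metric's mean and the exclusion count is reported.

## Stoichiometry rescaling

The stationary mean count per species at fixed gap is
`n̄ = n_total·k_on/(k_off + k_on)`.  Scaling copies by α is compensated
exactly by `k_on′ = k_on/α` and `k_off′ = k_off + (α−1)·k_on/α`, valid for
`α > k_on/(k_off + k_on)`; the implementation verifies the identity on
every call.  The compensation is applied at the profile maximum
(`g_on = 1`), i.e. at the level of `k_on,max`.  Applied to the published
reference rates this yields 51.4/88.6 s⁻¹ for Syt (9→7 copies) and a SNARE
assembly rate of 10.3 s⁻¹ (9→35 copies); the corresponding SNARE
disassembly rate comes out at 79.7 s⁻¹, whereas the reference table prints
76.7 s⁻¹ (consistent with compensating at the SNARE's maximal *reachable*
assembly rate, ≈0.9·k_on,max).  The builtin
`realistic_stoichiometry_rescaled` scenario uses the printed values
verbatim rather than guessing the intended convention.

## Force-free reweighting

To mimic dehydrated (freeze-substituted) EM preparations, each occupancy
visited by a trajectory has its composite density recomputed with
`E_hyd + E_el = 0` (uniform base density for the untethered state); the
densities are mixed by dwell-time proportions and renormalized.  In the
control condition the mixture piles up against the membrane (mode at
contact, roughly a third of the mass within 2 nm).

## What the simulations do and do not emulate

The simulator generates exactly the study conditions: a single SV started
untethered at 100 nm, 50 s of model time per replicate, 0.5 nm resolution,
copy-number knockouts.  It does not model Ca²⁺-dependent tether states,
fusion or priming kinetics, alternative Munc13 conformations, inter-vesicle
tethers, RIM/Bassoon, explicit tether–tether interactions, 2D/3D diffusion,
or multiple interacting vesicles.  Tether positions on the SV are
independent and unoriented.  Passing tests therefore validate the
stochastic model and its numerics, not the biology these simplifications
exclude; in particular absolute times carry no biological calibration.

## Problem sizes used by the test suite and acceptance script

Static results are exact at the default grids and run in seconds.
Stochastic checks are sized for a single CPU: the acceptance script uses 20
replicates of 50 s per simulated condition (the pooled medians are stable
to ~0.1 nm at that size); property tests use 8–10 replicates of 2–50 s
with 3σ Monte-Carlo bands estimated across replicates.  The full published
campaign (100 replicates per condition) is reproduced by
`svtether simulate <scenario> --n-reps 100`.

## Known limitations

- The Munc13 angle-normal support formally spans all heights up to `l`
  because the normal has unbounded tails; mass beyond mean ± a few SD is
  numerically negligible but the reported support bounds are wide.
- The stationary distribution of the *joint* (distance × occupancy) chain
  is only empirically invariant under fixed-ratio rate scaling; no
  product-form solution is claimed.
- Trajectory files store event-sparse states; analyses of quantities not
  expressible from dwell times (e.g. velocity autocorrelations) would need
  a different representation.
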