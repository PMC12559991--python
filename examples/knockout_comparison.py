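"""Tether-removal (knockout) scenarios at reduced scale.

Removing a species is a pure copy-number change (n_total = 0), so the model
keeps running without extra assumptions.  Prints the pooled median gap and
mean tethered lifetime for the control and the builtin removal conditions.
"""

from svtether.analysis import median_distance, summarize
from svtether.dynamics import SimConfig, run_replicates
from svtether.scenarios import build_model, builtin_scenarios

cfg = SimConfig(t_end=10.0, n_reps=5, base_seed=2)
names = ["control", "snare_ko", "munc13_ko", "munc13_snare_ko", "syt_ko"]

print(f"{'scenario':18s} {'median (nm)':>12s} {'tethered lifetime (s)':>22s}")
for name in names:
    scenario = builtin_scenarios()[name]
    trajs = run_replicates(build_model(scenario), cfg)
    s = summarize(trajs)
    life = (f"{s.mean_tethered_lifetime:10.3f}"
            if s.mean_tethered_lifetime is not None else "       n/a")
    print(f"{name:18s} {median_distance(trajs):12.2f} {life:>22s}")

print()
print("SNARE removal shifts the vesicle population outward and every removal")
print("shortens the tethered episodes.  (At the full published scale, 100")
print("replicates of 50 s, the medians settle at ~5 nm control vs ~8 nm")
print("without SNAREs; the short runs here carry more burn-in from the")
print("100 nm start.)")
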