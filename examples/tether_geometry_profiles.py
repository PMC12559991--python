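"""Effective tether heights and distance-dependent assembly profiles.

Builds the height distributions of the three tether species and the
assembly-rate profiles g_on(d) they imply for a 20 nm vesicle, then prints
where each species can bridge and where it binds fastest.
"""

import numpy as np

from svtether import control_model

model = control_model()
d = model.fine.d_grid

for spec, hpdf, prof in zip(model.specs, model.height_pdfs, model.fine.profiles):
    reach = d[prof.values > 0]
    peak = d[np.argmax(prof.values)]
    print(f"{spec.name:7s} heights {hpdf.h_min:5.2f}-{hpdf.h_max:5.2f} nm | "
          f"can bridge gaps up to {reach.max():5.2f} nm | "
          f"fastest assembly at d = {peak:4.2f} nm")

print()
print("Short tethers (SNARE) bind ever faster as the vesicle approaches: more")
print("of the vesicle surface comes within reach.  Syt is longer than the")
print("vesicle radius, so its binding rate peaks at 5-10 nm and then drops.")
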