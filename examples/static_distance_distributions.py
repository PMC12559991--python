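"""Steady-state vesicle-membrane distance versus number of formed tethers.

For each species, combines the membrane-repulsion density with n copies of
the single-tether density and prints the median gap and interquartile width.
More tethers of any species pull the vesicle closer and confine it more
tightly -- the cooperative effect of multiple protein copies.
"""

from svtether import control_model, pdf_median, pdf_quartile_width

model = control_model()

print(f"{'species':8s} {'n':>2s} {'median (nm)':>12s} {'IQR width (nm)':>15s}")
for i, spec in enumerate(model.specs):
    for n in (1, 3, 9):
        counts = [0, 0, 0]
        counts[i] = n
        pdf = model.composite_pdf(counts)
        print(f"{spec.name:8s} {n:2d} {pdf_median(pdf):12.2f} "
              f"{pdf_quartile_width(pdf):15.2f}")

print()
print("One SNARE holds the vesicle at ~4.9 nm median; nine SNAREs at ~3.3 nm.")
print("The untethered vesicle (repulsion only) has no preferred distance")
print("beyond ~5 nm, so its median sits near the middle of the tracked range.")
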