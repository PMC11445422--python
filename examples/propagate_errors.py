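"""Propagate the diffraction-precision-index (DPI) coordinate error to
distance uncertainties.

With DPI = 0.07 A and a uniform B-factor profile every atom carries the
average coordinate error, so every distance error is sqrt(2) * 0.07 A; with
per-atom B-factors the errors scale as sigma_i = DPI * sqrt(B_i / B_avg).
"""

from gfpstate import (STRUCTURE_PRESETS, annotate_errors, atom_sigma,
                      build_structure, distance_sigma, measure)

model = build_structure(STRUCTURE_PRESETS["I_like"])   # uniform B, DPI 0.07 A
report = annotate_errors(model, measure(model))

print(f"DPI (sigma_average)        : {model.dpi:.3f} A")
print(f"B average                  : {model.b_average:.1f} A^2")
print(f"d_his  = {report.d_his:.2f} +/- {report.sigma_his:.4f} A")
print(f"d_203  = {report.d_203:.2f} +/- {report.sigma_203:.4f} A")
print(f"atom at 4x the average B   : sigma = {atom_sigma(0.07, 80.0, 20.0):.4f} A")
print(f"distance between two such  : sigma = "
      f"{distance_sigma(atom_sigma(0.07, 80.0, 20.0), 0.07):.4f} A")
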