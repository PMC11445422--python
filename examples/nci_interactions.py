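"""Characterise non-covalent interactions with a reduced-density-gradient scan.

Evaluates the promolecular density, its reduced gradient s(r) and the
Hessian-signed density sign(lambda2)*rho on a grid around two fixtures: an
N-H...O hydrogen bond at the exemplar 2.85 A heavy-atom distance, and a
neon pair at van der Waals contact (3.1 A).  Low-s, low-rho clusters mark
interactions; the sign and size of sign(lambda2)*rho classifies them.
"""

import json

from gfpstate import build_density_fixture, nci_scan

for kind in ("hbond_triplet", "vdw_pair"):
    model = build_density_fixture(kind)
    _, summary = nci_scan(model, s_iso=0.4, rho_cutoff=0.05)
    print(f"== {kind} ==")
    for c in summary:
        print(f"  cluster between {c['between'][0]}-{c['between'][1]}: "
              f"{c['class']}  sign(l2)rho = {c['signed_rho_at_min_s']:+.5f} a.u.")
    print()

print("Negative sign(lambda2)rho of a few 1e-2 a.u. marks an attractive")
print("hydrogen bond; magnitudes near zero mark weak van der Waals contact.")
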