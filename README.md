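# gfpstate

Structure-based analysis of the green fluorescent protein (GFP) photocycle
ground states. GFP interconverts between three ground states — **A** (neutral,
protonated chromophore phenol), **B** (anionic chromophore stabilised by the
Thr203 hydroxyl) and the intermediate **I** (anionic chromophore in an A-like
protein environment). `gfpstate` implements the structural toolkit needed to
tell them apart from high-resolution crystal structures, plus the
spectroscopic and density-based companions:

* **Geometry** — chromophore-environment distances, side-chain χ1 torsions
  and rotamer wells, heavy-atom hydrogen-bond strength bins
  (2.5 ≤ d ≤ 3.0 Å normal, 3.0 < d ≤ 3.5 Å weak, d > 3.5 Å no bond), the
  bridging-water search and the Gln222 amide-orientation call.
* **Error propagation** — per-atom coordinate errors from the diffraction
  precision index, σᵢ = DPI·√(Bᵢ/B_avg), combined in quadrature per distance,
  σ_l = √(σᵢ² + σⱼ²).
* **State classification** — the A/B/I call from two distances:
  d_his = Nδ1(His148)···Oη(chromophore) and d_203 = Oγ1/Cγ2(203)···Oη.
  A normal-strength His148 bond with an unbonded 203 site ⇒ **I**; with a
  hydrogen-bonded Thr203 hydroxyl (O···O ≤ 3.2 Å) ⇒ **B**; a weak or absent
  His148 bond ⇒ **A**.
* **Titration** — weighted least-squares fit of the I-state fraction to the
  Henderson–Hasselbalch curve f(pH) = 1/(1 + 10^(pKa−pH)), with a
  curvature-based pKa uncertainty.
* **NCI analysis** — reduced density gradient
  s(r) = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}) and sign(λ₂)ρ on a grid over a
  promolecular density, classifying low-s/low-ρ clusters as attraction,
  weak contact or repulsion; cube-file output.
* **Synthetic data** — GFP-like structure fixtures with exactly prescribed
  distances, torsions and B-factors, Henderson–Hasselbalch titration
  datasets with replicate noise, and small atom sets for the NCI oracle
  tests. No downloads are ever required.

## Worked example

```python
from gfpstate import STRUCTURE_PRESETS, RunConfig, run_classification

config = RunConfig(presets=list(STRUCTURE_PRESETS), out_dir="out")
calls, table, failures = run_classification(config)
print(table[["structure_id", "d_his", "sigma_his", "d_203", "state"]])
```

prints

```
 structure_id  d_his  sigma_his  d_203 state
       I_like   2.85   0.098995    3.6     I
A_like_low_pH   3.24   0.098995    3.6     A
    A_like_wt   3.30   0.098995    3.4     A
  B_like_S65T   2.80   0.098995    2.8     B
 B_like_E222Q   2.90   0.098995    2.7     B
```

The 2.85 Å His148 bond is normal-strength hydrogen bonding and, with no
hydroxyl partner at position 203, marks the I state; at 3.24 Å the bond is
weak and the structure is an A-state one; the B-state structures bond the
chromophore on both axes. Every σ is √2·DPI = 0.0990 Å because these
fixtures carry uniform B-factors. The titration companion:

```python
from gfpstate import build_titration, fit_pka
fit = fit_pka(build_titration(seed=1))
print(f"pKa = {fit.pka:.3f} +/- {fit.pka_sd:.3f}")   # pKa = 6.015 +/- 0.011
```

More narrative scripts live in `examples/` (state classification, titration
fitting, DPI error propagation, NCI interaction scans); each prints the
numbers it computes and a line on what they mean. A thin CLI wraps the same
pipeline: `gfpstate classify --preset I_like`, `gfpstate titrate`,
`gfpstate nci --fixture hbond_triplet`, `gfpstate synth structure ...`.

## Scope

Diffraction data processing, refinement and the DPI computation itself are
out of scope (the DPI is an input), as are QM/MM geometry optimisation, DFT
electron densities (the NCI module uses promolecular densities) and
excited-state photophysics. See `docs/methods.md` for models, defaults and
limitations.
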