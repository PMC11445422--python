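# Methods

## The structural state model

GFP's ground states differ in the protonation of the chromophore phenol and
in how the protein pocket responds. `gfpstate` reduces the state call to two
heavy-atom distances measured on a single structure:

* `d_his` — Nδ1 of His148 to the chromophore phenol oxygen Oη,
* `d_203` — the distal side-chain atom at position 203 (Oγ1 for Thr, Cγ2
  for Val/Ile) to Oη.

Hydrogen-bond strength is binned on the donor–acceptor heavy-atom distance
alone: 2.5 ≤ d ≤ 3.0 Å *normal*, 3.0 < d ≤ 3.5 Å *weak*, d > 3.5 Å *no
bond*, d < 2.5 Å flagged as a clash. Distances of exactly 3.0 Å and 3.5 Å
are assigned to the stronger class. No angular criterion is applied because
crystallographic models at this resolution carry no hydrogens; this is a
documented limitation — a geometrically strained contact at a favourable
distance would still be counted.

The decision rule is a pure function of the His148 bond class and the
position-203 bonding:

| His148 bond | 203 site H-bonded to Oη | state |
|---|---|---|
| normal | yes (hydroxyl O, d ≤ 3.2 Å) | B |
| normal | no (carbon atom, or O beyond 3.2 Å) | I |
| weak / none | either | A |
| clash (< 2.5 Å) | either | unclassified |

A carbon at the distal 203 position (Val, Ile) never counts as
hydrogen-bonded regardless of distance: C–H···O contacts are weak
attraction in the NCI sense, not hydrogen bonds on these axes. The
3.2 Å O···O hydroxyl cutoff sits between the weak-bond limit (3.5 Å) and
the normal range, reflecting that a B-state-defining Thr203–phenolate bond
is an ordinary hydroxyl–oxyanion hydrogen bond; it is configurable. The
scatter-plot regions the rule operationalises are stated in the literature
verbally; the printed exemplar distances (2.85 Å → I context, 3.24 Å → A
context) are all separated correctly by the category rule, which we take as
the normative reading.

Supporting calls: the χ1 torsion (N–CA–CB–γ, IUPAC sign) is classified
into rotamer wells with inclusive lower edges — gauche− on [−120°, 0°),
gauche+ on [0°, 120°), trans elsewhere — a full partition of (−180°, 180°].
The Gln222 amide orientation compares d(Oε1, Oγ65) with d(Nε2, Oγ65); the
closer amide atom names the orientation, and differences under 0.2 Å
(conservative against the ~0.07–0.1 Å coordinate error of 1.2–1.5 Å
structures) give "undetermined". "Wat3" is operationally the water oxygen
within 3.5 Å of both the chromophore Oη and Ser205 Oγ that minimises the
summed distance; ties are broken on coordinates so the result is invariant
under record reordering.

Altloc policy: when alternative conformations exist the highest-occupancy
conformer is selected, ties broken by altloc letter. Reported single
distances require one representative conformer; whether deposited
structures used conformer A or an occupancy-weighted position is generally
unstated, so this is our convention, applied consistently to geometry and
B-factors.

## Coordinate-error propagation

The diffraction precision index (DPI) is an average coordinate error from
refinement and is an *input* here (computing it needs refinement statistics
that are out of scope). Per-atom errors scale with the atomic displacement
parameter, σᵢ = DPI·√(Bᵢ/B_avg) with B_avg the occupancy-weighted mean, and
each distance carries σ_l = √(σᵢ² + σⱼ²). With uniform B this collapses to
σ_l = √2·DPI for every distance (0.0990 Å at DPI = 0.07 Å), a closed form
the tests pin down. No covariance between atoms is modelled.

## Titration fitting

The I-state fraction follows the Henderson–Hasselbalch curve
f(pH) = 1/(1 + 10^(pKa−pH)) with the Hill coefficient fixed at 1 (a single
protonating site; no cooperativity is modelled). `fit_pka` minimises
Σ wₖ (fₖ − f(pHₖ))² with wₖ = 1/sdₖ² when per-point standard deviations are
given and unit weights otherwise; scaling all weights by a constant leaves
the estimate unchanged. The 1-σ uncertainty is the Gauss–Newton curvature
estimate: the weighted residual variance divided by Σ wₖ (∂f/∂pKa)², square
rooted. Data that never sample the transition (all fractions below 0.05 or
above 0.95) raise a non-identifiability error rather than returning an
arbitrary number. `fraction_from_spectra` performs two-state linear
unmixing of peak absorbances with a configurable extinction-coefficient
ratio (default 1.0); the pipeline fits fractions, not raw spectra — fitting
absorbance at a fixed wavelength would be the main alternative and differs
only in weighting.

## Reduced-density-gradient (NCI) analysis

Interactions are read from s(r) = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}) and sign(λ₂)ρ,
λ₂ the middle eigenvalue of the density Hessian (sign(0) = +1 by
convention). The density is **promolecular** — a sum of spherical,
unrelaxed atomic densities — not a DFT density; this preserves the
qualitative attraction/weak/repulsion classification the method is used
for, at the cost of quantitative ρ values at critical points. Atomic
densities are built in code from single-zeta Slater-type-orbital shells
with Slater's-rules exponents, giving radial terms c·rᵖ·e^(−r/ζ) (atomic
units) whose gradient and Hessian are assembled analytically; each
element's terms integrate to its electron count (tested). Parameters are
provided for H, C, N, O, Ne and S. Single-zeta valence shells decay faster
than Hartree–Fock tails, so very-low-density features (van der Waals
sheets) are thinner than with fitted multi-exponential promolecular
tables; the grid lattice is therefore anchored on the atom centroid so the
symmetry planes of symmetric fixtures — where |∇ρ| and hence s vanish —
fall exactly on grid planes.

Defaults: grid spacing 0.15 bohr, box padded 2 Å beyond the atoms,
s-isovalue 0.4, covalent exclusion ρ ≥ 0.05 a.u., vacuum floor
ρ ≤ 2×10⁻⁵ a.u., attraction/repulsion threshold |sign(λ₂)ρ| = 0.01 a.u.
(all configurable). Clusters are 26-connected components of the
low-s/low-ρ mask, classified by sign(λ₂)ρ at their minimum-s point and
attributed to the two nearest atoms. A cell-count guard (4×10⁶ points)
rejects runaway grids. At an exact nuclear position the gradient direction
is undefined and the code returns a zero gradient; grids should not (and by
the centroid-anchoring rarely do) sample a cusp exactly. Hydrogens must be
supplied by the caller — deposited crystal structures lack them, so NCI
runs on fixtures or on externally protonated models.

## Synthetic data

The generator is the package's source of study conditions, not a dial.

* **Structures**: minimal clusters containing only the residues the
  measurements touch (chromophore with Oη/Cζ/O2/N2 and the 65-hydroxyl,
  His148, the 203 residue, Ser205, Gln222, optionally the bridging water).
  Atoms are placed by explicit construction — Oη at the origin, each
  partner along a fixed unit vector at the prescribed distance, side-chain
  torsions by natural-extension (NeRF) placement — so realized geometry
  equals the preset exactly rather than to an optimiser's tolerance. The
  five named presets realise the exemplar geometries: I-like (d_his
  2.85 Å, Val203), A-like (3.24 Å Val203 and 3.30 Å Thr203) and B-like
  (2.80/2.90 Å with Thr203 bonded at 2.8/2.7 Å). B-factors are uniform
  (20 Å²) or a ramp; DPI defaults to 0.07 Å.
* **Titrations**: f(pH) = HH(pH; pKa=6) plus Gaussian noise (sd 0.02)
  clipped to [0, 1], three replicates on ten pH points spanning 4.0–8.5 —
  a realistic absorbance-titration design with replicate measurements.
  Clipping at the range ends slightly truncates the noise; the measured
  estimator bias over 200 seeds is below 10⁻² pH units.
* **Density fixtures**: one H atom; two Ne atoms at 3.1 Å (van der Waals
  contact); an N–H···O triplet with the H on the N–O axis, N–H 1.0 Å and
  N···O 2.85 Å (the exemplar hydrogen-bond length).

What passing tests on these fixtures do **not** show: robustness to real
crystallographic pathologies (disorder beyond simple altlocs, missing side
chains, insertion codes, occupancy refinement artefacts), to hydrogen-bond
geometry that distance bins misread, or to promolecular-vs-DFT density
differences. The deposited-structure checks exercise real data but are
opt-in because they require coordinate downloads.

## Numerical choices

* Torsions use atan2 of the standard normal-vector construction; collinear
  triples raise a geometry error rather than returning NaN.
* Rotamer and H-bond bin edges are half-open with the conventions above, so
  the partitions are exact (property-tested).
* The promolecular field accumulates atoms in a canonical sorted order, so
  the result is bit-identical under permutation of the atom list.
* PDB output stores three decimals; round-trip tests therefore compare
  coordinates at 5×10⁻⁴ Å per coordinate, while in-memory round trips are
  exact to machine precision.
* Problem sizes used by tests and the acceptance script — 200 simulated
  titrations, 100 random structure presets, NCI grids of order 10⁵ points —
  were chosen to exercise the statistics at desk scale; all run in seconds.

## Known limitations

Distance-only hydrogen bonds; single-conformer reporting; promolecular
densities (no polarisation, no charge transfer); no symmetry expansion
(all contacts of interest are intra-monomer); insertion codes rejected;
no excited-state analysis or spectral prediction.
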