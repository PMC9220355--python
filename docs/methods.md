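# Methods

## Binding-energy ledger

The ledger assembles supermolecular binding energies from tabulated total
electronic energies of three species — the complex AL, the free
active-site model A and the free ligand L — each in a defined context
(geometry: relaxed monomer or frozen complex geometry; basis: own or full
dimer basis with ghost functions; continuum: diethyl ether for the
protein-like environment, water for the free ligand). All energies are
converted to kJ/mol on ingest (1 hartree = 2625.4996394799 kJ/mol).

Two routes to ΔE_bind are implemented and must agree identically:

1. direct: `E(AL,DEE) − E(A,DEE) − E(L,H2O) + ΔE_BSSE`;
2. component sum: `ΔE_int + ΔE_def(A) + ΔE_def(L) + ΔE_dehydr(L) + ΔE_BSSE`,
   each component computed from its own energy differences.

The two expressions are the same algebra after cancellation, so their
agreement (asserted to 1e-9 relative on seeded random tables) is a pure
bookkeeping check: it fails only if a slot is wired to the wrong record.

**BSSE sign convention.** The counterpoise components are evaluated as
`E_ghost − E_own`, which is negative (extra basis functions lower a
monomer's energy) and therefore deepens ΔE_bind. The conventional
counterpoise correction has the opposite sign and weakens the binding.
Both conventions appear in practice, so the direction is an explicit flag
(`bsse_sign="printed" | "conventional"`, default the former); nothing else
in the pipeline depends on the choice. The monomer-own-basis references
`E_A(A)` and `E_L(L)` are taken at the complex geometry (the same records
as the deformation-energy monomers), which is standard counterpoise
practice; the schema can represent the relaxed-geometry alternative too,
and the route-consistency identity holds either way.

**Thermal corrections** are optional. When a `ΔG_corr` record is present
for all three species, `ΔG_bind,corr = ΔG_corr(AL) − ΔG_corr(A) − ΔG_corr(L)`
and `ΔG_bind = ΔE_bind + ΔG_bind,corr`; when absent, the ΔG fields stay
unset (never zero-filled) and downstream correlation runs on ΔE_bind.
Temperature enters only through the corrections themselves and the
K_D bridge (default 298.15 K).

Ranking sorts by ascending ΔE_bind (or ΔG_bind), ties broken by ligand id.
Published totals exist only for the two strongest chelators (citrate
−267 kJ/mol, oxalate −255 kJ/mol); the packaged ranking fixture fills the
other ligands with clearly labeled synthetic stand-ins chosen weaker than
both, so only the documented ordering is meaningful, not the stand-in
values.

## Assay kinetics

Specific activity converts a photometric slope (AU/min) to enzyme units:
blank-rate subtraction first, then Beer–Lambert (`ε469 = 53,200 M⁻¹cm⁻¹`
for coerulignone), scaling by the reaction volume to µmol/min and
normalising by enzyme mass; 1 U = 1 µmol coerulignone/min. Net rates below
zero are clipped to zero for reporting, with a warning, never silently.
Residual activity is `100 × activity / reference` and is scale-invariant.

Turbidimetric rates are least-squares slopes of intensity versus time over
a stated window (default 40–200 s), reported per minute as a magnitude
plus direction flag, because the sign of the raw trace depends on the
detector convention.

**IC50 model.** The dose–response model is a single-exponential decay
`A(c) = A0·exp(−k c)` fitted by unweighted nonlinear least squares
(initialisation: A0 from the maximum activity, k from a log-linear
regression of the positive activities), with `IC50 = ln 2 / k` and the
standard error propagated as `δIC50 = ln2·δk/k²`. This is the simplest
model consistent with "concentration at half the uninhibited rate"; no
per-point uncertainties are available, hence no weighting. A model-free
log-linear interpolation of the A0/2 crossing is reported alongside as a
sanity check. Non-decaying data raise a "no inhibition detected" error
rather than returning a meaningless IC50. Fitting activity versus
concentration and residual-percent versus concentration differ only in
A0, so only one path is needed; either input works.

**Bridges.** Cheng–Prusoff `K_i = IC50/(1 + [S]/K_M)` assumes competitive
inhibition; K_M is a required user input with no default. The exponential
link is implemented exactly as `K_D = e^(−ΔG/RT)` with `K_i ≈ 1/K_D`; note
this K_D grows with stronger binding, i.e. it behaves as an association
constant and K_i as its reciprocal — the convention is kept as stated
rather than silently "corrected", and the identity `K_i·K_D = 1` is
asserted. The empirical `ln(IC50) = a + b·ΔG` relation is ordinary least
squares on ln-transformed IC50.

## Hydration analysis

The RDF histograms single-reference → target (water-oxygen) distances
under the orthorhombic minimum-image convention, normalised per frame by
the shell volume `4πr²dr` and the bulk density `ρ = N/V` (user-supplied
for non-periodic fixtures). Defaults: `dr = 0.02 Å`, `r_max = 8 Å`
(`r_max` must not exceed half the smallest box length). Hydrogens are
ignored: coordination counts water molecules via their oxygens.
Triclinic boxes are rejected explicitly.

Shell detection runs on a 5-bin moving average and accepts only peaks with
prominence ≥ 0.5 in g units, so Poisson noise around the bulk level g = 1
is not reported as structure; peak positions are refined to sub-bin
precision with a three-point parabola. Coordination numbers integrate
`4πρ g(r) r²` by trapezoid between shell boundaries.

Superposition is the Kabsch algorithm (SVD with determinant sign fix;
reflections excluded). Clustering is the greedy neighbor-count
(GROMOS-style) procedure: repeatedly take the frame with the most
unassigned neighbors within the RMSD cutoff (default 2.5 Å) as a centroid
and remove it with its neighbors; ties go to the lowest frame index, and
clusters are reported by decreasing size. The atom selection for the RMSD
is a parameter (default: all non-hydrogen atoms), since published
cutoff-clustering analyses rarely state it.

## Site geometry

Donor roles follow the histidine-brace nomenclature: N_im(Me-His1),
N_am(Me-His1), N_im(His83), O(Tyr166), plus the exchangeable equatorial
(L_eq) and axial (L_ax) positions. The three nitrogen donors define the
equatorial plane; a donor whose Cu→donor vector is more than 45° out of
that plane is axial, with ties going to equatorial (the published
assignments are by inspection, so the threshold is a documented choice and
the boundary case is pinned by a test). A ligand donor atom within the
bond cutoff of the Cu counts toward denticity; the default cutoff of
2.6 Å covers all published bound positions (up to 2.53 Å) and excludes the
2.80/3.01/3.36 Å "unoccupied or dissociated" cases. π-coordination is
reported as the mean distance to explicitly tagged ring carbons and never
inferred. Hydrogen-bond contacts list polar-H ⋯ O/N pairs within 2.2 Å,
excluding covalent partners.

## Synthetic data

All generators draw from named streams derived from one global seed
(`default_rng([seed, crc32(name)])`), so outputs are bit-reproducible and
adding a generator never perturbs existing fixtures.

- **Energy tables** draw the decomposition components uniformly
  (ΔE_int ∈ [−400,−100], deformations ∈ [0,30]/[0,40],
  ΔE_dehydr ∈ [10,150], BSSE components ∈ [−30,−5]/[−20,−2] kJ/mol — an
  attractive interaction, modest deformation penalties, a dehydration cost
  growing with ligand polarity, and small negative ghost-basis terms) and
  then construct species energies consistent with every formula, recording
  the implied truth. Both ΔE_bind routes hold by construction.
- **Trajectories** fix the Cu at the center of a periodic 20 Å cube, place
  one water per shell at Normal(r, σ) radii in random directions (defaults:
  shells at 2.5 and 3.2 Å, σ = 0.1 Å, matching the two observed hydration
  maxima) over 200 uniform bulk waters. Bulk placements within 2.0 Å of
  the Cu are redrawn — the excluded volume of the ion; without it a
  uniform bulk would put waters on top of the copper and create spurious
  low-r spikes no physical RDF has. The ideal-gas fixture for
  homogeneity and particle-count conservation checks disables both shells
  and exclusion. The two-shell scenario uses 3000 frames by default: a
  one-water σ = 0.1 Å shell needs on the order of a few thousand samples
  for its histogram mode to be stable at the 0.02 Å bin width.
- **Geometries** realize a distance row on idealized orthogonal axes
  (three N donors and L_eq in the xy plane, O(Tyr166)/L_ax on ±z), so the
  distances round-trip exactly; bond angles are idealized and never
  asserted. Ligand-bound fixtures add the published Cu–O bond lengths
  (oxalate 1.978/2.146 Å; citrate with the tyrosine pushed to 3.36 Å) and
  the Gln164 amide hydrogen bond at 1.857 Å.
- **Dose–response** series follow `A0·exp(−ln2·c/IC50)·(1+ε)` with
  multiplicative Gaussian noise (defaults A0 = 100, IC50 = 1 mM, σ = 5%,
  8 concentrations over 0–8 mM); **correlation** sets draw energies
  uniformly in [−270, −100] kJ/mol and `ln(IC50) = a + bΔG + N(0,σ)`
  (defaults a = 1, b = 0.04, σ = 0.3, n = 11).

What the fixtures do not emulate: real water structure beyond the stated
shell model (no orientational correlations, no second-solvation
fine structure), enzyme kinetic mechanism (no K_M/k_cat), instrument
drift or baseline artifacts in traces, and — most importantly — the
quantum-chemical energies themselves, which come from an external
electronic-structure engine. Passing tests therefore demonstrate that the
bookkeeping, fitting and geometric analysis are correct, not that the
physics of any particular ligand is reproduced.

## Numerical choices and degenerate inputs

- Route-consistency and BSSE additivity asserted at 1e-9 relative; unit
  round-trips at 1e-12.
- curve_fit runs unweighted with analytic-free finite-difference
  Jacobians; k ≤ 0 after fitting raises rather than reporting a negative
  IC50.
- Degenerate correlation input (all energies equal) and empty ligand sets
  raise; residual activity requires a positive reference.
- RDF reference selection must resolve to exactly one atom per frame;
  empty target selections raise.
- Clustering of identical frames yields one cluster; the partition
  property (every frame in exactly one cluster, centroid a member) is
  asserted on every run.

## Known limitations

- Orthorhombic boxes only; triclinic minimum-image is out of scope.
- The exponential IC50 model cannot represent partial inhibition plateaus;
  for such data the interpolated crossing is the more honest number.
- The published assay tables are reproduced from printed (rounded) values;
  entries whose printed value does not exceed its printed uncertainty
  cannot be reproduced from the table at any meaningful tolerance and are
  excluded from numeric checks.
- Hexacoordination is described through the six fixed roles; additional
  exotic coordination modes would need new role labels.
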