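# Methods

`pmfkit` implements the free-energy and structural-analysis layer of a
QM/MM-style covalent-inhibition study: umbrella sampling on a reaction
coordinate, WHAM recombination into 1D/2D potentials of mean force,
dual-level spline correction of a cheap-Hamiltonian surface toward a
high-level one, maximum-probability path tracing, stationary-point profile
assembly, and the geometric/nonbonded descriptors used to interpret the
profile (nucleophilic-attack angles, hydrogen bonds, RMSD, ring puckering,
per-residue interaction energies, hydrophobicity maps).

The electronic-structure engine itself is out of scope.  In its place the
`toys` module provides analytic energy surfaces with closed-form PMFs and
barrier heights, paired low-level/high-level surfaces with a closed-form
difference, and molecular fixtures whose descriptors are prescribed by
construction.  Every estimator in the package is validated against these
closed forms.

## Units and constants

Lengths in Å, energies in kcal·mol⁻¹, times in ps, charges in e.
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹; the default temperature is 310 K
(kT ≈ 0.6160 kcal·mol⁻¹).  Quantities conventionally quoted in kJ·mol⁻¹
(the umbrella force constant, 2500 kJ·mol⁻¹·Å⁻²) are converted at the input
boundary with 1 kcal = 4.184 kJ, giving the internal default
k = 597.51 kcal·mol⁻¹·Å⁻².  The Coulomb constant is
332.0636 kcal·Å·mol⁻¹·e⁻².

## Reaction coordinates

Three kinds: interatomic distance, the antisymmetric combination
d(a,b) − d(c,d) (ordered breaking-minus-forming, so reactant states
evaluate negative), and the signed torsion in the IUPAC convention
(positive clockwise looking a→b along b→c).  Analytic Cartesian gradients
are provided for all three — the torsion gradient follows the standard
Blondel–Karplus construction — and are checked against central finite
differences in the test suite.  All coordinates are invariant under rigid
motion of the frame.

## Langevin sampler

Sampling on toy surfaces uses the BAOAB splitting of underdamped Langevin
dynamics with unit mass and reduced time units.  Defaults: dt = 0.01,
friction γ = 10 per time unit.  These are numerical-efficiency choices, not
physical claims: with the stiff default restraint the biased coordinate
oscillates at ω ≈ 24.4 and γ = 10 leaves the oscillator underdamped, which
empirically decorrelates window means faster than either light damping or
near-critical damping at the same step budget.  The equilibration/production
defaults are 5 000 discarded and 20 000 recorded steps per window (the
5 ps / 20 ps protocol at one sample per nominal femtosecond step);
equilibration is discarded by sample index.  Identical seeds give bitwise
identical trajectories; per-window seeds are spawned from one master seed.
A trajectory whose energy becomes non-finite (or exceeds 10⁸) aborts with a
diagnostic rather than returning garbage.

## Grid scans and window construction

`grid_scan` evaluates a model over a rectilinear axis grid with per-axis
steps (defaults 0.05 Å for hydrogen-transfer coordinates, 0.1 Å for
heavy-atom distances), marching so that each node continues from its
predecessor's configuration; for analytic surfaces the configuration is the
node coordinate itself.  `build_windows` places one umbrella window per
selected node, centred at the node and seeded with its configuration.

## WHAM

The estimator solves the standard self-consistent equations in log space.
Because plain Picard iteration approaches the fixed point geometrically and
can stall far from self-consistency while per-iteration changes are already
below any sensible threshold, the solver first maximises the (convex) WHAM
log-likelihood with L-BFGS, polishes the optimum with Newton steps on the
reduced Hessian to ~machine precision (this also makes the result invariant
under window reordering), and then runs the documented stopping rule: the
iteration is converged when the largest change in the window normalisation
free energies, in units of kT, falls below the density tolerance
(default 10⁻³).  Non-convergence raises an error carrying the last profile;
windows whose histograms share no occupied bin raise an explicit
"disconnected histogram" error; mixed-temperature window sets are rejected.

Binning: bin width defaults to half the window spacing, capped at the
thermal width σ = √(kT/k) of the stiffest restraint.  The cap matters: the
restraint Boltzmann factor is evaluated at bin centres, and with
k ≈ 600 kcal·mol⁻¹·Å⁻² it varies by orders of magnitude across a
half-spacing bin, which biases the recovered barrier by ≈ +0.3 kcal·mol⁻¹;
bins no wider than σ reduce that discretisation error below the statistical
noise of the prescribed sampling (≈ 0.1 kcal·mol⁻¹ on the 5 kcal·mol⁻¹
double-well barrier).  A bin-averaged restraint factor (exact via Gaussian
CDFs) is available as `bias_eval="bin-average"` but is *not* the default:
it assumes the underlying density is flat within a bin, and with stiff
springs the in-bin density is dominated by the window's own Gaussian, so it
systematically overcorrects.  Empty bins are reported as NaN with a
warning — flagged, never interpolated.

The activation free energy is read directly from the PMF as
ΔW‡ = max W(transition-state region) − min W(reactant region).  The small
free-energy term associated with fixing the coordinate at the reactant
state is deliberately neglected, as is standard for umbrella-sampling
profiles; the package mirrors that approximation rather than estimating
the term.

## Path tracing on 2D PMFs

The maximum-probability route between two bins is the minimum-cost path on
the 8-connected bin graph with node cost exp(+W/kT) (edge weight = mean of
the endpoint costs × step length; Dijkstra with lexicographic tie-breaking
for reproducibility; empty bins are impassable).  One local-descent sweep
then replaces any interior node by a lower-W bin adjacent to both its path
neighbours.  The 1D profile along the route integrates exp(−W/kT) over 5
bins on each side of the direction perpendicular to the local path tangent,
with bilinear interpolation; the *mean* (not the sum) of the integrand is
used so the profile is insensitive to how many perpendicular points fall
inside the grid near edges.  The profile is min-referenced.

## Dual-level correction

E(ξ) = E_LL(ξ) + S[ΔE](ξ) with ΔE = E_HL − E_LL tabulated on a rectilinear
node grid (at least 4 nodes per axis).  S is a cubic interpolating spline
in 1D and a bicubic tensor-product spline in 2D; both reproduce node values
exactly.  Not-a-knot boundaries are used in 1D: they reproduce polynomials
through degree 3 and avoid the O(h²) boundary layer of natural splines,
which at the default node spacing would alone exceed the 0.05 kcal·mol⁻¹
interpolation budget near the hull edge.  Corrections are applied to
energies at scan/bin nodes, never to individual samples, and evaluation
outside the node hull is a hard error — silent extrapolation is the
characteristic failure mode of dual-level schemes.  Corrected PMF grids are
re-referenced to min 0, so a constant ΔE leaves barriers exactly unchanged.

## Geometric descriptors

*Attack trajectory.*  For nucleophile Nu approaching an sp² carbon C with
carbonyl oxygen O and substituents R1, R2: d = |Nu−C|; the Bürgi–Dunitz
angle α_BD is the Nu–C–O angle; the Flippin–Lodge angle is
α_FL = arcsin(v̂·ŵ) with v̂ = unit(C→Nu), û = unit(C→O), n̂ the unit normal
of the (O, R1, R2) plane oriented so that ŵ = û×n̂ points toward R1.  α_FL
is therefore signed, positive toward R1; reported experimental values are
unsigned, so comparisons use |α_FL|.  The fixture generator inverts these
formulas exactly; combinations with |sin α_FL| > sin α_BD are geometrically
unreachable and rejected.

*Hydrogen bonds.*  Geometric criteria, donor···acceptor distance
≤ 3.0 Å and donor−H···acceptor angle ≥ 135°, both boundaries inclusive
(with a 10⁻⁹ guard so exact-boundary geometries are never lost to float
noise).  Donor hydrogens are located by a 1.3 Å covalent search; donors
without hydrogens are skipped with a warning.  Occupancy is the fraction of
frames in which a donor/acceptor pair satisfies both criteria.

*RMSD.*  Optionally Kabsch-superposed (via scipy's rotational alignment) on
an alignment selection before measurement; both aligned and laboratory-frame
modes are provided since either convention appears in practice.  Heavy-atom
selections exclude hydrogens.

*Ring puckering.*  The four-membered-ring puckering descriptor is the
signed improper torsion of the ring atoms; a sign change along a reaction
step marks puckering inversion.  Generalised (Cremer–Pople) puckering for
larger rings is out of scope.

*Hydrophobicity.*  The Eisenberg consensus normalised scale is embedded as
a 20-residue constant table; pocket aggregates are plain means over member
residues.  Unknown residue names raise with the offending name listed.

## Per-residue interaction energies

E_int = E_elec + E_vdW between a ligand selection and each environment
residue: Coulomb q_iq_j/r terms and 12-6 Lennard-Jones terms
(ε_ij[(R_min,ij/r)¹² − 2(R_min,ij/r)⁶], Lorentz–Berthelot combination),
both multiplied by the CHARMM-style C¹ switching function in r² that is 1
below 14.5 Å and exactly 0 above 16 Å.  Ligand and residue selections are
disjoint by construction so no intramolecular exclusions arise; per-frame
energies are averaged and reported as mean ± sample SD.  The per-residue
terms partition the total ligand–environment energy exactly.  This is the
point-charge MM analogue of an embedded-QM interaction analysis; absolute
values from a polarised QM density would differ, which is why published
per-residue numbers are treated as labels, not reproduction targets.
A comparison table (`rank_interactions`) keeps residues whose |ΔE_int|
between two systems exceeds 1 kcal·mol⁻¹, sorted by magnitude.

## Synthetic data: what it does and does not emulate

The toy surfaces reproduce the *estimation problem* — overlapping biased
histograms, barrier recovery, dual-level stitching, path tracing — with
known answers, at desk-scale sizes: 31 windows × 20 000 samples for the 1D
double well, 13×7 windows × 20 000 samples for the 2D separable surface
(the molecular study behind the design used ~1 800 windows on a ~150 000
atom model; window counts here are properties of the toy grids, not
replications).  The fixtures reproduce the *measurement geometry* of an
active site exactly but contain no conformational ensemble, no solvent, no
polarisation and no force-field realism.  Passing tests therefore
demonstrate correctness of the estimators and descriptors, not the accuracy
of any molecular free-energy prediction.

## Numerical choices and degenerate inputs

Histogram connectivity uses shared occupied bins between windows
(scipy connected components).  Path-cost exponentials are clipped at
exp(500) to avoid overflow on extreme grids.  Dihedrals of collinear atoms,
distance gradients of coincident atoms, and attack geometries with a
collinear carbonyl plane all raise immediately.  PDB parsing reports the
offending line number; insertion codes are an error, not a silent skip;
missing element columns are inferred from atom names with a warning.
Degenerate path ties are broken by lexicographic bin index.  The sampler's
zero-temperature limit reduces to damped relaxation and is tested as such.

## Known limitations

No bootstrap error bars on PMFs (interface stubbed for a later version), no
replica exchange or multi-temperature reweighting, no periodic boundary
conditions anywhere, no DCD/mmCIF readers, and no on-the-fly high-level
energy calls — high-level/low-level pairs always arrive as data.  The
1D/2D WHAM estimator assumes harmonic biases; generic tabulated biases are
not supported.
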