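# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Units and data model

All lengths are nm, energies kJ/mol, times ns, temperatures K; kcal/mol is a
reporting unit only (factor 4.184).  Structures are an ordered atom table
(name, element, residue, chain) plus per-frame coordinates and an
orthorhombic box; triclinic boxes are rejected explicitly rather than
silently mis-wrapped.  Atom indices are 0-based internally; residue numbers
follow the input file (biological numbering such as E14 is preserved).
Centers of mass are mass-weighted from element symbols; an unknown element
falls back to the carbon mass with a warning.  PDB, GRO and multi-frame XYZ
are read and written natively (XYZ in nm, with box and time on the comment
line); XTC/DCD go through MDAnalysis.  Selections are conjunctions of
keyword clauses (`chain`, `resid`, `resname`, `name`, `element`, `water`,
`protein`) and resolve deterministically.

## Hydrogen bonds and Grotthuss wires

A hydrogen bond requires donor–acceptor distance ≤ 0.35 nm (minimum image)
and an acceptor–proton–donor angle ≥ 120°.  The angle vertex is the proton,
so 180° is a perfectly linear bond.  Protons are assigned to donor heavy
atoms geometrically (same residue, within 0.125 nm); explicit hydrogens are
required, and a donor without one is a configuration error naming the
residue.  Neighbour search uses a periodic k-d tree; the test suite checks
it against an all-pairs 27-image brute force.

The wire graph has one node per water (any residue named HOH/SOL/TIP3/WAT/
SPC with exactly one oxygen) plus virtual SOURCE and TARGET nodes.  Edges
are *undirected*: the analysis establishes H-bond connectivity, not
proton-hop directionality — a directional treatment of Grotthuss chains is
out of scope.  SOURCE connects to waters H-bonded to any source atom in
either direction, so a protonated glutamate hydroxyl counts as a donor
while a deprotonated carboxylate only accepts.  TARGET connects to waters
whose oxygen lies beyond the bilayer phosphate level: the mean z of the
phosphate atoms in the relevant leaflet, leaflets partitioned by the sign
of z about the overall phosphate mean, with zero buffer (no buffer being a
deliberate choice; waters exactly in the phosphate plane are not bulk).
The wire search is breadth-first; among equally short paths the one with
the lexicographically smallest residue-id sequence is reported, so results
are reproducible under atom reordering.  Wire fractions are per-frame found
flags averaged per group (e.g. per umbrella window).  Presence series are
smoothed with a normalized Gaussian kernel (reflected boundaries, mass- and
range-preserving); the default width is 1% of the trajectory span, a purely
cosmetic choice exposed in the API.

## Solvation

The central cavity has no sharp geometric definition, so it is
operationalized as a sphere (default radius 0.6 nm) about the midpoint of
the two glutamate carboxyl carbons.  A water is *trapped* when a single
residence interval covers the final `min_residence` of the trajectory;
frame gaps up to a configurable tolerance (default 0) do not break an
interval.  The desolvation time of a presence series is the start of its
final all-zero tail (None while the last frame still shows a wire), which
is invariant under prepending earlier wire-present history.

## Umbrella sampling and WHAM

The bias is U(z) = ½k(z−z₀)² with k in kJ mol⁻¹ nm⁻² — note the ½, which
some force-field conventions fold into k.  The default translocation plan
is two segments: 36 windows from −0.3 to 1.45 nm spaced 0.05 nm with
k = 5000, and 8 windows from 1.6 to 3.0 nm spaced 0.2 nm with k = 200.
WHAM iterates the standard self-consistent equations in log space
(logsumexp throughout) until the window free energies move by less than
1e-6 kT (default), or flags non-convergence with the iteration count.
Defaults: bin width 0.025 nm, max 10⁵ iterations, z treated as
non-periodic.  Empty bins stay NaN — never interpolated.  Adjacent windows
sharing no occupied bin trigger a warning; fully disconnected histogram
groups are an error.  Profiles are anchored at min = 0 and are otherwise
defined up to an additive constant; alignment for comparison zeroes each
profile's mean over a reference region, by default z ≥ 2.5 nm (the bulk
plateau).  Consensus averaging is the per-bin arithmetic mean over aligned
profiles with the across-profile standard deviation as uncertainty; a
plain mean is used deliberately, keeping each method's profile equally
weighted.  Convergence analysis splits every window chronologically into
n batches (default 6) and runs WHAM on cumulative prefixes over a shared
binning.

## Alchemical pKa

BAR solves the maximum-likelihood self-consistency

    Σ_F 1/(1+exp(β(w_F − C))) = Σ_R 1/(1+exp(β(w_R + C))),
    C = ΔG + kT ln(n_R/n_F),

where w_F is the forward work (ΔU on state-A samples) and w_R the reverse
work (−ΔU on state-B samples).  The left-minus-right imbalance is strictly
monotone in C, so a bracketed Brent search finds the unique root;
antisymmetry under swapping the two directions is exact.  The standard
error is Bennett's asymptotic variance from the Fermi weights at the
solution; underflowing weights (distributions that do not overlap) raise a
degenerate-overlap error rather than returning a meaningless number.
Statistical-inefficiency subsampling is not applied by default — callers
with correlated samples should thin them first.

The conversion is ΔpKa = ΔΔG/(2.303·R·T) with R = 0.0083145 kJ mol⁻¹ K⁻¹,
added to the 4.25 solution reference of free glutamic acid.  Two entry
modes: two legs (protein minus reference), or a combined-system
construction in which the two transformations run together with swapped
states so one leg's ΔG already equals ΔΔG.  Sign convention: positive ΔΔG
(protonation harder in the protein than in water) raises the pKa.  The
default temperature is 310 K; the familiar coefficient 0.174 pKa units per
kJ/mol corresponds to ≈300 K and is treated as a rounded convention —
reported pKa values are rounded to 0.1 units in summaries, since absolute
protein pKa predictions are not meaningful beyond that.

## H-bond occupancy PCA

The featurization is binary presence (not distance-weighted) of
protein–protein hydrogen bonds, one column per (donor atom, acceptor atom)
pair — donor/acceptor roles are part of the identity, the proton choice is
not.  Same-residue bonds are excluded; water-mediated and ligand bonds are
excluded in protein-only mode; bonds observed in fewer than 1% of frames
(default) are dropped.  Bonds are flagged backbone/sidechain/mixed from
atom names.  Columns are mean-centred but not variance-scaled:
occupancies already share the [0, 1] scale and scaling would inflate rare
bonds.  Components carry a deterministic sign (largest-|loading| positive)
so projections are reproducible.  Chains are kept distinct in bond ids —
the dimer is asymmetric, so symmetric chain copies are not pooled.
Classification between two user-supplied frame segments uses the mean
occupancy difference Δ: gain at Δ ≥ 0.5, lose at Δ ≤ −0.5; a residue that
both loses one partner above threshold and gains another has those bonds
relabelled "change" (partner swap); everything else is stable.
Segmentation (e.g. apo vs bound) is an input, not an inference.

## Density maps

Frames are rigid-body superposed (Kabsch least squares) on the alpha
carbons of the protein selection in the first frame before binning —
a spatial density is only meaningful in the protein's own frame, and the
alignment choice is documented here because reasonable alternatives
(all heavy atoms, mass weighting) exist.  Default voxel spacing 0.1 nm;
normalization modes: raw counts, occupancy (counts per frame) or number
density (per frame per nm³), recorded on the grid.  z projection sums the
marginal counts per slab under the same mode; totals are conserved
exactly.  Grids are written in OpenDX.  Per-ligand z traces evaluate the
translocation coordinate — the z component of the ligand's central atom
minus the protein center of mass, open side positive — per frame, with the
per-ligand minimum as the entry-depth summary.  A cylinder mask (default
diameter 1.5 nm, height 6 nm about the protein COM z axis) is available as
a validity filter for the coordinate.

## Synthetic generators

Every generator owns one RNG stream seeded explicitly; identical seed and
parameters give bit-identical output, and each emits machine-readable
truth so every stage has a recovery test.

*Wire boxes* plant a glutamate-like source, a chain of waters with ideal
H-bond geometry (O–O 0.28 nm, linear O–H···O) reaching past a synthetic
phosphate level, and distractor waters kept ≥ 0.45 nm from the chain and
each other — beyond the 0.35 nm cutoff, so the planted wire is provably
the only source→bulk path.  Per frame, with the requested break
probability, one chain water is parked far from everything, which provably
disconnects the wire; coordinate jitter (σ = 0.004 nm) stays well inside
the geometric margins, so the detector agrees with the truth labels in
100% of frames by construction.

*Brownian dynamics* integrates the overdamped Langevin equation
z ← z − (D/kT)(F′(z) + k(z−z₀))Δt + √(2DΔt)η with Euler–Maruyama,
vectorized over windows, burn-in 10%.  The integrator widens a harmonic
stationary distribution by 1/(1 − θΔt/2), θ = Dk_total/kT, and the number
of effectively independent samples per window is ≈ n·θΔt, so the default
umbrella dataset uses a per-window Δt with θΔt = 0.15: window-anchor
statistics (which random-walk along the profile) then dominate the ~8%
variance bias, which the WHAM recovery tests show is the better trade at
10⁵ steps per window.  Defaults: D = 0.5 nm²/ns, T = 310 K.

*Analytic profiles*: a double well (two Gaussian basins, requested barrier,
flat far plateau) and a multi-minimum binding-like profile with basins near
z = 0.2, 0.8 and 1.5 nm, a bulk plateau beyond ~2.2 nm and a soft
repulsive wall below −0.3 nm.  The basin depths are synthetic: recovering
a study's actual profile depths requires tens of microseconds of all-atom
MD and is out of reach of these generators, so tests claim parameter
recovery of the planted shape, nothing more.

*Crooks work samples* are Gaussian with forward ~ N(ΔG + βσ²/2, σ²) and
reverse ~ N(−ΔG + βσ²/2, σ²), which satisfies the Crooks fluctuation
relation exactly in distribution.

*Occupancy matrices* start from random per-bond baselines, invert the
chosen flip set at the switch frame and apply independent per-entry flip
noise; each synthetic bond involves its own residue pair so planted gains
and losses never alias into partner swaps.

*The dimer fixture* is a ~10-frame toy: two mirror chains with glutamates
at position 14 meeting at the center, a water wire open to the upper
compartment only, 8 waters inside the 0.6 nm cavity, phosphate marker
leaflets at ±1.55 nm and a tetrahedral mock ligand.  It exercises the
plumbing end to end; it is a geometric cartoon, not a physical model.

What the generators do *not* emulate: real water structure and dynamics,
membrane deformation, correlated noise in work samples, conformational
heterogeneity of H-bond networks, and finite-sampling artifacts of actual
MD.  Passing recovery tests therefore demonstrates correctness of the
estimators on data satisfying their assumptions — not that a given MD
dataset satisfies them.

## Problem sizes used in validation

The acceptance-style checks run at desk scale: 44 umbrella windows × 10⁵
Brownian steps for WHAM recovery (RMSD to the planted double well
< 0.5 kJ/mol over the planned window range), 5000 work samples per
direction for BAR recovery (within 2 standard errors), 200 random ≤30-water
boxes for wire-search/oracle equivalence, 2000 frames for the binomial
wire-fraction check, and 400×40 occupancy matrices for PCA recovery.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* The wire search reports connectivity; it does not model proton-transfer
  kinetics or donor→acceptor orientation consistency along the chain.
* WHAM is 1D and non-periodic; no MBAR, no 2D reaction coordinates.
* Externally computed profiles (e.g. from metadynamics) enter only as
  inputs to alignment/averaging.
* No autocorrelation analysis of work samples; BAR standard errors assume
  independent samples.
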