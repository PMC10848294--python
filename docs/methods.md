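# Methods

## Scope and model

`surfads` treats interfacial adsorption geometrically. A protein
configuration is a set of spheres (atoms with van der Waals radii); the
solvent-accessible surface is the locus traced by the center of a probe
sphere rolled over them; and the water/vapor interface is a pair of
horizontal planes located from the solvent density profile. The
quantity of interest, A_ads, is the part of the accessible surface on
the vapor side of those planes. Everything else — ΔSASA, SAP, the
adsorption score, sequence mining — is built from per-atom and
per-residue decompositions of these two surfaces.

The package analyzes structures and trajectories; it does not simulate.
Sampling quality, force-field choices and protonation states are the
upstream simulation's responsibility.

## SASA engine

Each atom's sphere is expanded by the probe radius and covered with an
`n_points` Fibonacci lattice (default 960; a minimum of 92 is enforced
because coarser quadratures misrank small atoms). A point survives if
it is strictly outside every other expanded sphere; ties (a point
exactly on a neighbor's surface) count as buried, which makes results
reproducible bit-for-bit for a fixed input. The per-atom area is the
surviving fraction times 4π(r+probe)². Candidate occluders come from a
k-d tree query of radius `r_i + max_j r_j` (both probe-expanded), so
the test set is exact, not approximate.

The surviving points, each weighted by 4π(r+probe)²/n_points, form an
explicit `SurfacePointCloud`. Splitting SASA at the interface is then a
pure classification of points: a point contributes to A_ads iff its own
position (not its owner's center) lies above the upper plane or below
the lower one. This guarantees the partition property (per-atom sums
equal totals exactly) and the bound A_ads ≤ SASA at the same probe.

Probe radii: 0.14 nm for generic SASA, ΔSASA and SAP; 0.2 nm for
vapor-area work, matching the effective roughness of a simulated water
surface. Both live in the run configuration, never at call sites.

Radii default to the Bondi element set (H 0.120, C 0.170, N 0.155,
O 0.152, S 0.180, P 0.180 nm), recorded in output metadata and
replaceable by a user table.

Two accuracy caveats are inherent to any fixed-orientation quadrature
(including the double-cubic-lattice family this engine is equivalent
to):

* areas are translation-invariant to machine precision but only
  rotation-invariant to the quadrature's digitization error (≈0.5% of
  an atom's area at 960 points);
* the *relative* error on a nearly buried atom diverges as its exposed
  fraction shrinks — the absolute error stays at a few point weights,
  but the denominator vanishes. Validation therefore applies relative
  bounds to atoms with an appreciable exposed fraction (≥20% in the
  oracle-equivalence suite) and absolute, point-weight-scaled bounds
  below that.

An independent Monte-Carlo estimator (uniform sphere sampling with
rejection) serves as the unbiased oracle in tests, and
`biotite.structure.sasa` provides a second, external cross-check.

## Interface location

The solvent number density is histogrammed along the interface normal
(default z, bin width 0.05 nm, per-frame box-normalized, time
averaged). The bulk density is the mean over the central 50% of the
occupied region; each plane is placed where the profile crosses half
that value, linearly interpolated between bin centers, scanning inward
from either end (the Gibbs-dividing-surface convention — the method
string records it). Uniform or empty profiles raise "no interface
detectable". Planes can be located per frame (default) or once from
the time-averaged profile.

## Adsorption statistics

* **Time averaging** uses the trailing fraction of a series, default
  0.75 — the convention of averaging the last 150 ns of a 200 ns
  trajectory, kept as a fraction so it scales with series length.
* **Adsorption score** S: a residue's per-simulation time-averaged
  A_ads contributes only if strictly above 0.5 nm² (a value chosen
  close to the exposed area of glycine, the smallest side chain, so
  sub-glycine patches never score). Two denominators are defensible —
  the number of contributing simulations, or the total number — so both
  are implemented; the default is contributing-only, and the convention
  used is stored in the output metadata.
* **Sequence mining** finds maximal runs (same chain, consecutive
  residue indices, length ≥ 2) in which *every* member's mean A_ads
  exceeds 0.1 nm²; the lower cutoff captures mild adsorbers that the
  0.5 nm² score cutoff misses. Qualifying singletons are reported
  separately rather than dropped. The normalized sequence area is the
  per-residue mean of member areas; sequence hydrophobicity is the sum
  of member R_h values (glycine contributes exactly zero by the scale
  shift).
* **All cutoffs are strict** (>): a residue exactly at a threshold does
  not adsorb. Ties therefore never inflate scores or runs.
* **Hydrophobicity correlation** pools residues with A_ads above the
  0.1 nm² floor, groups them by identical R_h for mean/sd summaries,
  and reports the Pearson correlation and OLS slope.
* **Cumulative hydrophobic SASA** sums the per-residue SASA of a chosen
  surface-active set per sampled frame and smooths with a centered
  10-point running mean (output shortens by window−1 samples).
* **Free energy**: ΔG = γ·A_ads, with 1 mN/m·nm² = 10⁻²¹ J, reported
  in J, k_BT and kJ/mol. The default γ = 62 mN/m corresponds to a
  simulated water model's surface tension; real water at 298 K is
  ≈72 mN/m.

## SAP

For atom j, every residue with at least one side-chain atom whose
center lies within r = 0.5 nm of j's center contributes
(Σ side-chain SASA within r) / SASA_exposed(res) × R_h(res). Side
chains are all atoms outside the backbone name set {N, CA, C, O, OXT,
H, HA, terminal variants}; glycine's HA2/HA3 act as its side-chain
proxy for bookkeeping but never contribute (R_h(GLY) = 0 by the scale
shift). The hydrophobicity table is the Black–Mould normalized scale
shifted by −0.501; the reference exposures default to the Miller et
al. (1987) Gly-X-Gly side-chain areas (glycine assigned 0.50 nm²,
the exposed area of glycine in an Ala–Gly–Ala trimer). Both tables are
packaged as user-replaceable plain text, and
`reference_exposed_from_structure` recomputes reference values from
user-supplied trimer structures. Per-residue SAP is the mean over
member atoms; the SAP score sums the strictly positive residue values.
Time averages span the requested frame range; a single structure is a
one-frame average.

The neighbor search uses a k-d tree over side-chain atoms; a
brute-force double loop over atoms × residues reproduces it to 1e-9 in
tests.

## Conformation metrics

Rg is mass-weighted by default (flagged, since the convention is often
left unstated). RMSD superposes with the least-squares optimal proper
rotation (SVD-based, reflections excluded), unweighted over the
selection. Per-domain RMSD superposes each domain independently on its
reference counterpart, removing interdomain translation and rotation by
construction — the analysis needed when whole-molecule RMSD is
dominated by rigid-arm motion about a flexible hinge, as in antibodies.

## Synthetic data: what it emulates, and what it does not

The generators produce the study's geometry with known ground truth:

* **Sphere systems**: one pseudo-atom at a chosen height; the oracle is
  the spherical-cap closed form 2πR·h of the probe-expanded sphere.
* **Solvent slabs**: positions rejection-sampled from
  ρ(z) ∝ ½[tanh((z−z_l)/w) − tanh((z−z_u)/w)], planted planes at
  z_center ± half_width (defaults: 20,000 particles, 5×5×10 nm box,
  planes at 3 and 7 nm, w = 0.1 nm — enough particles that the
  half-density crossings are recoverable to a few hundredths of a nm
  with 0.05 nm bins).
* **Toy peptides**: one backbone and one side-chain bead per residue;
  extended (0.38 nm backbone spacing) or coarse-helix geometry;
  side-chain bead radii grow with residue heavy-atom count (GLY 0.10 …
  0.30 nm). The radii ORDER exposure correctly; they are fixture
  parameters, not physical radii.
* **Protrusion trajectories**: the peptide rigidly translated so its
  reference atom tracks a prescribed per-frame offset from the upper
  plane; the per-frame A_ads oracle is the same engine at ≥10× the
  production point density, so tolerances are deterministic
  (quadrature refinement, not Monte-Carlo).
* **Random clusters** (oracle tests): Gaussian clouds, scale 0.55 nm,
  chosen so neighbors genuinely occlude one another while every atom
  keeps a well-conditioned exposed fraction.

Passing on these fixtures validates the geometry, the conventions and
the arithmetic. It does not validate behavior on real proteins:
bead models have no backbone occlusion, no hydrogens, no realistic
packing; slabs have no capillary waves; protrusion is rigid rather
than conformationally coupled. Results on MD data inherit whatever
sampling and force-field limitations the data has.

## Numerical choices

* Strict occlusion and strict cutoffs everywhere; ties break toward
  "buried"/"not adsorbing".
* Wrapped-molecule guard: within-residue N–CA or CA–C distances above
  0.25 nm abort SASA with a clear error (bead models, which have no
  such bonds, pass vacuously).
* Degenerate inputs raise rather than return NaN: empty selections,
  uniform density profiles, windows longer than series, unknown
  elements/residues (named in the error).
* The acceptance script scales problem sizes to a desk-top run:
  20 Monte-Carlo cluster comparisons at 10⁵ samples, one 20,000-particle
  slab, 50-frame protrusion trajectories, nine 30-frame repeat
  simulations for the score pipeline.

## Known limitations

* Planar mean interfaces only; no intrinsic-surface or capillary-wave
  analysis.
* SASA only; no Connolly/SES molecular surface.
* Periodic boundaries are ignored for the protein (assumed whole); the
  slab must not straddle the box boundary.
* The packaged hydrophobicity and reference-exposure tables are
  documented substitutes assembled from published sources; users with
  their own trimer-derived reference values should load them in place
  of the defaults.
* Binary trajectory formats are out of scope; convert to the XYZ
  dialect (or construct `Trajectory` objects directly from an MDAnalysis
  or mdtraj reader in user code).
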