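# Methods

This note records the models, conventions and numerical choices behind
`poreform`, in the spirit of a simulation-analysis package's model
documentation: what each computation assumes, which knobs matter, and what
the synthetic generators do and do not emulate.

## Units and constants

Lengths nm, times ns, masses amu, temperatures K, energies kcal/mol
throughout.  The gas constant is R = 1.987204 × 10⁻³ kcal/(mol·K), so
RT = 0.6160 kcal/mol at the default temperature of 310 K.  Boxes are
orthorhombic only; triclinic input is rejected with a clear error.
Particle indices are 0-based internally and 1-based only inside file
formats that demand it.

## Trajectory model and I/O

A `Topology` labels particles with a role (peptide, lipid head/tail,
water, ion), a peptide chain id, a mass and a van der Waals radius; a
`Frame` holds time, box and coordinates; a `Trajectory` is frames over one
topology with strictly increasing times.  Roles are inferred from
residue/atom names through a declarative role map in `AnalysisConfig`, so
coarse-grained and atomistic naming dialects are both handled by
configuration rather than code.  Defaults are MARTINI-style CG values:
bead mass 72 amu and vdW radius 0.235 nm (half the 0.47 nm bead sigma);
both are overridable per input.

The native on-disk format is a plain-text multi-frame GRO dialect (frame
time encoded as `t= <ns>` in each title line); its 3-decimal fixed-point
coordinates give a 10⁻³ nm round-trip precision, and the files are
readable by standard tools (verified against MDAnalysis in the tests).
PDB topologies and XTC/DCD frame series are read through MDAnalysis when
it is importable.

Periodic geometry uses the minimum-image convention with each displacement
component in [−L/2, L/2).  Bonded chains are made whole by minimum-image
chaining along their sequence before any COM, R_g or axis computation, so
wrapped input is handled transparently.

## Clustering

Two chains share a cluster when connected by a path of pairs with
minimum-image COM distance strictly below the cutoff (default 1.5 nm);
"strictly" because the rule is stated as *less than*, and single linkage
because a cluster count implies connected components, not cliques.  COMs
are mass-weighted by default (`com_weighting: geometric` switches to the
unweighted mean — the right choice is genuinely open for CG beads of equal
mass, where the two coincide anyway).  The cutoff must stay below half the
smallest box edge or the minimum-image rule is ill-defined; this is
enforced, not assumed.  Correctness is tested by exact partition equality
against a brute-force oracle (all-pairs 27-image distances + `networkx`
connected components) on hundreds of random frames.

## SASA

Shrake–Rupley with a deterministic Fibonacci-lattice point set (default
960 points per sphere), so results are reproducible without a seed.  A
test point at radius r_i + probe is buried when strictly inside a
neighbour's expanded sphere; points exactly on a neighbour's surface — the
degenerate fully-overlapping case — are assigned to the lower-index
particle, so two coincident identical spheres report the area of one.
The probe radius defaults to 0.14 nm (a water probe) even for CG input;
this is a convention, not physics.  The default selection is all peptide
particles with only peptides occluding (`sasa_context: peptides_only`);
`with_lipids` makes lipid particles occlude without contributing area.
Accuracy checks: the isolated-sphere closed form 4π(r+probe)² to 1%, a
10⁵-random-point counting oracle to 2%, and an independent library
implementation (biotite) to 2%.

## Order parameter

Each chain's axis is the dominant principal axis (SVD) of its backbone
particles, sign-aligned to +z; S is the largest eigenvalue of the nematic
tensor Q = ⟨(3ûûᵀ − I)/2⟩, which lies in [−1/2, 1], is invariant to
flipping any axis, and equals 1 for a parallel bundle.  The nematic
definition is used because "more parallel arrangement" is exactly nematic
order; a `p2z` mode (mean P₂ of the angle to z) is available by config for
membranes where the normal is the physically meaningful director.  The 30°
cone construction with uniform azimuths gives S = P₂(cos 30°) = 0.625
exactly, which the tests assert to 10⁻⁹.

## Free-energy landscape

The (SASA, R_g) series is histogrammed on a regular grid (default 50 × 50,
range = observed extrema padded by half a bin) and inverted:
W = −RT ln P on occupied bins, shifted so min W = 0.  Empty bins are
*undefined* (+∞), never zero-filled — −RT ln 0 must not silently become a
number — and minimax paths cannot cross them.  No smoothing is applied by
default; an optional Gaussian blur (σ in bins) exists for presentation.

Basins are occupied bins no 8-connected occupied neighbour undercuts;
connected equal-W plateaus collapse to a single basin (hence a flat
surface has exactly one), and among candidates within `min_separation`
bins only the deepest survives.  Barriers use the widest-path variant of
Dijkstra: the saddle is the minimum over occupied-bin paths of the path
maximum of W, so forward/backward barriers satisfy
ΔG‡_fwd − ΔG‡_bwd = W(b) − W(a) identically.  The implementation is tested
against exhaustive path enumeration on small grids and against an analytic
two-well surface sampled at 10⁶ points, where it recovers a 1.0 kcal/mol
depth difference within 0.1 and a 2.5 kcal/mol barrier within 0.2.  Two
known, accepted biases at 50 × 50 binning: bin-averaging flattens sharp
wells by a few hundredths of kcal/mol (it cancels in the depth difference
when wells have similar curvature), and the recovered saddle sits ~0.1
kcal/mol below the plateau where the wells' Gaussian tails overlap.

## Axial density and density-based PMF

ρ(z) is the time-averaged count of a species inside a channel-centred
cylinder (axis = peptide-cluster COM in xy; default radius 1.0 nm, config
exposed) divided by the bin volume πr²Δz.  ρ_bulk is measured in slabs at
least 1 nm beyond the channel span — over the full box cross-section by
default, or restricted to the same cylinder (`bulk_cross_section:
cylinder`), which is the right normalisation when the sampled ensemble
itself lives in a cylinder, as the Boltzmann generator's does.  The PMF is
ΔG_PMF(z) = −RT ln(ρ_z/ρ_bulk) on bins with ρ_z > 0 (empty bins are
undefined, not 0), and the reported barrier is the maximum over defined
bins in the span.  This is a rough relative profile, not an equilibrium
PMF from enhanced sampling; its contract — recovering a prescribed U(z) −
min U in the exact-sampling limit — is what the tests enforce.

Default z-binning is 20 bins over the 2.32–6.55 nm span (~0.2 nm wide).
The width was chosen by a bias/variance analysis against generator ground
truth: at 10⁵ particles under a 2.5 kcal/mol barrier, ~0.1 nm bins leave
so few counts in the sparsest bin that the max-over-bins barrier estimate
is noisy and biased high (max of noisy values), while ~0.2 nm bins keep
enough counts for an essentially unbiased estimate and smear the Gaussian
top by only ~0.02 kcal/mol.

## Permeation events

Positions are wrapped into the box each frame, making detection invariant
to the input's wrapping convention; a particle crossing the periodic z
boundary moves directly between the two bulk reservoirs without touching
the slab.  A finite-state machine per particle records an event when it
enters the slab through one face and exits through the opposite face while
remaining inside the sampling cylinder for the whole traversal; retreating
out the entry face, or leaving the cylinder mid-slab, aborts the attempt.
There is no minimum residence time by default.  The frame interval must
resolve the crossing: a particle jumping the entire slab between two
stored frames is not counted.

## Pore radius

Cluster peptide particles within the channel z-span are projected onto the
xy plane as discs of their vdW radii (the cluster is first made whole
across the periodic boundary) and rasterised at `pore_grid_spacing`
(default 0.02 nm).  The lumen is the 4-connected free-space component
containing the cluster-COM projection; if it reaches the outside of the
cluster footprint the geometry is open (fiber-like) and the radius is 0
with a diagnostic, otherwise r = sqrt(A/π) with A the cell-count area.
Flood-fill from the COM projection is one concrete, deterministic reading
of "radius from the pore area"; the scalloped wall of a discrete bead ring
makes the estimate a few × 10⁻³ nm above the constructed lumen radius,
well inside the ±0.05 nm tolerance the geometry tests use, and halving the
grid spacing moves the result by < 2%.

## Synthetic generators

The generators exist to make the analyses testable, not to simulate
membranes; all randomness flows from one integer seed through one
`numpy.random.Generator`.

**Aggregation scenario.**  Defaults mirror the reference system geometry:
25 chains of 28 beads (one bead per residue of a 28-residue amyloid
fragment), initial COM grid spacing 4.0 nm, 20 × 20 × 11 nm box, 310 K.
Chains are rigid vertical helices confined to a membrane slab (z fixed);
clusters take isotropic in-plane Gaussian steps (σ = 0.08 nm/frame) plus a
0.05 nm/frame drift toward the nearest other cluster, and merge
*permanently* when member-chain COMs come within 1.5 nm — a kinetic
Monte-Carlo rule chosen because the observable of interest is the cluster
count series, and irreversible merging makes its monotonicity a
construction guarantee rather than a statistical accident.  Merged
clusters anneal into a ring (probability `pore_bias`, default 0.5) or a
line, with 1.2 nm adjacent spacing, and thereafter move rigidly.  Solvent
counts default to zero: the observables this generator feeds (clustering,
R_g/SASA, FEL, order) involve only peptides, and solvent ensembles for the
density/PMF/permeation analyses come from the Boltzmann generator, which
has exact ground truth.  What this generator does **not** emulate: real
chain flexibility and conformational exchange, reversible aggregation,
lipid interactions, and any real free-energy surface — so passing tests
validate the *analyses*, not membrane biophysics.

**Boltzmann particles.**  z is sampled exactly from
ρ(z) ∝ exp(−U(z)/RT) by inverse-CDF interpolation on a 10⁴-point grid
(trapezoidal CDF; grid resolution config-exposed), with x, y uniform in a
lateral disc.  Supported potentials: constant, Gaussian barrier,
piecewise-linear table.  This is the ground truth for the density-based
PMF: the recovered profile converges to U(z) − min U as n grows.

**Pore / fiber scenes.**  The pore scene tiles each chain's beads over an
arc segment of a ring wall (several beads per z level) so the wall is
closed and the enclosed free-space radius equals the requested lumen
radius by construction; the fiber scene is parallel vertical chains with
collinear COMs.  Both have exactly parallel chain axes, giving S = 1.

**Two-basin surface.**  Two Gaussian wells (σ = 0.22 nm², 0.10 nm) sunk
into a flat plateau 2.5 kcal/mol above the deeper well, centres ~7σ apart
so tail overlap perturbs the saddle by ≲ 0.01 kcal/mol; the wells sit at
(427.0 nm², 3.60 nm) and (428.0 nm², 4.12 nm) to mimic the scale of real
pore-like/fiber-like basins.  Sampling is fine-grid (400 × 400)
multinomial with uniform jitter inside cells.

## Problem sizes and degenerate inputs

Default test and pipeline sizes — ~10² frames of 25 × 28 beads for
end-to-end runs, 10⁵ particles for PMF recovery, 10⁶ samples for FEL
recovery — were chosen so each statistical check sits well inside its
tolerance while the whole suite stays interactive on a single CPU.
Degenerate inputs are defined, not accidental: a single particle has
R_g = 0; an empty selection, an all-empty histogram, a sub-3-chain pore
cluster, and a cutoff at or above half the box are errors; identical
frames give a delta-function landscape with one occupied bin; basins that
cannot be joined through occupied bins report an infinite barrier with a
diagnostic rather than a number.

## Known limitations

No force-field parsing, energy evaluation or MD integration; no
secondary-structure analysis (CG beads carry none); no reweighting, WHAM
or umbrella-sampling PMFs — the density-based PMF is explicitly a rough
estimate; absolute axial densities depend on the chosen sampling
cross-section, so only ratios (and hence PMF shapes) are meaningful; the
lumen-area pore radius assumes a roughly convex, singly-connected lumen
around the cluster COM projection.
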