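# Methods

This note documents the models, conventions and numerical choices behind
`synaptomet`, in the order data flows through the pipeline.

## Synthetic scenes

The generator exists so that every measurement can be validated against
known ground truth.  A scene is a density volume plus an aligned integer
label map (extracellular 0; per compartment: membrane, cytoplasm,
optional AZ membrane and PSD, and one label per vesicle) plus a complete
generative record (vesicle geometry, filament endpoints and lengths,
patch geometry, parameter echo, seed).  Identical parameters and seed
give byte-identical outputs; placement and noise use independent streams
spawned from the seed, so the same scene can be rendered at different
noise levels without disturbing the geometry draw order.

**Membrane.** A spherical-harmonic-perturbed ellipsoid: semi-axes are
the half max-diameter times two ratios drawn from U(0.75, 1), with a
random degree-2/3 real-harmonic radial perturbation (relative amplitude
0.04).  The shell is the set of solid voxels within 5 nm (default
membrane thickness) of the boundary, computed by Euclidean distance
transform, which also serves the flattened-cap compartments of paired
scenes.

**Vesicles** are prolate spheroids.  The outer (volume-equivalent)
diameter is drawn from the population distribution (GLU 40.4 ± 7.0 nm,
DA 45.1 ± 9.7 nm, clipped to [20, 120] nm); the axis ratio is solved by
bisection from a target Wadell index drawn per vesicle (GLU 0.98 ± 0.02,
DA 0.93 ± 0.05), because sphericity is the one shape statistic the
analysis reports.  Each vesicle's geometry is drawn once and positions
are retried for that fixed vesicle — retrying the size too would
size-bias acceptance toward small vesicles and shift the diameter
distribution, a bias we measured at several percent in small
compartments.  Placement enforces no membrane crossing (exact voxel
test near the wall) and positive bounding-sphere separation between
vesicles.  The vesicle count follows the density target (GLU 1956 µm⁻³,
DA 682 µm⁻³) times the membrane-enclosed volume.

**Active zone and tethering.**  GLU scenes carve an angular-cap AZ
patch out of the membrane (default area 0.079 µm², the measured mean;
scaled scenes pass a proportionally smaller area); DA scenes have none
and use the whole membrane as reference.  Among vesicles within 45 nm
of the reference, a Bernoulli draw at the tethered fraction (GLU 0.52,
DA 0.25) selects tethered vesicles, which are re-docked against a
random reference anchor at a half-normal membrane gap (scale 4 nm GLU /
14 nm DA).  The GLU scale is small so that the vesicle-occupancy
profile peaks about 20 nm from the membrane — the center of a ~40 nm
vesicle sitting nearly docked — as measured profiles do.  Because the
centroid ray is oblique to the membrane normal on aspherical membranes,
the docking walk is corrected iteratively against the distance field
until the realized gap matches the draw.  Tethers are rendered as 2 nm
radius cylinders (lengths are reported in the source studies, widths
are not); by default they are oblique, with the rendered length drawn
from the population distribution (GLU 13.9 ± 7.5 nm, DA 22.4 ± 12.7 nm)
and the lateral offset making up the difference from the gap, and close
vesicles carry up to 3 tethers.  A radial single-tether mode
(`tether_obliquity=False`, `max_tethers=1`) makes length equal gap for
unambiguous detection fixtures.  Connectors bridge vesicle pairs with
gaps under 40 nm, chosen greedily until the connected fraction (GLU
0.64, DA 0.24) is met or no candidates remain; their rendered length is
the inter-surface gap along the center line.

**Rendering.**  Ice sits at grey level 1; protein (membrane shell,
vesicle shells, filaments, PSD slab) subtracts its occupancy (dark, the
cryo-ET convention) or adds it (`contrast="bright"`).  Gaussian white
noise with sd expressed as a fraction of the membrane contrast (default
0.1) is added last; an optional missing-wedge surrogate applies an
anisotropic blur along z (off by default — full projection-space
simulation is out of scope).  The synthetic data do **not** emulate
CTF, molecular crowding, segmentation errors, or anisotropic noise, so
passing recovery tests demonstrates correctness of the measurements,
not robustness to every pathology of real tomograms.

**Paired scenes** place two sphere compartments with facing caps
flattened against parallel planes over a disk patch (default 0.06 µm²)
separated by the requested cleft width, an AZ label on the presynaptic
face, an optional PSD slab 10–25 nm beneath the postsynaptic face, and
an optional midline density.

## Morphometry conventions

Vesicle volume V is voxel count × voxel volume; the outer diameter is
`2*(3V/4π)^(1/3)` of the membrane-inclusive label (whether measured
diameters include the ~5 nm membrane is a convention; the generator and
the measurements use the same one, and an offset can be applied at
reporting).  Surface area comes from marching cubes on the label mask
smoothed with a 1-voxel Gaussian — the raw voxel staircase overestimates
the area of smooth organelles by ~6% and biases W_i low.  The Wadell
index is computed from the mesh volume and mesh area of that same
closed isosurface: using the voxel-count volume against the mesh area
mixes two estimators and can push W_i above 1 on coarse grids, while
the single-mesh form respects the isoperimetric bound by construction
(voxel-count V is still what the record reports as volume).  Measured
on digitized spheres this gives W_i ≈ 0.997 and diameters within one
voxel; on 2:1 spheroids W_i is within 0.003 of the closed form.

Maximal extension is the exact diameter of the membrane voxel set
(convex-hull vertices, then pairwise distances).  Visible volume is
everything enclosed by the membrane label, organelles included, and
vesicle density is count over that volume.

## Proximity and occupancy

Distances are edge-to-edge: the membrane distance field is the EDT of
the reference voxel set, and a vesicle's distance is the field minimum
over its voxels.  Layers are half-open one-voxel bands; occupancy is
vesicle voxels over cytoplasm voxels per band, with empty layers
reported as missing (NaN), never zero.  The cytoplasm denominator
excludes mitochondria and other large organelles by default
(configurable).  For DA-like compartments without an AZ the reference
defaults to the whole plasma membrane and the mode is recorded in the
outputs.  Tether counts are binned over half-open distance bins
(default edges 0/5/10/25/45 nm, configurable since the exact published
edges are not printed).

## Filament detection

Preprocessing standardizes intensities to zero mean and unit sd over
the cytoplasm, flips the sign if membrane voxels are darker than the
cytoplasm mean (so protein is always positive), smooths with a Gaussian
of sigma = 2 voxels, and then regresses out the boundary halo: the
smoothed indicator fields of the boundary segments and of their 1-voxel
rims are least-squares-fitted over the cytoplasm and subtracted.
Without this step the point-spread skirt of the membrane itself bridges
gaps below ~15 nm at permissive thresholds and masquerades as
filamentous density; the regression removes it while leaving the
filaments' own density intact (they are not in the regressor span).

Detection then runs a descending-stringency threshold ramp: ten levels
between the 95th and 60th percentile of supra-floor zone intensity,
with an absolute floor of 0.15 standardized units that suppresses
near-zero speckle and keeps structureless scenes empty.  The search
zone is cytoplasm within 45 nm of a boundary segment.  At each level,
26-connected components of supra-threshold unfrozen voxels that touch
(6-connectivity — corner touches do not count as contact) at least two
boundary segments and pass the size gate (3–3000 voxels) are accepted;
their voxels freeze, later components may not claim them, and a
remainder hugging an accepted filament with the same partners is an
extension, not a new filament.  Membrane + one vesicle is a tether, two
or more vesicles a connector, more than two segments a branching
component — kept in the output but excluded from length and count
statistics.  Length is the shortest path between the two
boundary-contact voxel subsets through the component's 26-connected
graph with Euclidean step weights, so curvature increases length.  Note
the consequence: for a vesicle docked a few nanometres from the
membrane, the minimal edge-to-edge length is the anchor gap (~2 nm at
2 nm voxels) regardless of how long the oblique tether structure is —
the method measures distances between contacted structures, not tether
contour length.

On noise-free fixture scenes (radial single tethers, spherical
vesicles, no sub-resolution gaps) detection achieves precision and
recall of 1.0 over 20 seeds with lengths within 2 voxels; fixtures
avoid vesicles placed closer than 6 nm to the membrane because no
density-based detector can distinguish a sub-resolution gap from a
contact, and real analyses face the same ambiguity for docked vesicles.

## Contacts and profiles

A contact zone is the set of membrane-A face voxels (faces adjacent to
extracellular space; the cytoplasm-facing inner surface never enters)
within the tight-apposition cutoff (default 15 nm) of membrane B; AZ
mode selects faces against the PSD label instead.  Voxel-center
distances include the two half-voxel offsets to the faces, so one voxel
is subtracted for the edge-to-edge cleft width; parallel-plane fixtures
recover configured separations within one voxel.  Patch area sums
marching-cubes triangles within one voxel of the selected faces;
discretization puts a half-voxel rim on the patch boundary, so areas of
patches only a few tens of voxels across carry a few-percent positive
bias.  Profiles (cleft midline, sampled on three z planes through the
patch; perpendicular cytoplasmic, averaged over the patch footprint
from 5 nm depth) are reported in protein-positive convention — the data
are reflected about the extracellular background mean when the scene is
protein-dark — and normalized by division: the midline by a flanking
background band 10–30 nm outside the patch (falling back to the
non-patch midline, then to self-normalization when the geometry leaves
no background), the cytoplasmic profile by its own 40–60 nm plateau.
Division makes profiles invariant to multiplicative intensity
rescaling; additive offsets are not invariant, matching the underlying
ratio-to-background definition.  The PSD call is positive when the
10–25 nm band exceeds the plateau by a 10% margin (configurable; the
visible effects in real profiles are about twice that).

## Spatial statistics

The random null approximates the synaptosome projection by a circle of
radius R = D/2 built from the mean maximal diameter D: the arc distance
between two uniform random points has mean `πR/2` (half the length of a
half circle, by symmetry) and variance `π²R²/12` — at R = 361 nm, 567
and 327 nm.  A Monte-Carlo twin samples angle pairs.  On segmented
membranes, arc distances are shortest paths on the membrane voxel graph
(26-connectivity, Euclidean weights; ~3% metrication overestimate on
digitized spheres), with the projected decomposition
`d = sqrt(d_xy² + d_z²)` also reported.  A tether's anchor is the
centroid of its membrane-contact voxels.  Compartments with fewer than
two tethers are excluded from nearest-neighbour statistics, not counted
as zero.

## Group statistics and reporting

All tests are two-tailed: Student's t for near-normal variables,
Mann–Whitney / Kolmogorov–Smirnov / Kruskal–Wallis for the rest,
chi-square for frequencies.  Degenerate all-identical inputs return
statistic 0 and p = 1 with a warning note.  Per-item pooled values and
per-synaptosome means are both emitted, never silently substituted; for
fractions the sem is computed between synaptosome means.  No
multiple-testing correction is applied — comparisons are planned and
orthogonal, and the report lists everything so users can correct
downstream.  Stars: p < 0.05 / 0.01 / 0.001.

## Problem sizes in the test suite

The recovery suites run on scaled-down synaptosomes (220 nm mean
maximal extension, 2 nm voxels, proportionally scaled AZ patch of
0.006 µm²) so that a 50-scene batch with full detection completes in a
few minutes; vesicle-level parameters are the population defaults
throughout, and the quantities under test (diameter mean, tethered
fraction, occupancy peak position) do not depend on the container size.
Discretization tolerances in the tests are stated in voxels for the
same reason.

## Known limitations

Vesicle overlap checks use bounding spheres, so strongly prolate
vesicles keep a slightly larger-than-minimal spacing.  The
missing-wedge surrogate is a directional blur, not a Fourier-space
wedge.  Detected tether multiplicity undercounts when several tethers
of one vesicle merge into a single component at the anchor.  Label maps
are limited to int16 ids (MRC mode 1).  The halo regression assumes the
segmentation covers the dominant non-filament density; unsegmented
large structures would leak into the zone.
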