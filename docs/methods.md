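# Methods

This note documents the models, conventions and numerical choices behind
`discquant`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinate and label conventions

Label volumes are 3D integer grids with anisotropic voxel spacing
(dx, dy, dz) in mm.  Axis 0 is +x, the left-to-right lateral axis; axis 1
is +y, posterior-to-anterior; axis 2 is +z, caudal-to-cranial.  The
convention is asserted by a flag on the container, never inferred from
image content.  Voxel indexing is 0-based; world coordinates are
voxel-center based (voxel i at i·spacing), with half-open extents.  Labels:
0 background, 1 vertebra, 2 annulus fibrosus (AF), 3 nucleus pulposus
(NP), 4 cavity.  The "disc" is AF ∪ NP ∪ cavity throughout — the cavity
counts toward the intact reference volume, and toward the disc outline
when constructing the centroid frame, so that a carved disc keeps its
pre-removal geometry.  Registration between pre- and post-removal volumes
is assumed (fixtures are generated pre-aligned, as a scanning jig would
ensure); the package performs none.

## Centroid frame and regional partition

On the mid-transverse slice (median z of disc voxels) the disc boundary is
extracted (mask minus its 4-connected erosion) and five landmarks located:

* P1/P5 — the posterior-most boundary points of the left and right halves,
  split at the lateral coordinate of the mask centroid.  When their
  posterior coordinates agree to within one voxel the posterior margin is
  convex at grid resolution and line 1 falls back to the lateral-axis
  tangent at the posterior pole; this tolerance is what makes the
  construction stable for circles and ellipses, whose discretized pole
  pixels would otherwise produce a spurious tilt.
* P2/P3 — the extreme boundary points along the line-1 direction; the
  distance between the perpendiculars through them is the lateral width W.
* P4 — the extreme point on the anterior side of line 1.

The rectangle of the four lines has geometric center C, the disc centroid.
Concentric circles about C with radii f·W/2 for f ∈ {0.2, 0.4, 0.6, 0.8}
(the fractions are circle *diameters* relative to W; a "radius" mode is
available by configuration) crossed with the four quadrants — split by the
line-1-parallel and perpendicular axes through C — partition the plane.
The diameter reading is the default because it keeps the largest circle
(radius 0.4 W) inside a disc of half-width 0.5 W and matches the "within
40 % of the lateral width from the center" summary statistic the partition
is used for.

The 2D partition is extruded to every axial slice: localization is a
transverse-plane concept, and a per-slice frame would make regional
volumes sensitive to slice-wise segmentation noise.  Voxels are assigned
by their center position, distances computed in world mm (anisotropy
respected).  Tie-breaks are deterministic and documented: a voxel center
exactly on a circle belongs to the outer band; exactly on the lateral axis
→ anterior; exactly on the AP axis → the specimen's entry side (metadata,
default left).  Every voxel is assigned; regional intact volumes sum to
the disc volume exactly by construction.

Two normalizations are reported per region: percentage of the total
removed volume (sums to 100) and percentage of that region's intact
volume.  The summary "% of removed volume within 0.4 W of C" uses the
0.4 W radius regardless of radius mode.

## Volumetry and disc height

Cavity volume is cavity-voxel count × voxel volume; given a pre/post pair
instead, the cavity is the symmetric difference of the AF∪NP footprints
with the intact reference from the pre volume.  Disc height follows the
coronal-slice protocol: on the mid-axial slice, choose the coronal slice
with the largest lateral disc width (ties → lower index); at the lateral
midpoint column (midpoint rounded toward the lower index) measure the
cranio-caudal disc extent, requiring vertebra above and below; average the
measurement over the chosen slice and its two neighbors.  Heights are
measured on whatever geometry the volume encodes (e.g. under a 50 N
holding load); no unloading correction is applied.  Repeatability of
repeated segmentations is summarized as mean, sample SD (n−1) and CV %;
a zero mean flags CV as undefined rather than raising.

## Loading model and stiffness extraction

The synthetic loading law is F(d) = α(e^{βd} − 1), the standard
soft-tissue stiffening idealization with closed-form inverse
d(F) = ln(F/α + 1)/β and window-secant stiffness
(F_hi − F_lo)/(d(F_hi) − d(F_lo)).  Preconditioning drift multiplies α by
1 + γ·e^{−i/τ} on cycle i, so stiffness itself converges across cycles;
with the defaults γ = 0.1, τ = 1 cycle the true cycle-4→5 toe-secant
change is ~0.06 %, and a slow-drift setting (γ = 1, τ = 10) violates the
1 % criterion, keeping the check non-vacuous.  Displacement is driven
sinusoidally between d(50 N) and d(1 kN) at 1 Hz, sampled at 100 Hz, with
white Gaussian force noise (default SD 0.25 N, the noise-floor scale of a
10 kN-class load cell read in this range).

Stiffness is the OLS slope of force against displacement over the raw
samples of a cycle's loading half with force in the half-open window
[F_lo, F_hi) — 50–200 N (toe) and 500–900 N (linear) by default.  OLS
equals the secant on affine data and is noise-robust; on curved data under
the sinusoidal drive it converges not to the secant but to a
sampling-measure-weighted regression limit, because time-uniform samples
cluster at the displacement trough.  The discrepancy grows roughly with
the square of the window's local-slope ratio: ~4 % below the secant for a
strongly curved toe (α = 100 N), ~0.3 % for the gentle default
(α = 3000 N, β = 0.2 /mm, giving k_toe ≈ 625 and k_lin ≈ 739 N/mm).  The
defaults are therefore gently curved so that secant recovery holds to
0.5 %; cohort specimens get realistic curvature (k_lin/k_toe ≈ 3.7)
solved from drawn stiffness pairs via a 1D root find (the secant ratio is
monotone in α), and for them only intact-vs-post *reductions* are
asserted, where the bias largely cancels (residual ≈ 1.3 points on a 30 %
toe reduction between states of different curvature).

Cycle boundaries are displacement minima detected on a 5-sample moving
average (raw samples are used for fitting); the series start/end counts as
a boundary when near the minimum level, segments that never reach 80 % of
the displacement range are discarded (truncated tails), and a series whose
smoothed range does not dominate its high-frequency residual is rejected
as containing no oscillation.  The preconditioning check computes
δ_i = 100·|k_i − k_{i−1}|/k_{i−1} and passes when the final δ is at or
below the threshold (default 1 %).

## Mass model and the two-line estimator

Specimen mass drifts linearly as surface water evaporates.  The generator
produces m(t) = m₀ − rt with the removed mass stepped out in equal parts
at the intra-procedure energy-mark sample times, plus Gaussian noise
(default SD 0.001 g, a laboratory balance's resolution).  The estimator
fits OLS lines to the labeled pre and post windows only — intra-procedure
samples are logged but never fitted, since mass is stepping down while
they are taken — and evaluates Δ(t) = line_pre(t) − line_post(t) at the
procedure boundaries, reporting (Δ(t1) + Δ(t2))/2.  This averaged reading
is the one in which both anchor times matter; for parallel fitted lines
the two gaps coincide.  t1/t2 default to the last pre and first post
sample times from the phase labels.  Negative estimates are flagged, never
clamped.  With the default regime (0.2 g removal, 0.002 g/min drift,
0.001 g noise, 11-point windows) the estimator's sampling SD is ~1.4 mg,
giving a median recovery accuracy above 99 %.

Derived arithmetic: dry mass = wet × (1 − water fraction), default 0.70
for nucleus tissue; Brinckmann height loss = 0.8 mm × hydrated grams
removed; an idealized cylindrical ablation-track volume π(w/2)²·L.  The
pressure-to-load helper returns the exact product (0.586 MPa × 1703 mm²
= 998 N); rounded literature figures near 1 kN reflect unrounded inputs.

## Synthetic cohort

The cohort generator draws a balanced three-technique cohort (default five
specimens each, levels L1–L5 and degeneration grades 2–4 spread across
groups as in a matched cadaveric design).  Phantoms are elliptical
cylinders (half-widths ~27 × 20 mm, height ~10 mm — cross-sectional area
~1700 mm², disc volume ~17 000 mm³) between vertebral slabs at 0.5 mm
isotropic voxels (the scanner-resolution grid 0.09 × 0.09 × 0.8 mm is a
configuration away; 0.5 mm keeps the suite fast).  Technique effect sizes
are configuration, not claims, set to the magnitudes this class of
experiment reports: removal targets ~353/478/21 mm³ (shaver / rongeurs /
laser), toe-stiffness reductions ~35/55/8 %, linear ~15/30/3 %, height
losses ~1.4/0.74/0.2 mm, wet masses ~4.18/0.88/0.23 g.  Cavity presets:
shaver — a compact nearest-voxel blob inside the NP (achieved volume exact
to voxel rounding); rongeurs — three lobes, the entry-side lobe at the NP
margin where it may relabel AF voxels; laser — a capsule along the entry
direction with default track dimensions 14.5 × 2.75 mm, optionally
rescaled in width to a drawn cavity volume, emulating the shrinkage of
ablation voids under internal pressure (the geometric track volume,
~86 mm³, exceeds the settled cavity volume by design).  Laser specimens
carry a mass series for the evaporation-corrected estimator; mechanical
specimens carry directly weighed masses.  A truth sidecar table records
every generated value so each estimator has a recovery target.  Where the
drawn post-state stiffness pair exceeds the exponential law's attainable
secant ratio (~6.3 for the standard windows) the toe reduction is capped
and the capped value recorded as truth.

## What the phantoms do not emulate

No MR signal simulation (intensities, partial volume, hyperintensity
interpretation), no segmentation error — masks are consumed as given, so
passing tests validate the quantification given a segmentation, not
segmentation itself.  Phantom discs are extruded 2D shapes; real discs
bulge, wedge and tilt, so the mid-slice frame extrusion is exact here but
an approximation on real anatomy.  The loading law is elastic and
noise-free in displacement; hysteresis, creep and neutral-zone behavior
are not modeled (a creep-like displacement offset is tested only as an
invariance).  Endplate and marrow changes are observer-graded outcomes and
appear only as metadata flags.

## Statistics

Classic formulations via scipy.stats: per-group Shapiro–Wilk and
across-group Levene for assumptions, two-sided paired t for intact-vs-post
changes, one-way ANOVA with Tukey HSD post hoc for between-technique
effects (no Welch correction, matching the classical battery), Pearson r
for associations.  Raw p-values are always emitted with the test name;
significance markers are derived downstream, never hard-coded.  Identical
pairs yield t = 0, p = 1 by convention; constant groups are flagged as
degenerate rather than tested.  Under a simulated null the ANOVA type-I
error at α = 0.05 is calibrated (empirically within [0.02, 0.09] over
1000 replicates in the suite).

## Reproducibility and problem sizes

All generators take integer seeds (numpy default_rng); the pipeline report
is byte-identical JSON under a fixed seed.  Suite problem sizes are chosen
for fast, deterministic runs: phantoms ≤ ~10⁶ voxels, brute-force oracle
grids ≤ 64³, 100-replicate simulations for estimator recovery and test
calibration (1000 for the ANOVA null), 20 kHz sampling only in the
dense-oracle comparison.
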