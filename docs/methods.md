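# Methods

This note records the models implemented by `hnphantom`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic test
volumes do and do not demonstrate.

## Volume model and conventions

A `VoxelVolume` is a 3D scalar grid in canonical axis order
(anterior–posterior, left–right, superior–inferior): `data[:, :, k]` is one
axial slice and axis 2 is always the axial (slice) axis. Readers normalize
to this order and record how the axial axis was identified
(`axial_axis_source`), so orientation handling is explicit rather than
guessed from file conventions. Indexing is 0-based and half-open; physical
positions are voxel-center based, which keeps mm↔voxel conversions for the
skin thickness and lymph-node axes free of off-by-one errors. Spacing is
always taken from file metadata; a volume without spacing metadata is an
error, never an assumed 1 mm.

A finished phantom is a `PhantomBundle` of four co-registered volumes —
pre-processed MRI, tissue labels, relative permittivity, conductivity — plus
the frequency, seed and the exact generating configuration. The primary
container is HDF5 (datasets `mri`, `labels`, `conductivity`,
`permittivity`); a MATLAB-v5-compatible writer provides the same four
arrays. Round-trips are bit-exact in both dialects. The output contract is
the four named arrays, not the container format.

## Stage 0 — preprocessing and segmentation

Normalization is min–max to [0, 1], with the minimum and maximum computed
over body voxels only so the zero background cannot pin the lower end of
the range; background is then zeroed by the mask. Masking happens before
filtering, and the mask is re-applied after filtering so edge bleed across
the body boundary is clipped.

Denoising is a median filter followed by a Gaussian low-pass, per axial
slice in 2D by default (MR noise statistics are per-slice; a full-3D scope
is available). The order matters and is part of the contract: the median
removes impulsive (salt-and-pepper) outliers before the Gaussian can smear
them; the reversed order leaves smeared bumps, which the tests demonstrate
on an impulse fixture. The Gaussian is implemented in the spatial domain,
truncated at 4σ.

Defaults: `median_kernel = 3` voxels, `gaussian_sigma = 0.5` voxels. The
kernel is the smallest odd window that removes isolated impulses. The
Gaussian width is a deliberate compromise: with the plateau-like intensity
structure of the tissues, σ = 0.5 voxel suppresses the residual broadband
noise left after the median stage while keeping the intensity transition
band at tissue interfaces narrow. Wider kernels (σ = 1 voxel) smear
interfaces over several voxels; those intermediate intensities form their
own clusters during segmentation and get attributed wholesale to one
neighbouring tissue, which measurably degrades label fidelity on the
synthetic neck (≈97 % voxel agreement with ground truth versus ≈99.9 % at
σ = 0.5). Both parameters are configuration-exposed.

Segmentation is Lloyd's K-means (k-means++ initialization, 10 restarts,
fixed seed) on scalar voxel intensity over body voxels only, so with the
default k = 5 all five clusters are tissue clusters. Cluster indices are
relabelled by ascending centroid, making labels deterministic given the
seed. Ties in distance are resolved toward the lower-centroid cluster by
the ascending relabelling. The cluster→tissue map is policy-driven: the
default rank table for k = 5 maps the two darkest clusters to fat, the
middle two to muscle and the brightest to mixed tissue (on fat-suppressed
T1 contrast fat is dark); because the correct map depends on the pulse
sequence, an explicit per-cluster override is accepted and, for the
synthetic fixture, the map is derived by matching centroids to the
fixture's known plateau means. Per-cluster intensity extrema are recorded
for the stage-3 mapping.

Stage 1 simplification relabels an excluded tissue (mixed and/or muscle) as
fat. The operation is idempotent per tissue, commutative across tissues,
and conserves voxel counts; the relabelled voxels keep their MRI
intensities, so stage 3 maps them within the enlarged fat population and
intra-tissue texture is preserved.

## Stage 2 — synthetic skin and lymph nodes

**Skin.** The skin layer is synthesized from the body mask per axial slice:
the layer thickness in voxels is `round(thickness_mm / in-plane spacing)`
per axis (minimum 1; per-axis counts under anisotropic in-plane spacing),
and the outermost body voxels within that distance of the mask's 0↔1
transition are relabelled skin. The default thickness is 1.4 mm — at
0.5 mm spacing, a 3-voxel layer. The layer replaces body voxels inward, so
the external silhouette given by the mask is preserved exactly; an
`outward` mode that grows the layer into the background is available as
the alternative reading. The slice-normal direction gets no skin: the top
and bottom of the neck volume are cut planes, not body surface. Distances
are Euclidean (distance transform in per-axis thickness units) with a
half-voxel allowance that compensates the offset between voxel centers and
the continuous mask boundary on curved contours; on axis-aligned edges the
layer is exactly the rounded voxel count, and on a cylinder the per-slice
skin count matches the analytic annulus area within discretization error.

**Level slabs.** Nodal levels I–VI are approximated as six axial slabs
partitioning the occupied slice range — equal fractions by default,
user-specified fractions or explicit per-level intervals via configuration.
The slab layout is reported to the user before placement. This is a
deliberate simplification: true level boundaries follow anatomical
landmarks that vary across slices and subjects, which is out of scope.

**Lymph nodes.** A node is an ellipsoid with semi-axes (a, b, b),
a = major_axis/2 and b = a·minor_ratio, the major axis along the
superior–inferior direction by default (typical nodal orientation;
configurable). Two regions: the interior (the node proper) is the
ellipsoid scaled by (1 − shell_fraction); the shell (perinodal adipose
tissue) is the set difference. Defaults `minor_ratio = 0.5` and
`shell_fraction = 0.2` reproduce the oval morphology of lymph nodes with a
thin fat rim; neither is dictated by the underlying morphology literature
with precision, so both are configuration-exposed. Rasterization is by
voxel-center inclusion; a node whose extent is below one voxel on any axis
is rejected with spacing guidance. Raster volume converges to the analytic
ellipsoid volume as spacing shrinks.

Placement enforces, as hard preconditions checked before any work: at most
12 nodes in total, at most 6 per level, major axis within 1.0–25.0 mm.
Nodes are placed at user-given centers (validated against the body mask
and the level slab) or at seeded-random candidates drawn uniformly from
body voxels of a random slab slice, with bounded rejection sampling
(default 1000 retries, then a placement error naming the node — never an
infinite loop). Overlap is tested on voxelized occupancy, since the label
map is the product and voxel-level disjointness is the binding constraint.
Node voxels overwrite any prior label; the stage order (skin before nodes)
therefore yields the precedence CLN > skin > segmented tissue.

Because the dielectric stage assigns state-specific curves to both node
regions, the label map distinguishes healthy and metastasized codes for
the interior *and* the shell (four node codes in total).

## Stage 3 — dielectric properties

The complex relative permittivity of each tissue follows the 4-pole
Cole–Cole model

    ε(ω) = ε∞ + Σₙ₌₁..₄ Δεₙ / (1 + (jωτₙ)^(1−αₙ)) + σs/(jωε₀)

with εr = Re ε and total conductivity σ = −ωε₀·Im ε (static plus
dispersive losses). ε₀ is fixed at 8.8541878128×10⁻¹² F/m. Lymph-node
spectra are single-pole Debye models embedded as pole 1 of the 4-pole form
(α = 0, poles 2–4 null); the embedding reproduces the closed-form Debye
expression to machine precision, which the tests assert.

Physiological variability of bone, fat and muscle is represented by bound
curves at ±5 % of the nominal *property values* — the scaling is applied in
output space (to evaluated εr and σ), not to the Cole–Cole parameters, so
upper/nominal is exactly 1.05 at every frequency and for both properties.
The ±5 % reading of the "5 % variation" is implemented (rather than a 5 %
total spread), and the fraction is configurable. Skin carries no bounds
(one curve). The mixed tissue, a composite of adipose through muscle and
small bone, spans from the fat lower bound to the muscle upper bound. The
stage-3 curve family over {skin, bone, fat, muscle} therefore has exactly
seven members: one skin curve plus lower/upper pairs for the other three.

Voxel mapping at the user-selected frequency (1–10 GHz, both ends
inclusive): for each segmented tissue population, the minimum and maximum
MRI intensity over its voxels are anchored to the tissue's lower and upper
curves, and every other voxel is interpolated linearly in between,
independently for permittivity and conductivity. The mapping population is
the final per-tissue label population (after stage-1 relabelling), which
re-ranges relabelled voxels over the enlarged fat population. Skin voxels
take the skin curve value; node interior/shell voxels take their
state-specific curve values directly, with no intensity mapping;
background is free space (εr = 1, σ = 0). A degenerate population with
constant intensity is assigned the midpoint of its bounds and logged — not
an error. The intensity volume used is the pre-processed exam stored in
the bundle.

**Parameter registry.** Tissue parameters ship as editable CSV tables. The
4-pole Cole–Cole table carries the standard Gabriel-compilation
parametrization for dry skin, cortical bone, infiltrated fat and muscle.
The lymph-node Debye table (`cln_debye_synthetic.csv`) contains *synthetic
placeholder* values — four distinct, physiologically plausible spectra for
healthy/metastasized × interior/surface with the expected ordering
(metastasized above healthy, interior above the fat-like perinodal
surface) — and is flagged as such in its filename and source column; users
with access to measured node parameters should substitute them. All
dielectric tests are written against structural and ratio properties, not
against absolute literature values.

## Assembly, determinism and caching

`build_phantom` runs stages 0–3 in a fixed, logged order and attaches the
stage name to any error. The whole build is deterministic given (input,
configuration, seed): one seed drives k-means initialization and node
placement, and two runs with the same seed produce bit-identical bundles.
Stage-0 products (pre-processed volume and cluster model) are cached in
memory keyed by a hash of the input voxels and the stage-0 configuration,
so re-running with different stage-1..3 choices skips the clustering.
Count constraints on nodes and the frequency gate are validated at
configuration time, before any computation.

## Synthetic test volumes

The fixture generator emulates the *statistical* structure of a neck MR
exam, not its anatomy: an elliptic-cylinder body on zero background, two
lateral muscle lobes, a central mixed-tissue core, remainder fat; each
tissue painted at a distinct intensity plateau (fat 0.25, muscle 0.55,
mixed 0.85 — fat darkest, as on fat-suppressed T1 contrast) and corrupted
by additive Gaussian noise (σ = 0.02) and salt-and-pepper impulses
(0.2 % of body voxels), both seeded. The default grid is 96×96×48 at
(0.5, 0.5, 1.0) mm — large enough for six level slabs and multi-node
placement, small enough for sub-minute tests. Plateau means must be
separated by more than 4 Gaussian σ, which guarantees a separable
clustering problem: with zero noise the pipeline recovers ground truth
exactly, and under default noise the full pipeline agrees with ground
truth on ≥99 % of body voxels (residual disagreement is confined to
tissue-interface voxels smoothed by denoising).

What passing these tests does *not* show: robustness to bias fields, to
partial-volume gradients, to Rician noise statistics, to anatomical tissue
geometry, or to contrasts where the plateau ordering differs — real exams
require a per-exam cluster→tissue map and possibly different filter
settings. Analytic shapes (cylinder, ellipsoid, slab) with closed-form
volumes back the skin and rasterization oracles.

## Numerical choices and limitations

- Fractional powers (jωτ)^(1−α) use principal-branch complex
  exponentiation; an independent cmath-based implementation agrees to
  1e-10 relative, asserted over all registry tissues × 20 frequencies.
- Min–max normalization requires at least two distinct values; constant
  volumes are rejected.
- The skin distance threshold includes a half-voxel allowance (below one
  voxel step on either axis) so curved boundaries are covered without
  changing axis-aligned thickness.
- Ellipsoid interior/shell thresholds include a 1e-9 relative tolerance so
  a vanishing shell fraction degenerates cleanly to an empty shell.
- K-means determinism relies on a fixed seed and ascending-centroid
  relabelling; with duplicate centroid values (pathological inputs) the
  stable sort keeps the labelling deterministic.
- Level slabs are axial intervals only; no lateral left/right split is
  implemented.
- The acceptance script probes limits (node counts, axis range, frequency
  band) on 0.5-unit grids; problem sizes there are the full default
  fixture (≈2.2×10⁵ body voxels), chosen to keep the whole script in a few
  seconds.
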