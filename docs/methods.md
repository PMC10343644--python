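# Methods

## The estimation problem

The package implements the classical design-based stereology workflow for a
small synovial joint (the rat metatarsophalangeal joint is the motivating
case): from a stack of equidistant histological sections, estimate

* the absolute joint volume **V** by Cavalieri point counting,
* the volume fraction **Vv** and absolute volume of each articular component
  (cartilage, bone, capsule, synovial space, synovial membrane) by the
  Delesse principle,
* the surface density **Sv** and absolute area of the cartilage–synovial
  interface and the synovial membrane from cycloid intersection counts on
  vertical sections,
* the 2-D numerical density **Nv** of chondrocyte profiles (isolated cells,
  isogenous groups, total) from unbiased counting frames, and
* the predicted coefficient of error (CE) of the volume estimate.

All estimators are simple ratios/sums of raw counts:

    V  = ΣP · T · (a/p)                 [µm³ → mm³]
    Vv = ΣP_comp / ΣP_ref               component volume = Vv · V
    Sv = 2·ΣI / (ΣP · l/p)              [µm⁻¹ → mm⁻¹]; surface = Sv · V [mm²]
    Nv = ΣQ / (ΣN_frames · Af)          [µm⁻² → mm⁻²]
    CE = sqrt(0.0724 · (B/√A) · √n / ΣP^{3/2})

with T the section spacing, a/p the grid area per test point, l/p the
cycloid test-curve length per test point, Af the counting-frame area, n the
number of sections, and B/√A the profile shape coefficient.

Because no raw count data accompany the published tables, correctness is
established the only way it can be: against synthetic specimens with known
ground truth. The package therefore contains a phantom generator and a
virtual-sectioning simulator that are first-class, tested code.

## Sampling design

Sections are **vertical uniform random (VUR)**: each specimen receives one
uniform random azimuth about the fixed vertical (z) axis and a systematic
stack of parallel planes at spacing T with a uniform random start in
[0, T). Under this design the Cavalieri estimator is unbiased for volume,
and test curves whose tangents are sine-weighted with respect to the
vertical axis (cycloids, minor axis parallel to vertical) give unbiased
surface estimates even for anisotropic structures — isotropy of the
specimen is *not* assumed.

Every probe is randomized independently per section (uniform random offset
within one probe period), as systematic uniform random sampling requires.
RNG streams are split hierarchically (study → specimen → section → probe)
through `SeedSequence` spawn keys, so enlarging one stage never perturbs
another and every run is bit-reproducible from one seed.

### The cycloid test system and the shared point total

The surface-density formula divides by the same reference point total ΣP
used by the Cavalieri and Delesse estimators (the published workflow counts
intersections on the very images used for point counting). For that ratio
to be consistent, the simulator anchors exactly one cycloid arc (length
l/p) per grid cell of area a/p, i.e. the cycloid system's test-point
density equals the point grid's. The absolute surface then reduces to
2·ΣI·T·(a/p)/(l/p), which is unbiased under the VUR design; this identity
is what the anisotropic-phantom validation exercises. l/p is not stated in
the source workflow; the default is 100 µm, configurable, and echoed in
all outputs.

### Counting-frame rule

A profile (treated as a point, its nucleus) is counted in a frame iff it
lies strictly inside or on the top/right (acceptance) edges; the left and
bottom (forbidden) edges and their corner extensions exclude. Frames that
tile a rectangle therefore count every profile exactly once — a property
tested exactly. An isogenous group is counted in `q_groups` when at least
one member is counted, and `q_group_cells` counts its counted members, so
a frame edge can legitimately yield one counted member of a two-cell group.

## Phantoms

A joint is idealized as five nested compartments around the origin: bone
core (0–r1), cartilage shell (r1–r2), synovial space (r2–r3), synovial
membrane (r3–r4), capsule (r4–r5). The point of the idealization is exact
ground truth, not anatomical realism; two controlled departures from
sphericity stress the estimators where a sphere cannot:

* **prolate stretch** (1, 1, c) along the vertical axis — surfaces become
  anisotropic, which is fatal to line probes that are not sine-weighted;
  the validation uses c = 2;
* **villosity** — a radial perturbation r3 + A·cos(m·θ) of the membrane's
  inner boundary (θ the polar angle), mimicking synovial folds while
  keeping the geometry axisymmetric.

Truth volumes and surfaces are closed-form for the plain sphere and 1-D
adaptive quadrature (surface of revolution; relative tolerance 1e-9,
validated to 1e-6) for stretched/villous cases; quadrature non-convergence
raises rather than silently falling back. Membership uses half-open shells
(a point exactly on an outer boundary belongs to the inner compartment) so
ties are deterministic.

The "surface area of cartilage" is defined as the cartilage edge facing
the synovial space — the r2 interface; the membrane surface is its inner
(r3) boundary.

### Group calibration

The synthetic five-group study (Arthritis, LNC, Diclofenac,
Diclofenac-LNC, No Arthritis; default 4 specimens/group) is calibrated to
the published group table. The published per-component means do not sum
exactly to the published joint means (real-data rounding), and the
published joint mean/SD is both what the calibration example targets and
what the effect-recovery check compares, so the calibration draws each
specimen's joint volume ~ Normal(joint mean, joint SD) (truncated at 10%
of the mean) and splits it across compartments by the fixed per-group
component shares (component means normalized to 1). Radii then follow
deterministically by inverting the shell-volume formulas innermost-out.
Consequences: expected component volumes are the shares times the joint
mean (within ~4% of the printed component means), and per-component SDs
are induced by the joint SD rather than set independently.

Chondrocyte fields are simulated directly as planar processes per section,
matching the 2-D profile estimator: isolated profiles are a homogeneous
Poisson process on the cartilage profile; isogenous groups are Poisson
parents with 2 + Poisson(mean − 2) members within a 15 µm cluster radius
(kept inside cartilage by rejection, so every group retains ≥ 2 members).
Default intensities per group follow the published density table with a
fixed membership of 2 (the published total/isolated/group columns imply a
mean membership below 2, which a group cannot have; the group count is
honoured and the total follows).

## Simulated counting

* **Point counts** — every grid point on a section is classified by 3-D
  membership; reference counts are points in any compartment, so component
  counts partition the reference count exactly.
* **Intersections** — cycloid arcs are polylines (chord error below the
  0.25 µm default tolerance, rendered length within 0.1% of l/p);
  crossings are sign changes of the inside indicator along the polyline,
  which the half-open membership rule makes deterministic, including exact
  touches. Halving the tolerance changes counts on well under 5% of
  sections.
* **Frames** — six frames (Af = 2700.28 µm²) are placed per section on a
  systematic lattice (pitch = one frame side, hence disjoint) with random
  offset, keeping only frames entirely inside the cartilage profile (exact
  rectangle-vs-ellipse tests in the de-stretched plane); sections whose
  cartilage cannot host six record fewer in `frames_used`.

Sections are geometric planes: the 5 µm physical thickness is ignored
because none of the estimator formulas carries a thickness term;
overprojection modelling is out of scope.

## CE prediction and its limits

The printed CE expression is typographically ambiguous; the default
reading is the point-counting noise prediction
CE = sqrt(0.0724·(B/√A)·√n/ΣP^{3/2}) (equivalently sqrt(var)/ΣP with
var = 0.0724·(B/√A)·sqrt(n·ΣP)), which reproduces the observed scaling of
the empirical CE with section count; the alternative reading
0.0724·(B/√A)·sqrt(n/ΣP) is selectable (`ce_variant="sqrt_ratio"`). The
shape coefficient defaults to the circle value 2√π ≈ 3.545 — exact for
spherical phantoms, and the mathematical minimum over planar profiles
(`shape_coefficient_from_profiles` estimates it when boundary/area
measurements exist). Note this prediction contains only the point-noise
component, not the between-section (systematic sampling) variance: when
sections are few but points per section are abundant it under-predicts.
Across the study's own regimes (n ≈ 10–36 sections, ΣP ≈ 700–10,000) the
prediction stays within a factor of two of the empirical coefficient of
variation.

Section-reduction analyses subsample every k-th section (T scaled by k);
averaging the subsampled volume over all k phases recovers the full-stack
volume exactly (algebraic identity). When a reduced design is emulated
across seeds, the retained phase is drawn uniformly so the reduced stack
has a uniform random start over its full period k·T.

## Statistics

Group comparisons are deliberately standard plumbing delegated to
scipy/statsmodels: one-way ANOVA with Sidak-adjusted pairwise pooled
t tests by default; when the Brown-Forsythe (median-centred Levene)
homogeneity diagnostic rejects at α = 0.05, a Brown-Forsythe
unequal-variance ANOVA with pairwise Welch t tests (Sidak-adjusted — the
studentized-maximum-modulus reference of Dunnett's T3 is approximated by
the Sidak bound, which is marginally conservative); Mann-Whitney U is
available explicitly. Degenerate zero-variance comparisons report p = 1
for equal means and p = 0 otherwise, keeping cloned-specimen tests
deterministic. Two-way (time × treatment) designs concern out-of-scope
kinetic endpoints and are not implemented.

## Problem sizes used in validation

Monte-Carlo validation uses the study conditions: sphere phantom at the
published arthritic joint scale (3.02 mm³), T = 50 µm, a/p = 23,470 µm²
(≈ 36 sections, ΣP ≈ 2600): 2000 replicates for volume, 500 for volume
fractions, 2000 for the prolate surface check, 1000 for profile densities
(intensity 1500 profiles/mm²), 1000 for the 28-section reduction
schedule {28, 14, 10}, 400 per CE regime, and 500 simulated five-group
studies for effect recovery. Each experiment draws its seeds from one
master seed.

## What passing does and does not show

The phantoms prove estimator correctness under the stated sampling design
— unbiasedness, orientation handling, counting rules, unit conversions —
with exact ground truth. They do not emulate real histology: no tissue
deformation, decalcification or staining artifacts, no section thickness
or shrinkage effects, no observer error in point/intersection
classification, and idealized compartment geometry. Agreement on phantoms
is therefore necessary, not sufficient, for accuracy on real material.

## Known limitations

* The CE prediction omits the systematic between-section variance term
  (see above).
* `Sv` as a stand-alone density is a ratio estimator (unbiased only
  asymptotically); the absolute surface Sv·V is the design-unbiased
  quantity, and the validation targets it.
* Villous and stretched geometries are axisymmetric by construction; fully
  triaxial or non-axisymmetric phantoms would require 2-D quadrature.
* Chondrocyte profiles are 2-D planar processes; 3-D number estimation
  (disector) is out of scope.
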