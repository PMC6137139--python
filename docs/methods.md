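# Methods

`maflow` quantifies the morphology and hemodynamics of retinal capillary
microaneurysms (MAs) starting from a 2-D labeled segmentation mask — MA
body, feeding/draining vessels, optional clot sub-region — plus an
isotropic pixel size in μm. This note records the models, the numerical
choices, and what the synthetic validation does and does not establish.

## Medial axis and inscribed radii

The MA silhouette (body ∪ clot ∪ vessels, holes filled) is traced with a
Moore-neighbor walk into an ordered boundary-pixel polygon. The polygon is
smoothed with a 3-point circular moving average — raw pixel staircases
otherwise seed dense spurious Voronoi branches — and its Voronoi diagram
is computed. Voronoi vertices strictly inside the polygon, joined by
their ridges, form the medial-axis graph; for a simply connected
silhouette this graph is a tree. The centerline is the maximal-arclength
leaf-to-leaf path of that tree (all side branches discarded), which
encodes the assumption that an MA is a single feeding→draining channel.
Terminal sub-paths whose inscribed circles are contained in a later
point's circle are peeled off, and each end is then trimmed by one local
caliber: the medial axis of a round-capped channel terminates at the cap
center, one radius short of the tip, so points beyond that carry
cap-curvature radii rather than vessel caliber. The path is resampled at
0.5 px spacing and oriented feeding→draining using the mask's flow hint
(falling back to ascending x).

The inscribed radius at a point is estimated as the mean of two
clearances: distance to the nearest foreground boundary-pixel center and
distance to the nearest adjacent background-pixel center. The physical
interface lies halfway between those two rings for any wall orientation,
so the average is an orientation-unbiased sub-pixel estimate. The
regression suite checks it against the Euclidean distance transform
evaluated (bilinearly) at the off-lattice path points; agreement is
within 0.71 px on every synthetic cohort fixture. A crest-refinement
variant that snapped path points onto the pixelated clearance ridge was
evaluated and rejected: the pixelated ridge is curvature-biased by
~0.2 px toward flatter walls, which measurably corrupted the asymmetry
split, whereas the raw Voronoi path is unbiased.

## Morphological indices

* **BNR** (body-to-neck ratio): the maximum inscribed radius over
  body-labeled centerline points divided by the minimum over
  vessel-labeled points. The numerator is restricted to the body
  centerline (following the caliber definition on the body rather than
  the global skeleton maximum). Denominator points within about two
  calibers of a path end are excluded (end-shaped radii), as are
  synthetically extended stub points. Being a ratio of single-point
  extrema, BNR carries an intrinsic orientation/discretization
  sensitivity of several percent at 8–12 px calipers — larger than AR's,
  which is an area ratio and stays within ~2% under arbitrary rotation.
  Recovery against exact phantom ground truth remains within 10%.
* **AR** (asymmetry ratio): the body polygon (traced and smoothed like
  the silhouette) is split by the body-segment centerline, extended past
  the polygon along its terminal tangents; AR = larger/smaller area ≥ 1.
  Split fragments are assigned to a side by the sign of the cross product
  between a window-smoothed local tangent and the fragment centroid
  offset, so multiple boundary crossings accumulate correctly.
* **Classification**: AR < 1.4 → fusiform, AR > 1.8 → saccular, the band
  in between → manual review. The thresholds are configuration values;
  the defaults implement the semi-automatic rule rather than a hard law.

## 3-D reconstruction

Assuming rotational symmetry, circular cross-sections of the local
inscribed radius are swept perpendicular to the local tangent along the
centerline, with parallel-transported frames (no torsion flips). Path
tangents are taken from a lightly smoothed copy of the path (σ = 2
samples) so sample-scale jitter does not twist the frames; radii are not
smoothed. Feeding/draining stubs are first extended along their terminal
tangents at constant end radius until each is at least as long as the
body's flow-axis extent and the laminar entrance length
Le = 0.035·D·Re; at capillary Reynolds numbers (≪ 1) Le is far below one
diameter, so the body-length rule dominates. Extended portions are
flagged and excluded from all index averages.

Where the sweep radius exceeds the path's radius of curvature, adjacent
rings overlap locally; the surface is emitted with a warning and *not*
clamped (clamping would pinch the lumen at genuine medial-path bends).
The voxelizer classifies voxel centers by the nonzero-winding rule along
axis-aligned rays — correct for locally self-overlapping closed meshes —
with the end caps temporarily closed by triangle fans. Lattice spacing
is 2·r_min/target with target ≥ 8 sites across the narrowest lumen.
Voxel region labels come from the nearest generating ring; clot flags
come from each body voxel's own 2-D projection onto the mask, because
the clot is delineated in the imaging plane and typically hugs the dome
wall away from the centerline.

## Lattice-Boltzmann solver

D3Q19, single relaxation time (BGK), on the sparse fluid-site list.
Blood is a Carreau-Yasuda shear-thinning fluid
η(γ̇) = η∞ + (η₀ − η∞)[1 + (λγ̇)^a]^((n−1)/a) with the standard human
blood parametrization η₀ = 0.16 Pa·s, η∞ = 3.5 mPa·s, λ = 8.2 s,
a = 0.64, n = 0.2128, ρ = 1060 kg/m³ (all overridable). Each step, the
local shear rate is read off the non-equilibrium momentum-flux tensor at
the previous relaxation time, the Carreau-Yasuda viscosity is evaluated,
and the site's relaxation time updated.

Unit bridge: capillary flow is deeply viscous (Re ~ 1e-4, Womersley
≪ 1), so the time step is chosen purely for numerical quality: the
infinite-shear viscosity is anchored at τ_ref = 0.9 (best wall accuracy
for the boundary scheme) and the shear-thinning excess is capped at
τ_max = 3. The cap truncates the zero-shear plateau: viscosities above
≈ 6×η∞ (shear rates below ~1 s⁻¹) are represented at the cap value.
This compresses the extreme low-shear tail inside stagnant MA domes —
ratios such as SRMD are therefore conservative there — but leaves the
directional structure intact. Both bounds are configuration values.

Boundaries: no-slip walls use linearly interpolated (Bouzidi) bounce-back
with exact per-link wall distances computed from the surface-of-revolution
rings (plain half-way bounce-back where the ring model does not apply,
e.g. at cap corners). The inlet layer imposes a parabolic profile by an
equilibrium distribution with interior-extrapolated density; because the
equilibrium inlet transmits a few percent less than its nominal flux, a
multiplicative controller trims the delivered flux onto the analytic
Poiseuille value each convergence check (exact in the Stokes regime by
linearity). The outlet layer fixes the reference density with
interior-extrapolated velocity. Convergence: the maximum velocity change
over 100 steps, relative to the maximum velocity, falls below the
tolerance (default 1e-5 for validation runs; 1e-4 for index runs, where
the indices are ratios of means and insensitive at that level).

Validation on a cylinder at the minimum resolution of 8 sites across the
diameter: Poiseuille velocity L2 error ≈ 1%, wall shear stress within
≈ 3% of 4ηū/R, interior cross-section flux conservation to < 0.1%,
circumferential WSS uniformity within a few percent at 16 sites.

Steady inlet velocity: the reference in-vivo measurement of 1.69 mm/s is
interpreted as the cross-section mean of the parabolic profile, giving a
centerline peak of 3.38 mm/s; a switch allows treating it as the peak
instead. Pulsatile runs scale the inlet by a mean-normalized waveform;
absent a measured trace the generator provides a rectified-sine-squared
template w(t) = 1 − p·cos(2πt/T) with period T = 3.13/4 s ≈ 0.78 s
(four cycles per 3.13 s recording) and pulsatility p (default 0.4,
mid-range for retinal capillary velocimetry). The waveform period is
mapped onto a configurable number of lattice steps per cycle; because
the Womersley number is ≪ 1 the flow is quasi-steady and the mapping is
faithful whenever the per-cycle step count well exceeds the viscous
relaxation time (the suite verifies snapshots against instantaneous
steady solutions to < 5%). The first cycle is discarded as transient.

Wall shear stress is the tangential traction |σn − (n·σn)n|. The
deviatoric stress is reconstructed from the non-equilibrium tensor and
local viscosity at the two fluid nodes inward along the wall normal and
linearly extrapolated to the wall; the wall-adjacent node itself is
skipped because its non-equilibrium moments carry a bounce-back
artifact. Normals and wall distances come from the generating rings (the
radial direction off the local centerline), far more accurate than
staircase link normals. Element areas are exposed axis-face counts.

## Perfusion indices

SRMD = mean shear rate over vessel fluid sites / mean over body fluid
sites; WSSMD = area-weighted mean WSS on vessel wall elements /
area-weighted mean on body wall elements. Volume means are unweighted
(uniform voxels). Inlet/outlet boundary layers are excluded (they hold
boundary-condition equilibria), as are extended stub portions (the
vessel averaging region is the segmented length, comparable to the body
length). For clotted lesions the body denominator is restricted to
clot-flagged or perfused sites/elements for the sub-region variants; the
low-shear map reports, per site, the fraction of the cardiac cycle with
γ̇ ≤ threshold (defaults 1 s⁻¹ and 15 s⁻¹).

## Synthetic phantoms and ground truth

Phantoms are built in continuous geometry before any raster exists: a
straight channel of half-width `neck_radius` with semicircular end caps,
plus either a one-sided circular bulge (saccular; center offset
`asymmetry` from the axis) or a raised-sine spindle with unequal upper
and lower amplitudes (fusiform). Default scales follow parafoveal
capillaries: neck radii 4–6 μm, body radii 10–25 μm, 1 μm pixels, stub
length equal to body length. Apex clots are the intersection of the body
with a disk of 0.6·body radius centered on the dome apex.

Ground truth is computed on the exact geometry, sharing no code with the
raster pipeline: per vertical slice, all local maxima of the exact
distance-to-boundary are located (two-stage grid search, containment
filtered, and pruned to genuine medial points by requiring a slope kink —
a smooth single-arc maximum is not a medial point); ridge points of
adjacent slices are linked by mutual-nearest matching and the
maximal-arclength left-to-right path selected by dynamic programming —
the same pruning rule the pipeline applies to its Voronoi tree. AR
ground truth integrates the slice measure above/below this curve; BNR
ground truth takes the extreme inscribed radii along it.

Cohort generation calibrates the asymmetry offset by bisection on the
exact-geometry AR. Saccular offsets are capped at 0.72 of the geometric
maximum: beyond that the bulge overhangs so sharply that the junction
cusps fall below raster resolution (recovery errors grow to 15–20%
there, against ≤ 5% below the cap). Realized saccular AR therefore
spans roughly 1.8–2.4; the far larger indices printed for real lesions
(SRMD up to ~350) reflect in-vivo geometries outside this validated
phantom envelope, so cohort-level agreement with those magnitudes is
*not* claimed — only the directional relationships are.

### What passing tests show — and what they do not

The phantoms are clean rotationally-symmetric channels with exactly two
stubs, no branching, no imaging noise beyond optional sub-pixel boundary
jitter, and no segmentation disagreement. Passing recovery tests shows
the pipeline is internally consistent and accurate on such geometry; it
does not establish accuracy on real adaptive-optics masks with irregular
lobes, multi-vessel topology, or grader variability. The published
per-lesion index table is used as a fixed input for the statistical
layer; its values are not recomputable without the original images.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test under the
normal approximation with tie-averaged ranks and no continuity
correction — this variant reproduces the published p-values (0.028 for
SRMD, 0.009 for WSSMD) from the five-lesion table, while the
continuity-corrected and exact variants (both available by flag) do not;
the suite pins this as a regression. Associations use Pearson's r.
Summaries are mean ± sample SD (n−1). Inter-grader agreement passes when
two delineated areas differ by < 10% of the larger. Significance is
α = 0.05; no multiple-testing correction is applied.

## Problem sizes

Validation and index runs use lattices of roughly 1.5k–60k fluid sites
(8 sites across the narrowest lumen; spacing ≈ 0.6–2 μm) and converge in
1–15k steps. These desk-scale resolutions sit at the lower end of the
45k–520k-site range typical of production runs of this kind of model;
grid-convergence checks (halving the spacing changes mean wall stress by
< 5%) justify them for ratio-type indices.
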