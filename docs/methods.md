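# Methods

## Discrete curvature estimation

At each vertex, all mesh vertices within a Euclidean ball of radius *r*
(the *fitting radius*) are expressed in the frame of the vertex normal, and
a polynomial height function z = f(x, y) containing every monomial of
degree 2–4 (no constant or linear terms: the surface passes through the
vertex tangent to its normal plane) is fit by least squares. The principal
curvatures are the eigenvalues of the shape operator of the degree-2 part,
[[2a, b], [b, 2c]].

**Why degree 4.** The classical quadric-only fit carries a systematic bias
of order (r/R)² on a sphere of radius R — about +5% per principal curvature
(+10% on Gaussian curvature) at r/R = 0.5, which would swamp a 2% sphere
calibration. The quartic terms absorb the next order of the local height
field; the residual bias measured on a unit icosphere at r = 0.5 mm is
−0.7%, and at the 10-mm averaging radius on 14–45-mm caps it stays ~1%.
Curvatures are still read only from the degree-2 coefficients.

**Sign convention (convex-negative).** A convex sphere of radius R gives
k₁ = k₂ = −1/R; flat regions are ≈ 0; concave dishes positive. This is the
only convention under which negative extraction thresholds coexist with
"flatter areas lie above the threshold". Raw Gaussian curvature K = k₁k₂
cannot distinguish a dome from a dish, so the reported signed Gaussian
curvature attributes the sign of the mean curvature:
K_signed = sign(−(k₁+k₂))·|K| — positive on convex, negative on concave
regions, zero where the mean curvature vanishes (e.g. perfect saddles).

**Numerics.** Tangent coordinates are scaled by the fitting radius before
forming normal equations (condition control) with a 1e-10 ridge; Gram
matrices are accumulated from shared monomial moments, and vertices are
processed in bounded chunks so memory stays flat on isosurfaced meshes with
hundreds of thousands of vertices. Neighborhoods smaller than ~2.5x the
12-term basis (30 points; a bare 12-point quartic fit is hopelessly
ill-conditioned) grow their radius by 50% up to three times, then the
offending vertices are reported. Balls larger than 400 points are thinned
deterministically (an even spread over the index range); twelve
coefficients do not benefit from thousands of samples. Two fitting
radii are used: 1.5 mm for extraction-stage thresholding (the per-bone
thresholds operate at the scale of facet rims) and 10 mm for Gaussian
averaging (≈ half the height of an articular surface); both are
configurable.

## Articular-surface extraction

Vertices with k₂ at or above the per-bone threshold (−0.25 mm⁻¹:
medial cuneiform, first metatarsal; −0.35 mm⁻¹: intermediate cuneiform,
second metatarsal) are flat; faces whose three vertices are all flat form
the candidate set (conservative at boundaries; speckle holes are recovered
by hole filling). Among edge-connected candidate components the one
nearest the seed point is chosen — with ties inside one fitting radius
broken toward the largest area, because segmentation noise can shed
zero-area slivers right at the seed — or the largest component when no
seed is given. Interior holes (every boundary loop except the longest one)
are filled by centroid fans. The facet must be a proper subset of the bone
surface; an entirely-flat or entirely-curved mesh is an error.

## Anatomic frames

Frames are built from surface centers of gravity and directional extrema
only. Cuneiforms: PD runs from the distal-surface centroid (the origin) to
the proximal-surface centroid; one extremum per surface along the dorsal
hint (medial variant) or its negation (intermediate variant); DP is the
mid-centroid→mid-extremum direction orthogonalized against PD and oriented
dorsally. Metatarsals: PD runs from the proximal-surface centroid (origin)
to the bone's volume centroid; MT1 takes the most lateral point of the
dorsal and plantar halves of the facet and derives ML from their midpoint;
MT2 takes the most plantar point and derives DP. Axes are
Gram-Schmidt-orthogonalized in the order PD → DP → ML.

**Handedness.** ML always points medially and DP dorsally. With
anatomically fixed senses, left and right frames are mirror images, so one
handedness cannot hold on both sides: medial is dp × d̂ (d̂ = the
distal-pointing direction) on the right side and its negation on the left.
Frames expose their handedness; orthonormality is exact.

**Hints.** The extremum constructions need an approximate dorsal (and for
MT1, lateral) reference, supplied implicitly by scan orientation in a
micro-CT protocol. They are explicit per-specimen unit vectors here
(defaulting to the scanner axes); only their half-space matters, and a
hint within 5° of PD is rejected as ambiguous.

## Morphometry

Width and height are ML- and DP-coordinate spans of the facet in its frame.
Width profiles intersect the facet's outer boundary loop, projected onto
the frontal plane through the centroid, with ML-parallel lines at 2-mm
height steps (the arthrodesis saw-blade thickness; heights are deliberately
not normalized to bone size). The medial (lateral) distance is the signed
coordinate of the outermost crossing on that side — negative when the whole
contour at that height lies on the other side of the DP axis, which
non-convex facet outlines do produce. Quadrants are cut by the sagittal and
transverse planes through the centroid; faces are assigned by centroid
sign, an exact area partition, so area-weighted quadrant curvature means
recombine exactly into the whole-surface mean (vertex weights are one third
of incident in-region triangle areas).

## Curvature similarity

For opposing mean curvatures the statistic
s = −sign(k_cun·k_met)/(1 + |log |k_cun/k_met||) maps equal magnitudes with
opposite sense (concave-on-convex, congruent) to +1, equal magnitudes with
the same sense to −1, and diverging magnitudes toward 0. The natural log is
the default; the base only rescales the decay, never the ±1 landmarks, and
is configurable. If either curvature is within 1e-9 of zero the statistic
carries no information (a tiny perturbation flips its sign) and 0 is
returned. Quadrants are paired by identical anatomical label.

## Statistics

Summaries are mean, sample SD and t-based 95% CIs. One-sample t-tests are
two-tailed against 0 (curvature) and against ±1 and 0 (similarity; the
one-tailed direction defaults to the side of the sample mean). Opposing
surfaces are compared with t-tests paired by specimen. The three-way ANOVA
is main-effects only with Type II sums of squares (robust to mild
imbalance from missing regions; interactions are not estimable with one
observation per cell). Specimen is treated as a fixed factor and side as a
plain factor without donor-level clustering. Games–Howell post-hocs use
Welch standard errors, Welch–Satterthwaite df and studentized-range
p-values (robust to unequal variances); the implementation is checked
against an independent one, and its critical values are cached on df
rounded to 0.1 (the quantile varies negligibly at that scale). Shapiro–Wilk
is the standard Royston approximation, verified against R's shapiro.test.

## Synthetic phantoms

A phantom bone is a closed prism-like solid: two spherical end caps with
prescribed signed Gaussian curvature and (width, height) extents, joined to
the shaft by a rim fillet. Three texture features mimic real periarticular
bone and are load-bearing for extraction fidelity: an egg-crate relief
(amplitude 0.2 mm, wavelength 3 mm) keeps the shaft walls nowhere flat at
the extraction scale; radial ridges across the rim (0.3 mm, spacing
2.5 mm, one-signed, vanishing at the cap edge and damped at the compass
extremes) chop the rim's threshold contour into short segments so imaging
noise cannot percolate a spurious band around the facet; and a gentle
metaphyseal neck (1 mm deep, 2.5 mm below each cap junction) adds meridian
turn below the rim, keeping the wall unreachable for the threshold contour
even under heavy curvature-field smoothing. Footprints are p = 4
superellipses (tall, narrow, squarish facets) whose boundary sampling
anchors vertices exactly at the dorsal/plantar/medial/lateral extremes, so
extremum-based frame recovery is not limited by sampling.

**Rim profile.** The rim meridian's curvature ramps linearly from the cap
value to 1/rim_radius over a 1.1-mm transition (curvature-continuous at the
cap edge), then holds until the tangent is vertical. Both halves of this
choice matter at the 1.5-mm extraction smoothing scale: a curvature jump at
the edge bleeds rim curvature into cap-boundary fits and erodes the facet
by ~0.5–1 mm, while a long soft shoulder lets the threshold contour creep
onto the rim; with rim_radius 0.6 mm and the 1.1-mm ramp the extracted
boundary coincides with the true cap boundary to within the mesh
resolution across the feasible curvature range, concave and convex.
The one-signed rim ridges leave the base ramp untouched between ridges,
so they break noise percolation without re-introducing flat spots.

**Feasibility.** A spherical cap of curvature |K| spans at most a polar
extent of 0.75·R, R = |K|^(−1/2); at realistic facet extents (12–18 mm wide,
20–29 mm tall) this caps |K| at ≈ 0.002–0.005 mm⁻². Infeasible
prescriptions are rejected. Cohort curvature magnitudes are drawn uniformly
on (8·10⁻⁴, 0.9·K_max) with random convex/concave sense; extents are drawn
from per-bone normal distributions with the means and SDs of published
cadaveric cohorts, truncated at ±2 SD. Default cohorts pose each joint with
a uniformly random rotation and translation; recorded hints are the posed
scanner axes.

**Imaging artifacts.** `voxelize_remesh` re-triangulates through a binary
occupancy grid (default study pitch 0.148 mm): occupancy is smoothed by a
one-voxel Gaussian and isosurfaced at Φ(0.5) ≈ 0.69 — occupancy marks every
voxel the surface touches, dilating the solid by half a voxel, and this
level compensates; a raw binary isosurface would overestimate areas by
~10%. `add_vertex_noise` displaces vertices along normals by seeded uniform
noise. Together they emulate segmentation staircase and jitter;
extraction still recovers caps with Jaccard ≳ 0.95 at 0.05-mm noise.

**What phantoms do not emulate:** real facets are not constant-curvature
spheres, subchondral texture and osteophytes are absent, and curvature
magnitudes are bounded by the spherical-cap feasibility above (real mean
Gaussian curvatures of small convex-and-concave surfaces can exceed it).
Passing phantom recovery therefore validates the geometry pipeline's
correctness and calibration, not its behavior on pathological anatomy.

## Problem sizes and determinism

Phantom meshes default to 0.3-mm edge length (≈ 2× the reference micro-CT
voxel); the validation cohort runs 12 joints (24 bones) at 0.35-mm
resolution, ≈ 30–50k faces per bone, the coarsest working point at which
extracted facet boundaries coincide with the true cap boundaries to within
the mesh resolution (at 0.45 mm the threshold contour begins to clip the
steep dorsal/plantar tips of strongly curved caps). All randomness flows through
seeded generators; report tables are written with fixed float formatting
and stable ordering, so a rerun with the same seed and configuration is
byte-identical. Per-stage timings go to the run log only, never into the
report bundle.

## Known limitations

- Euclidean (not geodesic) fitting neighborhoods: negligible on shallow
  facets, but curvature near deep concavities can mix across the void.
- The extraction boundary is localized to roughly the extraction fitting
  radius on surfaces whose rim sharpness is comparable to the facet
  curvature; the per-bone thresholds assume rims much sharper than facets.
- The similarity statistic is uninformative on nearly flat surfaces (both
  curvatures near zero), by construction.
- The ANOVA treats specimen as fixed and ignores bilateral donor
  correlation; a mixed model would be the modern refinement.
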