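# Methods

## Geometric model and assumptions

A single indoor photograph is modeled as a pinhole projection
m = K[R|t]X with zero skew, the principal point at the exact image
center ((W−1)/2, (H−1)/2 in 0-based pixel-center coordinates), zero yaw
and zero translation. The scene satisfies the Manhattan prerequisite:
the floor is horizontal, all walls are vertical and mutually orthogonal,
and at most three side walls are visible. All internal arithmetic uses
*centered* coordinates (pixels minus the principal point), and points
are homogeneous 3-vectors so vanishing points at infinity (frontal
walls, zero roll) are ordinary values rather than error cases.

Two annotated pairs of ground-parallel 3D-parallel segments give the
vanishing points V1 and V2 of two orthogonal horizontal directions; the
horizon H runs through them. Writing Oh for the foot of the
perpendicular from the principal point O to H, orthogonality of the two
directions yields

    f² = −(V1−O)·(V2−O) = h² − ‖OOh‖²  with  h² = ‖OhV1‖·‖OhV2‖.

Both forms are computed and must agree to 1e−9 relative; V1 and V2 must
lie on opposite sides of Oh (signed offsets along H), otherwise the
annotation is inconsistent and f² would be non-positive. The quantity h
has a concrete meaning used throughout: it is the 3D distance from the
camera center to the horizon line within the image plane, with the foot
of that perpendicular projecting to Oh.

### Rotation convention

The camera rotation is the Euler product **R = Rx(pitch)·Rz(roll)**
(roll about the optical axis applied first, then pitch about the camera
x-axis), columns r1/r2/r3 = world right/down/forward expressed in the
camera frame. Under this order the forward axis projects to
Vs = H ∩ (vertical line through O) *exactly*, for any roll — which is
precisely the construction the calibration uses — and the inverse map

    r3 = K⁻¹Vs/‖·‖, r1 = K⁻¹Vc/‖·‖, r2 = r3 × r1,
    pitch = atan2(r3_y, r3_z), roll = atan2(−r1_y, r2_y)

recovers the generating angles to rounding error. Signs: positive pitch
raises the optical axis (horizon below center in y-down pixel
coordinates); positive roll has r1 = (cos ρ, −sin ρ, 0). Pitch and roll
live in (−90°, 90°).

### Wall orientations: printed formula vs. exact pencil mapping

`wall_orientations` returns θa = atan(‖OhVa‖/h) and θo = atan(‖OhVo‖/h).
These satisfy θa + θo = 90° identically (because ‖OhVa‖‖OhVo‖ = h², an
exact consequence of orthogonality), but they measure angles from the
direction whose vanishing point is Oh — which coincides with straight
ahead only at zero roll. The aerial view therefore uses the exact pencil
mapping: a point at signed coordinate u along H (measured from Oh) is
seen at azimuth

    φ(u) = atan(u/h) − atan(u_s/h),

u_s being the coordinate of Vs. This is exact for any pitch and roll
(the horizon plane contains the camera center, its distance to H is h,
and the foot projects to Oh). Wall-plane orientation relative to frontal
is the azimuth of the wall's edge-direction vanishing point folded into
[0°, 90°] (0 = facing the observer); with this definition the annotated
wall's orientation equals the room heading exactly in the noise-free
synthetic round trip, including nonzero roll. At roll = 0 the two
readings coincide (orientation = 90° − θa).

## Layout reconstruction and rasterization

V3 comes from the orthocenter property of (V1, V2, V3); if H passes
through O the altitude never re-crosses and V3 is at infinity. The eight
layout corners follow the vanishing-point construction (Va through L2's
endpoints for the annotated wall's ceiling/floor conjunctions, V3
through L1's endpoints for the wall–wall conjunctions, Vo through
p2/p6/p3/p7 for the neighbor walls, outer corners clipped to the outer
pixel boundary −0.5…W−0.5). The annotation's `position` tag is treated
as labeling metadata: the construction always builds both neighbor
regions, and regions that fall outside the frame are simply empty, which
reproduces the identical construction used for scenes with fewer than
three visible walls.

Rasterization classifies every pixel center directly against the
boundary lines (sign tests on homogeneous line evaluations) rather than
filling clipped polygons: the two wall separators split the image into
left/middle/right regions, and each region's ceiling/floor lines split
it vertically. This is deterministic, bit-exact under reruns, and well
defined when corners fall outside the frame. Ties on a boundary go to
ceiling, then floor, then the wall. Wall labels are renumbered 3, 4, …
left→right over regions with at least one pixel. Ceiling/floor
boundaries crossing inside a region raise an invalid-corner-set error.

## Feature models

* **Orientation**: five triangular kernels with σ = FOV/5 and centers
  φᵢᶜ = −FOV/2 + (i−½)σ; Rᵢ integrates O(φ)·Fᵢ(φ) by the midpoint rule
  on a symmetric grid of FOV/2000 steps (≈ 0.03° for a 60° FOV —
  integration error orders of magnitude below every tolerance used).
  O(φ) is the wall-plane orientation in degrees of the wall covering φ,
  and 0 where no side wall is visible (the least-informative choice; an
  empty scene maps to the zero vector). Per-bin sums use `math.fsum`,
  which is summation-order independent, so mirrored scenes produce
  exactly reversed feature vectors. Kernel units make Rᵢ deg²; since the
  downstream RDM is rank-based city-block, the global unit cancels.
* **Relative distance**: strip boundaries round(k·W/5); each strip's own
  pixel count is the denominator, so bins are comparable when W is not
  divisible by 5. The Results-style "area difference" variant is not the
  operational definition used here; the per-strip side-wall proportion
  is.

## RSA and group inference

Partial Spearman = Pearson correlation of rank residuals: all
off-diagonal RDM vectors are rank-transformed (average ranks for ties),
neural and target ranks are each regressed on the control ranks plus an
intercept by least squares, and the residuals are correlated. Controls
are partialled from *both* sides (the standard symmetric definition).
With no controls this is exactly the Spearman correlation. Group
inference: one-sample t against 0 (upper-tailed by default — the
hypothesis is positive alignment), Benjamini–Hochberg step-up FDR across
all (model × region/window) cells of one analysis, two-tailed paired t
for task contrasts. Coefficients are not Fisher-transformed before the
t-test. A paired contrast with identical inputs returns t = 0, p = 1
(no effect) rather than a zero-variance error; genuinely degenerate
zero-variance data still raise.

## The synthetic generator

The generator emulates the study conditions: 650 × 520 px frames, focal
lengths uniform in [300, 1200] px, pitch in [−30°, 30°], roll in
[−10°, 10°], room heading in [−30°, 30°], room dimensions 3–6 m wide ×
3–8 m deep × 2.4–3.2 m high, camera 1.2–1.8 m above the floor, 2–6 m
from the back wall, within the middle half of the room's width.
Annotations follow the back wall's ceiling/floor junctions (left–right
axis), the left/right walls' floor junctions (depth axis), the back
wall's floor edge (L1) and vertical midline (L2). Jitter adds isotropic
Gaussian offsets to every endpoint; the standard-normal draws depend
only on the seed, so jitter levels share rooms *and* noise directions,
which makes the error-vs-jitter curves monotone per construction of the
noise model rather than by sampling luck.

Scenes are resampled (with an incremented stream from the same master
seed) when: the wall behind the camera enters the frame, the back wall
covers < 1 % of pixels, a visible side wall spans < 8 px (label-count
ambiguities at the raster level), an annotation point falls on or behind
the camera plane, or |heading| < 0.5°. The last constraint reflects a
genuine identifiability limit, not a numerical convenience: as the
heading approaches zero, one annotated vanishing point recedes to
infinity and the focal length becomes unconstrained by the annotation
(a pair at infinity carries no f information).

What the generator does **not** emulate: lens distortion (the source
images in the motivating studies are not distortion-corrected),
occluding furniture and clutter, annotator bias toward visible edge
portions (synthetic endpoints sit at exact corners even outside the
frame), non-Gaussian annotation error, and principal points away from
the image center. Passing the synthetic validation therefore
demonstrates correctness of the geometry and the pipeline's noise
response, not performance on real photographs.

### Problem sizes

The shipped experiments use 200 rooms for noise-free recovery, 100 rooms
per jitter level, 60 conditions × 8 subjects for the planted
dissociation, and 100 random 5-condition triples for the oracle
comparison — sizes at which every experiment completes in seconds to
tens of seconds while leaving the statistical conclusions unambiguous.

### Planted dissociation

Model RDMs come from 60 noise-free synthetic rooms; two simulated
regions get per-subject neural RDMs equal to the rank transform of one
layout model's RDM plus Gaussian noise. The noise SD is set analytically
from the desired planted full Spearman ρ: σ = sd(ranks)·√(1/ρ² − 1)
with ρ = 0.3. Each layout model's partial correlation controls for three
nuisance RDMs *and the other layout model*: the two layout RDMs are
correlated over random rooms, so without the sibling control the
non-planted model inherits a small systematic positive coefficient in
every subject and the group t-test flags it — the sibling control is
what isolates each model's unique contribution. Under the null the
non-planted cells' p-values are uniform, so across master seeds a
non-planted q < 0.05 occurs at roughly the nominal FDR rate; that is the
promised behavior of the procedure, not a defect.

## Numerical choices

* Parallel tolerance for annotated segments: 0.01° (sub-pixel noise on
  short segments otherwise yields absurd finite vanishing points);
  intersections under it return points at infinity; coincident lines
  (perpendicular distance < 1e−6 px) are degenerate.
* r1 is re-orthogonalized against r3 before forming r2 = r3 × r1, and
  sign conventions (r3_z > 0, r1_x > 0) pin the rotation uniquely.
* RDM symmetry/zero-diagonal validated to 1e−10; correlation-distance
  matrices are explicitly symmetrized before validation.
* Zero-variance guards compare against 1e−12 of the data scale (exact
  float equality is meaningless after averaging).
* CSV floats use 17 significant digits and round-trip parsing, PNG label
  maps a fixed 8-color palette; reruns are byte-identical.

## Known limitations

* Calibration accuracy degrades as the heading approaches 0° or the two
  vanishing points become very unbalanced; the generator's 0.5° heading
  floor marks the practical identifiability boundary.
* The printed θa/θo formulas are reported as-is for compatibility, but
  users should treat the aerial-view orientations as the authoritative
  wall angles at nonzero roll (see above).
* The rasterizer assumes ceiling/floor boundary lines are non-vertical
  and wall separators are not degenerate through the reference corner —
  both hold under the sampling bounds (|pitch| < 45°, |roll| < 30°) but
  extreme poses outside them are rejected rather than handled.
* The RSA layer deliberately stops at RDM-level inputs: searchlights,
  cluster statistics and decoding wrap this kernel but require
  neuroimaging I/O stacks outside this package's scope.
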