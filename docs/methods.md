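# Methods

This note documents the models, algorithms and numerical choices behind
`pinreg3d`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the design was genuinely open.

## Coordinate conventions and units

All geometry is in millimetres; unit conversion happens only at reporting
boundaries (traits in cm/cm²/cm³, exact ÷10/÷100/÷1000). Image coordinates
are (column u, row v), origin top-left, 0-based. The camera frame has +Z
into the scene, +X right, +Y down; back-projection follows the pinhole
model `Z = depth·depth_scale`, `X = (u−cx)Z/fx`, `Y = (v−cy)Z/fy`. Depth
PNGs are uint16 with a configurable `depth_scale` (default 1 mm/unit; the
synthetic fixtures use 0.1 mm/unit, i.e. 100 µm depth units, so that
quantization noise stays an order below the 0.3 mm sensor noise being
emulated). Dataset frame filenames carry a conveyor position key that
inverts the row axis (pos = image height − row); `frame_sort_key` restores
temporal order.

## Registration error metrics

`rmsd_one_way(S, T)` is the one-way Chamfer distance: the RMS over source
points of the distance to the nearest target point (k-d tree). It is
asymmetric by construction — the partial RGB-D cloud is always the source
and the complete SfM cloud the target, so missing regions in the source do
not contribute. Its floor on perfectly aligned clouds is set by the noise
plus the target sampling spacing, not zero. `rmse_correspondence` is the
RMS over nearest-neighbor pairs within a cutoff (default 1.0 mm, twice the
ICP convergence threshold; the cutoff is a free parameter because the
trimmed statistic is only meaningful relative to it) and also reports the
inlier fraction. Nearest-neighbor ties are broken deterministically by
index, but only distances enter either metric.

## Pin segmentation

The pin is an 11 mm diameter, ≈1 mm thick colored round-head push pin
(≈0.095 ml, negligible against tuber volume). Its reference color is the
channel-wise median HSV over the opaque pixels of a background-free swatch
image. The per-point distance is the weighted absolute HSV difference with
a wrap-aware hue term (Δh ← 1−Δh when Δh > 0.5), weights (0.5, 0.1, 0.3),
normalized by the maximum attainable weighted sum 0.5·w_h + w_s + w_v =
0.65 so that d ∈ [0, 1]. The normalizer is a design choice — it makes the
threshold schedule (0.35 stepping down by 0.05) sit in a meaningful part
of the scale.

The iterative selection accepts a threshold when the convex hull of the
denoised selection (radius outlier filter: ≥ 40 neighbors within 5 mm,
self excluded) encloses ≤ 60 mm³. A coplanar selection has hull volume 0
and is accepted; fewer than 4 survivors is a "pin not found" error naming
the tuber. Note the 60 mm³ limit is below the full pin-head volume
(≈95 mm³): in practice only the exposed top face of the head is ever seen,
and the synthetic pins reproduce exactly that.

The disk fit: principal axes (SVD) of the selection's convex-hull points
give an oriented box; all points are projected onto the perpendicular
bisector plane of its shortest axis; the 2D convex-hull rim is fitted with
the hyperaccurate ("Hyper") algebraic circle fit of Al-Sharadqah & Chernov
— exact on noiseless circles, with a leading radius-bias term that
vanishes, unlike the Kåsa fit that shrinks noisy circles (both are in
`circle_fit`, and the bias ordering is asserted in tests). The plane
normal is signed to point away from the tuber centroid; the tangent pair
(u, v) is a deterministic right-handed completion (u from x̂ × N, or ŷ × N
when |N·x̂| > 0.9), so repeated runs produce identical frames.

PCA boxes rather than exact minimal-volume boxes: the pin selection is a
thin disk for which the PCA box's shortest axis is stable, and exactness
is not needed — only the plane direction matters.

## Rough alignment

Mapping pin frame to pin frame (center→center, (u,v,N)→(u,v,N)) fixes all
but the rotation about N. The search grid is 10° about N; at each step the
two 1 mm-wide cross-strips through the pin center supply the small tilts:
the strip extending along u is rocked about v (and vice versa) over ±45°
in 5° steps, scored by strip-to-strip one-way RMSD, ties preferring the
smaller |angle|. The ±45° range is a design choice (the pin normal already
constrains the wobble; the grid step is the protocol constant). The three
rotations are applied in a fixed, documented order — θ_N, then θ_u, then
θ_v, all about the pin center and the fixed target-frame axes — and the
total error is the one-way RMSD over the full 3 cm neighborhood (not the
strips alone).

Candidates are the local minima of the circular 36-value profile, strict
against the nearest distinct neighbors, plateaus counted once at their
leftmost index, ranked by ascending RMSD. The global minimum is not always
correct — near-symmetric tubers produce twin minima ~180° apart — which is
why candidates are ranked for selection rather than auto-committed. The
automated stand-in for visual inspection (`rank="auto"`) refines the top
three candidates through the ICP stage and keeps the one with the lowest
final full-cloud RMSD; `rank=k` reproduces an operator's explicit choice.

## Binary-color ICP refinement

Both clouds are relabeled — pin points pure red (1,0,0), body pure blue
(0,0,1) — and voxel-downsampled at 1 mm (centroid position per occupied
voxel, origin-anchored grid; majority label with ties to red, preserving
the scarce pin class). Equalizing resolution this way prevents the dense
SfM cloud from dominating correspondences.

The red-label set matters more than it looks. The radius outlier filter
can erode the segmented pin rim unevenly, and a lopsided red patch drags
the 90 %-weighted color term about a millimetre off truth; conversely the
raw color selection can include scattered color-bled body points when the
pin hue sits nearer the body hue. The labels therefore use the raw
selection at the accepted threshold restricted to the fitted pin disk
(fitted center, radius = max(fitted, nominal 5.5 mm) + 2 mm); on the RGB-D
side, labels come from the 2D annotation projected into the cloud.

Each iteration finds nearest-target correspondences within a radius
(default 3 × voxel; unstated in the reference protocol, kept configurable)
and solves one Gauss–Newton step on the 6-DoF twist minimizing the
weighted squared residuals: 0.10 × point-to-plane distance (target normals
from 30-NN PCA, oriented outward from the centroid) plus 0.90 × the label
term. The label term uses the standard colored-ICP linearization (Park,
Zhou & Koltun 2017) applied to the scalar red/blue field: the target label
is linearized on each point's tangent plane and the residual is the source
label minus that prediction at the projected source point. Away from the
pin boundary the gradient vanishes and the residual is the plain label
mismatch; near the boundary it actively steers pin onto pin. A literal
constant mismatch penalty would have zero gradient and could not steer the
solve, which is why the linearized form is used.

Iterations stop when the mean correspondence distance falls below 0.5 mm
or the budget (default 5, the operator-adjustable knob) is exhausted. On
1 mm-voxel clouds the mean voxel-to-voxel distance rarely drops below
0.5 mm, so the budget is usually the effective stop; the end-to-end runs
in the tests use 15 iterations as their standard setting. The mean
correspondence distance is recorded per iteration as-is — it is not
guaranteed monotone. Final metrics (RMSD, inlier RMSE) are evaluated at
the original full resolution under the composed transform refine ∘ rough.

## Morphological traits

Surface area is the triangle-area sum; volume is the divergence-theorem
sum (1/6)Σ v₁·(v₂×v₃), absolute value, after verifying watertightness
(zero open edges; the open-edge count is reported on failure; hole-filling
is out of scope). Axis lengths are axis-aligned bounding-box extents —
orientation-dependent by construction, kept as the default for fidelity to
datasets produced that way (it is known to overestimate the thinnest
section); a PCA pre-alignment flag is available for analysis. Sphericity
(36πV²)^(1/3)/A is ≤ 1 for any closed surface by the isoperimetric
inequality; convexity V/V_hull is ≤ 1 with equality for convex bodies.
Both are verified against closed forms (icospheres, ellipsoids, the unit
cube) and against an independent mesh library on bumpy meshes.

## Synthetic fixtures

A tuber is a superellipsoid — implicit
`((|x/a|^(2/e₂)+|y/b|^(2/e₂))^(e₂/e₁)+|z/c|^(2/e₁)) = 1` — morphed
radially from an icosphere (topology therefore stays closed/2-manifold),
with per-direction radius solved by 60 bisection steps, plus a smooth
radial bump field (mean of three seeded sinusoids of random orientation).
Default semi-axes (45, 35, 28) mm and the random-spec ranges (a ∈ [35,60],
aspect up to ≈2, exponents [0.85, 1.35], bumps 1–2.5 mm) cover market-size
tubers with longest axes roughly 5–14 cm and sphericities ≈0.80–0.97.
Gentle low-frequency bumps perturb the surface without creating
concavities (their sagitta stays under the surface curvature); convexity
tests use frequency 8 where dents are guaranteed.

The pin is attached at a configurable surface direction: a cylinder mesh
for rendering/occlusion, and — as sensor-visible points — only its top
face, sampled at the body's surface density and colored from a palette
whose hues stay wrap-aware ≥ 0.2 from the body hue (≈0.10, yellow-brown);
red-ish pins would collapse the color margin against a potato body and are
excluded. Pin and body colors carry small clipped HSV jitter; a matching
RGBA swatch image is generated for the reference-color path.

The RGB-D side is produced by an actual render: a per-face z-buffer
rasterizer (screen-space barycentric depth, adequate for ≈3 mm triangles)
yields the RGBA + 16-bit depth frame from a 320×240, f = 320 px top-view
camera at 420 mm — ≈1.25 mm pixel footprint, deliberately coarse like a
conveyor depth camera. Gaussian depth noise (default σ = 0.3 mm) is added
before quantization, and the partial cloud is obtained by back-projecting
the frame through the package's own `frame_to_cloud`, so the I/O path is
exercised, not mocked. The pair's ground-truth transform is the inverse of
a random rigid displacement (rotation up to a set magnitude, translation
±15 mm) applied to the canonical-frame partial cloud; magnitude 0 yields
the identity. All randomness flows through explicit seeds.

What the fixtures do *not* emulate: specular reflections, soil and
blemish texture, depth shadowing/multi-path artifacts, mask annotation
errors, and SfM reconstruction noise (the full cloud is exact up to
sampling). Passing tests therefore certify the geometry and color
*algorithms* under realistic sampling, noise and occlusion — not
robustness to real sensor pathology.

## Problem sizes and tolerances

Standard test conditions: full clouds of 20 000 points (the middle of the
10–30 k dataset range), partial clouds of ≈3–5 k points, σ = 0.3 mm depth
noise, displacements up to 30°. End-to-end recovery on 20 seeded pairs is
asserted at < 1° rotation, < 0.5 mm translation at the pin center, and
< 1.5 mm final one-way RMSD; observed worst cases run ≈0.5°, ≈0.4 mm and
≈0.8 mm. Transform validation uses 1e-6 orthonormality tolerance at
construction and 1e-9 in round-trip assertions; metric primitives are
compared with brute-force oracles to 1e-9.

## Known limitations

Single pin only (by protocol); no pin-free or non-rigid registration; no
scale estimation (both sensors are metric). The rough search assumes the
pin neighborhood is shape-distinctive — nearly rotationally symmetric
tubers yield ambiguous candidate profiles, the documented reason for
ranked candidates and operator (or auto-RMSD) selection. Mesh hole-filling
and mask refinement are upstream concerns, out of scope here.
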