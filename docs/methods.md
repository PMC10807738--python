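# Methods

This note records the measurement model, its assumptions, the parameters
that matter, and the design decisions taken where the procedure left room.

## Coordinate conventions

Images are stored top-down: x increases to the right, y downward, so
"proximal" on the tibia means decreasing y.  All landmark indices are
1-based in the public API.  Left knees are mirrored about the vertical
image midline (`x → width − 1 − x`, pixel-center convention) before any
geometry, together with the image and the wedge ROI, so a single
"lateral = +x" convention holds everywhere.  Laterality must be supplied
(configuration or DICOM tag); automatic detection from contour asymmetry is
deliberately not attempted — it is error-prone, and a loud failure is
preferable to a silently flipped knee.

## The framework

"A line touching a bone contour" is formalized as a *supporting line*: the
convex-hull edge of the region's points whose outward normal best aligns
with the requested contact direction.  Every input point then lies within
1e-6 px on one side and at least one point touches.  Ties between equally
aligned hull edges are broken by touch count, then by the first touching
point's index, so reruns are bit-identical.  Collinear regions (common,
since plateau margins are nearly straight) fall back to the line through
the two extreme points.

The corner labels are: A = lateral tibial (L3∩L1), B = medial tibial
(L3∩L4), C = lateral femoral (L2∩L1), D = medial femoral (L2∩L4).  The
assignment only affects labeling — all band fractions are symmetric.  The
outer perpendicular of each compartment sits 2/15 of AB (tibial side) or CD
(femoral side) inward from its corner; the inner perpendicular a further
3/20 of the same scale length inward.  The 3/20 offset is read as a
fraction of AB/CD, consistent with every other offset in the construction.
Tibial and femoral bands are kept as separate arc-length stations along L3
and L2 rather than projected onto a shared axis, because the two lines are
generally non-parallel — that angle is exactly the JLCA.  Perpendiculars
are stored as full lines and clipped by their consumers.

## Joint space width

The procedure fixes the *number* of circles (30) but not their placement;
15 per compartment at uniform midpoint stations
(`station_i = outer + (i + 0.5)/15 · bandwidth`) is the symmetric reading,
configurable via `n_per_compartment`.  Midpoint stations keep circles off
the band edges where clipping artifacts live.  Each circle's center is
constrained to the perpendicular of L3 at its station, so each diameter is
a local width at a defined station rather than a free 2-D maximal inscribed
circle.  Boundaries are the condyle and plateau landmark polylines clipped
to the band; when the band extends past the annotated span, the terminal
segment is extrapolated linearly and the result flagged.  Distances to
polylines are exact point-to-segment minima (no sampling).  The radius
profile along the perpendicular — the minimum of the distances to the two
polylines, with the center restricted to the gap between them — is
maximized by a 65-point coarse scan that brackets the optimum followed by
bounded scalar minimization to 1e-6 px.  The coarse scan exists because the
profile need not be strictly unimodal for arbitrary boundary shapes; the
restriction of the center to the gap is essential, since outside it the
distance to both boundaries grows without bound.  Boundaries that touch or
cross at a station yield radius 0 with a crossing flag (never a negative
width), and the affected stations are listed in the result's warnings.

The default lateral plateau range is points 20–25; the alternative 20–26
documented for the same anatomy is a configuration switch
(`lateral_plateau_range="20-26"`), and the choice is hashed into the
report.

## JLCA and eminence heights

The JLCA magnitude is the acute angle between L2 and L3
(`arccos |d₂·d₃|`).  The sign convention — positive when the joint space
narrows toward the lateral side — is this package's choice for
interpretability; the absolute value is always reported alongside.  The
clinical tibial-line variant (through landmarks 7 and 26) is a first-class
method selected by configuration, and the report names the method used;
the two agree exactly whenever points 7 and 26 lie on L3.  Eminence
heights are unsigned perpendicular point-to-line distances of landmarks 15
and 19 to L3, converted by the pixel spacing.  Because the annotation
scheme does not fix which of the two indices is the medial apex, the
medial/lateral assignment follows the canonical x position (smaller x =
medial) and the rule is recorded in the report.

## Densitometry

MONOCHROME1 DICOMs are inverted on read so "more aluminum ⇒ higher grey"
holds uniformly.  Wedge steps are segmented inside a configured ROI by
k-means (k = number of steps, fixed random state) on the 1-D profile of
column (or row) mean greys; a silhouette score below 0.5 fails the
detection with an instruction to supply a manual ROI — full-image phantom
search is out of scope.  Each step mask is eroded by a sampling margin
(default 2 px) before averaging.  Calibration knots (mean grey, known mm
Al) must increase strictly in grey — a violation signals a wrong ROI or
photometric inversion — and are interpolated piecewise-linearly with
clamped extrapolation (flagged).  Any affine grey transform applied to both
image and wedge therefore cancels exactly.

The four subchondral circles per bone–compartment group have diameter 1/20
of the bone's scale length (AB tibial, CD femoral) and centers on four
perpendiculars spaced by the same 1/20, anchored at the compartment's outer
perpendicular and marching inward — this keeps them inside the measurement
band used for JSW; the anchor is configurable.  Circles sit tangent to the
bone's joint line on the bone side (below L3, above L2).  Pixel membership
uses the center-in rule (a pixel belongs if its center lies within the
radius), so pixel counts are reproducible.  Each circle's mean grey is
mapped through the calibration, and the group value is the mean of its
four circle values.

## Agreement statistics

ICC(A,1) — two-way, absolute agreement, single measures; the conventional
choice for method comparison of individual radiographs — is computed from
the two-way ANOVA mean squares with the McGraw–Wong F-based 95% CI; the
average-measures variant is available by flag.  Two byte-identical
nonconstant columns return exactly 1.0 with a degenerate (1, 1) interval,
the analytic limit as the residual variance vanishes; constant data raises
(the ICC is undefined), never returns NaN.  Bland–Altman limits are
mean ± 1.96·SD of the paired differences; the mean absolute error is
reported with its SD.  The test suite cross-checks the ICC against both a
naive ANOVA-table oracle (to 1e-10) and `pingouin.intraclass_corr`.

## The synthetic phantom generator

Phantoms emulate the geometry and densitometry the measurements consume:
two straight bone plates whose facing edges realize a specified tibial and
femoral joint line (position + tilt), vertical shaft borders, eminence
apexes at specified perpendicular offsets, a stamped aluminum step wedge
with known thicknesses and greys, and optional seeded Gaussian noise.
Landmarks are placed analytically on the rendered edges — never re-detected
— so the geometric ground truth is float-exact; the image exists to
exercise the intensity path.  With straight plates, constant and linear gap
profiles are both realized by the two lines' offsets and tilts, and every
expected value is closed-form: the maximal circle at a station with the
center on the L3-perpendicular has diameter `2·d₀/(1 + cos φ)` where `d₀`
is the perpendicular distance from the station point to the femoral line
and `φ` the angle between the lines; the JLCA is the tilt difference; the
eminence heights are the apex offsets times the pixel spacing; the mmAl
values follow from the wedge's grey→thickness map.

Defaults represent a typical digital knee radiograph: 512×512 px at
0.2 mm/px, joint gap 10 px (2.0 mm), shaft borders 340 px apart, a 5-step
wedge of 1–5 mm Al spanning greys 4 000–20 000, and noiseless rendering
(noise is opt-in and always seeded).  The named 12-phantom suite covers
parallel and tilted joint lines, narrowed compartments, gap extremes,
eminence variants, densitometric extremes and a mirrored left knee, stored
as generator configurations only.

What the phantoms do *not* model: trabecular texture, projective blur,
beam hardening and scatter, the curved and overlapping plateau margins that
make the anterior lateral border ambiguous on real radiographs, and
annotation error beyond isotropic Gaussian jitter.  Passing the recovery
suite therefore demonstrates correctness of the geometry and calibration
pipeline, not robustness to real-world boundary ambiguity — the latter is
exactly the known failure mode of lateral/minimal JSW measurement on real
images.

## Problem sizes and numerical tolerances

The reproducibility batch uses 20 random phantoms (two identical pipeline
runs), the recovery suite the 12 named phantoms, the oracle suites 100
random convex-gap fixtures / 100 random point clouds / 50 paired samples,
and the perturbation analysis 100 jitter seeds at σ = 0.5 px — sizes chosen
so the whole suite runs in well under a minute on one core while the
statistical checks remain stable.  Recovery tolerances are ±0.05 mm for
JSW and heights, ±0.05° for JLCA, ±0.02 mmAl for intensities; the
inscribed-circle optimizer is held to 1e-3 px against a dense grid oracle
and the supporting lines to 1e-6 px side/touch constraints.  Under σ =
0.5 px landmark jitter the compartment-mean JSW and JLCA deltas center on
zero (|mean| ≤ 0.1 mm and 0.25° asserted); extremum-based quantities
(minimal JSW, eminence heights after supporting-line refitting) carry the
expected small negative bias of a minimum statistic and are not asserted
to be unbiased.

## Known limitations

- The anterior lateral plateau ambiguity of real radiographs is consumed,
  not solved: the package measures whatever border the annotation marks.
- Wedge detection assumes a roughly axis-aligned wedge inside a known ROI.
- No scatter or heel-effect correction; mmAl is an equivalence, not a bone
  mineral density estimate.
- Patellar landmarks are carried but unused; shaft-axis angles (FTA, HKA,
  mMPTA, mLDFA) are out of scope.
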