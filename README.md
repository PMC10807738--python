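# kneequant

Automated radiographic morphometry of the knee for osteoarthritis (OA)
research.  Given a weight-bearing posteroanterior knee radiograph and a
99-point bone-contour annotation (the point-list output of a statistical
shape-model annotator covering distal femur, patella and proximal tibia),
`kneequant` computes, fully automatically:

- **mean medial and lateral joint space width (JSW)** and the **minimal
  JSW** — the standard radiographic surrogates for cartilage thickness and
  OA progression;
- the **joint line convergence angle (JLCA)** between the distal femoral and
  proximal tibial joint lines — a malalignment marker;
- the **tibial eminence heights** of the two intercondylar spines;
- **subchondral bone intensities** beneath each joint surface, calibrated to
  millimetres of aluminum equivalence (**mmAl**) via the step-wedge phantom
  included in quantitative knee radiographs;

plus the **agreement statistics** used to evaluate such measurements
(two-way absolute-agreement ICC with 95% CI, Bland–Altman limits of
agreement, mean absolute error).  Because every step after annotation is
deterministic geometry, repeated runs are bit-identical — the property that
makes automated measurement attractive for large longitudinal cohorts.

## Method

All geometry happens in a canonical frame (left knees are mirrored so the
lateral compartment is on the +x side; y runs down the image).  Four
supporting lines frame the joint:

- **L1/L4** touch the lateral/medial bone contours from outside,
- **L2** touches the femoral condyles from distal,
- **L3** touches the anterior tibial plateau margins from proximal.

Corners A, B = L3 ∩ {L1, L4} and C, D = L2 ∩ {L1, L4} give the knee's own
scale lengths AB and CD.  Each compartment's measurement band lies between
an outer perpendicular placed 2/15·AB (tibial, 2/15·CD femoral) inward from
the corner and an inner perpendicular a further 3/20·AB (resp. CD) inward.

Within the bands, **30 intra-articular circles** (15 per compartment, at
uniform stations) are inscribed between the condyle and plateau margins,
each center constrained to the perpendicular of L3 at its station; circle
diameters are the local JSWs, their per-compartment means the mean JSWs,
and the global smallest diameter the minimal JSW.  The JLCA is the angle
between L2 and L3 (a clinical variant using the line through landmarks 7
and 26 is available).  Eminence heights are the perpendicular distances of
the two apex landmarks (points 15 and 19) to L3.  For densitometry, the
step wedge is segmented in its ROI, the per-step mean greys define a
monotone grey→mmAl map, and four circles of diameter AB/20 (CD/20) placed
tangent against each joint boundary on the bone side are averaged per
bone–compartment group.

A first-class synthetic phantom generator renders radiograph-like images
with straight bone plates, analytic landmarks and a stamped wedge, so every
measurement has an exact closed-form ground truth; the test suite validates
the whole pipeline against it.

## Worked example

Generate a phantom whose femoral joint line is tilted 2° against a
horizontal tibial line (so the lateral compartment narrows), then measure
it:

```bash
kneequant phantom --out demo --name tilted_femoral
cat > demo/config.json <<'EOF'
{"pixel_spacing": 0.2, "wedge_thicknesses": [1, 2, 3, 4, 5], "wedge_roi": [16, 16, 100, 60]}
EOF
kneequant measure demo/tilted_femoral.png demo/tilted_femoral.pts \
    --config demo/config.json --laterality right --out demo/report.csv
```

The report contains (values in the column headers' units):

```
mean_medial_jsw_mm:      3.491531
mean_lateral_jsw_mm:     2.106763
minimal_jsw_mm:          1.940590
minimal_jsw_compartment: lateral
jlca_deg:                2.0
eminence_medial_mm:      2.4
eminence_lateral_mm:     3.0
tibia_medial_mmal:       2.25
femur_medial_mmal:       3.25
```

The medial gap is wider than the lateral one because of the tilt; the JLCA
recovers the constructed 2° exactly (positive = narrowing toward lateral);
the minimal JSW sits in the narrowed lateral compartment; and the bone
greys map through the wedge calibration to 2.25/3.25 mmAl.  All values
match the phantom's closed-form ground truth in
`demo/tilted_femoral.truth.json`.  `kneequant agree run1.csv run2.csv`
computes per-parameter ICC/Bland–Altman tables between two report files,
and `kneequant overlay` renders the framework and circles for debugging.

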