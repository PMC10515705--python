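# Methods

## Geometric model

Each radiographic view is a continuous 2-D plane in which the femoral
head is modelled as a circle (centre, radius), the femoral neck central
axis as a line (point + medially pointing unit direction), and the lag
screw as a ray from its tip along a medially pointing unit direction.
The canonical orientation is *medial = +x*; +y is superior in the AP
view and anterior in the lateral view.  Input files carry a hip-side
column and right-sided rows are mirrored (x and x-components negated)
at read time, so the geometry code never sees orientation ambiguity.

**Apex.**  The head apex is defined as the medial intersection of the
neck central axis with the head circle.  The clinical literature leaves
the apex construction implicit; the circle model is the natural reading
of the standard tip–apex technique and has the property that a screw
lying exactly on the neck axis has its far-surface point B coincide
with the apex C, which is precisely the "central screw: only one
distance" degenerate case of the modified TAD.

**Calibration.**  Radiograph coordinates are arbitrary image units with
unknown per-view magnification.  Every view carries the measured
on-image lag-screw diameter; the scale `true_diameter / measured`
(default true diameter 12.5 mm, a standard DHS lag screw) converts
in-view distances to millimetres.  AP and lateral views are calibrated
independently — radiographic magnification differs between projections
— which is what makes the two-term TAD sum meaningful.

## The modified TAD

In the AP view, with A the screw tip, B the far intersection of the
screw axis with the head circle and C the apex:

* `AB` = signed distance from A to B along the screw axis.  It is
  positive for any intact placement; a negative value means the tip
  lies beyond the head surface.  Such penetrating screws are flagged,
  not rejected: they are clinically real and the score remains defined.
* `BC` = straight-line chord from B to C (distances are ruler
  measurements on a radiograph, so a chord, not an arc).
* `sign(BC)` = +1 if B is superior to the neck central axis, −1 if
  inferior, 0 if within 1e−6 mm of it (an exact-arithmetic guard; at
  annotation precision the distinction below a micrometre is
  meaningless).

`mTAD = scale_AP · (AB + sign·BC) + TAD_LAT`, where `TAD_LAT` is the
ordinary calibrated lateral tip–apex distance.  The construction is
exactly antisymmetric: mirroring the AP screw across the neck axis
preserves AB and BC and flips the sign, so
`mTAD_superior − mTAD_inferior = 2·BC`.

## Comparator parameters

* **Cal TAD** — AP term measured from the tip to the intersection of
  the calcar-referenced axis (line through the annotated calcar point,
  parallel to the neck axis) with the head circle; lateral term
  unchanged.  Missing calcar annotation makes only this metric
  unavailable.
* **Parker's ratio** — the screw axis crossing of the head-circle
  diameter perpendicular to the neck axis, as a percentage from the
  inferior (AP) / anterior (LAT) end.  The original description
  (head vs neck width) is ambiguous in the secondary literature; the
  head-diameter chord is used here and the choice is isolated in one
  function so it can be swapped.  Values outside [0, 100] (axis
  crossing beyond the head) are returned and flagged rather than
  clamped.
* **Cleveland zone** — tip offsets from the neck axis are banded into
  equal thirds of the head radius per view (superior/central/inferior
  × anterior/central/posterior); `zone = 3·(row−1) + col` with zone 1
  superior-anterior.  This numbering puts the classically safe zones at
  {5, 6, 8, 9} (central-central, central-posterior, inferior-central,
  inferior-posterior).  A tip outside the head circle raises an error
  that still reports the nearest zone as a diagnostic.
* **ABA** — signed angle between neck-axis and screw-axis directions in
  the AP view, negated so that superior deviation is negative; the
  safety rule `ABA > −10°` then reads "no more than 10° of superior
  deviation".

Reported tables round millimetres, degrees and percentages to one
decimal and AUC to three; all internal values are full precision.

## Synthetic cohorts

No public landmark set exists for this problem, so the simulator
generates one in true millimetres and then *projects* it to image
units, exercising the calibration path end to end.

Per case (all defaults chosen to emulate an elderly DHS cohort):

| quantity | distribution (default) | rationale |
|---|---|---|
| head radius | Normal(23, 2) mm, floor 16 | adult femoral head ~44–48 mm diameter |
| AP screw offset at the centre chord | Normal(−1, 4) mm, clipped to ±0.7·r | surgeons aim central/slightly inferior |
| AP screw angle to neck axis | Normal(0, 6)°, clipped ±25° | guide-wire scatter |
| LAT offset / angle | Normal(0, 4) mm / Normal(0, 6)° | central aim in the lateral |
| tip-to-surface gap | LogNormal(median 9 mm, σ 0.45), shared between views ±10% | gives an mTAD distribution centred ~20 mm with a realistic 15–30 mm bulk and tail |
| per-view magnification | Uniform(1.05, 1.25) | intra-operative image intensifier |
| AO/OTA pattern | A1.2/A1.3/A2.2/A2.3 = .514/.257/.165/.064 | published cohort prevalences |
| reduction quality | Good/Acceptable/Poor = .532/.422/.046 | published cohort prevalences |
| Singh index | grades 1–6, ~80% in 3–4 | elderly osteoporotic cohort |

The screw axis intersects the head circle by construction (offset
< 0.7·radius), so every record is measurable; rarely the sampled gap
exceeds the chord length and the tip falls short of the head, which
makes only the Cleveland zone unavailable — exactly as in real data.

**Outcome models.**  Cut-out is Bernoulli with probability from a
pluggable risk model on the *latent true mTAD* (computed in closed form
from the un-magnified geometry; a test asserts it agrees with the
metric recomputed through the full landmark path to 1e−6 mm):

* `LogisticOutcomeModel` (default):
  `logit p = −3.4 + 0.25·(mTAD − 25) + pattern effect + reduction effect`,
  calibrated once so the marginal cut-out rate is ~12% and the
  population AUC of the mTAD is ~0.93, matching the qualitative
  associations reported clinically (risk rising with mTAD, unstable
  pattern and poor reduction).  `LogisticOutcomeModel.mtad_only()` is
  the covariate-free variant with slope 0.18 and intercept −2.6, whose
  population AUC is ~0.90 — the canonical condition for AUC-recovery
  checks.
* `StepOutcomeModel`: risk jumps 0.03 → 0.40 at mTAD = 25 mm, giving
  cut-off-recovery tests a known threshold to find.

Effect sizes are not estimable from published summary tables, so these
coefficients are the package's own calibration and are documented as
such.

Randomness: each case draws from a counter-derived substream
(`seed`, case index), so record *i* is byte-identical whatever the
cohort size; `sample_latent_risk` replays the same substreams without
building landmark objects for large-n population summaries.

**What the simulator does not emulate:** AP and lateral projections are
sampled as correlated 2-D views, not as consistent projections of one
3-D screw; landmark annotation noise is zero by default (geometry is
exact); cut-out timing, revision surgery and mortality are out of
scope.  Passing recovery tests therefore show that the pipeline is
correct and well calibrated under the stated generative model — not
that the clinical effect sizes are right.

## Statistics

* **AUC** is computed by the Mann–Whitney pair-ordering formula via
  midranks; a property test pins it to brute-force pair counting
  (1e−12) and to the trapezoidal area under the empirical ROC (curve
  points from scikit-learn).
* **CI** by DeLong's structural-components variance with a normal
  interval, clipped to [0, 1].  (Published tables in this literature
  sometimes show upper bounds above 1, indicating unclipped Wald
  intervals; that artefact is deliberately not reproduced.)
* **Cut-off** by the Youden index over midpoints between adjacent
  distinct observed values, ties broken toward higher specificity; the
  risk direction is fixed per parameter (higher TAD/Cal TAD/mTAD/
  Parker-AP = risk, lower ABA = risk) with an auto-orientation fallback.
  A "clinical" integer-mm cut-off is reported alongside the exact one,
  since published recommendations are integers.  All-tied scores yield
  J = 0 and are flagged degenerate.
* **Association tests**: Pearson chi-square (no continuity correction);
  when any expected count is below 5 the test switches to the exact
  conditional (Fisher) test — complete enumeration over fixed-margin
  r×2 tables in log-space, enumerating the smaller column margin, with
  a 5·10⁶-table feasibility guard (beyond it the Pearson p is reported
  and labelled).  2×2 enumeration is cross-checked against
  `scipy.stats.fisher_exact` in tests.
* **Group comparisons**: two-sided Mann–Whitney U, exact enumeration
  for combined n ≤ 20 without ties, tie-corrected normal approximation
  otherwise.
* **No multiplicity correction** is applied; every p-value is a
  univariate per-test value, as is conventional in this reporting
  format.
* Percentages are rounded half-up to one decimal (so 4/7 → 57.1).

`ThresholdRiskClassifier` wraps the orientation + Youden cut-off as a
scikit-learn binary classifier (`fit`/`predict`, `cutoff_`,
`direction_`, `auc_` fitted attributes) so the cut-off rule can be
cross-validated or embedded in pipelines.

## Problem sizes and tolerances

Geometric identity suites run on 1,000 simulated geometries at 1e−9 mm;
the analytic circle–line intersection is checked against numeric
root-bracketing at 1e−6 on 1,000 instances.  Recovery checks use
cohorts of n = 5,000 (cut-off within ±2 mm of a true 25 mm step; AUC
within 0.03 of the population value computed by probability-weighted
pair counting over n = 60,000 latent draws).  Calibration checks use
2,000 null contingency tables (type-I error 5% ± 1.5%) and 500 DeLong
replicates (coverage 92–98%).  These sizes keep the whole suite around
half a minute while leaving Monte-Carlo noise well inside the asserted
bands.

## Known limitations

* Landmarks are assumed annotated; no image processing.
* The head-circle model cannot represent aspherical heads or
  osteophytes; Parker's chord choice and the Cleveland banding are
  reconstructions of ambiguously specified originals, each isolated
  behind a single function.
* Exact association testing is implemented for r×2 tables only; larger
  sparse tables fall back to the Pearson p with an explicit method
  label.
* Only univariate discrimination is analysed; no multivariable or
  survival modelling.
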