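# tipapex

Lag-screw position metrics and cut-out risk analysis for trochanteric
hip fractures fixed with a dynamic hip screw (DHS).

Lag-screw *cut-out* — migration of the screw through the femoral head —
is the dominant mechanical failure after DHS fixation, and the position
of the screw within the head is its strongest modifiable predictor.
`tipapex` measures the six radiographic position parameters used in
this literature from paired AP/lateral landmark annotations:

* **TAD** (tip–apex distance, Baumgaertner):
  `TAD = d(tip, apex)_AP + d(tip, apex)_LAT`, each term calibrated in
  its own view against the known lag-screw diameter (12.5 mm);
* **Cal TAD**: the AP reference axis moved inferiorly to the calcar;
* **modified TAD (mTAD)**: `mTAD = (AB ± BC)_AP + TAD_LAT`, where A is
  the screw tip, B the far head-surface point along the screw axis, C
  the head apex, and BC is **added** for superior screws and
  **subtracted** for inferior ones — so the score encodes insertion
  depth *and* direction (a central screw has B = C and mTAD = TAD);
* **Parker's ratio** (AP/LAT), **Cleveland zone** (3×3 grid of the
  tip position) and the **axis–blade angle** (ABA, signed AP angle
  between neck axis and screw axis, negative = superior deviation).

Around the measurements it provides a synthetic-cohort simulator (hip
geometry, per-view magnification, covariates, and cut-out outcomes from
a latent mechanical-risk model on the true mTAD) and the evaluation
pipeline: Mann–Whitney AUC with DeLong confidence intervals, Youden
cut-off selection, chi-square/exact association tests, and per-case
placement-safety flags (TAD < 25 mm, mTAD ≤ 25 mm, ABA > −10°, safe
Cleveland zones {5, 6, 8, 9}).

It is intended for orthopaedic outcome researchers comparing placement
scores, and for methodologists who need a fully simulatable test bed
for cut-off selection pipelines.

## Worked example

A head circle of radius 22 units centred at the origin, neck axis along
+x, a superior screw with tip (12, 5) parallel to the neck axis, and a
central lateral screw with tip (12, 0):

```python
from tipapex import generate_worked_example, compute_all_metrics

case = generate_worked_example()
m = compute_all_metrics(case)
print(f"TAD      {m.tad_mm:6.1f} mm")
print(f"Cal TAD  {m.cal_tad_mm:6.1f} mm")
print(f"mTAD     {m.mtad_mm:6.1f} mm  (AB {m.ab_ap_mm:.1f} + BC {m.bc_sign:+d}*{m.bc_ap_mm:.1f} + LAT)")
print(f"Parker AP {m.parker_ap_pct:.1f}%  LAT {m.parker_lat_pct:.1f}%")
print(f"Cleveland zone {m.cleveland_zone}   ABA {m.aba_deg:.1f} deg")
```

prints

```
TAD        21.2 mm
Cal TAD    30.4 mm
mTAD       24.5 mm  (AB 9.4 + BC +1*5.0 + LAT)
Parker AP 61.4%  LAT 50.0%
Cleveland zone 5   ABA -0.0 deg
```

The screw sits 5 units superior to the neck axis, so the AP net
distance is AB + BC = 9.4 + 5.0 = 14.5 mm and the mTAD (24.5 mm) is
*larger* than the TAD (21.2 mm): the superior direction is penalised.
Mirroring the same screw inferiorly would give AB − BC = 4.4 mm and an
mTAD of 14.4 mm — same depth, opposite direction, lower score.

## Command line

```sh
tipapex simulate --seed 5 --n-cases 200 --out cohort/
tipapex measure  --landmarks cohort/landmarks.csv --out metrics.csv
tipapex evaluate --metrics metrics.csv --outcomes cohort/outcomes.csv --out report/
tipapex flags    --metrics metrics.csv --out flags.csv
```

`evaluate` writes one ROC row per parameter (AUC, DeLong 95% CI,
Mann–Whitney p, Youden cut-off with sensitivity/specificity) plus
categorical association and proportion tables.

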