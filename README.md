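# cryoplan

Adaptive needle-placement planning for MRI-guided focal cryoablation of
prostate cancer.

Focal cryoablation destroys a localized tumor by freezing it through
transperineal cryo-needles guided by a template grid. Success hinges on
the iceball covering the tumor with an adequate ablation margin (≥ 5 mm is
the common guideline), but needles deflect on their way through tissue, so
physicians adjust subsequent insertions from experience. `cryoplan`
computes that adjustment: given the tumor segmentation, the template
geometry, and the observed placement of the needle(s) already inserted, it
recommends the template hole and depth for the next needle.

It is written for researchers building or evaluating intra-procedural
planning tools: everything runs on label volumes (NRRD/NIfTI), needle
coordinates in millimeters, and plain JSON/CSV, and a synthetic phantom
module generates a complete test scene so no clinical data is needed.

## Method

Planning is a two-stage search over all legal candidate placements —
template holes whose in-plane distance to every placed needle lies in
[10, 20] mm, each at seven depths (0, ±5, ±10, ±15 mm relative to the
first needle).

**Stage 1 (fast ranking).** Each candidate is scored by the overlap of the
tumor *V*<sub>T</sub> with (a) a geometric iceball *V*<sub>Geo</sub> built
from vendor-chart 0 °C isotherm ellipsoids around the prospective needle
set, and (b) the 95 % needle-deflection confidence ellipsoid
*V*<sub>C,Nn</sub> centered on the candidate and aligned with the observed
deflection of the first insertion:

&nbsp;&nbsp;O<sub>S2</sub> = W₁·|V<sub>Geo</sub> ∩ V<sub>T</sub>|/|V<sub>T</sub>| + W₂·|V<sub>C,N2</sub> ∩ V<sub>T</sub>|/|V<sub>T</sub>|

(for a third needle the two ellipsoid terms are averaged). The deflection
ellipsoid comes from a multivariate Gaussian fitted to a table of historic
deflection vectors (|d| ≤ 15 mm retained), with semi-axes
√(χ²₃(0.95)·λᵢ) along the covariance eigenvectors.

**Stage 2 (precise scoring).** The five best candidates are re-evaluated
with a volumetric iceball predictor *V*<sub>AI</sub> — a pluggable
component; the bundled deterministic surrogate models per-needle
isotherms, freezing synergy between nearby needles, and the urethral
warmer's heat sink — and scored by

&nbsp;&nbsp;M = min { d(p,q) : p ∈ ∂V<sub>AI</sub>, q ∈ ∂V<sub>T</sub> } (signed: negative if tumor is uncovered)
&nbsp;&nbsp;P<sub>S</sub> = W₁·|V<sub>AI</sub> ∩ V<sub>T</sub>|/|V<sub>T</sub>| + W₂·clamp(M, 0, 10)/10

The candidate with the highest P<sub>S</sub> is suggested (both, on an
exact tie), together with the depth offset for the *first* needle that
maximizes P<sub>S</sub> with the new placement held fixed. W₁ = W₂ = 0.5
by default, weighing tumor coverage and margin/uncertainty equally.

## Worked example

```sh
cryoplan simulate --seed 1 --out demo
cryoplan fit-deflection --deflections demo/deflections.csv --out demo/model.json
cryoplan plan --tumor demo/tumor.nrrd --needles demo/needles.csv \
    --template demo/template.json --deflection-model demo/model.json \
    --urethra demo/urethra.nrrd --out demo/plan.json
```

`simulate` writes a 64³ phantom (prostate, a 12×10×10 mm posterior tumor,
urethra, pseudo-MR), a 13×13 template with 5 mm pitch, a table of 205
synthetic deflection vectors, and the first needle's intended/achieved
poses. `fit-deflection` reports `kept 205 of 205 deflection vectors
(|d| <= 15 mm)` and stores the Gaussian model. `plan` then prints

```
INFO cryoplan: suggestion: hole (8, 4), depth offset +0 mm, P_S=0.5000, M=0.00 mm
```

and `demo/plan.json` contains two tied suggestions (hole (8,4) at depth
offsets 0 and +5 mm, both P_S = 0.5) plus
`"needle1_depth_adjustment_mm": 0.0`. Read: placing needle 2 in hole (8,4),
14.0 mm from needle 1, just covers the tumor (coverage 1.0, minimum
margin 0.0 mm, hence P_S = 0.5·1.0 + 0.5·0.0); the first needle's depth
needs no correction. The `audit` array holds the overlap score of all 252
evaluated candidates. `cryoplan evaluate` computes margin, Dice and
Hausdorff metrics for any iceball/tumor pair and can export the
tumor-surface margin heatmap as CSV and PNG.

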