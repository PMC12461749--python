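# Methods

This note records the models implemented in `cryoplan`, the defaults and
their rationale, the numerical conventions, and what the synthetic test
surface does and does not demonstrate.

## Coordinate and voxel conventions

All coordinates are physical-space millimeters in RAS. NRRD and NIfTI are
read and written through SimpleITK; since SimpleITK's world frame is LPS,
the first two world axes are negated at the IO boundary, so the rest of
the package never sees a second convention. A voxel (i, j, k) has its
center at `origin + directions @ (spacing * (i, j, k))`; every geometric
membership test in the package (ellipsoid rasterization, needle marking,
overlap counting) is a voxel-center test with no partial-volume
weighting. This makes rasterization exactly checkable against analytic
point-in-shape oracles; its volume error at 1 mm spacing is under 2 % for
the default isotherm ellipsoid and halves with each spacing refinement.

Distances are always computed in mm via the exact Euclidean distance
transform with the grid spacing as sampling — doubling the spacing of the
same voxel data doubles every reported margin, which the suite asserts.

## Needle-deflection model

Deflection vectors (achieved minus intended tip) are filtered to
|d| ≤ 15 mm — the boundary is kept, reading "exceeding 15 mm" literally —
and fitted with the arithmetic mean and the *unbiased* (n−1) sample
covariance (the estimator choice is not dictated by anything upstream;
unbiased is the conventional default). The 95 % confidence ellipsoid uses
the χ²(3 dof) quantile: semi-axis i = √(q·λᵢ) along eigenvector i, the
standard confidence region of a trivariate Gaussian. A rank-deficient fit
is flagged and its zero eigenvalues floored at 10⁻⁶ mm² so a degenerate
sample still yields a usable sliver ellipsoid; an all-zero covariance is
an error.

When the ellipsoid is placed on a candidate location, only the covariance
*shape* is used (zero mean): a systematic mean deflection is treated as a
correctable aiming bias, not as placement spread. Its orientation is the
minimal rotation carrying the fitted major axis onto the observed
deflection direction of the first insertion; for a third needle, onto the
mean of the first two deflections (the orientation rule is only defined
upstream for the second needle; the mean is this package's choice). A
zero observed deflection falls back to template-axis alignment with a
warning.

Axis-length convention: the package always reports *semi*-axes.

## Iceball models

**Geometric model.** Isotherm dimensions are configuration
(`IsothermSpec`), not constants: the defaults — single needle 30 × 16 mm
with the ellipsoid center 5 mm proximal to the tip, merged two-needle
35 × 24 mm — are documented placeholders shaped like vendor planning-chart
isotherms and should be overridden with the chart values for the needle
in use. One or three needles give a union of per-needle ellipsoids, each
with its major axis along its needle; exactly two needles give the single
merged ellipsoid centered (tip-offset proximally) on the tip midpoint
with its major axis along the mean insertion axis. The midpoint/mean-axis
placement rule and the decision to apply the tip offset to the midpoint
are this package's choices; the merged-ellipsoid concept itself offers no
placement rule.

**Volumetric predictor.** The planner only assumes a contract: input is
the planning image with the distal 15 mm of each needle burned in at a
constant value strictly outside the intensity range; output is a binary
isotherm mask on the same grid. Predictors register by name, so a trained
network can be dropped in externally. The bundled `surrogate` predictor
is a deterministic analytic stand-in: per-needle geometric ellipsoids,
morphologically closed with a 3 mm ball when any two tips are within
20 mm (freezing synergy), minus all voxels within 4 mm of a supplied
urethra mask (the warmer catheter's heat sink). The synergy and carve
radii are configurable; they encode the qualitative effects a learned
model would capture, at magnitudes chosen to be plausible rather than
fitted to anything.

## Margin and agreement metrics

The minimum ablation margin M is the smallest Euclidean distance between
the iceball boundary and the tumor boundary. As a pure set distance this
is non-negative even when the iceball misses the tumor, so the default is
*signed*: when any tumor voxel is uncovered, M is the negated maximum
distance from an uncovered tumor voxel to the iceball boundary (a
penetration deficit). The literal unsigned value is available via
`signed=False`. Boundaries are foreground voxels with a six-connected
background neighbor (volume edges count as boundary); the "percentage of
margin above threshold" is the fraction of tumor *surface* voxels with
signed margin ≥ threshold (a surface-based rather than volume-based
reading; the margin is a surface quantity). Dice is plain voxel counting;
Hausdorff is the max of the two directed maximum boundary distances. All
of these match exhaustive boundary-pair brute force exactly on test
grids. The tumor-surface margin field that feeds the heatmap export is
the same signed quantity, so the heatmap minimum and M agree to within a
voxel diagonal by construction.

## Planner

Candidates are holes whose in-plane distance — measured perpendicular to
the template insertion axis, i.e. at tip depth — to *every* placed needle
lies inclusively in [10, 20] mm, each at depth offsets
{0, ±5, ±10, ±15} mm relative to the first needle's depth (seven planes).
Stage-1 overlap scores are computed by evaluating ellipsoid membership at
tumor voxel centers directly, which is exactly equivalent to rasterizing
and intersecting (rasterization *is* voxel-center membership) and avoids
a full-grid rasterization per candidate. The geometric term uses the full
prospective needle set (placed needles plus the candidate), not the
candidate alone.

Printed as volume intersections plus a millimeter margin, the two score
equations would mix units; all intersection terms are therefore
normalized by tumor volume and the margin is clamped to [0, cap] and
divided by the cap (default 10 mm), so W₁ = W₂ = 0.5 weighs two
dimensionless [0, 1] quantities. The raw-unit variant remains available
via `normalize_scores=false`.

The shortlist keeps the five highest overlap scores; ties are ordered
deterministically by smaller |depth offset|, then smaller in-plane
distance, then hole index, and candidates indistinguishable from the cut
on score, |depth offset| and in-plane distance are all retained — hole
index orders but never severs a tie, so mirror-symmetric candidates
survive together. Two final suggestions are emitted only on an exact
performance-score tie (|ΔP_S| ≤ 10⁻⁹; floating-point equality needs a
stated epsilon). The first-needle depth adjustment is greedy: chosen
after fixing the next-needle suggestion, by sweeping the seven offsets
and keeping the best (smallest |offset| on ties). With the shortlist
widened to all candidates the recommendation provably equals the
exhaustive argmax, which the suite checks on a 32³ phantom.

## Synthetic phantom

The generator emulates only what the planner consumes: nested analytic
shapes (prostate ellipsoid 48 × 44 × 44 mm; a 12 × 10 × 10 mm posterior
peripheral-zone tumor, the typical two-needle indication, placed clear of
the urethra; a 2.5 mm-radius straight urethra), a 13 × 13, 5 mm-pitch
template facing +S, a pseudo-MR with per-tissue intensities, a mild
axial gradient and Gaussian noise, and deflection samples drawn from a
Gaussian whose 95 % ellipsoid has semi-axes ≈ 7.5, 6.4, 1.0 mm with a
small (0.5, 1.0, 1.5) mm systematic bias — dispersion of the magnitude
reported for transperineal insertions. One integer seed drives all
randomness.

What passing tests on this phantom do *not* show: performance on real
anatomy (deformable tissue, irregular tumors, MR artifacts), the accuracy
of any real iceball predictor (the surrogate is analytic by
construction), or clinical margin statistics. They do show that the
optimization machinery is correct: scores computed as specified, the
recommendation optimal for the supplied models, metrics exact against
brute force, and the whole pipeline deterministic per seed.

## Problem sizes and numerical choices

Test and acceptance runs use 24³–64³ grids at 1–3 mm spacing — small
enough for exhaustive pairwise-distance oracles and full-candidate
brute-force planning to serve as references, while the 280-candidate
reference lattice is the same size the default template and annulus
produce. Tolerances: orthonormality 10⁻⁶, unit axes 10⁻⁹, score ties
10⁻⁹; margins are quoted to within half a voxel diagonal of analytic
values, the intrinsic quantization of voxel-center geometry.

## Known limitations

More than three needles is rejected (the models are defined for one to
three). The geometric model ignores needle synergy and heat sinks; the
surrogate encodes them only qualitatively. The planner optimizes one
needle at a time (greedy, matching the intra-procedural workflow) and
does not re-optimize during freezing. Registration of the template to
the scanner, DICOM ingestion, and MR intensity processing are out of
scope.
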