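# Methods

`sichpipe` re-implements, as a tested pipeline, the quantitative chain of
a pilot severity analysis in spontaneous intracerebral hemorrhage (sICH):
CT-based hematoma/edema volumetry, circularity-based scoring of
NET-forming neutrophils on blood smears, flow-cytometry quadrant counting
of the DEspR+CD11b+ ("rogue") neutrophil subset, and the rank-correlation
statistics that relate these markers to clinical severity. This note
records the models, the parameters that matter, and the choices made
where the procedure left room.

## Cohort table

The unit of analysis is a 13-patient table with, per patient: index ICH
score (0–6), same-day Glasgow Coma Scale (3–15), 90-day modified Rankin
Scale (0–6), intraparenchymal hemorrhage (IPH) and perihematomal edema
(PHE) volumes in ml, modified Graeb score (0–32), neutrophil-to-lymphocyte
ratio (NLR), and absolute DEspR+CD11b+ and NET-forming neutrophil counts
in cells/μl. Validation enforces the scale bounds and sign constraints at
load time; empty cells are explicit missing values. Derived flags:
`survivor` (no recorded death day), `ivh` (modified Graeb score > 0 — the
only intraventricular-hemorrhage indicator the table carries), `cmo`
(comfort-measures-only day present). Counts convert to K/μl by an exact
factor of 1000; Tables of composite markers use that scale (below).

## ABC/2 volumetry

The bedside estimate models the lesion as an ellipsoid: on the axial
slice with the largest lesion cross-section the rater measures the
longest in-plane diameter A (cm) and the widest diameter B orthogonal to
it; C is the craniocaudal extent. Volume = A·B·C/2 — the /2 is the
ellipsoid correction (π/6 ≈ 1/2 of the bounding box). C is implemented
as a length, eligible-slice count × slice thickness (default 0.5 cm),
because the ellipsoid correction only makes dimensional sense when all
three factors are lengths. A slice is *eligible* when its lesion area is
at least 25% of the reference (largest) slice's area; the denominator of
that rule is a parameter since conventions vary. Ties for the reference
slice break to the lowest index. PHE volume is the edema-extent ABC/2
minus the hematoma volume, clamped at zero with the clamp flagged.

A systematic property of the eligibility rule worth knowing: for an
ellipsoid, slices above 25% of the central area span only √0.75 ≈ 0.87
of the axis, so at fine slice spacing the rule truncates C and biases
the estimate low. At the protocol's 0.5 cm slices the coarse
quantization of the slice count largely offsets this; recovery tests use
0.5 cm slices for that reason.

## Dual-clustering CT segmentation

Each voxel is tested twice: its HU value must fall in a tissue window,
and at least a fraction (default 0.5) of its 26-neighborhood (radius 1)
must fall in the window too — suppressing isolated noise voxels.
Survivors are grouped into connected components (26-connectivity
default); components smaller than `min_cluster_voxels` or with mean HU
below `intensity_floor` are discarded. At the grid edge the neighbor
fraction is taken over the neighbors that exist, so a uniform in-window
volume maps to itself.

Stage order: brain is extracted with a soft-tissue window ([0, 80] HU
default) plus a largest-component rule, which removes skull (~1000 HU)
and air; hemorrhage is segmented inside the brain with a blood window
([45, 90] HU default); the edema candidate region is built by dilating
the hemorrhage mask (6-connected structuring element, default limit 10
iterations), subtracting the core and clipping to brain, then
re-segmenting that ring with an edema window ([5, 23] HU default,
neighbor fraction 0.3 because the ring is thin). All windows are
configuration, not constants: the source procedure describes them only
as user-defined. Mask invariants (hemorrhage ⊆ brain, edema ⊆ brain,
hemorrhage ∩ edema = ∅) are asserted on every pipeline output. Volumes
are voxel counts × voxel volume, in ml.

## NET circularity scoring

Nuclei are segmented on the DAPI channel (Otsu threshold per field by
default, hole filling, 8-connectivity, minimum area 20 μm²). Each
nucleus is scored with the circularity index

    circularity = 4π · (area of minimum enclosing circle) / perimeter²

where the perimeter traces the DNA outline *including extrusions* and
the enclosing circle covers the whole object. For a compact disk the
index is 1; extruded DNA inflates the perimeter quadratically and drives
the index down. Nuclei below 0.8 are NET-positive; 0.8 exactly is
negative. Because the enclosing-circle area is at least the pixel area,
discretization can push a rough disk nominally above 1; values are
clamped at 1.0 and the clamp recorded.

The minimum enclosing circle is computed exactly on the pixel centers
(shapely's minimum bounding circle) plus a half-pixel pad. The perimeter
estimator is a subpixel traced contour (marching squares at the 0.5
level), chosen over the Crofton multi-direction estimator after
measuring both on rasterized phantoms: on spiky (extruded) shapes the
Crofton-based index drifted by ~0.05 under a doubling of resolution at
the working scale and sat ~0.10 above the closed-form value, while the
traced contour converges faster and keeps the index scale-stable within
0.03. Crofton remains available (`perimeter_method="crofton"`).

Marker positivity is the conjunction of mean CD11b and mean DEspR
intensity over the nucleus pixels exceeding per-channel backgrounds
(default: mean + 3·sd of the cell-free region of the same field). A
whole slide is scored by aggregating fields (protocol: 100 evenly spaced
positions); the NET fraction is computed among DEspR+CD11b+ nuclei.
Conversion of fractions to cells/μl requires an external anchor
neutrophil concentration, always an explicit input — the pipeline never
infers it.

## Flow-cytometry quadrant gating

Events carry forward scatter, side scatter and two fluorescence channels
(DEspR, CD11b). The neutrophil cloud is selected with a polygon gate on
the scatter plane (boundary inclusive); positivity thresholds per
channel are a high quantile (default 0.999) of the isotype control's
fluorescence (FMO controls selectable); quadrants use strict inequality
above threshold, so Q2 (double positive) = DEspR > t₁ and CD11b > t₂.
The quadrant partition is exhaustive and exclusive by construction.
No compensation/spillover model is applied; synthetic channels are
generated pre-compensated. Absolute Q2 concentration again requires an
explicit anchor concentration.

## Severity statistics

All rank statistics use midranks for ties and define Spearman's r as the
Pearson correlation of the rank vectors — with the heavily tied clinical
scores this is the convention standard packages print, and it differs
from the tie-free 1 − 6Σd²/(n³−n) shortcut (the two agree exactly on
tie-free data, which is tested). Two-sided p-values come from the
t transform t = r·√((n−2)/(1−r²)) on n−2 df, or from exact permutation
enumeration for n ≤ 8 (seeded Monte-Carlo above). Bonferroni correction
is min(1, m·p) with the family size m explicit configuration: the family
sizes behind any given published corrected p are generally not
recoverable, so corrected p-values are report output, never a
reproduction surface. Power at an observed |r| uses the Fisher-z normal
approximation Φ(√(n−3)·atanh|r| − z₁₋α/₂), ignoring the negligible
opposite tail; at ρ = 0.71, n = 13, α = 0.05 this gives 0.801, the basis
of the "strong marker" screen (|r| > 0.7, power > 0.8, corrected
p < α).

Group comparisons use the two-tailed Mann–Whitney test: exact two-sided
p by enumeration over all C(n₁+n₂, n₁) assignments when n₁+n₂ ≤ 12 and
the data are tie-free, otherwise a normal approximation with tie and
continuity corrections. Hedges' g offers the standard J factor
1 − 3/(4(n₁+n₂) − 9) and a flat fixed-percent mode (default 4%)
sometimes quoted for n < 20; the two differ materially at n ≈ 13
(J ≈ 0.94), so the mode is explicit.

Composite severity markers are per-patient arithmetic sums of raw
component values with neutrophil counts on the K/μl scale. The scale
convention is fixed because it is the one under which the composite
correlations against 90-day mRS reproduce the published combinatorial
values to all three printed decimals (sums with counts in cells/μl
reduce the composite to the dominant count and do not).

## Synthetic data

The generators provide ground truth for the stages whose original inputs
(images, event files) are not published. Each is a pure function of its
spec, seed included.

* **CT phantom** — ellipsoidal brain (default semi-axes 34/42/42 mm)
  inside a 4 mm skull shell at 1000 HU, air at −1000 HU; ellipsoidal
  hematoma (default 10/12/14 mm semi-axes, 60 HU) with a 6 mm edema
  shell at 15 HU, brain tissue at 30 HU, additive Gaussian noise
  (default sd 3 HU, tested to 5 HU — the plausible range for modern CT).
  All compartment volumes are closed-form ellipsoid/shell volumes; the
  voxelized masks agree with them within a one-voxel surface shell.
  What this phantom does *not* model: partial-volume effects, beam
  hardening, anatomical texture, irregular lesion shape — so passing
  recovery tests demonstrate the algorithm's correctness on its stated
  model, not clinical accuracy.
* **Smears** — round nuclei are disks (radius 5 μm — a realistic
  neutrophil nucleus — at 0.25 μm/px); NET-like nuclei are alternating-
  radius star polygons whose outer radius fixes the enclosing circle and
  whose inner radius is solved in closed form to hit a requested
  analytic circularity (default 0.6, the moderate-extrusion morphology
  class). Cells sit on a jittered grid so they never overlap; marker
  channels are painted over double-positive cells. Real NET morphology
  (diffuse chromatin clouds, RBC-adherent DNA) is not modeled.
* **Flow events** — Gaussian scatter clouds for neutrophils, monocytes
  and lymphocytes, separated by ≥3 sd so the default polygon gate is
  effectively pure (the structure a scatter gate assumes); lognormal
  fluorescence background with a planted double-positive fraction among
  neutrophils shifted 3.5 log-units up, cleanly above the 99.9% isotype
  quantile, which is available in closed form for testing.
* **Cohorts** — Gaussian copula: the target Spearman matrix is converted
  to the latent Pearson scale with the exact relation
  ρ_P = 2 sin(πρ_S/6) (so tests must not convert again), a latent normal
  draw is pushed through Φ, and configurable marginal families (defaults
  lognormal for volumes/counts/NLR, uniform for bounded scores) are
  applied by inverse CDF. Rounding scores to integers is available but
  introduces ties that pull empirical rank correlations slightly toward
  zero; recovery tests therefore use continuous columns.

## Problem sizes and numerical choices

Default test/validation sizes: 80×96×96 phantom voxels at 1 mm³, six
512×512 smear fields, 50,000 stained flow events + 20,000 isotype
events, n = 2000 copula cohorts — sizes at which binomial/sampling error
is comfortably inside the asserted tolerances. Report rounding is
half-even at the printed precision. Degenerate inputs fail loudly:
empty lesion masks, all-air volumes, constant statistical vectors,
zero-perimeter objects and empty gated tables each raise a typed error
rather than returning a silent zero.

## Known limitations

The published per-patient table fixes fewer significant digits than the
raw measurements had; reproduced correlations are exact because ranks,
not magnitudes, enter them. The Bonferroni family sizes and the
fraction-to-count anchors used upstream of the published table are not
recoverable and are treated as explicit configuration. The Mann–Whitney
comparison of improved vs non-improved survivors is implemented and
oracle-tested, but the published group memberships are not printed, so
those specific values are not reproduced.
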