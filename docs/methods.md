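# Methods

## Problem and model

After a failed total knee arthroplasty, the proximal tibia around the
implant contains a mixture of remaining bone, the metal component, its
cement mantle, and osteolytic voids. The package quantifies that mixture
from CT and grades it on the AORI ordinal scale. Everything is voxel-based:
a volume is a count of voxels times the voxel volume, and every boundary is
a transverse plane at a slice index. Axis convention: axis 0 runs
medial→lateral, axis 1 anterior→posterior, axis 2 superior→inferior (slice
index increases distally); voxel positions are `index × spacing` in mm and
all slice intervals are half-open.

## Segmentation

Voxels are classified by closed HU intervals: defect [−1024, 200], bone
[200, 1800], cement [300, 1400], implant [2000, 3071]. Three rules resolve
the intervals' overlaps and gaps; each replaces a step that is done by
manual refinement when a human segments these scans:

* **Boundary at 200 HU** — assigned to bone, never defect. Interface
  artifacts around metal are easily misread as osteolysis; resolving the
  shared endpoint toward bone means artifacts never inflate the defect.
* **Cement vs cancellous bone** — their HU ranges overlap completely, so
  thresholds alone cannot separate them. A cement mantle is by definition at
  the bone–implant interface: cement-range voxels are labelled cement only
  within `cement_adjacency_mm` (default 3 mm, Euclidean distance transform)
  of the implant mask. The default equals the phantom's mantle thickness;
  with a mantle thinner than the adjacency radius, a shell of interface
  bone is deliberately attributed to cement — a property of the rule, not
  an error.
* **The 1800–2000 HU gap** — unassigned by the thresholds; treated as a
  partial-volume rim: implant when within one voxel of the implant mask,
  otherwise bone.
* **Defect envelope** — defect-range voxels count as defect only inside the
  *bone envelope*: the hole-filled morphological closing (ball radius 3
  voxels, configurable) of bone ∪ cement ∪ implant. Closing bridges
  surface-breaking voids; hole-filling is required because a fully enclosed
  cavity larger than the closing ball is not inside a plain closing.
  Exterior air stays background.

Tibia and fibula are separated by 26-connected components: largest = tibia;
largest remaining component with a centroid lateral to the tibial centroid =
fibula; stray fragments within 2 voxels of the tibia are merged into it,
others discarded. A size tie is broken toward the component with more
voxels in the proximal half.

## Zones and landmarks

The region of interest runs from the tibial cut (first implant-tray slice,
or first tibial-bone slice without an implant) to the most distal depicted
tibial slice. The epiphysis ends at the widest mediolateral plane of the
fibular head; the metaphysis ends `round(W / slice_spacing)` slices below
the cut, where `W` is the widest mediolateral extent of the tibial
foreground between the cut and the fibular-widest plane (rule of the
square). The square is anchored at the cut plane, the joint-line surrogate.
Zone boundaries are full transverse planes — zones are complete
cross-sections, because volumes are reported per zone along the bone.

Two distinct fibular landmarks are used deliberately: the *widest-head*
plane bounds the epiphysis for zone accounting, while AORI type-II grading
uses the more proximal *tip* plane. The tibial tubercle level cannot be
detected from image content with this geometry and is always supplied as a
landmark (phantoms provide it; clinical use would take it from the scan
annotation). The mediolateral midline defaults to the shaft centroid in the
distal half of the region of interest, which is robust to plateau defects.

## AORI grading

Only the void class counts as defect for grading (implant and cement voxels
are occupied, not lost). Rule order, with `min_involvement_cm3` (default
0.5 cm³) as the minimal volume for any criterion to fire: defect volume
distal to the tubercle plane → III; otherwise defect crossing the
fibular-tip plane → IIb when the medial and lateral sides *each* exceed the
threshold, IIa otherwise (including the ambiguous case where the total
crossing volume qualifies but neither condyle does alone); otherwise I. The
0.5 cm³ default suppresses single-voxel noise; no clinical source
quantifies "involvement", so it is configurable. Component subsidence and
ligament damage are clinical criteria invisible to a static preoperative
image and are not modelled.

## Volumetrics

Per scope (whole region of interest and each zone):
`v_total_defect = v_cement + v_implant + v_defect` (everything that is not
bone after component removal), `v_total_tibial = v_bone + v_total_defect`,
`remaining_ratio = v_bone / v_total_tibial`. Fibular bone is excluded from
every tibial tally; the implant volume is only the part inside the region
of interest. Zone tallies sum exactly to the totals (same voxels, disjoint
slabs). Empty scopes yield an undefined (None) ratio, never 0, and are
excluded from cohort summaries with a warning. Reports round volumes to
3 decimals (cm³) and ratios to 4 — sub-voxel precision would be spurious.

## Phantoms

The generator builds the simplest geometry that exposes every landmark the
pipeline needs: stacked elliptical tibial cross-sections (75 mm wide, 55 mm
anteroposterior plateau by default) tapering linearly over 50 mm into a
12.5 mm-radius cylindrical shaft; a separate fibula (ellipsoidal 8 mm head,
4.5 mm shaft) never voxel-connected to the tibia; an elliptical tray (4 mm
thick, 85% plateau coverage) with a 30 mm central stem; a 3 mm cement
mantle built with the same distance-transform rule the segmenter applies;
and ellipsoidal voids carved strictly out of tibial bone. Default grid
(160, 112, 224) voxels at 0.625 mm isotropic — 100 × 70 × 140 mm, large
enough for the full epiphysis, the fibula, and a non-empty diaphysis below
the rule-of-the-square junction. The slice thickness matches the scanning
protocol the pipeline targets; in-plane spacing is set equal to it for
simplicity.

Noise-free class HU values sit at the midpoints of the threshold intervals
(defect −400, bone 1000, cement 850, implant 2500, air −1000), so a
noise-free phantom is exactly re-segmentable up to a one-voxel boundary
shell; at 50 HU Gaussian noise every class margin is ≥ 10σ, so per-class
Dice against truth stays ≥ 0.95 (in practice ≥ 0.998). Optional radial
streak artifacts (deterministic cosine pattern around the implant,
amplitude-configurable) let tests probe robustness without modelling CT
physics. The random seed feeds only the additive noise.

Ellipsoids are voxelized by voxel-centre inclusion. This is unbiased for
generic placement (< 0.4% volume error at 5 mm semi-axes and 0.625 mm
spacing) but a centre exactly on the lattice with integer-voxel semi-axes
undercounts by ~2.6% (lattice-count bias); the packaged scenario grid
therefore places centres at generic off-lattice positions, as real lesions
are. The 12-scenario grid (3 zones × medial/lateral/both/central) spans all
four grades with comfortable margins on every grading criterion
(per-condyle crossing volumes ≥ 20% away from the 0.5 cm³ threshold).

What the phantom does **not** emulate: partial-volume mixing at tissue
interfaces, beam hardening, motion artifacts, anatomical shape variation,
cortical/cancellous distinction, and surgical defect debridement. Passing
phantom tests therefore demonstrates correctness of the geometry, the
accounting and the rules — not clinical segmentation accuracy on real
metal-artifact CT.

## Cohort simulator

Grading cohorts are simulated per knee: the intraoperative grade is drawn
from a 4-category distribution, and the CT / X-ray grades conditionally
from row-stochastic confusion matrices. Defaults are the row-normalized
counts of a published 99-knee agreement table (intraoperative distribution
21/29/35/14), whose large-n limit reproduces that table's κ values
(0.663 CT, 0.304 X-ray) by construction; the simulator's purpose is to let
the statistics be exercised at arbitrary n with known truth.

## Statistics

* **Cohen's κ** — unweighted; the printed agreement values of the reference
  table are consistent with unweighted κ (verified during implementation);
  p-values use Fleiss' large-sample null standard error. Landis–Koch bands
  with inclusive upper edges (0–0.20 slight, 0.21–0.40 fair, 0.41–0.60
  moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect; ≤ 0 poor).
* **Spearman r_s** — midranks for ties (Pearson correlation of midrank
  vectors), two-sided t-approximation p.
* **Ordinal median/IQR** — closest-observation quantiles (Hyndman–Fan
  type 3), which always return an observed grade and reproduce the
  reference table's three printed median/IQR triples exactly; the common
  inverse-ECDF (type 1) convention does not (it disagrees on one Q3).
* **Friedman** — within-row midranks with tie correction; post-hoc pairwise
  Wilcoxon signed-rank with Bonferroni, the usual SPSS companion (the
  procedure behind published pairwise p-values is rarely named; this is an
  assumption).
* **Kruskal–Wallis** — tie-corrected H; post-hoc Dunn z with Bonferroni.
* **Power analysis** — Fisher-z: `power = Φ(atanh ρ · √(n−3) − z_{1−α/2})`
  and its inverse for the minimal detectable ρ. The Monte-Carlo check
  treats its ρ argument as the population *Spearman* correlation and
  samples bivariate normals at Pearson `2 sin(πρ/6)` (Greiner's relation);
  sampling at Pearson ρ directly would understate the Spearman effect by
  ~5% and bias the comparison.

All p-values are large-sample approximations; exact permutation p-values
are out of scope.

## Numerical and design notes

* Determinism: every stochastic component (noise, cohort draws, Monte-Carlo
  power) is driven by an explicit integer seed; noise-free phantoms are
  bit-identical across seeds.
* Degenerate inputs: all-air volumes, missing implant (cement class empty,
  warning), missing fibula (landmarks must be supplied), empty zones
  (undefined ratios), single-category tables (κ undefined, error) are
  handled explicitly and tested.
* Problem sizes: the test suite validates the full 12-scenario grid at the
  default 4-megavoxel grid and cohort convergence at n = 100 000; both
  choices keep the whole suite under a couple of minutes on one core while
  leaving the statistical tolerances comfortably non-binding.

## Known limitations

* The zone partition anchors the square at the tibial cut; if the cut is
  unusually distal the epiphysis shrinks accordingly. No alternative
  joint-line estimate is implemented.
* Real cohort-level volumetric findings (zone defect shares, zone-wise
  grade correlations) depend on patient anatomy and are only covered by
  parameter-recovery properties on phantoms, not reproduced numerically.
* The X-ray arm of the cohort simulator is a confusion model, not an image
  model: it reproduces the statistical structure of radiographic grading,
  not its mechanism.
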