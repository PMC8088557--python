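# Methods

## Scope and model

`rtqa-bench` models the benchmark-case (BC) review loop of a radiotherapy
trial QA programme: institutions submit structure sets (and, after volume
approval, a treatment plan) for a standard head-and-neck case; reviewers
compare them against a gold standard; every criterion is classified
*per protocol*, *acceptable variation* or *unacceptable*; any unacceptable
deviation triggers a resubmission request; the procedure completes when all
criteria are conformal or within the accepted limits. The package makes each
of those steps an explicit, deterministic computation.

## Contour agreement

Masks are boolean occupancies on a regular (possibly anisotropic) grid,
axis order (slice, row, column), physical coordinate = origin + index ·
spacing (voxel-centre convention). Metrics require co-registered grids;
resampling is an explicit I/O step, never implicit.

* **DSI** = 2|A∩B| / (|A|+|B|). The denominator is the sum of the two
  volumes (the standard Sørensen–Dice form): with the union in the
  denominator the quantity would be the Jaccard index and could not reach
  the "1 for identical contours" reading used throughout the field. Two
  empty masks raise an error — an absent contour is a review deviation, not
  a metric value.
* **Surfaces** are the centres of occupied voxels with at least one
  6-connected unoccupied (or out-of-grid) neighbour. This definition is
  deliberately simple: it is exactly reproducible by an exhaustive
  neighbour scan, which the test suite uses as an oracle.
* **Percentile Hausdorff distance.** Directed distances are
  nearest-neighbour distances between the two surface point sets (exact,
  via a k-d tree); the directed percentile HD is the nearest-rank p-th
  percentile of that distance multiset, and the symmetric value is the
  maximum of the two directions. p is a configuration parameter. Default
  p = 95; p = 100 gives the classical HD. Nearest-rank was chosen because it
  is exactly checkable against a sorted list and monotone in p by
  construction; max-combination (rather than pooling both directions) was
  chosen because it preserves the "largest mismatch" reading of the HD.
  Note one subtlety of boundary-based distances: dilating the target mask is
  only guaranteed not to increase a directed distance when the source
  surface lies outside the target (the property tests cover that regime).

## Dosimetry

Dose grids are non-negative Gy values on the same grid type. Resampling onto
a mask grid is trilinear; target voxels outside the dose extent receive
0 Gy with a logged warning (benchmark dose grids normally cover all
structures, so a hard error would only block edge cases). The cumulative DVH
is computed over the structure's voxel doses with equal voxel volumes.
Metrics: `Dmean` (voxel mean), `Dmax` (voxel maximum — deliberately distinct
from D2%, since the protocol lists both), and `Dx%` as the (100−x)-th
percentile of the voxel doses with linear interpolation between order
statistics. The ordering D95% ≤ Dmean ≤ D2% ≤ Dmax is asserted throughout
the tests; the middle inequality is a property of the smooth dose
distributions the generator produces, not a theorem for arbitrarily
concentrated ones.

Institutional DVHs are computed on the institution's own accepted contours
(matching a review sequence in which plans are made only after volume
approval); a switch allows evaluation on the gold-standard contours instead.

## Review rules

Dose constraints are transcribed verbatim from the protocol's requirement
table (15 structures; strict inequalities, so `Dmax < 35 Gy` is violated at
exactly 35.0). Banded rules (`Dmean < 5–10 Gy`) put the strict limit at
per-protocol and the lenient limit at the unacceptable boundary. Delineation
criteria are configuration, not code: predicates are structure presence,
minimum DSI, maximum percentile HD, and a volume-ratio band. The protocol's
detailed criterion list is not public, so the shipped thresholds
(DSI ≥ 0.7, HD95 ≤ 15 mm) are explicit placeholders — they are the IOV
screening thresholds used in the published benchmark analysis itself.
Human-adjudicated judgements that cannot be automated (e.g. "inclusion of
natural barriers in the CTV") can be merged as externally supplied deviation
records.

Sequencing follows the real workflow: volumes are reviewed every round; a
plan accompanying a round is only evaluated if the volumes are approved (in
an earlier round or that same round), otherwise the run aborts with a
sequencing error. A round is accepted iff it produced no unacceptable
record.

## Cohort aggregation

* Per-pair first/final differences are computed on unrounded values and
  rounded only for display (DSI two decimals, HD one decimal), so the mean
  difference equals the difference of means exactly — the only convention
  consistent with published first/final tables.
* SDs are sample SDs (n − 1).
* Category percentages use largest-remainder apportionment so the printed
  triple sums to exactly 100 (40/27/9 of 76 → 53/35/12; nearest-integer
  would give 101). Per-structure percentages are nearest-integer. The
  resubmission percentage is displayed truncated (23/35 → 65 %), matching
  the convention of the published figures; raw fractions are always kept in
  machine output.
* The count of structures whose mean HD improved by more than 10 mm is
  computed from the unrounded differences, never hard-coded.

## Synthetic phantom and cohort

The emulated benchmark case has no public imaging data, so the generator
builds geometric stand-ins with closed-form properties: ellipsoids for
glands, z-axis tubes for cord/esophagus/larynx structures, half-annulus
shells for the pharyngeal constrictors and the mandible horseshoe, and
boxes for the target volumes, voxelised by a voxel-centre-inside test on a
2 mm isotropic 100×80×80 grid. The therapeutic PTV is nested inside the
prophylactic PTV by construction and the containment is verified voxelwise.

Perturbation modes emulate the observed error taxonomy: `dilate`/`erode`
(systematic over/under-contouring, spherical element in mm),
`translate` (nearest-voxel shift of an mm vector), `crop_longitudinal` /
`extend_longitudinal` (cranio-caudal boundary errors — the mode percentile
HD is most sensitive to), `boundary_noise` (seeded flips of
boundary-adjacent voxels; magnitude is the flip probability), and
`omit_structure`. Randomness uses one seed with per-(institution,
structure, purpose) substreams derived from hashed names, so results do not
depend on evaluation order.

The dose model is analytic: prescription dose (66 Gy) inside the
therapeutic PTV, elective dose (54.45 Gy) inside the prophylactic PTV, both
expanded by a 5 mm planner margin, and exponential falloff with distance
outside (default length 8 mm, per-institution jitter ±5 %). This produces a
plan that satisfies every shipped dose constraint for all institutions; the
scripted planning error adds a hotspot (45 Gy, 8 mm radius) on the
spinal-cord PRV, violating exactly its Dmax rule.

**Default cohort conditions.** The scripted 35-institution schedule
reproduces the study conditions of the emulated benchmark programme:
12 clean single-round institutions; 23 institutions that fail at least one
round, accumulating exactly 76 unacceptable deviations — 40 OAR delineation
and 27 target delineation errors distributed over structures with the
published per-structure counts (19 prophylactic PTV, 8 constrictor, 8
therapeutic PTV, 6 mandible, …, 1 omitted submandibular gland), plus 9
planning violations — with round counts of median 2 and range 1–4. Each
scripted delineation error uses the perturbation that trips exactly one
review criterion: longitudinal crops (17–31 mm, jittered) violate the HD
threshold while leaving DSI ≥ 0.7 on elongated organs; generous dilations
(8–12.5 mm) violate the DSI threshold while staying under 15 mm HD on
compact structures. Accepted contours carry mild boundary noise (flip
probability 0.05–0.15), which keeps every structure within both thresholds
while giving realistic nonzero cohort spreads.

**What the generator does not emulate:** real anatomy and CT appearance,
deformable (non-rigid) contouring disagreement, observer-specific bias,
partial-volume effects, and realistic IMRT dose gradients. Passing tests
therefore demonstrate the correctness of the metrics, the rule engine and
the aggregation arithmetic under controlled conditions — not clinical
performance of any contouring or planning method.

## Numerical choices

* Nearest-rank percentile: smallest distance d with ≥ p % of distances ≤ d.
* DVH inverse: linear interpolation between adjacent order statistics
  (`numpy.percentile` linear method).
* Grid equality: exact shape match, spacing/origin within 1e−9 mm.
* Masks are written as 8-bit 0/1 volumes; NIfTI output uses the NIfTI-2
  header so grid geometry round-trips at float64 precision and metrics are
  bit-identical after I/O. Oblique/rotated affines are rejected on read.
* Millimetre values are kept at full precision internally and logged to
  3 decimals; table rounding happens only at report emission.

## Problem sizes

The shipped configuration runs everything at desk scale: the phantom grid is
100×80×80 at 2 mm, the default cohort 35 institutions × 15 structures ×
1–4 rounds (about one minute for the full pipeline on one CPU), the metric
oracle suites use grids up to 12³ with 1000 random mask pairs. All sizes
are configuration, not constants.

## Known limitations

* Surface distances are voxel-centre based; sub-voxel (mesh) surface
  distances, added path length and surface-DSC are out of scope.
* DICOM support is import-only for RTSTRUCT closed planar contours;
  RTDOSE/RTPLAN are not read.
* The rule engine evaluates numeric predicates; anatomical plausibility
  (correct lymph-node-level selection, natural barriers) requires human
  adjudication and enters only as imported records.
* Published summary statistics can be reconstructed to exact moments, but
  the underlying clinical per-institution values remain unavailable; cohort
  means beyond the scripted bookkeeping (e.g. our phantom's dose means) are
  properties of the synthetic conditions, not of the clinical cohort.
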