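# Methods

## Scope and model

`noduleval` evaluates lesion-detection output against a multi-slice
reference standard. Both sides are stacks of axis-aligned per-slice
bounding boxes in pixel coordinates, half-open (`[x_min, x_max) ×
[y_min, y_max)`), on 0-based slice indices; a box center is the midpoint of
each axis. Reference nodules additionally carry a six-way type label
(solid, part-solid, pure ground-glass, calcified, pleural, pleural
calcified), per-slice long/short diameters in mm, and an average diameter
used for size binning. Pixel↔mm conversion uses per-case (row, col) pixel
spacing; distances are in-plane only, since slice pairing already
constrains the through-plane axis. Slice pairing requires equal slice
index on both sides — pairing across neighboring slices would need a
tolerance with no principled value.

## Mark-labeling rules

For one reference slice and one predicted box on the same slice:

* **center hit**: success iff the predicted center lies in the closed
  reference box (boundary inclusive).
* **center distance**: success iff the anisotropic in-plane center
  distance (mm) is strictly below the reference nodule's adaptive radius,
  the maximum over its slices of (long + short)/4. The threshold is
  per-nodule, never global.
* **area overlap**: success iff intersection area over *reference* area is
  strictly above the threshold (default 0.5). Note the denominator is the
  reference box, not the union: a prediction fully covering the reference
  scores 1 regardless of its own size.

Both inequalities are deliberately strict, so a distance equal to the
radius or a fraction equal to the threshold fails; this is bit-exact,
documented behavior. A multi-slice prediction detects a multi-slice
reference as soon as one shared slice succeeds; zero shared slices is a
failure.

## Greedy one-to-one assignment

Per case, references are processed in a canonical order — descending
largest-slice box area, ties by ascending nodule id (`--match-order
file|size|id`). Largest-first prevents a small neighbor from consuming the
prediction that belongs to a large nodule, and the order is deterministic.
Each reference claims its best still-unmatched candidate: smallest center
distance for the center rules, largest overlap fraction for the overlap
rule. For center hit, the tiebreak among multiple hitting candidates is
the distance to the reference's **largest slice**, measured on the
candidate's box at that slice index if present, else at its nearest slice
— the natural reading of comparing "the distance to the largest slice" for
stacks that may not cover that slice. Candidates tied on the score resolve
to the lowest pred id. Consumed predictions leave the pool; leftover
references are FN and leftover predictions FP, so tp+fn = |refs| and
tp+fp = |preds| always hold. A brute-force queue walk-through of the same
flowchart, implemented independently in the test suite, agrees with the
matcher on thousands of random cases under all three rules.

When an AUT declares a detectable-type subset (`--type-scope`), references
outside the scope leave TP/FN accounting, and leftover predictions are
shadow-matched against the excluded references: those that match are
dropped rather than counted FP, so an algorithm not designed for pleural
nodules is neither credited nor penalized for finding one. Default is no
filtering.

## Metrics and statistics

Counts are pooled over cases before ratios (micro-averaging); 0/0 ratios
are defined as 0. Panel summaries are mean ± sample (n−1) SD of per-AUT
pooled metrics on the percent scale. Rule deltas are signed differences of
means in percentage points (2 decimals); the relative difference
RD = (TP_rule − TP_baseline)/TP_baseline uses center hit as the default
baseline and is undefined (error) at zero baseline TP.

Rules are compared as independent groups of per-AUT values: one-way
fixed-effects ANOVA, then uncorrected pairwise two-sided t-tests.
Student's pooled-variance test is the default; `--welch` and a paired
variant exist because per-AUT values are in fact paired by AUT — the
independent-groups default mirrors the common reporting style and is
logged as such. Labels: `**` p ≤ 0.01, `*` 0.01 < p ≤ 0.05, `ns`
otherwise, boundaries inclusive. Zero-variance degeneracies: equal means →
(t = 0, p = 1); unequal means → an explicit error rather than a silent
infinity.

Miss rate per stratum is FN over reference count, so per-type miss rate is
1 − per-type recall; strata with no references are undefined (`None`),
never 0. The "most missed" heatmap counts, per size bin, the AUTs whose
highest defined miss rate falls on each type; exact ties credit every tied
type and are reported in a tie list, so column sums can exceed the AUT
count only in the presence of ties.

Size bins over average diameter are left-closed/right-open —
[0,4), [4,6), [6,10), [10,∞) mm — so they partition the positive axis;
4.0 mm falls in [4,6) and 10.0 mm in [10,∞).

## Annotation quality control

Annotator qualification matches the candidate's nodules to the expert
panel's (center hit by default), pooled over cases; Dice is averaged over
matched pairs, computed on boundary polygons when annotated and on
bounding boxes otherwise, with intersection accumulated over shared slices
and each region's area over all of its slices. Passing requires precision,
recall and Dice **all strictly above 0.8**; exactly 0.8 fails.
Precision/recall are per-nodule (detection-level), not per-slice.

Three-reader consensus builds a match graph from all three pairwise
matchings; a connected component is consistent only if it is a triangle —
one nodule per reader, all three pairs mutually matched. Consistent groups
merge to the per-slice union of the readers' regions (enclosing box of the
union; diameters take the per-slice maxima, the type is the majority
label, and the merged id is the sorted join of member ids, so the output
is invariant to reader order). Every slice of every detection outside a
consistent group is flagged `(case_id, slice_index)` for senior
arbitration; the arbitration itself is a human act outside the package.

## Synthetic data

The generator emulates the composition of a real sequestered lung-CT test
set: type mixture (solid .4266, part-solid .0506, pure ground-glass .1958,
calcified .0740, pleural .2306, pleural calcified .0224), size-bin mixture
(.6991/.1963/.0728/.0318), Poisson nodule count with mean 10.3 per case,
in-plane pixel spacing uniform in 0.5–0.9 mm and slice thickness in
1–2 mm. Within a bin the average diameter is log-uniform ([0,4) is
supported on [1,4) mm since sub-millimeter nodules are not annotated in
practice; [10,∞) truncates at 30 mm, the upper bound of the nodule
definition). Long/short diameters are 1.1 and 0.9 of the average so their
mean recovers it and the matching radius equals half the average diameter;
the slice count is diameter over slice thickness, with an elliptic
in-plane taper toward end slices normalized so the largest slice carries
exactly the annotated diameters (min taper 0.35). Placement is rejection
sampling with non-overlapping dilated neighborhoods (100 tries, then one
diameter halving; then an explicit generation error). One seeded PRNG
drives each run; every emitted file records its seed in a comment line,
and fixed seeds give byte-identical CSVs.

Simulated AUTs detect each nodule independently with a per-(type, bin)
sensitivity; detections copy the reference stack with one shared Gaussian
center offset (σ = jitter fraction × nodule radius per axis), one
log-normal size multiplier, and optional truncation of each end slice.
False positives are Poisson per case and placed with centers outside every
reference box dilated by its radius, so configured sensitivities remain
identifiable from measured recall — FPs cannot be accidentally credited as
detections.

The canonical ten-AUT panel fixes per-type sensitivities at pure
ground-glass 0.41, pleural 0.50, solid 0.58, pleural calcified 0.65,
part-solid 0.71, calcified 0.73 — the detection-difficulty ordering
reported for real CAD panels, with the pleural-calcified value
interpolated since published panels do not report it — with jitter 0.15,
box-scale σ 0.25, 8 FP/case (placing precision near 40% at recall near
55%) and truncation 0.05; panel members differ only by seed. Acceptance
runs use 194 cases (~2000 nodules), a size at which per-type binomial
uncertainty is small while the full three-rule, ten-AUT evaluation
completes in seconds.

What the generator does **not** model: image voxels and texture, scanner
physics, reader-dependent annotation noise in the reference itself,
correlated misses (real algorithms miss the *same* hard nodules, the
simulator misses independently), and spatially clustered false positives
near vessels or pleura. Passing tests therefore demonstrate the
correctness of the evaluation machinery under controlled error structure,
not the performance of any real algorithm on real CT data.

## Numerical and degenerate-input choices

* Box coordinates are real-valued; validation rejects zero-area boxes and
  negative slice indices at construction.
* CSV round-trips write floats via shortest-exact decimal (`repr`) so
  write→read reproduces values bit-for-bit.
* Largest-slice ties resolve to the lowest slice index; score ties in
  matching to the lowest pred id; heatmap argmax ties credit all tied
  types.
* Readers reject duplicate (case, id, slice) rows, name the offending
  lines, and enforce the six-value type vocabulary; an empty prediction
  file is valid (an AUT may output nothing).
* Predictions for a case with no reference annotations are logged and
  scored as FP within that case.

## Known limitations

* The greedy pass is order-dependent by design (it reproduces the stated
  flowchart); it is not an optimal assignment, and on adversarial
  geometries it can differ from Hungarian matching.
* FROC/score-sweep analysis is out of scope: AUT operating points are
  treated as fixed.
* The statistics treat per-AUT values as independent across rule groups;
  the paired structure is acknowledged and available but not the default.
* Consensus merging defines consistency via the package's own matching
  rules; other sites may use different consistency programs.
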