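# noduleval

Standardized, third-party-style evaluation of computer-aided detection (CAD)
algorithms for pulmonary nodules on CT.

When a CAD algorithm outputs per-slice bounding boxes and radiologists have
annotated a reference standard, the headline metrics — recall, precision,
F₁ — depend heavily on the *mark-labeling* rule: the criterion that decides
whether a predicted box stack matches a reference nodule. `noduleval`
implements the three rules in common regulatory-testing use, the greedy
one-to-one matching procedure that applies them, the downstream metrics and
stratified error analyses, statistical comparison of rules across a panel of
algorithms under test (AUTs), annotator-qualification and three-reader
consensus tooling, and a synthetic data generator so the entire pipeline is
testable without any patient data.

## The matching model

A reference nodule is a stack of per-slice boxes with long/short diameters
(mm); a prediction is a stack of per-slice boxes. A prediction detects a
reference nodule if **at least one shared slice** succeeds under the active
rule:

* **center hit** — the predicted box center lies inside the reference box
  (closed region: the boundary counts);
* **center distance** — the in-plane center distance *d* (mm, per-axis pixel
  spacing applied) satisfies *d* < *r*, with the adaptive per-nodule radius
  *r* = maxₛ (longₛ + shortₛ)/4 over the reference's slices;
* **area overlap** — |pred ∩ ref| / |ref| > 0.5 (threshold configurable;
  inequality strict).

Matching is greedy and order-driven: references are walked largest-first
(configurable), each claiming its best remaining candidate — nearest center
for the center rules (for center hit, distance to the reference's largest
slice), highest overlap fraction for the overlap rule. A consumed prediction
cannot match again; leftover references are FN, leftover predictions FP.
Metrics pool counts over cases (micro-averaging): recall = TP/(TP+FN),
precision = TP/(TP+FP), F₁ their harmonic mean. A panel of AUTs is
summarized as mean ± sample SD across AUTs; rules are compared by one-way
ANOVA and pairwise t-tests with the usual `ns` / `*` / `**` labels, and by
the per-AUT relative TP difference RD = (TP_rule − TP_hit)/TP_hit against
the center-hit baseline. Error analysis reports per-type miss rates
(FN/type count) and a type × size-bin "most-missed" heatmap over the bins
[0,4), [4,6), [6,10), [10,∞) mm.

## Worked example

Simulate a 40-case dataset with ten AUTs whose predictions carry center
jitter (σ = 0.15 of the nodule radius) and box-size error (log-σ = 0.25),
then compare the three rules:

```bash
noduleval simulate --n-cases 40 --n-auts 10 --seed 1 \
    --center-jitter 0.15 --box-scale-sigma 0.25 --fp-per-case 4 --out-dir data
# wrote 40 cases / 407 nodules and 10 AUTs to data

noduleval compare-rules --refs data/reference.csv \
    --preds-dir data/predictions --cases data/cases.csv --out-dir results
```

`results/rule_comparison.json` then contains (abridged):

```
center_hit       recall 59.02 ± 2.63   precision 59.98 ± 2.53   f1 59.48 ± 2.42
center_distance  recall 59.02 ± 2.63   precision 59.98 ± 2.53   f1 59.48 ± 2.42
area_overlap     recall 53.86 ± 2.46   precision 54.72 ± 1.93   f1 54.27 ± 2.05

recall ANOVA p = 9.0e-05
center_hit vs center_distance  p = 1.0000  ns
center_hit vs area_overlap     p = 0.0003  **
```

Read: on identical predictions, the area-overlap rule credits ~5 percentage
points less recall than the center rules because jittered, resized boxes
still contain the nodule center while covering less than half of the
reference box; the two center-based rules agree almost exactly. This is the
qualitative behavior expected of bounding-box CAD output and the reason the
choice of mark-labeling rule must be reported alongside the metrics.

Single-AUT scoring and error analysis:

```bash
noduleval evaluate --refs data/reference.csv \
    --preds data/predictions/aut01.csv --cases data/cases.csv \
    --rule center_hit --out-dir results
# recall=0.6372 precision=0.7697 f1=0.6972   (+ per-nodule audit.csv)

noduleval error-analysis --refs data/reference.csv \
    --preds-dir data/predictions --cases data/cases.csv --out-dir results
# miss_rates.csv (type × AUT + mean ± SD), heatmap.csv (size bin × type)
```

`qualify` scores a candidate annotator against an expert panel (pass
requires precision, recall and Dice all strictly above 0.8) and `consensus`
merges three readers' annotations, flagging slices they disagree on.

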