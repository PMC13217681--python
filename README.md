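# ctveval

Contour evaluation for clinical-target-volume (CTV) delineation studies.

When radiation oncologists contour a CTV — for example the pelvic target in
cervical-cancer external-beam radiotherapy — different observers draw
appreciably different volumes, and training programs are evaluated by
comparing every observer's pre- and post-training contours against an
expert consensus reference. `ctveval` is the analysis side of such a study,
for medical physicists and radiation-oncology researchers: it scores 3-D
binary masks against a reference, summarises interobserver variability,
runs the paired pre/post statistics with effect sizes, applies the usual
participant-exclusion rules, and correlates 5-point Likert self-assessments
with objective contour quality. A synthetic-cohort generator makes every
stage testable end to end without any clinical data.

## What it computes

For a test mask $A$ and reference $B$ on a shared voxel grid:

* **DSC** (Dice similarity coefficient) $= 2|A\cap B|/(|A|+|B|)$
* **CI** (conformity index, the Jaccard index) $= |A\cap B|/|A\cup B|$,
  tied to Dice by $CI = DSC/(2-DSC)$
* **Inclusion** $= |A\cap B|/|B|$, the fraction of the reference covered
* **RVD** (relative volume difference) $= (V_A - V_B)/V_B$, signed
* **ASD** — symmetric average surface distance (mm): mean of the pooled
  bidirectional nearest-surface distances
* **95%HD** — 95th-percentile Hausdorff distance (mm): max of the two
  directed 95th percentiles
* **DC** — distance between centres of mass (mm)
* **Volume** (cm³)

Surfaces are foreground voxels with a background 6-neighbour; distances are
Euclidean between voxel centres honouring anisotropic spacing, computed via
exact distance transforms.

Cohort statistics: interobserver variability of structure volumes (sample
SD, coefficient of variation, max/min volume ratio MVR); paired pre/post
comparison per metric with a Shapiro–Wilk gate choosing the paired *t*-test
(effect size $d = |t|/\sqrt{n}$) or the Wilcoxon signed-rank test (effect
size $r = |Z|/\sqrt{n}$); Spearman correlations between questionnaire items
and metrics, with the correlations of lower-is-better metrics (95%HD, ASD,
DC, RVD) negated so positive always means "better self-rating, better
contour".

## Worked example

Simulate a small training cohort (8 observers on a coarse desk-scale grid),
score everyone against the reference, and run the paired statistics:

```python
from ctveval import CohortSpec, simulate_cohort, evaluate_cohort
from ctveval.pipeline import compare_metrics, summarize_table

spec = CohortSpec.small(n_observers=8)
reference, records, likert = simulate_cohort(spec, master_seed=7)
metrics = evaluate_cohort(records, {("case1", "CTV"): reference})
table = summarize_table(compare_metrics(metrics))
print(table[["metric", "pre", "post", "test", "p", "effect_size"]].to_string(index=False))
```

prints

```
   metric                            pre                           post     test      p effect_size
      dsc        0.75 ± 0.05 (0.67–0.83)        0.89 ± 0.04 (0.83–0.94) paired_t 0.000*   d = 2.547
       ci        0.61 ± 0.07 (0.50–0.71)        0.81 ± 0.06 (0.71–0.89) paired_t 0.000*   d = 2.682
inclusion        0.79 ± 0.09 (0.63–0.88)        0.90 ± 0.03 (0.87–0.95) wilcoxon 0.012*   r = 0.891
      rvd       0.11 ± 0.27 (-0.27–0.52)       0.03 ± 0.09 (-0.06–0.17) paired_t  0.381   d = 0.331
      asd       7.38 ± 2.13 (4.96–11.28)        2.54 ± 0.87 (1.28–3.89) paired_t 0.000*   d = 2.499
       dc       9.90 ± 4.56 (5.37–18.52)       5.39 ± 2.85 (2.09–10.22) paired_t 0.016*   d = 1.114
     hd95     39.78 ± 9.71 (17.24–46.97)       7.63 ± 3.06 (5.00–12.26) wilcoxon 0.012*   r = 0.891
   volume 370.58 ± 89.38 (244.03–508.06) 344.14 ± 28.51 (315.78–391.69) paired_t  0.381   d = 0.331
```

Each row compares a metric before and after training as
`mean ± SD (min–max)`. In this simulated cohort post-training severities
are half the pre-training ones, so overlap metrics rise and distance
metrics fall significantly (starred p-values, large effect sizes), while
volume and its signed error RVD barely move — exactly the signature a real
training study looks for.

The same pipeline is available from the shell:

```sh
ctveval simulate --seed 7 --out cohort/          # NIfTI masks + manifest + Likert CSV
ctveval evaluate --manifest cohort/manifest.csv --references cohort/references.csv --out metrics.csv
ctveval compare  --metrics metrics.csv --out stats/
ctveval run      --seed 7 --out full_run/        # all stages at once
```

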