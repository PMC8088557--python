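# rtqa-bench

Benchmark-case quality assurance for radiotherapy trials.

Before a centre may enrol patients in a radiotherapy trial, it typically
submits a **benchmark case**: it contours a standard test patient, and — once
the volumes are approved — submits a treatment plan. Reviewers compare both
against a gold standard, classify every criterion on the Global Harmonization
Group scale (*per protocol* / *acceptable variation* / *unacceptable*), and
request resubmissions until no unacceptable deviation remains. `rtqa-bench`
implements this entire review pipeline for head-and-neck benchmark cases —
contour agreement metrics, DVH dose-constraint checking, deviation
classification with the multi-round resubmission workflow, and cohort-level
reporting — together with a synthetic phantom generator so every stage can be
exercised and validated without clinical data.

It is aimed at RTQA physicists and trial methodologists who want a
reproducible, scriptable version of a benchmark review, and at researchers
studying inter-observer variability (IOV) in contour delineation.

## Metrics and model

For a gold-standard mask *A* and a submitted mask *B* on a co-registered
voxel grid (all distances in millimetres):

* **Sørensen–Dice similarity index**
  `DSI = 2|A ∩ B| / (|A| + |B|)` — volume overlap in [0, 1]; 1 means
  identical contours.
* **Percentile Hausdorff distance** — for each boundary-voxel centre of one
  surface, the minimum Euclidean distance to the other surface; the directed
  distance takes the *p*-th nearest-rank percentile of these (p = 100 is the
  classical "largest minimal distance between the boundaries"), and
  `HD = max(directed(A→B), directed(B→A))`. Default p = 95, the common RTQA
  choice, which suppresses single-voxel outliers.
* **DVH metrics** — `Dmean`, `Dmax` (voxel maximum), near-maximum `D2%`
  (minimum dose to the hottest 2 % of the volume) and coverage `D95%`
  (minimum dose received by 95 % of the volume), both evaluated as inverse
  cumulative-DVH order statistics with linear interpolation.

Dose constraints are evaluated with strict inequalities exactly as the
protocol prints them (`Dmax < 35 Gy`: 35.0 violates); banded rules such as
`Dmean < 5–10 Gy` classify the strict side per-protocol, the band as
acceptable variation, and beyond the lenient bound as unacceptable. Only
unacceptable deviations block acceptance. Plans are reviewed only after
volume approval (a dose submitted earlier is a sequencing error).

## Worked example

```python
from rtqa_bench import (compare_masks, default_rules, make_cohort,
                        run_benchmark)
from rtqa_bench.cohort import build_report

# scripted 35-institution synthetic benchmark on the bundled
# head-and-neck phantom (15 structures, 2 mm grid)
cohort = make_cohort(35, seed=7)
delin_rules, dose_rules = default_rules()
histories = run_benchmark(cohort.submissions, cohort.gold,
                          delin_rules, dose_rules)
report = build_report(histories, dose_rules)

print(report.resubmissions.n_multiple, report.resubmissions.percent)
print(report.tally.total, report.tally.category_percent)
```

prints

```
23 65
76 {'target_delineation': 35, 'oar_delineation': 53, 'planning': 12}
```

i.e. 23 of the 35 institutions (65 %) needed more than one submission before
clearance, and the review raised 76 unacceptable deviations, 53 % of them
OAR delineation errors, 35 % target delineation errors and 12 % planning
(dose-constraint) violations. `report.paired` holds the per-structure
first-vs-final DSI/HD statistics (how much the review reduced IOV),
`report.finals` the final-volume agreement means, and `report.doses` the
institutional dose summary next to each protocol requirement.

The same run is available from the shell:

```bash
rtqa-bench benchmark --n-institutions 35 --seed 7 --out out/
# out/: deviations.csv, paired_first_final.csv, final_metrics.csv,
#       dose_summary.csv, deviation_tally.csv, metrics_long.csv, summary.json
```

plus `rtqa-bench generate` (write the phantom / a scripted cohort as NIfTI),
`rtqa-bench evaluate` (review one submission directory against a gold
directory) and `rtqa-bench report` (re-aggregate a deviation table).

## Layout

```
src/rtqa_bench/geometry.py    masks, surfaces, DSI, percentile HD
src/rtqa_bench/dosimetry.py   dose grids, DVHs, Dmean/Dmax/D2%/D95%
src/rtqa_bench/qa_rules.py    GHG classification, accept/resubmit workflow
src/rtqa_bench/cohort.py      tallies, paired first/final stats, summaries
src/rtqa_bench/phantoms.py    phantom generator, perturbations, dose model
src/rtqa_bench/io.py          NIfTI/NRRD I/O, RTSTRUCT import, pipeline
src/rtqa_bench/cli.py         generate / evaluate / benchmark / report
src/rtqa_bench/data/          rule set + published summary inputs
```

See `docs/methods.md` for the modelling choices, parameter defaults and
limitations.
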