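"""The repeated-experiment protocol on a phantom cohort (reduced scale).

Each repetition re-draws the per-patch tensor sample with a derived seed,
re-splits 30/70, trains afresh and is scored on its held-out set; the
aggregate is mean +/- a Student-t 95% confidence half-width. This mirrors
how performance is reported when datasets are small and the sampling itself
contributes variance. (The full 10-repetition run lives in
scripts/acceptance.py; 3 repetitions here keep the example quicker.)

Cohort size matters: at the default 12 images the model separates all three
classes, while cohorts much smaller than that starve the calcification
class and the classifier collapses to predicting healthy tissue.
"""

from mammotensor.pipeline import run_default_experiment

report = run_default_experiment(seed=3, repetitions=3)

for i, rep in enumerate(report.per_repetition):
    print(f"repetition {i}: accuracy {rep.accuracy:.3f}, macro-F1 {rep.f1:.3f}")
    print(f"  confusion (rows = truth: healthy, calcification, mass):")
    for row in rep.confusion:
        print(f"    {row}")
agg = report.aggregate
print(f"aggregate: accuracy {agg['mean_accuracy']:.3f} ± {agg['accuracy_ci95']:.3f}, "
      f"macro-F1 {agg['mean_f1']:.3f} ± {agg['f1_ci95']:.3f} "
      f"({agg['n_repetitions']} repetitions, 95% CI half-widths)")
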