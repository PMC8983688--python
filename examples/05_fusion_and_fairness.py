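"""Late fusion across prediction horizons, with a fairness audit.

Runs the full study on a 120-patient synthetic cohort: per-horizon analog
ECG models, two EMR models (demographics-only for setting 1, plus
comorbidity text for setting 2), and a logistic meta-learner fusing the
two score streams.  Prints held-out accuracy per horizon and the
false-positive-rate disparity table for race at the shortest horizon.
"""

from sepsisfuse.analog import TrainConfig
from sepsisfuse.cohort import CohortConfig
from sepsisfuse.pipeline import run_study

config = CohortConfig.desk_scale(n_patients=200, seed=6)
bundle = run_study(
    config,
    seed=6,
    meta_types=("logistic",),
    ecg_train_cfg=TrainConfig(seed=6, epochs=40),
)

metrics = bundle["metrics"]
print("held-out accuracy by horizon (setting 2: demographics + comorbidity + ECG):")
s2 = metrics[metrics.setting == 2]
for h in sorted(s2.horizon.unique()):
    row = {m: s2[(s2.horizon == h) & (s2.model == m)].accuracy.iloc[0]
           for m in ("ecg_only", "emr_only", "fusion_logistic")}
    print(f"  h={h}: ECG {row['ecg_only']:.2f}  EMR {row['emr_only']:.2f}  "
          f"fusion {row['fusion_logistic']:.2f}")

print("\nECG accuracy decays with horizon (the sepsis signature ramps up "
      "only near onset) while the static EMR signal is horizon-independent. "
      "At this cohort size the meta-learner can dip below the best single "
      "modality at mid horizons: it is fit on training-side scores, where "
      "the random forest's near-zero training error makes the EMR score "
      "look more informative than it is on held-out patients.  The effect "
      "shrinks with cohort size.")

print("\nFPR disparity by race at the 4-step horizon (fair band 0.8-1.25):")
table = bundle["disparity"]["race_h4"]
print(table[["group", "fpr", "n", "ratio", "fair", "insufficient_n"]]
      .to_string(index=False))
print("\nGroups with fewer than 10 held-out negatives are flagged "
      "insufficient_n: their ratios are reported but not evidence of bias. "
      "Demographics are independent of physiology in this generator, so "
      "any stable disparity at scale would indicate a pipeline defect.")
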