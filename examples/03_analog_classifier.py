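"""Train the simulated analog classifier with error-aware co-design.

Extracts labelled windows at the 1-step horizon from a 60-patient cohort,
then trains the 14-20-6-1 network through its analog path (4-bit DACs,
charge-sharing MACs bounded to [-1, 1], amplifier-lookup activations) and
compares against the same architecture in ideal mathematical mode.
"""

from sepsisfuse.analog import (
    AnalogANN,
    FeatureScaler,
    TrainConfig,
    patient_split,
    train_error_aware,
)
from sepsisfuse.cohort import CohortConfig
from sepsisfuse.ecg import FEATURE_NAMES
from sepsisfuse.pipeline import featurize_cohort

config = CohortConfig.desk_scale(n_patients=60, seed=2)
features = featurize_cohort(config, horizons=(1,), k=10)
X = features[list(FEATURE_NAMES)].to_numpy()
y = features["label"].to_numpy(dtype=float)
pid = features["patient_id"].to_numpy()

cfg = TrainConfig(epochs=60, seed=2)
train_mask, _ = patient_split(pid, cfg.split, cfg.seed)
for mode in ("analog", "ideal"):
    ann = AnalogANN(mode=mode, dac_bits=4).init_weights(cfg.seed)
    # both modes see identically scaled inputs; only the analog path
    # additionally quantizes, normalizes MACs and uses lookup activations
    ann.scaler = FeatureScaler.fit(X[train_mask])
    ann, report = train_error_aware(X, y, pid, ann=ann, cfg=cfg)
    last = report.iloc[-1]
    print(f"{mode:6s} mode: train accuracy {last['train_accuracy']:.3f}, "
          f"held-out accuracy {last['test_accuracy']:.3f}")

print("\nError-aware training runs gradients through the quantizers and "
      "lookup activation curves, so the 4-bit analog network tracks the "
      "ideal network's accuracy despite its hardware non-idealities.")
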