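"""Generate a small synthetic ICU cohort and inspect its structure.

Builds 20 patients at desk scale (0.5 h records, 300 Hz), prints the class
balance, one patient's demographics and the heart-rate difference near
onset recovered from the generator's own ground-truth R peaks.
"""

import numpy as np

from sepsisfuse.cohort import CohortConfig, cohort_profiles, generate_ecg

config = CohortConfig.desk_scale(n_patients=20, seed=0)
profiles = cohort_profiles(config)

n_sepsis = sum(p.is_sepsis for p in profiles)
print(f"{len(profiles)} patients, {n_sepsis} sepsis / {len(profiles) - n_sepsis} non-sepsis")

p = profiles[0]
print(f"\n{p.patient_id}: {p.label}, onset at {p.onset_time_s:.0f} s")
print(f"  {p.age_bin}, {p.gender}, {p.race}, {p.ethnicity}")
print(f"  comorbidities: {'; '.join(p.comorbidity_texts[:3])} ...")

# Heart rate in the final 90 s before (pseudo-)onset, from truth R-R intervals.
rates = {"sepsis": [], "non-sepsis": []}
for p in profiles:
    rec = generate_ecg(p, config)
    end_s = p.onset_time_s if p.is_sepsis else rec.duration_s - 30.0
    pk = rec.ground_truth_r_peaks
    sel = pk[(pk >= (end_s - 90) * config.fs) & (pk <= end_s * config.fs)]
    rates[p.label].append(60.0 / (np.diff(sel) / config.fs).mean())

gap = np.mean(rates["sepsis"]) - np.mean(rates["non-sepsis"])
print(f"\nmean HR near onset: sepsis {np.mean(rates['sepsis']):.1f} bpm, "
      f"non-sepsis {np.mean(rates['non-sepsis']):.1f} bpm (gap {gap:.1f} bpm)")
print("The gap approaches the programmed 30 bpm elevation (slightly less, "
      "because the linear pre-onset ramp has not fully saturated over the "
      "measurement span).")
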