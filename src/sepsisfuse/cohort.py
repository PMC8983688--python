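"""Synthetic ICU cohort generator: ECG waveforms, demographics, comorbidity
text, sepsis labels and onset times.

The generator emulates the data a continuous bedside/wearable sepsis
monitor would see: single-lead ECG sampled at 300 Hz with at least 8 h per
patient, a ~53/47 sepsis/non-sepsis class balance, and a demographics table
with controllable group proportions.  Sepsis is encoded physiologically as
heart-rate elevation, reduced heart-rate variability, and prolonged,
lower-amplitude QRS complexes, all ramping linearly over a configurable
window before the assigned onset time.  Every record carries a
ground-truth R-peak list so detection and feature recovery can be scored
exactly.

All outputs are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._phrases import ALL_PHRASES, RISK_PHRASES

__all__ = [
    "EffectProfile",
    "CohortConfig",
    "PatientProfile",
    "ECGRecord",
    "CohortConfigError",
    "generate_cohort",
    "generate_ecg",
    "generate_emr",
    "DEFAULT_GROUP_PROPORTIONS",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


# Demographic marginals of a mixed urban ICU population (sepsis study
# cohorts of this kind skew elderly); each vector sums to 1.
DEFAULT_GROUP_PROPORTIONS: dict[str, dict[str, float]] = {
    "gender": {"Male": 495 / 965, "Female": 470 / 965},
    "race": {
        "Black": 381 / 965,
        "White": 493 / 965,
        "Asian": 15 / 965,
        "Other": 6 / 965,
        "Unknown": 70 / 965,
    },
    "ethnicity": {
        "Hispanic or Latino": 16 / 965,
        "Non-Hispanic": 770 / 965,
        "Unknown": 179 / 965,
    },
    "age_bin": {"16-35": 94 / 965, "36-55": 311 / 965, "56+": 560 / 965},
}

# PQRST template: (time offset from R in s, amplitude, Gaussian sigma in s).
# Q/R/S belong to the QRS complex and are the bumps modulated by sepsis.
# P (PR interval 160 ms) and T (180 ms after R) sit inside a 200 ms
# refractory neighbourhood of the much larger R wave, so a
# threshold-plus-refractory detector sees exactly one peak per beat.
_PQRST = {
    "P": (-0.160, 0.08, 0.020),
    "Q": (-0.040, -0.04, 0.010),
    "R": (0.000, 1.00, 0.012),
    "S": (0.040, -0.05, 0.010),
    "T": (0.160, 0.12, 0.035),
}
_QRS_KEYS = ("Q", "R", "S")


@dataclass(frozen=True)
class EffectProfile:
    """Programmable effect sizes separating sepsis from non-sepsis records.

    ``ramp_hours`` is the window before onset over which all effects grow
    linearly from 0 to full strength; it is a free knob of the generator,
    not a physiological claim.
    """

    hr_baseline_bpm: float = 70.0
    hr_sepsis_delta_bpm: float = 30.0
    qrs_width_scale: float = 1.3
    qrs_amp_scale: float = 0.7
    hrv_sd_ms: float = 50.0
    hrv_sepsis_scale: float = 0.5
    ramp_hours: float = 6.0
    noise_sd: float = 0.02
    # Realism terms shared by both classes: respiratory amplitude
    # modulation, slow baseline wander and per-beat amplitude jitter.
    # They create the beat-to-beat amplitude spread that makes the R-peak
    # threshold setting matter (too low picks up noise, too high misses
    # low-amplitude beats).
    resp_mod_depth: float = 0.08
    resp_freq_hz: float = 0.25
    wander_amp: float = 0.05
    wander_freq_hz: float = 0.30
    amp_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.qrs_width_scale < 1:
            raise CohortConfigError("qrs_width_scale must be >= 1")
        if not 0 < self.qrs_amp_scale <= 1:
            raise CohortConfigError("qrs_amp_scale must be in (0, 1]")
        if not 0 < self.hrv_sepsis_scale <= 1:
            raise CohortConfigError("hrv_sepsis_scale must be in (0, 1]")
        if self.ramp_hours <= 0:
            raise CohortConfigError("ramp_hours must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    ``horizons`` (in units of ``horizon_unit_s``) determine how far before
    onset prediction windows will be placed downstream; onset times are
    drawn so that every horizon plus a block of analysis windows fits
    inside the record.  The default horizon unit is one hour; desk-scale
    runs shrink both the records and the horizon unit together (see
    :meth:`desk_scale`).
    """

    n_patients: int = 100
    sepsis_fraction: float = 514 / 965
    fs: float = 300.0
    record_hours: float = 8.0
    effect: EffectProfile = field(default_factory=EffectProfile)
    group_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_PROPORTIONS.items()}
    )
    horizons: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    horizon_unit_s: float = 3600.0
    onset_margin_s: float = 300.0
    comorbidities_per_patient: tuple[int, int] = (1, 5)
    emr_risk_odds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise CohortConfigError("n_patients must be positive")
        if not 0 <= self.sepsis_fraction <= 1:
            raise CohortConfigError("sepsis_fraction must be in [0, 1]")
        if self.fs <= 0:
            raise CohortConfigError("fs must be > 0")
        if self.record_hours <= 0:
            raise CohortConfigError("record_hours must be > 0")
        for col, probs in self.group_proportions.items():
            if not probs:
                raise CohortConfigError(f"group_proportions[{col!r}] is empty")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise CohortConfigError(
                    f"group_proportions[{col!r}] sums to {total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise CohortConfigError(f"group_proportions[{col!r}] has negative entries")
        if self.emr_risk_odds <= 0:
            raise CohortConfigError("emr_risk_odds must be > 0")

    @property
    def record_samples(self) -> int:
        return round(self.fs * self.record_hours * 3600.0)

    @property
    def horizon_max_s(self) -> float:
        return max(self.horizons) * self.horizon_unit_s

    @classmethod
    def desk_scale(cls, n_patients: int = 100, seed: int = 0, **overrides) -> "CohortConfig":
        """A scaled-down configuration for fast experimentation and testing.

        Records shrink from 8 h to 0.5 h and the horizon unit from 1 h to
        3 min, preserving the six-step horizon structure and the linear
        ramp geometry at 1/20 of the time scale.
        """
        effect = overrides.pop("effect", EffectProfile(ramp_hours=0.3))
        return cls(
            n_patients=n_patients,
            record_hours=0.5,
            horizon_unit_s=180.0,
            effect=effect,
            seed=seed,
            **overrides,
        )


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    label: str  # "sepsis" | "non-sepsis"
    onset_time_s: float | None
    age_bin: str
    gender: str
    race: str
    ethnicity: str
    comorbidity_texts: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == "sepsis") != (self.onset_time_s is not None):
            raise CohortConfigError("onset_time_s must be present iff label is sepsis")

    @property
    def is_sepsis(self) -> bool:
        return self.label == "sepsis"

    @property
    def index(self) -> int:
        return int(self.patient_id.lstrip("P"))


@dataclass
class ECGRecord:
    patient_id: str
    fs: float
    samples: np.ndarray
    ground_truth_r_peaks: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        self.ground_truth_r_peaks = np.asarray(self.ground_truth_r_peaks, dtype=np.int64)
        if np.any(np.diff(self.ground_truth_r_peaks) <= 0):
            raise ValueError("ground_truth_r_peaks must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _patient_rng(config: CohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    # Named substreams keyed on (master seed, patient, stage) so any single
    # patient's ECG or EMR can be regenerated independently and identically.
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, patient_index, stream])
    )


def _ramp_fraction(t_s: np.ndarray | float, onset_s: float, ramp_s: float) -> np.ndarray | float:
    """Linear 0→1 ramp over [onset − ramp, onset], clamped outside."""
    return np.clip((np.asarray(t_s, dtype=float) - (onset_s - ramp_s)) / ramp_s, 0.0, 1.0)


def generate_ecg(profile: PatientProfile, config: CohortConfig) -> ECGRecord:
    """Synthesize one patient's ECG record.

    The waveform is a sum of per-beat PQRST Gaussian-bump templates placed
    at R-R intervals drawn from a Gaussian, plus white noise.  For sepsis
    patients the QRS width, QRS amplitude, heart rate and R-R variability
    are modulated by the linear pre-onset ramp.
    """
    eff = config.effect
    fs = config.fs
    duration_s = config.record_hours * 3600.0
    ramp_s = eff.ramp_hours * 3600.0
    if ramp_s > duration_s:
        raise CohortConfigError(
            f"ramp_hours={eff.ramp_hours} exceeds record length {config.record_hours} h"
        )
    n_samples = config.record_samples
    rng = _patient_rng(config, profile.index, stream=1)

    onset_s = profile.onset_time_s if profile.is_sepsis else None

    # Sequential beat placement; instantaneous HR/HRV follow the ramp.
    beat_times: list[float] = []
    t = float(rng.uniform(0.0, 0.5))  # random phase of the first beat
    while t < duration_s - 0.35:  # leave room for the T wave
        beat_times.append(t)
        if onset_s is not None:
            r = float(_ramp_fraction(t, onset_s, ramp_s))
        else:
            r = 0.0
        hr = eff.hr_baseline_bpm + r * eff.hr_sepsis_delta_bpm
        sd = (eff.hrv_sd_ms / 1000.0) * (1.0 - r * (1.0 - eff.hrv_sepsis_scale))
        rr = 60.0 / hr + (float(rng.standard_normal()) * sd if sd > 0 else 0.0)
        t += max(rr, 0.3)  # refractory floor: no physiologic beat above 200 bpm

    beat_times_arr = np.asarray(beat_times)
    if onset_s is not None:
        ramps = np.asarray(_ramp_fraction(beat_times_arr, onset_s, ramp_s))
    else:
        ramps = np.zeros_like(beat_times_arr)

    clean = np.zeros(n_samples, dtype=np.float64)
    r_peaks = np.round(beat_times_arr * fs).astype(np.int64)
    resp_phase = float(rng.uniform(0.0, 2 * math.pi))
    wander_phase = float(rng.uniform(0.0, 2 * math.pi))
    for t_beat, r in zip(beat_times_arr, ramps):
        w_scale = 1.0 + r * (eff.qrs_width_scale - 1.0)
        a_scale = 1.0 - r * (1.0 - eff.qrs_amp_scale)
        beat_amp = 1.0
        if eff.resp_mod_depth > 0:
            beat_amp *= 1.0 + eff.resp_mod_depth * math.sin(
                2 * math.pi * eff.resp_freq_hz * t_beat + resp_phase
            )
        if eff.amp_jitter_sd > 0:
            beat_amp *= 1.0 + float(rng.normal(0.0, eff.amp_jitter_sd))
        beat_amp = max(beat_amp, 0.1)
        for key, (dt, amp, sigma) in _PQRST.items():
            if key in _QRS_KEYS:
                dt, amp, sigma = dt * w_scale, amp * a_scale, sigma * w_scale
            amp *= beat_amp
            center = t_beat + dt
            half = 4.0 * sigma
            lo = max(0, int(math.floor((center - half) * fs)))
            hi = min(n_samples, int(math.ceil((center + half) * fs)) + 1)
            if hi <= lo:
                continue
            tt = np.arange(lo, hi) / fs
            clean[lo:hi] += amp * np.exp(-0.5 * ((tt - center) / sigma) ** 2)

    if eff.wander_amp > 0:
        t_all = np.arange(n_samples) / fs
        clean += eff.wander_amp * np.sin(
            2 * math.pi * eff.wander_freq_hz * t_all + wander_phase
        )

    # The truth channel is the sampled waveform's actual R maximum: snap
    # each rounded beat time to the local argmax of the noise-free signal.
    for i, p in enumerate(r_peaks):
        lo = max(int(p) - 2, 0)
        hi = min(int(p) + 3, n_samples)
        if hi > lo:
            r_peaks[i] = lo + int(np.argmax(clean[lo:hi]))

    if eff.noise_sd > 0:
        clean += rng.normal(0.0, eff.noise_sd, size=n_samples)

    keep = (r_peaks >= 1) & (r_peaks < n_samples - 1)
    return ECGRecord(
        patient_id=profile.patient_id,
        fs=fs,
        samples=clean,
        ground_truth_r_peaks=r_peaks[keep],
    )


def generate_emr(
    profile_seed: int, config: CohortConfig, is_sepsis: bool
) -> tuple[dict[str, str], tuple[str, ...]]:
    """Draw demographics and comorbidity phrases for one patient.

    Categorical fields follow ``config.group_proportions``.  Comorbidity
    phrases are sampled without replacement from the bundled dictionary;
    for sepsis patients the designated risk-phrase subset has its sampling
    odds multiplied by ``config.emr_risk_odds``.
    """
    if not ALL_PHRASES:
        raise CohortConfigError("phrase dictionary is empty")
    rng = _patient_rng(config, profile_seed, stream=2)
    demographics: dict[str, str] = {}
    for col in ("age_bin", "gender", "race", "ethnicity"):
        probs = config.group_proportions[col]
        cats = sorted(probs)
        p = np.asarray([probs[c] for c in cats], dtype=float)
        demographics[col] = cats[int(rng.choice(len(cats), p=p / p.sum()))]

    odds = config.emr_risk_odds if is_sepsis else 1.0
    weights = np.asarray(
        [odds if ph in RISK_PHRASES else 1.0 for ph in ALL_PHRASES], dtype=float
    )
    lo, hi = config.comorbidities_per_patient
    n_phrases = int(rng.integers(lo, hi + 1))
    n_phrases = min(n_phrases, len(ALL_PHRASES))
    idx = rng.choice(
        len(ALL_PHRASES), size=n_phrases, replace=False, p=weights / weights.sum()
    )
    return demographics, tuple(ALL_PHRASES[i] for i in sorted(idx))


def generate_profile(i: int, is_sepsis: bool, config: CohortConfig) -> PatientProfile:
    """Build patient ``i``'s profile (label, onset, demographics, EMR text)."""
    rng = _patient_rng(config, i, stream=0)
    duration_s = config.record_hours * 3600.0
    onset: float | None = None
    if is_sepsis:
        lo = config.horizon_max_s + config.onset_margin_s
        hi = duration_s - 30.0
        if hi <= lo:
            raise CohortConfigError(
                f"record_hours={config.record_hours} too short for horizon_max_s="
                f"{config.horizon_max_s} plus onset_margin_s={config.onset_margin_s}"
            )
        onset = float(rng.uniform(lo, hi))
    demographics, phrases = generate_emr(i, config, is_sepsis)
    return PatientProfile(
        patient_id=f"P{i:04d}",
        label="sepsis" if is_sepsis else "non-sepsis",
        onset_time_s=onset,
        comorbidity_texts=phrases,
        **demographics,
    )


def generate_cohort(config: CohortConfig) -> list[tuple[PatientProfile, ECGRecord]]:
    """Generate the full cohort: exactly ``round(n × sepsis_fraction)``
    sepsis patients, each with a profile and an ECG record.

    Deterministic given ``config`` (including its seed).  For large
    cohorts prefer :func:`iter_cohort`, which yields patients one at a
    time without holding every record in memory.
    """
    return list(iter_cohort(config))


def iter_cohort(config: CohortConfig):
    """Yield ``(PatientProfile, ECGRecord)`` pairs one patient at a time."""
    for profile in cohort_profiles(config):
        yield profile, generate_ecg(profile, config)


def cohort_profiles(config: CohortConfig) -> list[PatientProfile]:
    """All patient profiles (no waveforms); sepsis patients come first."""
    n_sepsis = round(config.n_patients * config.sepsis_fraction)
    return [
        generate_profile(i, i < n_sepsis, config) for i in range(config.n_patients)
    ]


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
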