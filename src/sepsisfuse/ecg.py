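"""On-sensor ECG pre-processing and time-domain feature extraction.

The pipeline mirrors what a low-power feature extractor computes on-chip:
each 9000-sample (30 s at 300 Hz) segment is min-max normalized to [0, 1],
baseline wander is removed by subtracting the segment median, R peaks are
found by amplitude thresholding at 30% of the segment's dynamic range, and
14 time-domain features are computed — first-order amplitude statistics,
R-peak statistics, R-R interval statistics and mean heart rate.  Only
time-domain quantities are used; frequency-domain features are deliberately
out of scope (they are too power-hungry for an on-sensor implementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .cohort import CohortConfig, ECGRecord, PatientProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ECGWindow",
    "FeatureVector",
    "PeakConfig",
    "DegenerateWindowError",
    "FEATURE_NAMES",
    "normalize_window",
    "remove_baseline",
    "segment",
    "detect_r_peaks",
    "extract_features",
    "label_windows",
]

#: Canonical feature order; the analog classifier's 14 inputs.
FEATURE_NAMES: tuple[str, ...] = (
    "amplitude_mean",
    "amplitude_median",
    "amplitude_mode",
    "amplitude_std",
    "amplitude_variance",
    "amplitude_skewness",
    "amplitude_kurtosis",
    "r_peak_count",
    "r_amplitude_mean",
    "r_amplitude_variance",
    "rr_mean_s",
    "rr_std_s",
    "rr_rmssd_s",
    "heart_rate_bpm",
)

_MODE_BINS = 16  # histogram bins over [0,1] for the amplitude mode


class DegenerateWindowError(ValueError):
    """Raised for constant windows (max == min), which cannot be normalized."""


@dataclass(frozen=True)
class PeakConfig:
    """R-peak detector settings.

    ``threshold_frac`` is the fraction of the segment's (max − min) above
    the minimum that a local maximum must exceed.  ``refractory_s``
    enforces a physiological minimum inter-beat gap (0.2 s ≈ 300 bpm upper
    bound); among candidates closer than this, only the largest survives
    (ties break to the earliest index).
    """

    threshold_frac: float = 0.30
    refractory_s: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass
class ECGWindow:
    """One fixed-length, pre-processed analysis segment.

    ``samples`` hold the normalized, median-removed signal; the subtracted
    median is kept so the pre-baseline-removal [0, 1] signal (needed for
    the histogram amplitude mode) can be recovered as
    ``samples + baseline_median``.
    """

    samples: np.ndarray
    fs: float
    start_index: int
    patient_id: str
    baseline_median: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class FeatureVector:
    """The 14 time-domain features of one window, plus provenance."""

    values: tuple[float, ...]
    patient_id: str
    start_index: int
    horizon: int | None = None
    sparse_peaks: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}")
        if not all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]


def normalize_window(samples: np.ndarray) -> np.ndarray:
    """Affinely map a segment onto [0, 1] (min → 0, max → 1)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateWindowError("constant window cannot be normalized")
    return (x - lo) / (hi - lo)


def remove_baseline(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the window median (baseline-wander removal).

    Returns the corrected signal and the median that was removed.
    """
    x = np.asarray(samples, dtype=np.float64)
    med = float(np.median(x))
    return x - med, med


def segment(
    record: ECGRecord,
    window_samples: int = 9000,
    stride_samples: int | None = None,
    start_sample: int = 0,
    max_windows: int | None = None,
) -> list[ECGWindow]:
    """Cut a record into fixed-length windows and pre-process each one.

    Windows are consecutive and non-overlapping by default (stride equals
    the window length); a trailing partial window is discarded.  Each
    window is normalized to [0, 1] and then median-baseline-removed, in
    that order.  Constant (degenerate) windows are skipped with a warning.
    """
    if stride_samples is None:
        stride_samples = window_samples
    if stride_samples <= 0 or window_samples <= 0:
        raise ValueError("window_samples and stride_samples must be positive")
    n = len(record.samples)
    if n - start_sample < window_samples:
        raise ValueError(
            f"record has {n - start_sample} usable samples; "
            f"at least {window_samples} required"
        )
    windows: list[ECGWindow] = []
    for start in range(start_sample, n - window_samples + 1, stride_samples):
        raw = record.samples[start : start + window_samples]
        try:
            norm = normalize_window(raw)
        except DegenerateWindowError:
            logger.warning(
                "skipping degenerate (constant) window at sample %d of %s",
                start, record.patient_id,
            )
            continue
        corrected, med = remove_baseline(norm)
        windows.append(
            ECGWindow(
                samples=corrected,
                fs=record.fs,
                start_index=start,
                patient_id=record.patient_id,
                baseline_median=med,
            )
        )
        if max_windows is not None and len(windows) >= max_windows:
            break
    return windows


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior indices that start a (possibly flat) local maximum:
    strictly above the previous sample and at least as high as the next."""
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def detect_r_peaks(window: ECGWindow, cfg: PeakConfig = PeakConfig()) -> np.ndarray:
    """Threshold-based R-peak detection on a pre-processed window.

    Candidates are local maxima above ``min + threshold_frac × (max − min)``
    of the window itself; a greedy refractory pass keeps the largest
    candidate within each ``refractory_s`` neighbourhood (earliest index on
    amplitude ties).  Candidates closer than ``refractory_s`` to the window
    edge are dropped: their neighbourhood is truncated, so a streaming
    detector cannot confirm them (they belong to the adjacent window).
    A constant window yields no peaks.
    """
    x = window.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.asarray([], dtype=np.int64)
    threshold = lo + cfg.threshold_frac * (hi - lo)
    candidates = _local_maxima(x)
    candidates = candidates[x[candidates] > threshold]
    edge = int(round(cfg.refractory_s * window.fs))
    if edge > 0:
        candidates = candidates[(candidates >= edge) & (candidates < x.size - edge)]
    if candidates.size == 0:
        return candidates.astype(np.int64)
    refractory = int(round(cfg.refractory_s * window.fs))
    if refractory <= 0:
        return np.sort(candidates).astype(np.int64)
    # Greedy: take candidates by descending amplitude (earliest first on
    # ties), suppressing anything within the refractory distance.
    order = sorted(range(candidates.size), key=lambda i: (-x[candidates[i]], candidates[i]))
    kept: list[int] = []
    for i in order:
        c = int(candidates[i])
        if all(abs(c - k) >= refractory for k in kept):
            kept.append(c)
    return np.asarray(sorted(kept), dtype=np.int64)


def extract_features(
    window: ECGWindow,
    peaks: np.ndarray,
    fs: float | None = None,
    horizon: int | None = None,
) -> FeatureVector:
    """Compute the 14 time-domain features of one window.

    Amplitude statistics use the median-removed signal except the mode,
    which is the midpoint of the fullest of 16 equal-width histogram bins
    over the pre-baseline-removal [0, 1] signal (lowest bin on ties).
    R-R intervals are ``diff(peaks)/fs`` in seconds; mean heart rate is
    ``60 × (count − 1) / elapsed`` between the first and last peak.  With
    fewer than 2 peaks the rate features are 0 and the vector carries a
    sparse-peaks flag; R-R dispersion features are 0 with fewer than 3.
    """
    if fs is None:
        fs = window.fs
    x = window.samples
    peaks = np.asarray(peaks, dtype=np.int64)

    pre_baseline = x + window.baseline_median  # back on the [0, 1] scale
    counts, edges = np.histogram(pre_baseline, bins=_MODE_BINS, range=(0.0, 1.0))
    k = int(np.argmax(counts))  # argmax takes the lowest bin on ties
    mode = float((edges[k] + edges[k + 1]) / 2.0)

    n_peaks = int(peaks.size)
    sparse = n_peaks < 2
    if n_peaks >= 1:
        r_amp = x[peaks]
        r_amp_mean = float(r_amp.mean())
        r_amp_var = float(r_amp.var())
    else:
        r_amp_mean = r_amp_var = 0.0
    if n_peaks >= 2:
        rr = np.diff(peaks) / fs
        rr_mean = float(rr.mean())
        heart_rate = 60.0 / rr_mean
    else:
        rr_mean = heart_rate = 0.0
    if n_peaks >= 3:
        rr = np.diff(peaks) / fs
        rr_std = float(rr.std())
        rr_rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    else:
        rr_std = rr_rmssd = 0.0

    values = (
        float(x.mean()),
        float(np.median(x)),
        mode,
        float(x.std()),
        float(x.var()),
        float(sstats.skew(x)),
        float(sstats.kurtosis(x)),  # Fisher convention, uncorrected
        float(n_peaks),
        r_amp_mean,
        r_amp_var,
        rr_mean,
        rr_std,
        rr_rmssd,
        heart_rate,
    )
    return FeatureVector(
        values=values,
        patient_id=window.patient_id,
        start_index=window.start_index,
        horizon=horizon,
        sparse_peaks=sparse,
    )


def label_windows(
    record: ECGRecord,
    profile: PatientProfile,
    horizon_h: int,
    config: CohortConfig | None = None,
    *,
    horizon_unit_s: float | None = None,
    k: int = 10,
    window_samples: int = 9000,
    peak_cfg: PeakConfig = PeakConfig(),
) -> list[tuple[FeatureVector, int]]:
    """Emit ``k`` labelled feature vectors for one patient at one horizon.

    For sepsis patients the positive windows are the ``k`` consecutive
    windows ending ``horizon_h`` horizon units before onset.  Non-sepsis
    patients contribute negative windows at the matched offset computed
    from a pseudo-onset at ``record_end − 30 s``, so negative windows
    shift with the horizon exactly as positives do.

    Returns an empty list (with a warning) when the record is too short
    for the requested placement.
    """
    if horizon_unit_s is None:
        horizon_unit_s = config.horizon_unit_s if config is not None else 3600.0
    fs = record.fs
    if profile.is_sepsis:
        anchor_s = profile.onset_time_s
        label = 1
    else:
        anchor_s = record.duration_s - 30.0
        label = 0
    end_sample = int(round((anchor_s - horizon_h * horizon_unit_s) * fs))
    start_sample = end_sample - k * window_samples
    if start_sample < 0 or end_sample > len(record.samples):
        logger.warning(
            "patient %s skipped at horizon %d: record too short for placement",
            profile.patient_id, horizon_h,
        )
        return []
    windows = segment(
        record,
        window_samples=window_samples,
        start_sample=start_sample,
        max_windows=k,
    )
    out: list[tuple[FeatureVector, int]] = []
    for w in windows:
        peaks = detect_r_peaks(w, peak_cfg)
        out.append((extract_features(w, peaks, horizon=horizon_h), label))
    return out
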