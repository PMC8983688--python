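"""Pre-processing, R-peak detection and the 14 time-domain features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sepsisfuse.cohort import cohort_profiles, generate_ecg
from sepsisfuse.ecg import (
    DegenerateWindowError,
    ECGWindow,
    FEATURE_NAMES,
    PeakConfig,
    detect_r_peaks,
    extract_features,
    label_windows,
    normalize_window,
    remove_baseline,
    segment,
)


# ---------------------------------------------------------------- normalize

def test_normalize_affine_example():
    assert normalize_window([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]


def test_normalize_identity_on_unit_range():
    x = np.array([0.0, 0.25, 1.0])
    assert np.array_equal(normalize_window(x), x)


def test_normalize_constant_window_raises():
    with pytest.raises(DegenerateWindowError):
        normalize_window(np.full(10, 3.3))


@settings(max_examples=50, deadline=None)
@given(
    hnp.arrays(
        np.float64, st.integers(5, 200),
        elements=st.floats(-50, 50, allow_nan=False),
    ).filter(lambda a: a.max() > a.min())
)
def test_normalize_range_and_order_preserved(x):
    z = normalize_window(x)
    assert z.min() == 0.0 and z.max() == 1.0
    # order is (weakly) preserved by the affine map
    assert np.all(np.diff(z[np.argsort(x, kind="stable")]) >= 0)


# ------------------------------------------------------------ baseline removal

def test_remove_baseline_median_example():
    out, med = remove_baseline(np.array([1.0, 2.0, 3.0]))
    assert med == 2.0
    assert out.tolist() == [-1.0, 0.0, 1.0]


def test_remove_baseline_sine_with_offset():
    t = np.arange(9000)
    x = np.sin(2 * np.pi * t / 500) + 0.4
    out, med = remove_baseline(x)
    assert med == pytest.approx(np.median(x))
    assert np.allclose(out, x - np.median(x))
    assert abs(np.median(out)) < 1e-12


# ----------------------------------------------------------------- segment

@pytest.mark.parametrize(
    "n,stride,expected_starts",
    [
        (27000, None, [0, 9000, 18000]),
        (26999, None, [0, 9000]),
        (27000, 4500, [0, 4500, 9000, 13500, 18000]),
    ],
)
def test_segment_counts(n, stride, expected_starts, rng):
    from sepsisfuse.cohort import ECGRecord

    rec = ECGRecord("p", 300.0, rng.normal(size=n), np.array([1, 2]))
    wins = segment(rec, 9000, stride_samples=stride)
    assert [w.start_index for w in wins] == expected_starts
    for w in wins:
        assert len(w.samples) == 9000
        # pre-processing applied: normalized then median-removed
        assert abs(np.median(w.samples)) < 1e-12
        restored = w.samples + w.baseline_median
        assert restored.min() == pytest.approx(0.0, abs=1e-12)
        assert restored.max() == pytest.approx(1.0, abs=1e-12)


def test_segment_too_short_record_errors(rng):
    from sepsisfuse.cohort import ECGRecord

    rec = ECGRecord("p", 300.0, rng.normal(size=100), np.array([1, 2]))
    with pytest.raises(ValueError, match="9000"):
        segment(rec, 9000)


# ------------------------------------------------------------- peak detection

def _brute_force_peaks(x, fs, threshold_frac, refractory_s):
    """Independent enumeration oracle: local-max test at every interior
    index, amplitude threshold, then iterative greedy refractory pruning."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return []
    thr = lo + threshold_frac * (hi - lo)
    refractory = int(round(refractory_s * fs))
    candidates = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] >= x[i + 1] and x[i] > thr
        and refractory <= i < len(x) - refractory
    ]
    kept = []
    for c in sorted(candidates, key=lambda i: (-x[i], i)):
        if all(abs(c - k) >= refractory for k in kept):
            kept.append(c)
    return sorted(kept)


def test_detect_constant_window_empty():
    w = ECGWindow(np.zeros(600), fs=300.0, start_index=0, patient_id="p")
    assert detect_r_peaks(w).size == 0


def test_detect_single_triangular_pulse():
    x = np.zeros(600)
    x[40:101] = np.linspace(0.0, 1.0, 61)
    x[100:161] = np.linspace(1.0, 0.0, 61)
    w = ECGWindow(x, fs=300.0, start_index=0, patient_id="p")
    assert detect_r_peaks(w, PeakConfig(threshold_frac=0.3)).tolist() == [100]


@pytest.mark.parametrize("threshold_frac", [0.1, 0.3, 0.6])
def test_detect_matches_brute_force_oracle(rng, threshold_frac):
    for _ in range(10):
        x = rng.normal(size=rng.integers(300, 2000))
        x[rng.integers(60, len(x) - 60, size=5)] += 4.0
        w = ECGWindow(x, fs=300.0, start_index=0, patient_id="p")
        got = detect_r_peaks(w, PeakConfig(threshold_frac=threshold_frac)).tolist()
        want = _brute_force_peaks(x, 300.0, threshold_frac, 0.20)
        assert got == want


def test_detection_exact_on_noise_free_ecg(clean_config):
    """Without noise, detection recovers the generator's truth peaks
    exactly (edge-margin peaks excluded: the streaming detector defers
    peaks whose refractory neighbourhood is truncated)."""
    profile = cohort_profiles(clean_config)[0]
    rec = generate_ecg(profile, clean_config)
    margin = 60  # refractory_s * fs
    for w in segment(rec, max_windows=12):
        det = detect_r_peaks(w) + w.start_index
        truth = rec.ground_truth_r_peaks
        interior = truth[
            (truth >= w.start_index + margin) & (truth < w.start_index + 9000 - margin)
        ]
        assert np.array_equal(det, interior)


def test_detection_close_to_truth_under_noise(small_config, small_cohort):
    profiles, records = small_cohort
    rec = records[profiles[0].patient_id]
    hits = total = 0
    for w in segment(rec, max_windows=5):
        det = detect_r_peaks(w) + w.start_index
        truth = rec.ground_truth_r_peaks
        for d in det:
            total += 1
            hits += np.abs(truth - d).min() <= 5
    assert total > 100
    assert hits / total > 0.99


# ------------------------------------------------------------------ features

def test_feature_vector_has_exactly_14_values(rng):
    w = ECGWindow(rng.normal(size=9000), fs=300.0, start_index=0, patient_id="p")
    fv = extract_features(w, detect_r_peaks(w))
    assert len(fv.values) == 14
    assert len(FEATURE_NAMES) == 14
    assert all(np.isfinite(fv.values))


def test_uniform_peak_spacing_features():
    x = np.zeros(9000)
    peaks = np.arange(0, 9000, 300)  # one peak per second at 300 Hz
    x[peaks] = 1.0
    w = ECGWindow(x, fs=300.0, start_index=0, patient_id="p")
    fv = extract_features(w, peaks)
    assert fv["rr_mean_s"] == pytest.approx(1.0)
    assert fv["rr_std_s"] == 0.0
    assert fv["rr_rmssd_s"] == 0.0
    assert fv["heart_rate_bpm"] == pytest.approx(60.0)
    assert fv["r_peak_count"] == len(peaks)


def test_amplitude_moments_match_direct_summation(rng):
    """Mean/median/variance/skewness/kurtosis against an independent
    direct-summation oracle (population moments, Fisher kurtosis)."""
    x = rng.normal(size=9000)
    w = ECGWindow(x, fs=300.0, start_index=0, patient_id="p")
    fv = extract_features(w, np.array([], dtype=int))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    assert fv["amplitude_mean"] == pytest.approx(mu, abs=1e-9)
    assert fv["amplitude_median"] == pytest.approx(float(np.median(x)), abs=1e-12)
    assert fv["amplitude_variance"] == pytest.approx(m2, abs=1e-9)
    assert fv["amplitude_skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-9)
    assert fv["amplitude_kurtosis"] == pytest.approx(m4 / m2**2 - 3.0, abs=1e-9)
    assert fv.sparse_peaks  # no peaks supplied


def test_sparse_peaks_flagged_and_rates_zero(rng):
    w = ECGWindow(rng.normal(size=9000), fs=300.0, start_index=0, patient_id="p")
    fv = extract_features(w, np.array([4000]))
    assert fv.sparse_peaks
    assert fv["heart_rate_bpm"] == 0.0
    assert fv["rr_mean_s"] == 0.0


def test_features_invariant_under_time_translation(rng):
    """Rolling the window and shifting the peaks by the same offset leaves
    every feature unchanged: all 14 are time-shift invariant."""
    x = rng.normal(size=9000)
    peaks = np.sort(rng.choice(np.arange(100, 8000), size=25, replace=False))
    w1 = ECGWindow(x, fs=300.0, start_index=0, patient_id="p", baseline_median=0.3)
    shift = 700
    w2 = ECGWindow(np.roll(x, shift), fs=300.0, start_index=0, patient_id="p",
                   baseline_median=0.3)
    f1 = extract_features(w1, peaks)
    f2 = extract_features(w2, peaks + shift)
    # equality up to summation-order rounding from the roll
    assert f2.values == pytest.approx(f1.values, rel=1e-9, abs=1e-12)


# -------------------------------------------------------------- label_windows

def test_label_window_placement_arithmetic(small_config, small_cohort):
    profiles, records = small_cohort
    sep = next(p for p in profiles if p.is_sepsis)
    rec = records[sep.patient_id]
    pairs = label_windows(rec, sep, 2, small_config, k=1)
    assert len(pairs) == 1
    fv, label = pairs[0]
    assert label == 1
    expected_end = int(round((sep.onset_time_s - 2 * small_config.horizon_unit_s) * 300))
    assert fv.start_index == expected_end - 9000
    assert fv.horizon == 2


def test_non_sepsis_windows_all_negative(small_config, small_cohort):
    profiles, records = small_cohort
    non = next(p for p in profiles if not p.is_sepsis)
    pairs = label_windows(records[non.patient_id], non, 1, small_config, k=4)
    assert len(pairs) == 4
    assert all(label == 0 for _, label in pairs)


def test_too_short_record_skips_patient(small_config, small_cohort):
    profiles, records = small_cohort
    sep = next(p for p in profiles if p.is_sepsis)
    pairs = label_windows(records[sep.patient_id], sep, 40, small_config, k=10)
    assert pairs == []
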