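"""Readers, writers and run configuration.

File formats are deliberately plain: ECG as CSV with a ``# fs=<Hz>``
metadata line and one sample per row, EMR and truth-peak tables as CSV,
model checkpoints as JSON, run configuration as flat YAML with a resolved
JSON snapshot written next to every run's outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, ECGRecord, EffectProfile, PatientProfile, iter_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "UnsupportedFormatError",
    "read_ecg",
    "write_ecg",
    "write_cohort",
    "read_emr",
    "RunConfig",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file and location."""


class UnsupportedFormatError(FormatError):
    """Requested a format this build does not provide."""


def write_ecg(record: ECGRecord, path: str | Path) -> Path:
    """Write one record as CSV: ``# fs=<Hz>`` metadata line, then one
    sample per row under a ``sample`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write("sample\n")
        np.savetxt(fh, np.asarray(record.samples, dtype=np.float64), fmt="%.7g")
    return path


def read_ecg(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read one ECG record.

    Only the CSV layout written by :func:`write_ecg` is supported; the
    sampling rate must be present in the metadata line.  Non-numeric or
    NaN samples raise :class:`FormatError` naming the offending row.
    """
    path = Path(path)
    if format == "wfdb":
        raise UnsupportedFormatError(
            "WFDB input is not available in this build; convert to CSV "
            "(one sample per row with a '# fs=<Hz>' header line)"
        )
    if format != "csv":
        raise UnsupportedFormatError(f"unknown ECG format {format!r}")
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise FormatError(f"{path}: missing '# fs=<Hz>' metadata line")
        try:
            fs = float(first.removeprefix("# fs="))
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable sampling rate {first!r}") from exc
        header = fh.readline().strip()
        if header != "sample":
            raise FormatError(f"{path}: expected 'sample' column header, got {header!r}")
        samples = []
        for lineno, line in enumerate(fh, start=3):
            text = line.strip()
            if not text:
                continue
            try:
                v = float(text)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric sample at row {lineno}") from exc
            if np.isnan(v):
                raise FormatError(f"{path}: NaN sample at row {lineno}")
            samples.append(v)
    return ECGRecord(
        patient_id=path.stem,
        fs=fs,
        samples=np.asarray(samples),
        ground_truth_r_peaks=np.asarray([], dtype=np.int64).reshape(0),
    )


def write_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Materialize a synthetic cohort on disk.

    Writes ``emr.csv`` (demographics, pipe-delimited comorbidities, label,
    onset), one ``ecg/<patient>.csv`` per record, and
    ``truth_peaks/<patient>.csv`` as the generator's ground-truth R-peak
    side channel.
    """
    out_dir = Path(out_dir)
    (out_dir / "ecg").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth_peaks").mkdir(parents=True, exist_ok=True)
    rows = []
    for profile, record in iter_cohort(config):
        write_ecg(record, out_dir / "ecg" / f"{profile.patient_id}.csv")
        pd.DataFrame({"r_peak_index": record.ground_truth_r_peaks}).to_csv(
            out_dir / "truth_peaks" / f"{profile.patient_id}.csv", index=False
        )
        rows.append(
            {
                "patient_id": profile.patient_id,
                "age_bin": profile.age_bin,
                "gender": profile.gender,
                "race": profile.race,
                "ethnicity": profile.ethnicity,
                "comorbidities": "|".join(profile.comorbidity_texts),
                "label": profile.label,
                "onset_time_s": profile.onset_time_s,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "emr.csv", index=False)
    snapshot = dataclasses.asdict(config)
    with open(out_dir / "cohort_config.json", "w") as fh:
        json.dump(snapshot, fh, indent=1, default=str)
    return out_dir


def read_emr(path: str | Path) -> pd.DataFrame:
    """Read the EMR table written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "age_bin", "gender", "race", "ethnicity", "comorbidities"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing EMR columns {sorted(missing)}")
    df["comorbidities"] = df["comorbidities"].fillna("")
    return df.set_index("patient_id", drop=False)


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    out_dir: str = "runs/demo"
    n_patients: int = 60
    record_hours: float = 0.5
    horizon_unit_s: float = 180.0
    horizons: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    window_samples: int = 9000
    threshold_frac: float = 0.30
    k_windows: int = 10
    dac_bits: int = 4
    arch: tuple[int, ...] = (20, 6)
    max_features: int = 20
    split: float = 0.8
    epochs: int = 60
    meta_types: tuple[str, ...] = ("logistic",)
    emr_model: str = "random_forest"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("horizons", "arch", "meta_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def snapshot(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    def cohort_config(self) -> CohortConfig:
        ramp_hours = max(self.horizons) * self.horizon_unit_s / 3600.0
        return CohortConfig(
            n_patients=self.n_patients,
            record_hours=self.record_hours,
            horizons=self.horizons,
            horizon_unit_s=self.horizon_unit_s,
            effect=EffectProfile(ramp_hours=ramp_hours),
            seed=self.seed,
        )


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the evaluation bundle's CSVs.

    Stages: simulate → featurize → train ECG per horizon → train EMR →
    fuse → evaluate → disparity → report.  The feature table is cached in
    the output directory keyed on the relevant settings and reused when
    they match.
    """
    from .analog import TrainConfig
    from .ecg import PeakConfig
    from .pipeline import featurize_cohort, run_study

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.snapshot(out / "run_config.json")
    cohort_cfg = config.cohort_config()

    cache_key = json.dumps(
        {
            "n": config.n_patients, "hours": config.record_hours,
            "unit": config.horizon_unit_s, "horizons": config.horizons,
            "window": config.window_samples, "threshold": config.threshold_frac,
            "k": config.k_windows, "seed": config.seed,
        },
        sort_keys=True, default=str,
    )
    cache_file = out / "features.csv"
    key_file = out / "features.key"
    features = None
    if cache_file.exists() and key_file.exists() and key_file.read_text() == cache_key:
        logger.info("reusing cached features from %s", cache_file)
        features = pd.read_csv(cache_file, dtype={"patient_id": str})
    if features is None:
        features = featurize_cohort(
            cohort_cfg,
            config.horizons,
            k=config.k_windows,
            window_samples=config.window_samples,
            peak_cfg=PeakConfig(threshold_frac=config.threshold_frac),
        )
        features.to_csv(cache_file, index=False)
        key_file.write_text(cache_key)

    bundle = run_study(
        cohort_cfg,
        seed=config.seed,
        meta_types=config.meta_types,
        emr_model_type=config.emr_model,
        ecg_train_cfg=TrainConfig(seed=config.seed, epochs=config.epochs),
        k=config.k_windows,
        window_samples=config.window_samples,
        peak_cfg=PeakConfig(threshold_frac=config.threshold_frac),
        split=config.split,
        features=features,
    )
    bundle["metrics"].to_csv(out / "metrics.csv", index=False)
    for name, table in bundle["disparity"].items():
        table.to_csv(out / f"disparity_{name}.csv", index=False)
    for setting, table in bundle["scores"].items():
        table.to_csv(out / f"scores_setting{setting}.csv", index=False)
    logger.info("evaluation bundle written to %s", out)
    return bundle
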