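"""End-to-end experiment orchestration.

Ties the stages together: synthesize (or load) a cohort, extract labelled
ECG feature windows per prediction horizon, train the analog ECG
classifier per horizon, train the EMR classifiers (demographics-only and
demographics+comorbidity), fuse with a meta-learner per horizon and
setting, and evaluate with subgroup fairness tables.  One master seed fans
out to named per-stage substreams; two runs from the same master seed are
identical.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import fusion
from .analog import AnalogANN, TrainConfig, patient_split, train_error_aware
from .cohort import CohortConfig, ECGRecord, PatientProfile, generate_ecg, cohort_profiles
from .ecg import FEATURE_NAMES, PeakConfig, label_windows
from .emr import EMRFeaturizer, train_emr

logger = logging.getLogger(__name__)

__all__ = [
    "featurize_cohort",
    "profiles_frame",
    "train_ecg_models",
    "run_study",
    "sweep",
]


def profiles_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Patient table (one row per patient) from a list of profiles."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "label": [1 if p.is_sepsis else 0 for p in profiles],
            "onset_time_s": [p.onset_time_s for p in profiles],
            "age_bin": [p.age_bin for p in profiles],
            "gender": [p.gender for p in profiles],
            "race": [p.race for p in profiles],
            "ethnicity": [p.ethnicity for p in profiles],
            "comorbidities": ["|".join(p.comorbidity_texts) for p in profiles],
        }
    ).set_index("patient_id", drop=False)


def featurize_cohort(
    config: CohortConfig,
    horizons: tuple[int, ...] | None = None,
    k: int = 10,
    window_samples: int = 9000,
    peak_cfg: PeakConfig = PeakConfig(),
    records: dict[str, ECGRecord] | None = None,
    profiles: list[PatientProfile] | None = None,
) -> pd.DataFrame:
    """Labelled feature windows for every patient at every horizon.

    Records are generated (or taken from ``records``) one patient at a
    time, so memory stays flat in the cohort size.  Returns a tidy frame
    with the 14 feature columns plus patient_id, start_index, horizon,
    label, and a count of skipped (patient, horizon) placements in
    ``.attrs["skipped"]``.
    """
    if horizons is None:
        horizons = config.horizons
    if profiles is None:
        profiles = cohort_profiles(config)
    rows: list[dict] = []
    skipped = 0
    for profile in profiles:
        if records is not None:
            record = records[profile.patient_id]
        else:
            record = generate_ecg(profile, config)
        for h in horizons:
            pairs = label_windows(
                record, profile, h, config,
                k=k, window_samples=window_samples, peak_cfg=peak_cfg,
            )
            if not pairs:
                skipped += 1
                continue
            for fv, label in pairs:
                row = dict(zip(FEATURE_NAMES, fv.values))
                row.update(
                    patient_id=fv.patient_id,
                    start_index=fv.start_index,
                    horizon=h,
                    label=label,
                )
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    if skipped:
        logger.warning("%d (patient, horizon) placements skipped (record too short)", skipped)
    return out


def train_ecg_models(
    features: pd.DataFrame,
    horizons: tuple[int, ...],
    train_ids: set[str],
    cfg: TrainConfig,
    arch: tuple[int, ...] = (20, 6),
    dac_bits: int = 4,
    mode: str = "analog",
) -> tuple[dict[int, AnalogANN], pd.DataFrame]:
    """Fit one analog classifier per horizon on training-side windows.

    Returns the per-horizon models and a window-level score table over
    *all* rows (training and held-out), for downstream fusion.
    """
    X_cols = list(FEATURE_NAMES)
    models: dict[int, AnalogANN] = {}
    score_rows = []
    for h in horizons:
        sub = features[features["horizon"] == h]
        tr = sub[sub["patient_id"].isin(train_ids)]
        ann = AnalogANN(
            layer_sizes=(len(X_cols), *arch, 1), dac_bits=dac_bits, mode=mode
        ).init_weights(cfg.seed + h)
        ann, _ = train_error_aware(
            tr[X_cols].to_numpy(),
            tr["label"].to_numpy(dtype=float),
            tr["patient_id"].to_numpy(),
            ann=ann,
            cfg=cfg,
            masks=(np.ones(len(tr), dtype=bool), np.zeros(len(tr), dtype=bool)),
        )
        models[h] = ann
        scores = ann.forward(sub[X_cols].to_numpy())
        score_rows.append(
            pd.DataFrame(
                {
                    "patient_id": sub["patient_id"].to_numpy(),
                    "horizon": h,
                    "start_index": sub["start_index"].to_numpy(),
                    "label": sub["label"].to_numpy(),
                    "score": scores,
                }
            )
        )
    return models, pd.concat(score_rows, ignore_index=True)


def run_study(
    config: CohortConfig,
    seed: int = 0,
    horizons: tuple[int, ...] | None = None,
    settings: tuple[int, ...] = (1, 2),
    meta_types: tuple[str, ...] = ("logistic",),
    emr_model_type: str = "random_forest",
    ecg_train_cfg: TrainConfig | None = None,
    k: int = 10,
    window_samples: int = 9000,
    peak_cfg: PeakConfig = PeakConfig(),
    split: float = 0.8,
    aggregate: str = "mean",
    disparity_attrs: tuple[str, ...] = ("race", "gender", "ethnicity", "age_bin"),
    features: pd.DataFrame | None = None,
    profiles: list[PatientProfile] | None = None,
) -> dict:
    """Run the complete fusion study on a synthetic cohort.

    One patient-level 80/20 split drives everything: the per-horizon ECG
    models, both EMR models and every meta-learner are fitted on the
    training side; all reported metrics come from the held-out side.

    Returns the evaluation bundle: ``metrics`` (per horizon × setting ×
    meta rows plus ECG-only and EMR-only baselines), ``disparity`` tables
    per attribute, the per-(patient, horizon) ``scores`` table, and the
    fitted models.
    """
    if horizons is None:
        horizons = config.horizons
    if ecg_train_cfg is None:
        ecg_train_cfg = TrainConfig(seed=seed)
    if profiles is None:
        profiles = cohort_profiles(config)
    patients = profiles_frame(profiles)

    ids = patients["patient_id"].to_numpy()
    train_mask, _ = patient_split(ids, split, seed)
    train_ids = set(ids[train_mask])

    if features is None:
        features = featurize_cohort(
            config, horizons, k=k, window_samples=window_samples,
            peak_cfg=peak_cfg, profiles=profiles,
        )

    ecg_models, window_scores = train_ecg_models(
        features, horizons, train_ids, ecg_train_cfg
    )

    # EMR models: setting 1 fuses a demographics-only EMR model, setting 2
    # the demographics+comorbidity model.
    emr_scores: dict[int, pd.Series] = {}
    emr_models: dict[int, object] = {}
    y_patient = patients["label"]
    train_tbl = patients[patients["patient_id"].isin(train_ids)]
    for setting in (1, 2):
        fz = EMRFeaturizer(include_comorbidities=(setting == 2))
        X_tr = fz.fit_transform(train_tbl)
        model = train_emr(
            X_tr, y_patient.loc[train_tbl.index].to_numpy(),
            model_type=emr_model_type, seed=seed,
        )
        X_all = fz.transform(patients)
        emr_scores[setting] = pd.Series(
            model.predict_score(X_all), index=patients.index
        )
        emr_models[setting] = (fz, model)

    metric_rows: list[dict] = []
    disparity_tables: dict[str, pd.DataFrame] = {}
    score_tables: dict[int, pd.DataFrame] = {}
    for setting in settings:
        table = fusion.collect_scores(
            window_scores, emr_scores[setting], patients, aggregate=aggregate
        )
        score_tables[setting] = table
        is_train = table["patient_id"].isin(train_ids)
        for h in horizons:
            sub = table[table["horizon"] == h]
            sub_tr = sub[is_train.loc[sub.index]]
            sub_te = sub[~is_train.loc[sub.index]]
            y_te = sub_te["label"].to_numpy(dtype=int)

            # single-modality baselines (same held-out patients)
            for name, col in (("ecg_only", "ecg_score"), ("emr_only", "emr_score")):
                m = fusion.evaluate(y_te, sub_te[col].to_numpy())
                metric_rows.append(
                    {"horizon": h, "setting": setting, "model": name, **m.as_dict()}
                )

            for meta_type in meta_types:
                meta = fusion.train_meta(sub_tr, meta_type=meta_type, seed=seed)
                s_te = fusion.meta_scores(meta, sub_te)
                m = fusion.evaluate(y_te, s_te)
                metric_rows.append(
                    {
                        "horizon": h,
                        "setting": setting,
                        "model": f"fusion_{meta_type}",
                        **m.as_dict(),
                    }
                )
                if setting == max(settings) and meta_type == meta_types[0]:
                    pred = (s_te >= 0.5).astype(int)
                    for attr in disparity_attrs:
                        groups = sub_te[attr]
                        ref = groups.mode().iloc[0]  # largest group as reference
                        disparity_tables[f"{attr}_h{h}"] = fusion.disparity(
                            pred, y_te, groups, ref
                        )

    bundle = fusion.report(
        metric_rows,
        disparity_tables=disparity_tables,
        config={
            "n_patients": config.n_patients,
            "record_hours": config.record_hours,
            "horizon_unit_s": config.horizon_unit_s,
            "horizons": list(horizons),
            "settings": list(settings),
            "meta_types": list(meta_types),
            "k": k,
            "window_samples": window_samples,
            "threshold_frac": peak_cfg.threshold_frac,
            "split": split,
        },
        seed=seed,
    )
    bundle["scores"] = score_tables
    bundle["ecg_models"] = ecg_models
    bundle["emr_models"] = emr_models
    bundle["features"] = features
    bundle["train_ids"] = train_ids
    return bundle


def _ecg_accuracy_for(
    config: CohortConfig,
    profiles: list[PatientProfile],
    records: dict[str, ECGRecord],
    horizon: int,
    threshold_frac: float,
    window_samples: int,
    arch: tuple[int, ...],
    cfg: TrainConfig,
    k: int,
) -> dict:
    """Train the ECG model under one sweep setting; report accuracies."""
    features = featurize_cohort(
        config, (horizon,), k=k, window_samples=window_samples,
        peak_cfg=PeakConfig(threshold_frac=threshold_frac),
        records=records, profiles=profiles,
    )
    X = features[list(FEATURE_NAMES)].to_numpy()
    y = features["label"].to_numpy(dtype=float)
    pid = features["patient_id"].to_numpy()
    ann = AnalogANN(layer_sizes=(len(FEATURE_NAMES), *arch, 1)).init_weights(cfg.seed)
    ann, rep = train_error_aware(X, y, pid, ann=ann, cfg=cfg)
    last = rep.iloc[-1]
    return {
        "train_accuracy": float(last["train_accuracy"]),
        "test_accuracy": float(last["test_accuracy"]),
    }


def sweep(
    config: CohortConfig,
    axis: str,
    values: list,
    cfg: TrainConfig | None = None,
    base_horizon: int = 4,
    base_threshold: float = 0.30,
    base_window: int = 9000,
    base_arch: tuple[int, ...] = (20, 6),
    k: int = 10,
    profiles: list[PatientProfile] | None = None,
    records: dict[str, ECGRecord] | None = None,
) -> pd.DataFrame:
    """One-axis sensitivity sweep of the ECG model's training accuracy.

    ``axis`` is one of ``threshold_frac``, ``architecture``, ``horizon``
    or ``window_samples``; the other settings stay at their defaults
    (horizon 4, threshold 0.30, 9000-sample windows, 20/6 hidden layers).
    The same synthetic cohort (same seed) is reused across the axis, so
    differences come from the varied setting alone.
    """
    if cfg is None:
        cfg = TrainConfig(seed=config.seed)
    if profiles is None:
        profiles = cohort_profiles(config)
    if records is None:
        records = {p.patient_id: generate_ecg(p, config) for p in profiles}
    rows = []
    for v in values:
        horizon, threshold, window, arch = base_horizon, base_threshold, base_window, base_arch
        if axis == "horizon":
            horizon = v
        elif axis == "threshold_frac":
            threshold = v
        elif axis == "window_samples":
            window = v
        elif axis == "architecture":
            arch = tuple(v)
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        res = _ecg_accuracy_for(
            config, profiles, records, horizon, threshold, window, arch, cfg, k
        )
        rows.append({axis: v if axis != "architecture" else "/".join(map(str, v)), **res})
    out = pd.DataFrame(rows)
    out.attrs["axis"] = axis
    return out
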