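"""Late fusion of the ECG and EMR models, evaluation, and fairness audit.

A meta-learner is trained per prediction horizon on the two base models'
scores — the patient-level aggregate of the analog ECG classifier's window
scores, and the (horizon-independent) EMR classifier's score.  Setting 1
fuses ECG with a demographics-only EMR model; setting 2 fuses ECG with the
demographics-plus-comorbidity EMR model.  Base models and meta-learner are
all fitted on the training side of one patient-level 80/20 split; metrics
are reported on the held-out side.

The fairness audit compares subgroup false-positive rates (fraction of
false positives among a group's labelled negatives) against a reference
group; ratios within [0.8, 1.25] are deemed fair (the 80% rule).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .emr import EMRClassifier, train_emr

logger = logging.getLogger(__name__)

__all__ = [
    "Metrics",
    "collect_scores",
    "aggregate_window_scores",
    "train_meta",
    "evaluate",
    "auroc",
    "disparity",
    "report",
    "FAIR_BAND",
]

#: Fair band for disparity ratios (the 80% rule).
FAIR_BAND: tuple[float, float] = (0.8, 1.25)

GROUP_COLUMNS: tuple[str, ...] = ("race", "gender", "ethnicity", "age_bin")


@dataclass(frozen=True)
class Metrics:
    """Confusion-count metrics at a fixed threshold plus AUROC.

    ``sensitivity``/``specificity``/``auroc`` are None when the held-out
    rows contain no positives or no negatives respectively.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auroc: float | None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auroc": self.auroc,
        }


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUROC by the rank (pairwise-concordance) definition, ties counted ½.

    Equals the probability that a random positive outscores a random
    negative.  None when either class is absent.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # average ranks give the ½-tie convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Confusion counts at ``threshold`` (score ≥ threshold ⇒ positive)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    total = tp + fp + tn + fn
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
        auroc=auroc(y, s),
    )


def aggregate_window_scores(
    window_scores: pd.DataFrame, rule: str = "mean"
) -> pd.DataFrame:
    """Collapse per-window ECG scores to one score per (patient, horizon).

    ``window_scores`` needs columns patient_id, horizon, score, label (and
    optionally start_index for the ``last`` rule).
    """
    if rule == "mean":
        agg = window_scores.groupby(["patient_id", "horizon"])["score"].mean()
    elif rule == "max":
        agg = window_scores.groupby(["patient_id", "horizon"])["score"].max()
    elif rule == "last":
        agg = (
            window_scores.sort_values("start_index")
            .groupby(["patient_id", "horizon"])["score"]
            .last()
        )
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    labels = window_scores.groupby(["patient_id", "horizon"])["label"].first()
    return pd.DataFrame({"ecg_score": agg, "label": labels}).reset_index()


def collect_scores(
    window_scores: pd.DataFrame,
    emr_scores: pd.Series,
    demographics: pd.DataFrame,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Assemble the per-(patient, horizon) score table for fusion.

    ``emr_scores`` is indexed by patient_id and horizon-independent (EMR
    data is static), so it is repeated across horizons.  ``demographics``
    (indexed by patient_id) supplies the subgroup columns for the
    fairness audit.  Patients lacking windows at a horizon are simply
    absent from ``window_scores`` and are counted in a log line.
    """
    table = aggregate_window_scores(window_scores, rule=aggregate)
    table["emr_score"] = table["patient_id"].map(emr_scores)
    missing = table["emr_score"].isna().sum()
    if missing:
        logger.warning("%d (patient, horizon) rows lack an EMR score; dropped", missing)
        table = table.dropna(subset=["emr_score"])
    for col in GROUP_COLUMNS:
        if col in demographics.columns:
            table[col] = table["patient_id"].map(demographics[col])
    return table.reset_index(drop=True)


def train_meta(
    scores: pd.DataFrame,
    meta_type: str = "logistic",
    seed: int = 0,
    cv_folds: int = 10,
) -> EMRClassifier:
    """Fit the fusion meta-learner on base-model scores.

    ``scores`` must contain only meta-training rows (training-side
    patients) for one horizon, with columns ecg_score, emr_score, label.
    The meta-learner reuses the classifier suite (linear SVM, logistic,
    random forest, 2-hidden-layer MLP) with 10-fold CV selection.
    """
    X = scores[["ecg_score", "emr_score"]].to_numpy(dtype=np.float64)
    y = scores["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("meta-training rows contain a single class")
    return train_emr(X, y, model_type=meta_type, seed=seed, cv_folds=cv_folds)


def meta_scores(meta: EMRClassifier, scores: pd.DataFrame) -> np.ndarray:
    return meta.predict_score(scores[["ecg_score", "emr_score"]].to_numpy(dtype=np.float64))


def disparity(
    predictions: np.ndarray,
    labels: np.ndarray,
    groups: pd.Series | np.ndarray,
    reference_group: str,
    rate: str = "fpr",
    min_count: int = 10,
) -> pd.DataFrame:
    """Subgroup error-rate disparity against a reference group.

    For ``rate="fpr"`` each group's false-positive rate is the fraction of
    false positives among its labelled negatives; ``rate="fnr"`` audits
    false negatives among labelled positives instead.  The ratio to the
    reference group is flagged fair when inside [0.8, 1.25]; groups with
    fewer than ``min_count`` eligible members are reported but marked
    ``insufficient_n``.
    """
    if rate not in ("fpr", "fnr"):
        raise ValueError(f"unknown rate {rate!r}")
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    g = pd.Series(np.asarray(groups).astype(str))
    if reference_group not in set(g):
        raise ValueError(f"reference group {reference_group!r} absent from data")

    def _rate(mask: np.ndarray) -> tuple[float | None, int]:
        if rate == "fpr":
            eligible = mask & (y == 0)
            errors = eligible & (pred == 1)
        else:
            eligible = mask & (y == 1)
            errors = eligible & (pred == 0)
        n = int(eligible.sum())
        return (float(errors.sum()) / n if n else None), n

    ref_rate, _ = _rate((g == reference_group).to_numpy())
    rows = []
    for group in sorted(g.unique()):
        r, n = _rate((g == group).to_numpy())
        ratio = None
        fair = None
        if r is not None and ref_rate not in (None, 0.0):
            ratio = 1.0 if group == reference_group else r / ref_rate
            fair = FAIR_BAND[0] <= ratio <= FAIR_BAND[1]
        rows.append(
            {
                "group": group,
                rate: r,
                "n": n,
                "ratio": ratio,
                "fair": fair,
                "reference": group == reference_group,
                "insufficient_n": n < min_count,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["rate"] = rate
    out.attrs["reference_group"] = reference_group
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def report(
    metric_rows: list[dict],
    roc_points: pd.DataFrame | None = None,
    disparity_tables: dict[str, pd.DataFrame] | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble the evaluation bundle (metrics × horizon × setting × meta).

    Every metric row carries the seed and a hash of the resolved
    configuration, so a regenerated bundle from the same artifacts is
    identical and traceable.
    """
    metrics = pd.DataFrame(metric_rows)
    h = _config_hash(config or {})
    metrics["seed"] = seed
    metrics["config_hash"] = h
    return {
        "metrics": metrics,
        "roc_points": roc_points,
        "disparity": disparity_tables or {},
        "config_hash": h,
        "seed": seed,
    }
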