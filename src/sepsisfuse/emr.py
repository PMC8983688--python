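"""EMR (demographics + comorbidity text) sepsis classifier.

Demographic columns (age bin, gender, race, ethnicity) are label-encoded;
free-text ICD-10-style comorbidity descriptions are vectorized with TF-IDF
capped at 20 terms; the two blocks are concatenated and standardized with
statistics fitted on training rows only.  Four classifier families are
offered (linear SVM, logistic regression, random forest, two-hidden-layer
neural network, plus gradient boosting), with hyperparameters chosen by
10-fold cross-validation on the training rows.

TF-IDF conventions, fixed deliberately: TF is the term count normalized by
document length; IDF is the natural log of N/DF with no smoothing (every
vocabulary term has DF ≥ 1 by construction, and a term present in every
document gets weight exactly 0); the vocabulary is the top-``max_features``
terms by document frequency with lexicographic tie-breaking.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = [
    "TFIDFModel",
    "EMRFeaturizer",
    "EMRClassifier",
    "clean_text",
    "label_encode",
    "tf",
    "idf",
    "tfidf_fit",
    "tfidf_transform",
    "standardize",
    "train_emr",
    "CATEGORICAL_COLUMNS",
    "DEFAULT_GRIDS",
]

CATEGORICAL_COLUMNS: tuple[str, ...] = ("age_bin", "gender", "race", "ethnicity")

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def clean_text(description: str) -> list[str]:
    """Lowercase, replace non-alphanumeric characters with spaces, tokenize.

    Empty input (an empty EMR cell) yields an empty token list.
    """
    if not description:
        return []
    return _NON_ALNUM.sub(" ", description.lower()).split()


def label_encode(
    table: pd.DataFrame,
    columns: tuple[str, ...] = CATEGORICAL_COLUMNS,
    codebook: dict[str, dict[str, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Integer-code categorical columns.

    The codebook maps each column's sorted unique training values to
    ``0..k−1``; a value unseen at fit time encodes to the reserved code
    ``k`` with a warning.  Pass an existing codebook to encode test rows.
    """
    if codebook is None:
        codebook = {
            col: {v: i for i, v in enumerate(sorted(table[col].astype(str).unique()))}
            for col in columns
        }
    out = pd.DataFrame(index=table.index)
    for col in columns:
        book = codebook[col]
        unseen_code = len(book)

        def _code(v: str, book=book, unseen=unseen_code, col=col):
            if v in book:
                return book[v]
            logger.warning("unseen %s value %r encoded as reserved code %d", col, v, unseen)
            return unseen

        out[col] = table[col].astype(str).map(_code).astype(int)
    return out, codebook


def label_decode(codes: pd.Series, book: dict[str, int]) -> pd.Series:
    inverse = {i: v for v, i in book.items()}
    return codes.map(inverse)


@dataclass(frozen=True)
class TFIDFModel:
    """Fitted vocabulary and document-frequency statistics."""

    vocabulary: tuple[str, ...]
    df: dict[str, int]
    n_docs: int

    def __post_init__(self) -> None:
        for t in self.vocabulary:
            if not 1 <= self.df[t] <= self.n_docs:
                raise ValueError(f"DF({t!r}) = {self.df[t]} outside [1, {self.n_docs}]")


def tf(term: str, doc_tokens: list[str]) -> float:
    """Normalized term frequency: count of ``term`` over document length.

    An empty document contributes a zero vector, so TF is defined as 0.
    """
    if not doc_tokens:
        return 0.0
    return doc_tokens.count(term) / len(doc_tokens)


def idf(term: str, model: TFIDFModel) -> float:
    """Inverse document frequency ``ln(N / DF(term))`` (no smoothing)."""
    if term not in model.df:
        raise KeyError(f"term {term!r} not in vocabulary")
    return float(np.log(model.n_docs / model.df[term]))


def tfidf_fit(corpus: list[list[str]], max_features: int = 20) -> TFIDFModel:
    """Fit vocabulary and DF statistics on a tokenized corpus.

    Vocabulary is the top-``max_features`` terms by document frequency,
    with lexicographic ordering breaking DF ties.
    """
    if not any(corpus):
        raise ValueError("all-empty corpus: nothing to fit")
    df_counts: dict[str, int] = {}
    for doc in corpus:
        for term in set(doc):
            df_counts[term] = df_counts.get(term, 0) + 1
    ranked = sorted(df_counts, key=lambda t: (-df_counts[t], t))[:max_features]
    vocab = tuple(ranked)
    return TFIDFModel(
        vocabulary=vocab, df={t: df_counts[t] for t in vocab}, n_docs=len(corpus)
    )


def tfidf_transform(model: TFIDFModel, doc_tokens: list[str]) -> np.ndarray:
    """The TF×IDF vector of one document over the fitted vocabulary.

    Out-of-vocabulary tokens contribute nothing (they still count toward
    the document length in TF's denominator).
    """
    return np.asarray(
        [tf(t, doc_tokens) * idf(t, model) for t in model.vocabulary], dtype=np.float64
    )


def tfidf_matrix(model: TFIDFModel, corpus: list[list[str]]) -> np.ndarray:
    return np.vstack([tfidf_transform(model, doc) for doc in corpus]) if corpus else np.zeros((0, len(model.vocabulary)))


def standardize(
    train_matrix: np.ndarray, test_matrix: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict[str, np.ndarray]]:
    """Column-wise standardization with train-only statistics.

    Population (ddof=0) SD; constant columns are left at 0 rather than
    divided by zero.  Test rows are transformed with the train statistics.
    """
    train_matrix = np.asarray(train_matrix, dtype=np.float64)
    if train_matrix.size == 0:
        raise ValueError("empty training matrix")
    mean = train_matrix.mean(axis=0)
    sd = train_matrix.std(axis=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    stats = {"mean": mean, "sd": sd}
    train_std = (train_matrix - mean) / safe_sd
    test_std = None
    if test_matrix is not None:
        test_std = (np.asarray(test_matrix, dtype=np.float64) - mean) / safe_sd
    return train_std, test_std, stats


@dataclass
class EMRFeaturizer:
    """End-to-end EMR feature builder (fit on training patients only).

    Concatenates label-encoded demographics with the TF-IDF block
    (optional, for the demographics-only variant) and standardizes with
    train statistics.  Each patient's comorbidity phrases are joined into
    one document before tokenization.
    """

    include_comorbidities: bool = True
    max_features: int = 20
    codebook: dict[str, dict[str, int]] | None = None
    tfidf: TFIDFModel | None = None
    scaler_stats: dict[str, np.ndarray] | None = None

    def _documents(self, table: pd.DataFrame) -> list[list[str]]:
        return [clean_text(" ".join(str(c) for c in texts) if not isinstance(texts, str) else texts)
                for texts in table["comorbidities"]]

    def _raw_matrix(self, table: pd.DataFrame) -> np.ndarray:
        coded, self.codebook = label_encode(table, codebook=self.codebook)
        blocks = [coded.to_numpy(dtype=np.float64)]
        if self.include_comorbidities:
            docs = self._documents(table)
            blocks.append(tfidf_matrix(self.tfidf, docs))
        return np.hstack(blocks)

    def fit_transform(self, train_table: pd.DataFrame) -> np.ndarray:
        self.codebook = None
        if self.include_comorbidities:
            self.tfidf = tfidf_fit(self._documents(train_table), self.max_features)
        raw = self._raw_matrix(train_table)
        out, _, self.scaler_stats = standardize(raw)
        return out

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if self.scaler_stats is None:
            raise ValueError("featurizer not fitted")
        raw = self._raw_matrix(table)
        sd = self.scaler_stats["sd"]
        safe_sd = np.where(sd == 0, 1.0, sd)
        return (raw - self.scaler_stats["mean"]) / safe_sd

    @property
    def n_features(self) -> int:
        n = len(CATEGORICAL_COLUMNS)
        if self.include_comorbidities and self.tfidf is not None:
            n += len(self.tfidf.vocabulary)
        return n


# Hyperparameter grids searched by 10-fold CV; deliberately small and
# fixed here so every run is reproducible.
DEFAULT_GRIDS: dict[str, dict] = {
    "linear_svm": {"C": [0.1, 1.0, 10.0]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [200], "max_depth": [None, 6]},
    "gradient_boosting": {"n_estimators": [200], "learning_rate": [0.1]},
    "neural_net_2h": {"alpha": [1e-4, 1e-2]},
}


@dataclass
class EMRClassifier:
    """A fitted EMR model exposing calibrated-ish scores in [0, 1].

    SVM margins are mapped through a logistic link; tree ensembles and
    the MLP expose their native class-1 probabilities.
    """

    model_type: str
    estimator: object
    cv_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        margin = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))


def _make_estimator(model_type: str, seed: int):
    if model_type == "linear_svm":
        return LinearSVC(random_state=seed)
    if model_type == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model_type == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if model_type == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if model_type == "neural_net_2h":
        return MLPClassifier(
            hidden_layer_sizes=(16, 8), max_iter=3000, random_state=seed
        )
    raise ValueError(f"unknown model_type {model_type!r}")


def train_emr(
    X: np.ndarray,
    y: np.ndarray,
    model_type: str = "random_forest",
    seed: int = 0,
    cv_folds: int = 10,
    grids: dict[str, dict] = DEFAULT_GRIDS,
) -> EMRClassifier:
    """Fit one EMR classifier with 10-fold CV hyperparameter selection.

    ``X`` must already be standardized (see :class:`EMRFeaturizer`);
    ``y`` is binary.  Deterministic given ``seed``.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes present")
    est = _make_estimator(model_type, seed)
    # small training sets cannot sustain the full fold count
    n_minority = int(np.bincount(y.astype(int)).min())
    cv_folds = max(2, min(cv_folds, n_minority))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grids[model_type], cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(X, y)
    report = pd.DataFrame(search.cv_results_)[
        ["params", "mean_test_score", "std_test_score", "rank_test_score"]
    ]
    return EMRClassifier(
        model_type=model_type, estimator=search.best_estimator_, cv_report=report
    )
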