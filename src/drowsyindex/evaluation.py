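"""Statistical and classification evaluation of candidate indices.

Two complementary protocols:

* Per-subject Wilcoxon signed-rank tests between the W and S1 halves of
  each index series, Bonferroni-corrected across (subjects x indices)
  tests at a base level of 0.01 (144 tests at full scale give a corrected
  threshold of 6.9e-5), with best-channel selection for the
  single-channel baselines.

* Leave-one-subject-out (LOSO) epoch classification: a gradient-boosted
  tree classifier (eta 0.3, gamma 0, max depth 6) — and optionally the
  standard scikit-learn panel (naive Bayes, kNN, logistic regression,
  decision tree, random forest, SVM) — is trained on all-but-one subject
  and scored on the held-out subject's epochs.  Reported per subject:
  accuracy over all epochs and precision of drowsiness detection (S1 is
  the positive class).  Per-subject min-max-normalized index values feed
  the classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ratio_indices import IndexSeries

__all__ = [
    "ALPHA_0",
    "StatReport",
    "ClassReport",
    "wilcoxon_stage_test",
    "bonferroni_threshold",
    "best_channel_selection",
    "make_classifier",
    "loso_classify",
    "classifier_panel",
    "CLASSIFIER_NAMES",
]

#: Base significance level before multiple-testing correction.
ALPHA_0 = 0.01

#: The boosted-tree settings used for the headline classification runs.
XGB_SETTINGS = {"learning_rate": 0.3, "gamma": 0.0, "max_depth": 6}

CLASSIFIER_NAMES = (
    "xgboost",
    "naive_bayes",
    "knn",
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "svm",
)


@dataclass
class StatReport:
    """Per-(subject, index) p-values and the corrected significance level."""

    p_values: pd.DataFrame          # rows: subjects, columns: indices
    alpha0: float
    n_tests: int

    @property
    def alpha_corrected(self) -> float:
        return bonferroni_threshold(self.alpha0, self.n_tests)

    def significant_counts(self) -> pd.Series:
        """Per index: number of subjects below the corrected level."""
        return (self.p_values < self.alpha_corrected).sum(axis=0)


@dataclass
class ClassReport:
    """Per-subject LOSO accuracy/precision for one feature set."""

    accuracy: pd.Series             # index: subject ids
    precision: pd.Series            # NaN where no epoch was predicted S1
    classifier: str
    settings: dict = field(default_factory=dict)
    fold_manifest: dict = field(default_factory=dict)  # subject -> train ids
    predictions: dict = field(default_factory=dict)    # subject -> 0/1 array

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_precision(self) -> float:
        """Average over subjects with defined precision."""
        return float(self.precision.dropna().mean())

    @property
    def n_precision_undefined(self) -> int:
        return int(self.precision.isna().sum())


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value, tie-aware.

    Uses the conditional null distribution of the rank sum given the
    observed (possibly tied, hence half-integer) ranks, computed by
    convolution over doubled ranks.  Two-sided p is the probability that
    the smaller of the two rank sums is at most the observed one.
    """
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    s2 = int(ranks2.sum())
    t2_obs = int(np.round(2 * stats.rankdata(np.abs(d))[d > 0].sum()))
    m_obs = min(t2_obs, s2 - t2_obs)
    counts = np.zeros(s2 + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    t2 = np.arange(s2 + 1)
    mask = np.minimum(t2, s2 - t2) <= m_obs
    return float(counts[mask].sum() / 2 ** len(d))


def wilcoxon_stage_test(
    series: IndexSeries,
    unequal: str = "error",
    zero_method: str = "wilcox",
) -> float:
    """Two-sided Wilcoxon signed-rank p-value between the W and S1 halves.

    Pairs the k-th W epoch with the k-th S1 epoch (within-stage rank
    pairing).  Zero differences are dropped by default (``wilcox``);
    ``pratt`` keeps them in the ranking.  Exact (tie-aware) null
    distribution for up to 25 non-zero pairs, normal approximation with
    continuity correction otherwise.  ``unequal="truncate"`` trims both
    stages to the shorter one instead of raising.
    """
    w = series.stage_values("W")
    s1 = series.stage_values("S1")
    if len(w) != len(s1):
        if unequal == "truncate":
            m = min(len(w), len(s1))
            w, s1 = w[:m], s1[:m]
        else:
            raise ValueError(
                f"unequal stage epoch counts ({len(w)} W vs {len(s1)} S1); "
                "pass unequal='truncate' to trim"
            )
    d = s1 - w
    if zero_method == "wilcox":
        nz = d[d != 0]
        if nz.size == 0:
            return 1.0
        if nz.size <= 25:
            return _exact_signed_rank_p(nz)
    res = stats.wilcoxon(s1, w, zero_method=zero_method,
                         alternative="two-sided", correction=True,
                         method="approx")
    return float(res.pvalue)


def bonferroni_threshold(alpha0: float, n_tests: int) -> float:
    """Corrected per-test significance level alpha0 / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha0 / n_tests


def best_channel_selection(p_matrix: pd.DataFrame) -> str:
    """Channel with the lowest across-subject mean p-value.

    ``p_matrix``: rows subjects, columns channels.  Ties keep the first
    channel in column order.
    """
    means = p_matrix.mean(axis=0)
    return str(means.index[int(np.argmin(means.to_numpy()))])


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the panel classifiers at its standard settings."""
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(**XGB_SETTINGS, random_state=seed,
                             n_estimators=100, verbosity=0)
    if name == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier()
    if name == "logistic_regression":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=1000)
    if name == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _subject_xy(features: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = (np.asarray(labels) == "S1").astype(int)
    return X, y


def loso_classify(
    subject_features: dict[str, np.ndarray],
    subject_labels: dict[str, np.ndarray],
    classifier: str = "xgboost",
    seed: int = 0,
) -> ClassReport:
    """Leave-one-subject-out epoch classification.

    ``subject_features`` maps subject id -> (epochs,) or (epochs, k)
    feature array (one column for a multichannel index, six for a
    single-channel baseline evaluated per channel); ``subject_labels``
    maps subject id -> per-epoch "W"/"S1" labels.  For each subject a
    fresh classifier is trained on all other subjects and scored on the
    held-out epochs: accuracy over all epochs, precision of the S1 class
    (NaN when no epoch is predicted S1 — flagged, never coerced to 0).
    """
    subjects = list(subject_features)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    for s in subjects:
        y = np.asarray(subject_labels[s])
        if len(np.unique(y)) < 2:
            raise ValueError(f"subject {s!r} has a single class only")

    acc, prec, manifest, preds = {}, {}, {}, {}
    for held_out in subjects:
        train_ids = [s for s in subjects if s != held_out]
        Xtr = np.vstack([_subject_xy(subject_features[s],
                                     subject_labels[s])[0]
                         for s in train_ids])
        ytr = np.concatenate([_subject_xy(subject_features[s],
                                          subject_labels[s])[1]
                              for s in train_ids])
        Xte, yte = _subject_xy(subject_features[held_out],
                               subject_labels[held_out])
        clf = make_classifier(classifier, seed=seed)
        clf.fit(Xtr, ytr)
        yhat = np.asarray(clf.predict(Xte))
        acc[held_out] = float(np.mean(yhat == yte))
        n_pos = int(np.sum(yhat == 1))
        if n_pos == 0:
            warnings.warn(
                f"no epoch predicted S1 for held-out subject {held_out!r}; "
                "precision undefined"
            )
            prec[held_out] = np.nan
        else:
            prec[held_out] = float(np.sum((yhat == 1) & (yte == 1)) / n_pos)
        manifest[held_out] = train_ids
        preds[held_out] = yhat
    return ClassReport(
        accuracy=pd.Series(acc), precision=pd.Series(prec),
        classifier=classifier,
        settings=XGB_SETTINGS if classifier == "xgboost" else {},
        fold_manifest=manifest, predictions=preds,
    )


def classifier_panel(
    index_features: dict[str, dict[str, np.ndarray]],
    subject_labels: dict[str, np.ndarray],
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    seed: int = 0,
) -> pd.DataFrame:
    """Average LOSO accuracy for every (classifier, index) combination.

    ``index_features`` maps index name -> per-subject feature arrays.
    Returns a (classifiers x indices) table of mean accuracies.
    """
    rows = {}
    for clf_name in classifiers:
        rows[clf_name] = {
            idx_name: loso_classify(feats, subject_labels, clf_name,
                                    seed=seed).mean_accuracy
            for idx_name, feats in index_features.items()
        }
    return pd.DataFrame(rows).T
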