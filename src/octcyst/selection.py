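"""Feature-ranking harness: train a binary classifier per feature method on
a patient-level 80/20 split and rank methods by test accuracy.

The split is always by patient, never by scan — consecutive B-scans of the
same eye are strongly correlated, so scan-level splitting would leak test
information into training.  Classification uses off-the-shelf linear-margin
SVM (decision by the sign of w'x + b) or a k-nearest-neighbour vote;
labels at this boundary are +1 (cystic) / -1 (non-cystic) and predictions
are mapped back to the canonical {1, 2} encoding for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from . import features as feat
from .errors import DegenerateError, ParameterError
from .metrics import EvalReport, confusion_metrics, roc_auc

__all__ = ["SplitSpec", "FeatureRanking", "split_patients", "train_eval_classifier", "rank_features"]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.80
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must lie strictly in (0, 1)")


@dataclass
class FeatureRanking:
    reports: dict[str, EvalReport]
    ordering: list[str]  # methods sorted by test accuracy, descending

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m, **{k: v for k, v in self.reports[m].as_dict().items() if k != "flags"}}
            for m in self.ordering
        ]
        return pd.DataFrame(rows)


def split_patients(manifest: pd.DataFrame, spec: SplitSpec = SplitSpec()):
    """Disjoint, exhaustive patient-id split: |train| = round(fraction * n)."""
    spec.validate()
    ids = np.array(sorted(manifest["patient_id"].unique()))
    n = len(ids)
    if n < 2:
        raise DegenerateError("need at least 2 patients to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_ids = set(ids[perm[:n_train]])
    test_ids = set(ids[perm[n_train:]])
    return train_ids, test_ids


def _predict(kind: str, X_train, y_train, X_test, knn_k: int = 5):
    """Fit and return (signed test predictions, continuous test scores)."""
    if kind == "svm":
        clf = LinearSVC()
        clf.fit(X_train, y_train)
        scores = clf.decision_function(X_test)
        return np.where(scores >= 0, 1, -1), scores
    if kind == "knn":
        k = min(knn_k, len(y_train))
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(X_train, y_train)
        proba = clf.predict_proba(X_test)
        pos_col = list(clf.classes_).index(1)
        scores = proba[:, pos_col]
        return np.asarray(clf.predict(X_test)), scores
    raise ParameterError(f"unknown classifier kind {kind!r}")


def train_eval_classifier(
    features_train, labels_train, features_test, labels_test,
    kind: str = "svm", knn_k: int = 5,
) -> EvalReport:
    """Train on the train split only; report test-split confusion metrics.

    Labels are +1 (cystic) / -1 (non-cystic).  The report includes ROC/AUC
    from the classifier's continuous score when both classes appear in the
    test split.
    """
    X_train = np.asarray(features_train, dtype=float)
    y_train = np.asarray(labels_train)
    X_test = np.asarray(features_test, dtype=float)
    y_test = np.asarray(labels_test)
    if len(X_train) != len(y_train) or len(X_test) != len(y_test):
        raise ParameterError("features and labels must be aligned")
    if len(np.unique(y_train)) < 2:
        raise DegenerateError("training labels contain a single class")
    pred_signed, scores = _predict(kind, X_train, y_train, X_test, knn_k)
    to12 = lambda y: np.where(np.asarray(y) == 1, 1, 2)
    report = confusion_metrics(to12(pred_signed), to12(y_test))
    if len(np.unique(y_test)) == 2:
        report.roc, report.auc = roc_auc(scores, to12(y_test))
    else:
        report.flags.append("auc undefined: single-class test split")
    return report


def rank_features(
    manifest: pd.DataFrame,
    methods: list[str],
    kind: str = "svm",
    split: SplitSpec = SplitSpec(),
    loader=None,
    feature_config: dict | None = None,
) -> FeatureRanking:
    """Extract each feature method, classify, and rank by test accuracy.

    ``manifest`` needs patient_id, path and label (1=cystic, 2=non-cystic)
    columns; ``loader`` maps a path to a [0, 1] grayscale array (defaults to
    :func:`octcyst.io.load_image`).  All methods share the same patient
    split.  Ties in accuracy break alphabetically.
    """
    if not methods:
        raise ParameterError("need at least one feature method")
    if loader is None:
        from .io import load_image as loader  # noqa: PLC0415
    feature_config = feature_config or {}
    train_ids, test_ids = split_patients(manifest, split)
    in_train = manifest["patient_id"].isin(train_ids).to_numpy()
    labels_pm = np.where(manifest["label"].to_numpy(int) == 1, 1, -1)
    images = [loader(p) for p in manifest["path"]]

    reports: dict[str, EvalReport] = {}
    for method in methods:
        cfg = feature_config.get(method, {})
        X = np.stack([feat.extract_feature(img, method, cfg).values for img in images])
        reports[method] = train_eval_classifier(
            X[in_train], labels_pm[in_train], X[~in_train], labels_pm[~in_train], kind=kind
        )
    ordering = sorted(reports, key=lambda m: (-reports[m].accuracy, m))
    return FeatureRanking(reports=reports, ordering=ordering)
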