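"""t-test-gated SVM classification of case vs control from nodal features.

Only feature columns significant in a group t-test enter the model; a linear
support-vector machine is then evaluated with stratified fourfold
cross-validation, standardizing features on the training folds only. Decision
scores are pooled out-of-fold into one ROC curve; the area under it equals
the Mann-Whitney concordance probability of the scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import (
    EmptySelectionError,
    StatisticalError,
    StratificationError,
)
from .graphs import NodalFeatureVector
from .stats import two_sample_ttest

POSITIVE_LABEL = "case"


@dataclass
class FeatureMatrix:
    """Subjects x named-features table with group labels."""

    values: pd.DataFrame  # rows: subjects (index = subject_id)
    labels: pd.Series  # "case"/"control", aligned with values.index
    family: str = ""
    signal_type: str = ""
    sparsity: Optional[float] = None

    def __post_init__(self):
        if not self.values.index.equals(self.labels.index):
            raise StatisticalError("feature rows and labels must share the subject index")
        if self.values.isna().any().any():
            raise StatisticalError("feature matrix contains missing entries")
        present = set(self.labels.unique())
        if not {"case", "control"} <= present:
            raise StatisticalError(f"both classes required, got {sorted(present)}")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def subset(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[list(columns)], self.labels, self.family, self.signal_type, self.sparsity
        )


def build_feature_matrix(
    features: Dict[str, NodalFeatureVector],
    groups: Dict[str, str],
    family: str,
    signal_type: str = "",
) -> FeatureMatrix:
    """Assemble one feature family (one column per node) across subjects.

    ``features`` maps subject_id -> nodal feature vector; ``groups`` maps
    subject_id -> "case"/"control". Column names encode family, node,
    signal type and sparsity so selections stay traceable.
    """
    if not features:
        raise StatisticalError("no subjects supplied")
    sids = sorted(features)
    first = features[sids[0]]
    cols = [
        f"{family}|{node}|{signal_type}|s={first.sparsity:g}" for node in first.node_labels
    ]
    rows = np.vstack([features[s].family(family) for s in sids])
    values = pd.DataFrame(rows, index=pd.Index(sids, name="subject_id"), columns=cols)
    labels = pd.Series([groups[s] for s in sids], index=values.index, name="group")
    return FeatureMatrix(values, labels, family, signal_type, first.sparsity)


def select_features_by_ttest(fm: FeatureMatrix, alpha: float = 0.05) -> FeatureMatrix:
    """Keep columns whose two-sided case/control t-test p-value is below alpha."""
    case = fm.values[fm.labels == "case"]
    control = fm.values[fm.labels == "control"]
    keep: List[str] = []
    for col in fm.values.columns:
        x, y = case[col].to_numpy(), control[col].to_numpy()
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            continue  # constant feature carries no group signal
        _, p = two_sample_ttest(x, y)
        if p < alpha:
            keep.append(col)
    if not keep:
        raise EmptySelectionError(
            f"no feature of family {fm.family or '<unnamed>'!r} passed the t-test gate "
            f"at alpha={alpha}; no model can be trained"
        )
    return fm.subset(keep)


def roc_from_scores(
    scores: Sequence[float], labels: Sequence[str]
) -> Tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from decision scores.

    Thresholds sweep the unique scores from high to low; tied scores move as
    one block, so the AUC equals the Mann-Whitney concordance probability
    (ties credited 1/2) exactly.
    """
    scores = np.asarray(scores, float)
    y = np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticalError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # tied block moves together
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


@dataclass
class ClassificationReport:
    feature_family: str
    selected_features: Tuple[str, ...]
    fold_assignments: np.ndarray  # fold index per subject, aligned with subjects
    subjects: Tuple[str, ...]
    fold_accuracies: Tuple[float, ...]
    accuracy_max: float  # percent
    accuracy_mean: float  # percent
    roc_points: np.ndarray
    auc: float
    scores: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "feature_family": self.feature_family,
            "selected_features": list(self.selected_features),
            "fold_accuracies": list(self.fold_accuracies),
            "accuracy_max": self.accuracy_max,
            "accuracy_mean": self.accuracy_mean,
            "auc": self.auc,
            "seed": self.seed,
        }


def crossvalidated_svm(
    fm: FeatureMatrix,
    folds: int = 4,
    seed: int = 0,
    kernel: str = "linear",
    c: float = 1.0,
) -> ClassificationReport:
    """Stratified k-fold SVM with out-of-fold score pooling.

    Standardization is fit on each training split only (no leakage into the
    held-out fold). ``accuracy_max`` is the best single-fold accuracy,
    ``accuracy_mean`` the across-fold average, both in percent.
    """
    y = (fm.labels == POSITIVE_LABEL).to_numpy().astype(int)
    n_per_class = min(int(y.sum()), int((1 - y).sum()))
    if n_per_class < folds:
        raise StratificationError(
            f"{folds}-fold stratification impossible with {n_per_class} subjects "
            "in the smaller class"
        )
    x = fm.values.to_numpy(float)
    if np.any(x.std(axis=0) == 0):
        warnings.warn("constant feature column(s): uninformative for classification")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    fold_of = np.empty(len(y), int)
    accs: List[float] = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        scaler = StandardScaler().fit(x[tr])
        clf = SVC(kernel=kernel, C=c)
        clf.fit(scaler.transform(x[tr]), y[tr])
        xs = scaler.transform(x[te])
        scores[te] = clf.decision_function(xs)
        accs.append(float((clf.predict(xs) == y[te]).mean()))
        fold_of[te] = fold
    pts, auc = roc_from_scores(scores, fm.labels.to_numpy())
    return ClassificationReport(
        feature_family=fm.family,
        selected_features=tuple(fm.values.columns),
        fold_assignments=fold_of,
        subjects=tuple(fm.values.index),
        fold_accuracies=tuple(100.0 * a for a in accs),
        accuracy_max=float(100.0 * max(accs)),
        accuracy_mean=float(100.0 * np.mean(accs)),
        roc_points=pts,
        auc=auc,
        scores=scores,
        seed=seed,
    )
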