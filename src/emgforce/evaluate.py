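"""Classifier training, force-level case schemes, trial-wise cross-validation,
confusion-derived metrics, and the Bonferroni-corrected ANOVA comparison.

Evaluation follows the standard myoelectric-control protocol: windows from
four of the five trials train the classifier, the held-out trial tests it,
and the fold index rotates over trials (5-fold cross-validation by trial, so
no window of a test trial ever appears in training).  The four *cases* vary
which force levels are present in training: same force (1), one force (2),
two forces (3), or all three (4); testing in cases 2-4 uses all forces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .features import LABEL_COLUMNS
from .reduce import fit_srda, transform
from .signal_io import FORCES

CLASSIFIERS = ("LDA", "SVM", "KNN")

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class CaseScheme:
    """One training/testing force-level scheme."""

    case_id: int
    train_forces: tuple[str, ...]
    test_forces: tuple[str, ...]

    def __post_init__(self) -> None:
        for f in self.train_forces + self.test_forces:
            if f not in FORCES:
                raise ValueError(f"unknown force level {f!r}")

    @property
    def label(self) -> str:
        return "+".join(self.train_forces)


def case_schemes(case: int) -> list[CaseScheme]:
    """The training-force schemes of one of the four cases."""
    if case == 1:
        return [CaseScheme(1, (f,), (f,)) for f in FORCES]
    if case == 2:
        return [CaseScheme(2, (f,), FORCES) for f in FORCES]
    if case == 3:
        return [CaseScheme(3, pair, FORCES) for pair in combinations(FORCES, 2)]
    if case == 4:
        return [CaseScheme(4, FORCES, FORCES)]
    raise ValueError(f"case must be 1..4, got {case}")


class _KNN3:
    """k-nearest-neighbour classifier (Euclidean) with ties broken by the
    label of the single nearest neighbour among the tied labels."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X, y):
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(np.asarray(X, float))
        self._y = np.asarray(y)
        return self

    def predict(self, X):
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        out = []
        for row in idx:
            labels = self._y[row]  # sorted by distance
            uniq, counts = np.unique(labels, return_counts=True)
            best = counts.max()
            tied = set(uniq[counts == best])
            if len(tied) == 1:
                out.append(tied.pop())
            else:
                out.append(next(l for l in labels if l in tied))
        return np.asarray(out)


def make_classifier(kind: str, quadratic: bool = True):
    """Instantiate one of the three classifiers with its standard settings.

    ``LDA`` is discriminant analysis with a quadratic decision boundary
    (per-class covariances); set ``quadratic=False`` for the pooled-
    covariance linear variant.  ``SVM`` is an RBF-kernel machine with unit
    box constraint and kernel scale 1/n_features; ``KNN`` uses k = 3.
    """
    kind = kind.upper()
    if kind == "LDA":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6) if quadratic else LinearDiscriminantAnalysis()
    if kind == "SVM":
        return SVC(C=1.0, kernel="rbf", gamma="auto")
    if kind == "KNN":
        return _KNN3(k=3)
    raise ValueError(f"unknown classifier {kind!r}; choose from {CLASSIFIERS}")


# ------------------------------------------------------------------ metrics

def confusion_counts(y_true, y_pred) -> dict:
    """One-vs-rest TP/TN/FP/FN counts per gesture."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be aligned")
    total = y_true.size
    counts = {}
    for cls in np.unique(y_true):
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        counts[cls] = {"tp": tp, "fp": fp, "fn": fn, "tn": total - tp - fp - fn}
    return counts


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; defining the term as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_counts(counts: dict) -> dict:
    """Macro-averaged accuracy, sensitivity, specificity, precision and F1,
    in percent, from per-gesture one-vs-rest confusion counts."""
    per = {m: [] for m in METRICS}
    for cls, c in counts.items():
        tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
        acc = _safe_ratio(tp + tn, tp + tn + fp + fn, f"accuracy[{cls}]")
        sen = _safe_ratio(tp, tp + fn, f"sensitivity[{cls}]")
        spe = _safe_ratio(tn, tn + fp, f"specificity[{cls}]")
        pre = _safe_ratio(tp, tp + fp, f"precision[{cls}]")
        f1 = _safe_ratio(2 * pre * sen, pre + sen, f"f1[{cls}]")
        for m, v in zip(METRICS, (acc, sen, spe, pre, f1)):
            per[m].append(v)
    return {m: 100.0 * float(np.mean(v)) for m, v in per.items()}


def metrics_from_predictions(y_true, y_pred) -> dict:
    return metrics_from_counts(confusion_counts(y_true, y_pred))


# --------------------------------------------------------- cross-validation

def crossvalidate(
    features: pd.DataFrame,
    scheme: CaseScheme,
    classifier: str = "SVM",
    reg: float = 0.01,
    n_folds: int = 5,
    quadratic: bool = True,
) -> pd.DataFrame:
    """Trial-wise k-fold cross-validation of one feature table.

    ``features`` is a tidy table from :func:`emgforce.features.feature_table`
    (one subject's windows).  In fold *f* the windows of trial *f* are held
    out; training windows come from the scheme's training forces of the
    remaining trials, test windows from the scheme's testing forces of the
    held-out trial.  The SRDA projection is fitted inside each fold on the
    training windows only.

    Returns one row per fold with the five macro-averaged metrics (percent).
    """
    feat_cols = [c for c in features.columns if c not in LABEL_COLUMNS]
    folds = range(1, n_folds + 1)
    needed = set(folds)
    for g in sorted(features["gesture"].unique()):
        for f in set(scheme.train_forces) | set(scheme.test_forces):
            have = set(features.loc[(features.gesture == g) & (features.force == f), "trial"])
            if not needed <= have:
                raise ValueError(
                    f"missing trials {sorted(needed - have)} for gesture {g}, force {f!r}"
                )
    rows = []
    for fold in folds:
        tr = features[(features.trial != fold) & features.force.isin(scheme.train_forces)]
        te = features[(features.trial == fold) & features.force.isin(scheme.test_forces)]
        model = fit_srda(tr[feat_cols].to_numpy(), tr["gesture"].to_numpy(), reg=reg)
        clf = make_classifier(classifier, quadratic=quadratic)
        clf.fit(transform(model, tr[feat_cols].to_numpy()), tr["gesture"].to_numpy())
        pred = clf.predict(transform(model, te[feat_cols].to_numpy()))
        m = metrics_from_predictions(te["gesture"].to_numpy(), pred)
        rows.append({"fold": fold, "n_train": len(tr), "n_test": len(te), **m})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- ANOVA

def compare_methods_anova(
    performance: dict[str, np.ndarray],
    proposed: str = "proposed",
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Pairwise one-way ANOVA of the proposed method against each baseline.

    Each value of ``performance`` is a vector of per-subject (x per-scheme)
    scores; vectors must have equal length.  Raw p-values are Bonferroni
    corrected by multiplying with the family size (default: the number of
    comparisons made) and clipping at 1.  A pair whose two groups both have
    zero within-group variance is flagged degenerate (p undefined).
    """
    if proposed not in performance:
        raise ValueError(f"{proposed!r} missing from the performance table")
    a = np.asarray(performance[proposed], dtype=float)
    others = [m for m in performance if m != proposed]
    n = n_comparisons if n_comparisons is not None else len(others)
    rows = []
    for m in others:
        b = np.asarray(performance[m], dtype=float)
        if b.shape != a.shape:
            raise ValueError(f"performance vector length mismatch for {m!r}")
        if np.var(a) == 0 and np.var(b) == 0:
            rows.append(
                {"method": m, "f_stat": np.nan, "p_raw": np.nan,
                 "p_corrected": np.nan, "degenerate": True}
            )
            continue
        stat = f_oneway(a, b)
        rows.append(
            {
                "method": m,
                "f_stat": float(stat.statistic),
                "p_raw": float(stat.pvalue),
                "p_corrected": float(min(1.0, stat.pvalue * n)),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
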