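"""Comparison battery between normative-model QC, visual QC and
quantitative QC (QQC).

Implements inter-rater reliability (ICC3k), a class-balanced repeated
subsample linear-SVM evaluation of the quantitative descriptors against
visual labels, precision-recall sweeps of the normative-model outlier
score across z thresholds, the 2-SD quantitative-QC outlier rule, and the
cross-method correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SVMEvalConfig",
    "icc3k",
    "balanced_svm_evaluation",
    "pr_curve",
    "pr_threshold_sweep",
    "qqc_outlier_frequency",
    "qc_correlation_matrix",
]


# ------------------------------------------------------------------ ICC


def icc3k(ratings) -> float:
    """Two-way mixed, average-measures, consistency intraclass correlation.

    ``ratings`` is a subjects x raters array (k >= 2).  From the two-way
    ANOVA decomposition, ICC3k = (MS_subjects - MS_error) / MS_subjects.
    Returns ``nan`` when the between-subject mean square is zero (no
    subject variance to agree on).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2-D subjects x raters array with k >= 2")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0.0:
        logger.warning("zero between-subject variance; ICC3k undefined")
        return float("nan")
    return float((ms_rows - ms_err) / ms_rows)


# ------------------------------------------------------------------ SVM


@dataclass(frozen=True)
class SVMEvalConfig:
    """Configuration of the balanced repeated-subsample SVM evaluation.

    Visual scores 1 and 2 are grouped into class 0 (acceptable) and score
    3 is class 1 (not acceptable); the majority class is downsampled to
    the minority size in each of ``n_subsamples`` draws, and performance
    is 5-fold cross-validated within each draw then averaged.
    """

    n_subsamples: int = 20
    n_folds: int = 5
    C: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def binarize_scores(scores) -> np.ndarray:
    """Visual scores {1,2} -> 0 (acceptable), {3} -> 1 (not acceptable)."""
    scores = np.asarray(scores)
    if not np.all(np.isin(scores, (1, 2, 3))):
        raise ValueError("visual scores must be in {1, 2, 3}")
    return (scores == 3).astype(int)


def balanced_svm_evaluation(features, scores, config: SVMEvalConfig | None = None) -> dict:
    """Class-balanced, repeated-subsample, cross-validated linear SVM.

    Parameters
    ----------
    features : DataFrame or array
        Numeric QC descriptors, one row per subject.
    scores : array
        Visual severity scores in {1, 2, 3} (the ground truth).

    Returns
    -------
    dict with mean and SD across subsamples of accuracy, sensitivity
    (recall of the artefact class) and specificity, plus the per-subsample
    values.  Deterministic given ``config.seed``.
    """
    config = config or SVMEvalConfig()
    X = pd.DataFrame(features).to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = binarize_scores(scores)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present after binarization")
    if len(pos) < config.n_folds:
        raise ValueError(
            f"artefact class has {len(pos)} members; need >= n_folds={config.n_folds}"
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_subsamples):
        sub_neg = rng.choice(neg, size=min(len(pos), len(neg)), replace=False)
        idx = np.concatenate([pos, sub_neg])
        Xi, yi = X[idx], y[idx]
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        accs, sens, specs = [], [], []
        for train, test in skf.split(Xi, yi):
            clf = make_pipeline(
                StandardScaler(), SVC(kernel="linear", C=config.C)
            )
            clf.fit(Xi[train], yi[train])
            pred = clf.predict(Xi[test])
            truth = yi[test]
            accs.append(float(np.mean(pred == truth)))
            tp = np.sum((pred == 1) & (truth == 1))
            fn = np.sum((pred == 0) & (truth == 1))
            tn = np.sum((pred == 0) & (truth == 0))
            fp = np.sum((pred == 1) & (truth == 0))
            sens.append(tp / (tp + fn) if tp + fn else np.nan)
            specs.append(tn / (tn + fp) if tn + fp else np.nan)
        rows.append(
            {
                "accuracy": float(np.mean(accs)),
                "sensitivity": float(np.nanmean(sens)),
                "specificity": float(np.nanmean(specs)),
            }
        )
    per = pd.DataFrame(rows)
    return {
        "accuracy_mean": float(per["accuracy"].mean()),
        "accuracy_sd": float(per["accuracy"].std(ddof=1)) if len(per) > 1 else 0.0,
        "sensitivity_mean": float(per["sensitivity"].mean()),
        "sensitivity_sd": float(per["sensitivity"].std(ddof=1)) if len(per) > 1 else 0.0,
        "specificity_mean": float(per["specificity"].mean()),
        "specificity_sd": float(per["specificity"].std(ddof=1)) if len(per) > 1 else 0.0,
        "per_subsample": rows,
    }


# ------------------------------------------------------------ PR curves


def pr_curve(scores, truth) -> dict:
    """Precision-recall curve over all score cut-points, plus AUC.

    AUC uses the step-wise rule (sum of precision times recall increment),
    which avoids the optimistic linear interpolation of the trapezoid.
    Ties in score are grouped at one cut-point.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.sum() == 0:
        raise ValueError("truth must contain at least one positive")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    precision, recall, thresholds = precision_recall_curve(truth, scores)
    auc = float(average_precision_score(truth, scores))
    return {
        "precision": precision.tolist(),
        "recall": recall.tolist(),
        "thresholds": thresholds.tolist(),
        "auc": auc,
    }


def pr_threshold_sweep(
    z,
    truth,
    thresholds=(2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
    svm_scores=None,
) -> dict:
    """PR curves of the normative-model outlier score at several z thresholds.

    For each threshold ``t`` the per-subject score is the outlier
    frequency: the number of IDPs with |z| > t.  A curve for continuous
    ``max |z|`` (key ``"max_abs_z"``) and, if given, for the SVM decision
    values (key ``"svm"``) are included for comparison.

    Parameters
    ----------
    z : DataFrame or 2-D array
        Subjects x IDPs z-score matrix.
    truth : array of {0, 1}
        Ground-truth artefact labels (1 = not acceptable).
    """
    z = pd.DataFrame(z).to_numpy(dtype=float)
    truth = np.asarray(truth, dtype=int)
    out = {}
    for t in thresholds:
        freq = (np.abs(z) > t).sum(axis=1)
        out[f"z>{t:g}"] = pr_curve(freq, truth)
    out["max_abs_z"] = pr_curve(np.abs(z).max(axis=1), truth)
    if svm_scores is not None:
        out["svm"] = pr_curve(svm_scores, truth)
    return out


# --------------------------------------------------------- QQC outliers


def qqc_outlier_frequency(qqc: pd.DataFrame, threshold_sd: float = 2.0):
    """Per-subject count of quantitative-QC descriptors beyond the 2-SD rule.

    A cell is an outlier when |value - column mean| > threshold_sd * column
    SD (two-sided).  Zero-variance columns are excluded with a warning.
    Returns ``(frequency, flags)``.
    """
    qqc = pd.DataFrame(qqc)
    num = qqc.select_dtypes(include=[np.number])
    sds = num.std(ddof=0)
    dead = sds[sds == 0.0].index
    if len(dead):
        logger.warning("excluding zero-variance QQC columns: %s", list(dead))
        num = num.drop(columns=dead)
        sds = sds.drop(dead)
    flags = (num - num.mean()).abs() > threshold_sd * sds
    return flags.sum(axis=1), flags


# ---------------------------------------------------------- correlation


def qc_correlation_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of the QC summary measures.

    Intended columns: T1 discrepancy, FA-template discrepancy, SNR,
    normative-model outlier frequency, QQC outlier frequency and visual
    QC score.  Zero-variance columns yield NaN entries (sentinel, with a
    warning).
    """
    measures = pd.DataFrame(measures)
    if len(measures) < 3:
        raise ValueError("need at least 3 rows")
    num = measures.select_dtypes(include=[np.number])
    if not np.all(np.isfinite(num.to_numpy())):
        raise ValueError("measures must be finite")
    dead = num.columns[num.std(ddof=0) == 0.0]
    if len(dead):
        logger.warning("zero-variance columns yield NaN correlations: %s", list(dead))
    return num.corr(method="pearson")
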