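"""Supervised motif selection and linear-discriminant classification.

Given a column-normalized enrichment matrix and class labels per sample
(e.g. day vs night), motifs are ranked by greedy minimum-redundancy
maximum-relevance (mRMR) selection on mutual information between
3-level-discretized scores, a linear discriminant classifier is evaluated
by stratified cross-validation as ranked motifs are added one at a time,
and the error curve (smoothed with a 3-wide running average) picks the
motif count.  Performance is judged against a majority-class baseline
(± the standard error of a proportion) and against classifiers built from
randomly chosen motif subsets of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from ._rng import as_rng

__all__ = [
    "discretize_columns",
    "mrmr_rank",
    "incremental_cv_error",
    "select_motif_count",
    "majority_class_error",
    "random_subset_baseline",
    "ClassifierReport",
    "classifier_report",
]

DEFAULT_TOP = 250
DEFAULT_FOLDS = 10
DEFAULT_SMOOTH = 3
LDA_SHRINKAGE = 1e-4  # mild ridge on the pooled covariance for k >= n prefixes


def discretize_columns(x: np.ndarray) -> np.ndarray:
    """Discretize each column into 3 states at mean ± 1 SD.

    The classic preprocessing for continuous mRMR: state 0 below mean − SD,
    1 between, 2 above mean + SD.  Zero-SD columns map to state 1.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    out = np.ones(x.shape, dtype=np.int8)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


def _encode_labels(y) -> np.ndarray:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes


def _mi_columns(xd: np.ndarray, yd: np.ndarray, x_levels: int) -> np.ndarray:
    """Mutual information (nats) between each column of ``xd`` and ``yd``."""
    n, m = xd.shape
    y_levels = int(yd.max()) + 1
    cells = x_levels * y_levels
    joint = xd.astype(np.int64) * y_levels + yd[:, None]
    joint += np.arange(m) * cells
    counts = np.bincount(joint.ravel(), minlength=m * cells).reshape(m, x_levels, y_levels)
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pxy * np.log(pxy / (px * py))
    return np.nansum(term, axis=(1, 2))


def mrmr_rank(m, labels, top: int = DEFAULT_TOP, variant: str = "mid") -> np.ndarray:
    """Greedy mRMR ranking of motif columns against sample labels.

    The first motif maximizes mutual information with the labels; each
    subsequent motif maximizes relevance minus (``mid``, difference scheme)
    or divided by (``miq``, quotient scheme) its mean mutual information
    with the motifs already chosen.  Ties resolve to the lowest column
    index.  Returns column positions, best first.
    """
    x = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    xd = discretize_columns(x)
    yd = _encode_labels(labels)
    n_cols = x.shape[1]
    top = min(top, n_cols)
    relevance = _mi_columns(xd, yd, 3)

    chosen: list[int] = []
    redundancy_sum = np.zeros(n_cols)
    available = np.ones(n_cols, dtype=bool)
    for step in range(top):
        if step == 0:
            score = relevance.copy()
        else:
            redundancy_sum += _mi_columns(xd, xd[:, chosen[-1]], 3)
            red = redundancy_sum / len(chosen)
            if variant == "mid":
                score = relevance - red
            elif variant == "miq":
                with np.errstate(divide="ignore", invalid="ignore"):
                    score = np.where(red > 0, relevance / red, np.inf * np.sign(relevance))
            else:
                raise ValueError(f"unknown mRMR variant {variant!r}")
        score = np.where(available, score, -np.inf)
        pick = int(np.argmax(score))
        chosen.append(pick)
        available[pick] = False
    return np.asarray(chosen)


def _make_folds(y, folds, seed, groups):
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    max_folds = int(counts.min())
    if groups is not None:
        max_folds = min(max_folds, len(np.unique(groups)))
    if folds > max_folds:
        warnings.warn(f"reducing folds from {folds} to {max_folds}")
        folds = max_folds
    if folds < 2:
        raise ValueError("need at least 2 samples per class (and 2 groups) for CV")
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def _cv_errors_for_subset(x, y, splits) -> np.ndarray:
    errs = []
    for train, test in splits:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=LDA_SHRINKAGE)
        lda.fit(x[train], y[train])
        errs.append(100.0 * np.mean(lda.predict(x[test]) != y[test]))
    return np.asarray(errs)


def incremental_cv_error(
    m,
    labels,
    ranked,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    groups=None,
):
    """Cross-validated error (%) as ranked motifs are added one at a time.

    Prefix k of the ranking is evaluated with a linear discriminant under
    stratified k-fold CV (grouped by animal when ``groups`` is given, so
    rows from one animal never straddle train and test).  Returns
    (mean %, SD %) arrays over folds, one entry per prefix.
    """
    x = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    y = _encode_labels(labels)
    ranked = np.asarray(ranked)
    splits = _make_folds(y, folds, seed, groups)
    means, sds = [], []
    for k in range(1, len(ranked) + 1):
        errs = _cv_errors_for_subset(x[:, ranked[:k]], y, splits)
        means.append(errs.mean())
        sds.append(errs.std(ddof=0))
    return np.asarray(means), np.asarray(sds)


def select_motif_count(curve, smooth_width: int = DEFAULT_SMOOTH) -> tuple[int, float]:
    """Motif count at the minimum of the smoothed error curve.

    The curve is smoothed with a centered running average ``smooth_width``
    wide; windows shrink symmetrically at the edges (the endpoints are
    unsmoothed at width 3).  Returns (1-based count, smoothed error there);
    ties resolve to the smallest count.
    """
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    if n == 0:
        raise ValueError("empty error curve")
    if n < smooth_width:
        i = int(np.argmin(curve))
        return i + 1, float(curve[i])
    half = (smooth_width - 1) // 2
    smoothed = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        smoothed[i] = curve[i - h : i + h + 1].mean()
    i = int(np.argmin(smoothed))
    return i + 1, float(smoothed[i])


def majority_class_error(labels) -> tuple[float, float]:
    """Majority-class baseline error (%) and SE of the proportion (%).

    Always predicting the most frequent class errs on the remaining
    samples: error = 100 (1 − max class fraction), with standard error
    100 sqrt(p(1−p)/n) where p is the error fraction.
    """
    y = np.asarray(labels)
    n = len(y)
    if n == 0:
        raise ValueError("no labels")
    counts = pd.Series(y).value_counts()
    p = 1.0 - counts.iloc[0] / n
    se = float(np.sqrt(p * (1 - p) / n))
    return 100.0 * p, 100.0 * se


def random_subset_baseline(
    m,
    labels,
    count: int,
    repeats: int = 10,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    groups=None,
) -> tuple[float, float]:
    """CV error of classifiers built from random motif subsets.

    Each repeat draws ``count`` motifs uniformly without replacement and
    runs the same CV protocol; returns (mean %, SD %) across repeats.
    """
    x = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    if count > x.shape[1]:
        raise ValueError(f"count={count} exceeds the {x.shape[1]} motifs")
    y = _encode_labels(labels)
    rng = as_rng(seed)
    splits = _make_folds(y, folds, seed, groups)
    errors = []
    for _ in range(repeats):
        cols = rng.choice(x.shape[1], size=count, replace=False)
        errors.append(_cv_errors_for_subset(x[:, cols], y, splits).mean())
    errors = np.asarray(errors)
    return float(errors.mean()), float(errors.std(ddof=0))


@dataclass
class ClassifierReport:
    """One row of a motif-classifier performance table."""

    comparison: str
    ranked: np.ndarray  # mRMR ranking (column positions, best first)
    n_selected: int
    cv_error: float
    cv_sd: float
    mc_error: float
    mc_se: float
    rm_error: float
    rm_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": self.comparison,
                    "motifs": self.n_selected,
                    "cv_error_pct": self.cv_error,
                    "cv_std_pct": self.cv_sd,
                    "mc_error_pct": self.mc_error,
                    "mc_ep_pct": self.mc_se,
                    "rm_error_pct": self.rm_error,
                    "rm_std_pct": self.rm_sd,
                }
            ]
        )


def classifier_report(
    m,
    labels,
    comparison: str = "",
    top: int = DEFAULT_TOP,
    folds: int = DEFAULT_FOLDS,
    smooth_width: int = DEFAULT_SMOOTH,
    repeats: int = 10,
    seed: int = 0,
    groups=None,
) -> ClassifierReport:
    """Full selection + evaluation for one contrast.

    Runs mRMR, the incremental CV error curve, the smoothed-minimum motif
    count, and the majority-class and random-subset baselines.  The same
    fold seed is shared by the curve and the baselines.
    """
    ranked = mrmr_rank(m, labels, top=top)
    means, sds = incremental_cv_error(m, labels, ranked, folds=folds, seed=seed,
                                      groups=groups)
    n_sel, _ = select_motif_count(means, smooth_width)
    mc_err, mc_se = majority_class_error(labels)
    rm_err, rm_sd = random_subset_baseline(
        m, labels, n_sel, repeats=repeats, folds=folds, seed=seed, groups=groups
    )
    return ClassifierReport(
        comparison=comparison,
        ranked=ranked,
        n_selected=n_sel,
        cv_error=float(means[n_sel - 1]),
        cv_sd=float(sds[n_sel - 1]),
        mc_error=mc_err,
        mc_se=mc_se,
        rm_error=rm_err,
        rm_sd=rm_sd,
    )
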