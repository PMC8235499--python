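"""Diagnostic evaluation of candidate marker miRNAs.

ROC/AUC per marker via the Mann-Whitney identity (ties count one half),
Gaussian naive-Bayes classification under stratified cross-validation,
and the cohort association statistics (chi-square, odds ratio, relative
risk, absolute risk) for categorical patient characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "ROCResult",
    "NBayesReport",
    "roc_auc",
    "naive_bayes_cv",
    "cohort_association",
]


@dataclass
class ROCResult:
    """ROC curve and AUC for one marker.

    ``low_predicts_tumor`` records the auto-selected orientation: for a
    down-regulated marker the tumor class scores *lower*, so scores are
    negated before thresholding and the recorded AUC is >= 0.5.
    """

    symbol: str
    auc: float
    p_value: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    low_predicts_tumor: bool

    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos == neg), via the U statistic."""
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


def roc_auc(scores, labels, symbol: str = "") -> ROCResult:
    """ROC analysis of one per-sample score vector.

    ``labels`` marks each sample tumor (positive) or control (negative);
    samples with NaN scores are dropped.  The p-value tests AUC = 0.5 via
    the normal-approximation Mann-Whitney U test with tie correction.
    """
    s = pd.Series(scores, dtype=float)
    if isinstance(labels, (pd.Series, dict)):
        lab = pd.Series(labels).reindex(s.index)
    else:
        lab = pd.Series(list(labels), index=s.index)
    lab = lab.astype(str).str.lower()
    keep = s.notna()
    s, lab = s[keep], lab[keep]
    pos = s[lab == "tumor"].to_numpy()
    neg = s[lab == "control"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    auc = _mann_whitney_auc(pos, neg)
    low_predicts_tumor = auc < 0.5
    oriented = -s if low_predicts_tumor else s
    if low_predicts_tumor:
        auc = 1.0 - auc
    mw = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                            method="asymptotic")
    p = float(mw.pvalue)

    # explicit threshold sweep over the oriented scores
    y = (lab == "tumor").to_numpy()
    sc = oriented.to_numpy()
    order = np.argsort(-sc, kind="stable")
    y_sorted = y[order]
    sc_sorted = sc[order]
    distinct = np.r_[np.diff(sc_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / y.sum()]
    fpr = np.r_[0.0, fps / (~y).sum()]
    thresholds = np.r_[np.inf, sc_sorted[distinct]]
    return ROCResult(
        symbol=symbol, auc=auc, p_value=p, fpr=fpr, tpr=tpr,
        thresholds=thresholds, low_predicts_tumor=bool(low_predicts_tumor),
    )


@dataclass
class NBayesReport:
    """Stratified cross-validation report for the naive-Bayes classifier."""

    folds: int
    seed: int | None
    fold_accuracy: list
    mean_accuracy: float
    confusion: pd.DataFrame
    class_priors: dict
    fold_assignment: pd.Series = None
    zero_variance_flagged: list = field(default_factory=list)


def naive_bayes_cv(features: pd.DataFrame, labels, folds: int = 5,
                   seed: int | None = None) -> NBayesReport:
    """Gaussian naive Bayes under stratified k-fold cross-validation.

    ``features`` is symbols x samples (the pipeline's natural layout);
    samples are rows internally.  Within-class variances are floored at
    1e-9 by the Gaussian model's smoothing; features whose pooled
    variance is zero are flagged in the report.
    """
    if isinstance(labels, (pd.Series, dict)):
        lab = pd.Series(labels).astype(str)
    else:
        lab = pd.Series(list(labels), index=features.columns).astype(str)
    lab = lab[[c for c in lab.index if c in features.columns]]
    x = features[lab.index].to_numpy(float).T  # samples x features
    if np.isnan(x).any():
        col_med = np.nanmedian(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(col_med, inds[1])
    y = lab.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"each class needs >= {folds} samples, got {counts.to_dict()}"
        )
    zero_var = [
        features.index[i] for i in range(x.shape[1]) if np.var(x[:, i]) == 0
    ]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    fold_of = pd.Series(index=lab.index, dtype=int)
    y_true_all, y_pred_all = [], []
    classes = sorted(set(y))
    for f, (tr, te) in enumerate(skf.split(x, y)):
        clf = GaussianNB(var_smoothing=1e-9)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        accs.append(float((pred == y[te]).mean()))
        fold_of.iloc[te] = f
        y_true_all.extend(y[te])
        y_pred_all.extend(pred)
    conf = pd.DataFrame(
        confusion_matrix(y_true_all, y_pred_all, labels=classes),
        index=classes, columns=classes,
    )
    priors = (pd.Series(y).value_counts(normalize=True)).to_dict()
    return NBayesReport(
        folds=folds, seed=seed, fold_accuracy=accs,
        mean_accuracy=float(np.mean(accs)), confusion=conf,
        class_priors=priors, fold_assignment=fold_of,
        zero_variance_flagged=zero_var,
    )


def cohort_association(table, continuity_correction: bool = False) -> dict:
    """Chi-square test of independence plus 2x2 risk measures.

    For a 2x2 table [[a, b], [c, d]] (rows = exposure, columns =
    outcome/not): OR = ad/bc, RR = [a/(a+b)] / [c/(c+d)],
    AR = a/(a+b) - c/(c+d).  A zero cell triggers the Haldane-Anscombe
    +0.5 correction for the OR/RR, flagged in the result.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, dof, _ = stats.chi2_contingency(
        t, correction=continuity_correction
    )
    out = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    if t.shape == (2, 2):
        a, b, c, d = t.ravel()
        corrected = False
        aa, bb, cc, dd = a, b, c, d
        if 0 in (a, b, c, d):
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        out["odds_ratio"] = (aa * dd) / (bb * cc)
        out["relative_risk"] = (aa / (aa + bb)) / (cc / (cc + dd))
        out["absolute_risk"] = a / (a + b) - c / (c + d)
        out["haldane_corrected"] = corrected
    return out
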