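"""Flag combination, threshold tuning and performance evaluation.

The final verdict for a contour is the logical OR of the single-contour
feature model flag, the CCR flag and the connectedness flag.  Single-model
thresholds are tuned on a validation set to maximise the *combined*
balanced accuracy (mean of sensitivity and specificity) while the CCR and
connectedness flags stay fixed; the test set is always scored with the
thresholds chosen on validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ACCEPTABLE, ERRONEOUS = "acceptable", "erroneous"


@dataclass
class EvalMetrics:
    """Confusion counts plus derived sensitivity/specificity/BA."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def rounded(self, ndigits: int = 3) -> dict:
        """Counts and metrics rounded for reporting."""
        return {
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "balanced_accuracy": round(self.balanced_accuracy, ndigits),
        }


def combine_flags(single_flag, ccr_flag, conn_flag):
    """Logical OR of the three model verdicts (elementwise for arrays)."""
    return np.logical_or(np.logical_or(single_flag, ccr_flag), conn_flag)


def confusion_metrics(pred, truth) -> EvalMetrics:
    """Confusion counts of boolean predictions against truth labels.

    ``pred`` holds booleans (True = flagged erroneous); ``truth`` holds
    ``"acceptable"`` / ``"erroneous"`` labels or booleans.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = _truth_bool(truth)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return EvalMetrics(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
    )


def roc_auc(metrics, truth) -> float:
    """Area under the ROC curve of a score that is larger for errors.

    Computed as the Mann-Whitney concordance probability
    P(score_err > score_acc) + 0.5 P(tie) via midranks, which equals the
    trapezoidal ROC area.
    """
    scores = np.asarray(metrics, dtype=float)
    truth = _truth_bool(truth)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = sps.rankdata(scores)  # midranks handle ties as half-concordant
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tune_threshold(metrics, truth, fixed_flags=None) -> tuple[float, float]:
    """Threshold maximising combined balanced accuracy on validation data.

    A contour is flagged by the single model when its metric exceeds the
    threshold; the combined verdict ORs in ``fixed_flags`` (CCR |
    connectedness).  Candidates are midpoints between consecutive sorted
    unique metric values plus -inf/+inf; ties in balanced accuracy resolve
    to the highest threshold, favouring specificity.  Returns
    ``(threshold, balanced_accuracy)``.
    """
    scores = np.asarray(metrics, dtype=float)
    truth = _truth_bool(truth)
    if truth.all() or not truth.any():
        raise ValueError("threshold tuning needs both classes present")
    fixed = (np.zeros_like(truth) if fixed_flags is None
             else np.asarray(fixed_flags, dtype=bool))
    finite = np.unique(scores[np.isfinite(scores)])
    mids = (finite[:-1] + finite[1:]) / 2.0 if finite.size > 1 else np.array([])
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best_thr, best_ba = np.inf, -np.inf
    for thr in candidates:  # ascending; >= keeps the highest tied threshold
        pred = combine_flags(scores > thr, fixed, False)
        m = confusion_metrics(pred, truth)
        ba = m.balanced_accuracy
        if ba >= best_ba:
            best_ba, best_thr = ba, thr
    return float(best_thr), float(best_ba)


def subsample_balanced(acceptable_table, erroneous_table, n_per_oar: int = 5,
                       seed: int = 0, oar_column: str = "oar_type"):
    """Random per-OAR subsample of acceptable rows, merged with all errors.

    Draws ``n_per_oar`` acceptable rows per OAR type (all of them, with a
    warning-free fallback, when fewer exist) so statistical tests see a
    less imbalanced mix.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    picks = []
    for _, group in acceptable_table.groupby(oar_column, sort=True):
        if len(group) <= n_per_oar:
            picks.append(group)
        else:
            idx = rng.choice(len(group), size=n_per_oar, replace=False)
            picks.append(group.iloc[np.sort(idx)])
    import pandas as pd
    parts = [p for p in picks if len(p)] + [erroneous_table]
    return pd.concat(parts, axis=0, ignore_index=True)


def mcnemar_midp(preds_a, preds_b, truth) -> float:
    """Two-sided mid-p McNemar test for paired classifiers.

    With ``b`` = cases A correct / B wrong, ``c`` = A wrong / B correct,
    ``n = b + c`` and ``m = min(b, c)``:
    ``p = 2 P(X <= m) - P(X = m)`` for X ~ Binomial(n, 1/2); p = 1 when no
    discordant pairs exist.
    """
    a = np.asarray(preds_a, dtype=bool)
    bb = np.asarray(preds_b, dtype=bool)
    truth = _truth_bool(truth)
    correct_a, correct_b = a == truth, bb == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    return mcnemar_midp_counts(b, c)


def mcnemar_midp_counts(b: int, c: int) -> float:
    """Mid-p McNemar p-value from the two discordant-pair counts."""
    n = b + c
    if n == 0:
        return 1.0
    m = min(b, c)
    p = 2.0 * sps.binom.cdf(m, n, 0.5) - sps.binom.pmf(m, n, 0.5)
    return float(min(p, 1.0))


def _truth_bool(truth) -> np.ndarray:
    arr = np.asarray(truth)
    if arr.dtype.kind in "bi":
        return arr.astype(bool)
    return arr == ERRONEOUS
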