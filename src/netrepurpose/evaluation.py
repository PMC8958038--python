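"""Classification evaluation of scored drug–disease pairs.

All routines consume oriented scores (higher = stronger association, as
produced by :func:`netrepurpose.scoring.oriented_score`), so one code path
serves both the proximity and the crosstalk methods. Covers ROC/AUROC,
step-wise PR/AUPR, the sensitivity–specificity-intersection threshold,
recall, class-balanced resampled AUROC, Wilcoxon method comparison,
Benjamini–Hochberg correction and the mu+2*sigma prediction cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSummary",
    "RocCurve",
    "auroc",
    "aupr",
    "roc_points",
    "sens_spec_threshold",
    "recall_at",
    "balanced_auroc",
    "negative_draws",
    "compare_methods",
    "bh_correct",
    "prediction_cutoff",
    "prediction_sets",
    "evaluate_scores",
]


class EvaluationError(ValueError):
    pass


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    keep = np.isfinite(scores)
    if not keep.all():
        logger.info("evaluation: excluding %d NA/degenerate score(s)", (~keep).sum())
        scores, labels = scores[keep], labels[keep]
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("both classes must be present")
    return scores, labels


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray


@dataclass
class EvalSummary:
    """Per-method evaluation summary on one benchmark."""

    auroc: float
    aupr: float
    threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    recall: float
    balanced_aurocs: list[float] = field(default_factory=list)
    recall_new_positives: float | None = None
    mcc: float = math.nan
    f1: float = math.nan

    def to_dict(self) -> dict:
        d = {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "threshold": self.threshold,
            "sensitivity_at_threshold": self.sensitivity_at_threshold,
            "specificity_at_threshold": self.specificity_at_threshold,
            "recall": self.recall,
            "recall_new_positives": self.recall_new_positives,
            "mcc": self.mcc,
            "f1": self.f1,
            "balanced_auroc_mean": float(np.mean(self.balanced_aurocs))
            if self.balanced_aurocs
            else math.nan,
            "balanced_aurocs": list(map(float, self.balanced_aurocs)),
        }
        return d


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Step-wise (non-interpolated) area under the precision–recall curve."""
    scores, labels = _validate(scores, labels)
    return float(average_precision_score(labels, scores))


def roc_points(scores, labels) -> RocCurve:
    scores, labels = _validate(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus ±inf."""
    s = np.unique(scores)
    mids = (s[1:] + s[:-1]) / 2 if s.size > 1 else np.array([])
    return np.concatenate(([-np.inf], mids, [np.inf]))


def sens_spec_threshold(scores, labels) -> float:
    """Score threshold at the intersection of sensitivity and specificity.

    Enumerates midpoints between consecutive distinct scores (plus ±inf)
    and returns the threshold minimizing |sensitivity − specificity|, ties
    broken toward higher sensitivity (i.e. the lower threshold).
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_gap, best_sens = math.nan, math.inf, -1.0
    for t in _candidate_thresholds(scores):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12 or (abs(gap - best_gap) <= 1e-12 and sens > best_sens):
            best_t, best_gap, best_sens = t, gap, sens
    return float(best_t)


def recall_at(scores, labels, threshold: float) -> float:
    """Fraction of positives scoring at or above the threshold."""
    if not np.isfinite(threshold):
        raise EvaluationError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[(labels == 1) & np.isfinite(scores)]
    if pos.size == 0:
        raise EvaluationError("no positives")
    return float((pos >= threshold).mean())


def negative_draws(
    n_negatives: int, n_positives: int, n_resamples: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index draws (without replacement) of n_positives negatives per resample.

    Precomputing the draws and passing them to :func:`balanced_auroc` for
    several methods gives the paired design used for method comparison.
    """
    if n_negatives < n_positives:
        raise EvaluationError("need at least as many negatives as positives")
    return [
        rng.choice(n_negatives, size=n_positives, replace=False)
        for _ in range(n_resamples)
    ]


def balanced_auroc(
    scores,
    labels,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
    draws: list[np.ndarray] | None = None,
) -> list[float]:
    """AUROC on resampled sets of all positives plus equally many negatives.

    Addresses class imbalance: each resample keeps every positive and an
    equal-size uniform draw of negatives. Pass precomputed ``draws`` (see
    :func:`negative_draws`) to reuse the same negatives across methods.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if draws is None:
        if rng is None:
            raise ValueError("balanced_auroc needs a seeded Generator (or explicit draws)")
        draws = negative_draws(neg.size, pos.size, n_resamples, rng)
    out = []
    ones = np.ones(pos.size, dtype=int)
    zeros = np.zeros(pos.size, dtype=int)
    for d in draws:
        s = np.concatenate([pos, neg[d]])
        l = np.concatenate([ones, zeros])
        out.append(float(roc_auc_score(l, s)))
    return out


def compare_methods(aurocs_a, aurocs_b, paired: bool = True) -> float:
    """Two-sided Wilcoxon p-value comparing two AUROC samples.

    Signed-rank on paired resamples by default; rank-sum otherwise. If all
    paired differences are zero, p = 1 with a warning.
    """
    a = np.asarray(aurocs_a, dtype=float)
    b = np.asarray(aurocs_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise EvaluationError("paired comparison needs equal-length vectors")
        if np.allclose(a, b):
            logger.warning("compare_methods: all differences zero; p = 1")
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise EvaluationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prediction_cutoff(zscores) -> float:
    """Prediction cutoff mu_z + 2*sigma_z over all scored pairs.

    Uses the population (divide-by-n) standard deviation; a zero-variance
    input returns the mean with a warning.
    """
    z = np.asarray(zscores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 2:
        raise EvaluationError("need at least 2 z-scores")
    sd = float(z.std())
    if sd == 0:
        logger.warning("prediction_cutoff: zero variance; cutoff equals the mean")
    return float(z.mean() + 2 * sd)


def prediction_sets(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cutoff_a: float,
    cutoff_b: float,
    score_column: str = "z",
) -> tuple[set, set, set]:
    """Partition above-cutoff pairs into (agreed, unique_a, unique_b).

    Tables must cover the same (drug_id, disease_id) universe; scores are
    compared as oriented values in ``score_column``.
    """
    keys_a = set(zip(table_a["drug_id"], table_a["disease_id"]))
    keys_b = set(zip(table_b["drug_id"], table_b["disease_id"]))
    if keys_a != keys_b:
        diff = sorted(keys_a ^ keys_b)[:10]
        raise EvaluationError(f"pair universes differ; symmetric difference starts {diff}")
    above_a = {
        k
        for k, s in zip(zip(table_a["drug_id"], table_a["disease_id"]), table_a[score_column])
        if np.isfinite(s) and s >= cutoff_a
    }
    above_b = {
        k
        for k, s in zip(zip(table_b["drug_id"], table_b["disease_id"]), table_b[score_column])
        if np.isfinite(s) and s >= cutoff_b
    }
    return above_a & above_b, above_a - above_b, above_b - above_a


def _mcc_f1(scores, labels, threshold) -> tuple[float, float]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    return float(mcc), float(f1)


def evaluate_scores(
    scores,
    labels,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
    draws: list[np.ndarray] | None = None,
    new_positive_mask=None,
) -> EvalSummary:
    """Full evaluation of one method's oriented scores against binary labels."""
    raw_scores = np.asarray(scores, dtype=float)
    if new_positive_mask is not None:
        # keep the mask aligned with the NA filtering done below
        new_positive_mask = np.asarray(new_positive_mask, dtype=bool)[
            np.isfinite(raw_scores)
        ]
    scores, labels = _validate(scores, labels)
    t = sens_spec_threshold(scores, labels)
    if not np.isfinite(t):
        t = float(np.median(scores))
    sens = recall_at(scores, labels, t)
    neg = scores[labels == 0]
    spec = float((neg < t).mean())
    mcc, f1 = _mcc_f1(scores, labels, t)
    recall_new = None
    if new_positive_mask is not None:
        mask = np.asarray(new_positive_mask, dtype=bool)
        if mask.any():
            recall_new = float((scores[mask & (labels == 1)] >= t).mean())
    bal = balanced_auroc(scores, labels, n_resamples=n_resamples, rng=rng, draws=draws)
    return EvalSummary(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        threshold=t,
        sensitivity_at_threshold=sens,
        specificity_at_threshold=spec,
        recall=sens,
        balanced_aurocs=bal,
        recall_new_positives=recall_new,
        mcc=mcc,
        f1=f1,
    )
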