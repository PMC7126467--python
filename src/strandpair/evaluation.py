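"""Residue-level scoring: precision / recall / F1, PR curves, AUPRC,
cross-validation cutoff selection and per-protein report tables.

All counting is over unordered residue pairs with sequence separation
>= 3 — the pairs that can physically be cross-strand hydrogen-bond
partners.  The 0/0 convention is 0 throughout, so a predictor that outputs
nothing scores zero rather than undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MIN_SEPARATION, PairingLabels, PairingProbMap


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other):
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


@dataclass
class PRCurve:
    """Precision-recall points, one per distinct cutoff (descending), plus
    the step-integrated area under the curve."""

    points: list  # (threshold, precision, recall)
    auprc: float

    def plot(self, ax=None, **kwargs):
        """Draw the recall/precision staircase with matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rec = [p[2] for p in self.points]
        prec = [p[1] for p in self.points]
        ax.step([0.0] + rec, [prec[0] if prec else 1.0] + prec, where="post", **kwargs)
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.02)
        return ax


def _valid_pair_scores(pred: PairingProbMap, truth: PairingLabels):
    """Scores and binary labels over unordered valid pairs."""
    if pred.length != truth.length:
        raise ValueError(
            f"prediction (L={pred.length}) and truth (L={truth.length}) disagree")
    length = pred.length
    iu, ju = np.triu_indices(length, k=MIN_SEPARATION)
    scores = pred.probs[iu, ju]
    y = truth.to_matrix()[iu, ju]
    return scores, y


def confusion_counts(pred: PairingProbMap, truth: PairingLabels,
                     cutoff: float) -> ConfusionCounts:
    """Counts over unordered pairs: predicted means score >= cutoff."""
    scores, y = _valid_pair_scores(pred, truth)
    hit = scores >= cutoff
    pos = y > 0
    return ConfusionCounts(TP=int(np.sum(hit & pos)),
                           FP=int(np.sum(hit & ~pos)),
                           FN=int(np.sum(~hit & pos)))


def precision_recall_f1(c: ConfusionCounts):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean; 0/0 -> 0."""
    p = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    r = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def f1_from_rates(precision_pct: float, recall_pct: float) -> float:
    """F1 (in percent) from precision and recall given in percent."""
    if not (0 <= precision_pct <= 100 and 0 <= recall_pct <= 100):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    p, r = precision_pct / 100.0, recall_pct / 100.0
    if p + r == 0:
        return 0.0
    return 100.0 * 2 * p * r / (p + r)


def pr_curve(pred: PairingProbMap, truth: PairingLabels) -> PRCurve:
    """One PR point per distinct predicted value, thresholds descending.

    AUPRC uses step (right-continuous) integration sum_k (R_k - R_{k-1}) P_k
    with R_0 = 0, which never interpolates optimistically between points.
    """
    scores, y = _valid_pair_scores(pred, truth)
    n_true = int(y.sum())
    if n_true == 0:
        raise ValueError("PR curve undefined: no true pairs")
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    # cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(scores))[0]
    last = np.concatenate([distinct, [len(scores) - 1]])
    tp = np.cumsum(y)[last]
    npred = last + 1
    prec = tp / npred
    rec = tp / n_true
    points = [(float(scores[k]), float(p), float(r))
              for k, p, r in zip(last, prec, rec)]
    prev_r = 0.0
    auprc = 0.0
    for _, p, r in points:
        auprc += (r - prev_r) * p
        prev_r = r
    return PRCurve(points=points, auprc=float(auprc))


def _pool_scores(pairs):
    """Concatenate valid-pair scores and labels over a list of
    (PairingProbMap, PairingLabels) tuples."""
    all_scores, all_y = [], []
    for pred, truth in pairs:
        s, y = _valid_pair_scores(pred, truth)
        all_scores.append(s)
        all_y.append(y)
    return np.concatenate(all_scores), np.concatenate(all_y)


def _best_f1_over_cutoffs(scores, y):
    """Exhaustive scan of distinct scores; returns (best F1, cutoff).

    Candidate cutoffs are midpoints between adjacent distinct score values
    (and between the lowest score and 0), so the returned cutoff sits
    strictly inside the open interval that realizes the optimum.  Ties
    break toward the higher cutoff.
    """
    n_true = int(y.sum())
    if n_true == 0:
        raise ValueError("cutoff selection needs at least one true pair")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    distinct = np.nonzero(np.diff(s))[0]
    last = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(yy)[last]
    npred = last + 1
    prec = tp / npred
    rec = tp / n_true
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.maximum(denom, 1e-300), 0.0)
    k = int(np.argmax(f1))  # argmax takes the first (highest-cutoff) optimum
    upper = s[last[k]]
    lower = s[last[k + 1]] if k + 1 < len(last) else 0.0
    mid = (upper + lower) / 2.0
    if not lower < mid <= upper:  # adjacent floats: the open interval is empty
        mid = upper
    return float(f1[k]), float(mid)


def select_cutoff(pool) -> float:
    """Cutoff maximizing pooled F1 over a validation pool.

    ``pool`` is a list of (PairingProbMap, PairingLabels) tuples (counts are
    pooled before the scan, i.e. micro-averaged).  Ties break toward the
    higher cutoff; the returned value is the midpoint of the optimal open
    interval between adjacent distinct scores.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty validation pool")
    scores, y = _pool_scores(pool)
    _, cutoff = _best_f1_over_cutoffs(scores, y)
    return cutoff


def evaluate_per_protein(preds, truths, cutoff: float, ids=None) -> pd.DataFrame:
    """Per-protein precision/recall/F1 plus a micro-averaged pooled row."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    ids = list(ids) if ids is not None else [f"p{k}" for k in range(len(preds))]
    rows = []
    total = ConfusionCounts()
    for pid, pred, truth in zip(ids, preds, truths):
        c = confusion_counts(pred, truth, cutoff)
        total = total + c
        p, r, f1 = precision_recall_f1(c)
        rows.append({"id": pid, "precision": p, "recall": r, "f1": f1})
    p, r, f1 = precision_recall_f1(total)
    rows.append({"id": "pooled", "precision": p, "recall": r, "f1": f1})
    return pd.DataFrame(rows)


def f1_win_fraction(preds_a, preds_b, truths, cutoff_a: float,
                    cutoff_b: float | None = None) -> float:
    """Fraction of proteins where prediction set A's F1 is strictly higher."""
    cutoff_b = cutoff_a if cutoff_b is None else cutoff_b
    wins = 0
    n = 0
    for pa, pb, truth in zip(preds_a, preds_b, truths):
        _, _, fa = precision_recall_f1(confusion_counts(pa, truth, cutoff_a))
        _, _, fb = precision_recall_f1(confusion_counts(pb, truth, cutoff_b))
        wins += fa > fb
        n += 1
    if n == 0:
        raise ValueError("empty comparison")
    return wins / n
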