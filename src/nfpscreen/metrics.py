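"""Classification metrics for virtual-screening enrichment.

Confusion counts, precision, recall and F1 follow the standard screening
definitions (a "hit" is the positive class: a molecule whose docking energy
falls below the percentile threshold). ROC and precision–recall curves with
their areas delegate to scikit-learn. The predictive enrichment probability
(PEP) is the fraction of true hits the model recovers, reported both as an
aggregate (identical to recall) and per 0.01 kcal/mol energy bin, so the
recovery of the deepest-binding tail can be inspected directly.

Undefined ratios (e.g. precision with no predicted hits) are returned as
NaN — a flagged value that poisons downstream ranking instead of silently
scoring zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)

GRANULARITY = 0.01  # kcal/mol energy-bin width for the PEP curve


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PEPCurve:
    """Per-energy-bin enrichment: (bin center kcal/mol, PEP, molecule count)."""

    bins: list[tuple[float, float, int]]
    granularity: float
    energy_threshold: float
    aggregate: float  # over all true hits; equals recall on the same records


def confusion(predicted_labels, true_labels) -> ConfusionCounts:
    pred = np.asarray(predicted_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
    )


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN when no hits were predicted."""
    denom = c.tp + c.fp
    return math.nan if denom == 0 else c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN when there are no true hits."""
    denom = c.tp + c.fn
    return math.nan if denom == 0 else c.tp / denom


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall: 2/(precision⁻¹ + recall⁻¹)."""
    return f1_from_rates(precision(c), recall(c))


def f1_from_rates(p: float, r: float) -> float:
    if math.isnan(p) or math.isnan(r):
        return math.nan
    if p == 0.0 or r == 0.0:
        return 0.0
    return 2.0 / (1.0 / p + 1.0 / r)


def _check_two_class(true: np.ndarray) -> None:
    if true.min() == true.max():
        raise ValueError("need at least one positive and one negative label")


def roc_curve(scores, true_labels):
    """ROC curve over all unique score thresholds, plus its area.

    Returns ((fpr, tpr, thresholds), auc); the area equals the Mann–Whitney
    concordance probability P(score_hit > score_nonhit).
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    _check_two_class(true)
    fpr, tpr, thr = _sk_roc_curve(true, scores)
    return (fpr, tpr, thr), float(roc_auc_score(true, scores))


def pr_curve(scores, true_labels):
    """Precision–recall curve plus its area (stepwise / average precision)."""
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    _check_two_class(true)
    prec, rec, thr = precision_recall_curve(true, scores)
    return (prec, rec, thr), float(average_precision_score(true, scores))


def _round_half_away(x: float, decimals: int = 2) -> float:
    q = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


def pep_curve(
    energies,
    predicted_labels,
    energy_threshold: float,
    granularity: float = GRANULARITY,
) -> PEPCurve:
    """Predictive enrichment probability over the true-hit energy range.

    Inputs are the docking energies and hard predictions of the *true hits*
    only (energy < threshold). Energies are rounded (half away from zero) to
    the granularity; each populated bin reports predicted-hit count / total
    count. Empty bins are omitted. The aggregate PEP over all hits equals
    recall computed on the same records.
    """
    energies = np.asarray(energies, dtype=float)
    pred = np.asarray(predicted_labels, dtype=int)
    if energies.shape != pred.shape:
        raise ValueError("energies and predictions must align")
    mask = energies < energy_threshold
    if not mask.any():
        raise ValueError("no true hits below the threshold; PEP is undefined")
    energies, pred = energies[mask], pred[mask]
    decimals = max(0, -int(round(math.log10(granularity))))
    binned: dict[float, list[int]] = {}
    for e, p in zip(energies, pred):
        key = _round_half_away(e, decimals)
        binned.setdefault(key, [0, 0])
        binned[key][0] += int(p)
        binned[key][1] += 1
    bins = [(center, hit / tot, tot) for center, (hit, tot) in sorted(binned.items())]
    return PEPCurve(
        bins=bins,
        granularity=granularity,
        energy_threshold=energy_threshold,
        aggregate=float(pred.sum() / pred.size),
    )


def metrics_report(scores, predicted_labels, true_labels, energies=None, energy_threshold=None) -> dict:
    """One-stop JSON-ready metric bundle for an evaluated split."""
    c = confusion(predicted_labels, true_labels)
    _, roc_auc = roc_curve(scores, true_labels)
    _, pr_auc = pr_curve(scores, true_labels)
    report = {
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1(c),
        "roc_auc": roc_auc,
        "pr_auc": pr_auc,
        "confusion": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
    }
    if energies is not None and energy_threshold is not None:
        energies = np.asarray(energies, dtype=float)
        pred = np.asarray(predicted_labels, dtype=int)
        mask = energies < energy_threshold
        if mask.any():
            report["pep_aggregate"] = pep_curve(
                energies[mask], pred[mask], energy_threshold
            ).aggregate
    return report
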