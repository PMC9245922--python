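"""Performance measures for three-way (pathogenic / benign / UV) calls.

All measures derive from the binary confusion counts of the covered
(non-UV) predictions: PPV, NPV, sensitivity, specificity, accuracy, the
Matthews correlation coefficient (MCC), its normalization
nMCC = (1 + MCC) / 2, and the overall performance measure

    OPM = (PPV + NPV)(Sensitivity + Specificity)(Accuracy + nMCC) / 8,

a single balanced summary in [0, 1].  Coverage is the fraction of cases
receiving a hard call among all cases, so reject-option evaluation reads
as a (performance, coverage) pair.  A measure whose denominator is zero
is reported as None (flagged undefined), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from varitol.core import BENIGN, PATHOGENIC
from varitol.model import UV, PredictionResult


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN; reals are admitted so fold averages remain valid."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one confusion count must be positive")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The eight performance measures; None marks an undefined ratio."""

    ppv: Optional[float]
    npv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    mcc: Optional[float]
    nmcc: Optional[float]
    opm: Optional[float]
    auc: Optional[float] = None
    coverage: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> Dict[str, Optional[float]]:
        """Display form: values rounded to the table precision."""
        return {
            f.name: (None if v is None else round(v, ndigits))
            for f in fields(self)
            if (v := getattr(self, f.name)) is not None or f.name not in ("auc", "coverage")
        }


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """All eight measures from one confusion table.

    MCC uses the product-of-marginals denominator; when any marginal is
    zero the MCC (and everything derived from it) is undefined.  OPM is
    the product of the three pair-sums divided by 8 and is undefined if
    any constituent is.
    """
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
        nmcc = (1 + mcc) / 2
    else:
        mcc = nmcc = None
    parts = (ppv, npv, sens, spec, acc, nmcc)
    if any(p is None for p in parts):
        opm = None
    else:
        opm = (ppv + npv) * (sens + spec) * (acc + nmcc) / 8
    return MetricReport(
        ppv=ppv, npv=npv, sensitivity=sens, specificity=spec,
        accuracy=acc, mcc=mcc, nmcc=nmcc, opm=opm,
    )


def compute_coverage(n_classified: int, n_total: int) -> float:
    """Fraction of cases receiving a hard (non-UV) call."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_classified <= n_total:
        raise ValueError("n_classified must lie in [0, n_total]")
    return n_classified / n_total


def auc_rank(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with mid-rank tie handling.

    ``labels`` hold the positive class :data:`~varitol.core.PATHOGENIC`
    and negative class :data:`~varitol.core.BENIGN`.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([lab == PATHOGENIC for lab in labels])
    n_pos = int(pos.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # mid-ranks for ties
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def tally(
    predictions: Sequence[PredictionResult],
    labels: Sequence[str],
    with_rejection: bool = True,
):
    """Confusion counts of covered calls + number classified.

    With rejection, UV predictions are excluded from the counts; without,
    every case is forced to the side of 0.5 its mean probability falls on
    (an exact 0.5 forces benign — the conservative call).
    """
    tp = tn = fp = fn = n_classified = 0
    for pred, lab in zip(predictions, labels):
        decision = pred.decision
        if not with_rejection and decision == UV:
            decision = PATHOGENIC if pred.mu > 0.5 else BENIGN
        if decision == UV:
            continue
        n_classified += 1
        if decision == PATHOGENIC:
            if lab == PATHOGENIC:
                tp += 1
            else:
                fp += 1
        else:
            if lab == BENIGN:
                tn += 1
            else:
                fn += 1
    counts = ConfusionCounts(tp, tn, fp, fn) if (tp + tn + fp + fn) else None
    return counts, n_classified


def evaluate_predictions(
    predictions: Sequence[PredictionResult],
    labels: Sequence[str],
    groups: Optional[Sequence[str]] = None,
    auc_on_covered: bool = True,
) -> Dict[str, Dict[str, Optional[MetricReport]]]:
    """Metric reports per cohort, each with and without rejection.

    Returns ``{cohort: {"with_rejection": report, "without_rejection":
    report}}``; cohort ``"all"`` covers every case, plus one cohort per
    distinct group tag when ``groups`` is given.  UV predictions are
    excluded from confusion counts but included in the coverage
    denominator.  AUC ranks the ensemble-mean probabilities against the
    labels (covered cases only by default).  A cohort whose covered set
    is empty gets a None report (metrics undefined) with coverage 0.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if not predictions:
        raise ValueError("empty test set")
    cohorts: Dict[str, List[int]] = {"all": list(range(len(predictions)))}
    if groups is not None:
        for i, g in enumerate(groups):
            cohorts.setdefault(str(g), []).append(i)
    out: Dict[str, Dict[str, Optional[MetricReport]]] = {}
    for name, idx in cohorts.items():
        preds = [predictions[i] for i in idx]
        labs = [labels[i] for i in idx]
        out[name] = {}
        for key, with_rej in (("with_rejection", True), ("without_rejection", False)):
            counts, n_cls = tally(preds, labs, with_rejection=with_rej)
            coverage = compute_coverage(n_cls, len(preds))
            if counts is None:
                out[name][key] = MetricReport(
                    ppv=None, npv=None, sensitivity=None, specificity=None,
                    accuracy=None, mcc=None, nmcc=None, opm=None,
                    auc=None, coverage=coverage,
                )
                continue
            report = compute_metrics(counts)
            if with_rej and auc_on_covered:
                pairs = [
                    (p.mu, l) for p, l in zip(preds, labs) if p.decision != UV
                ]
            else:
                pairs = [(p.mu, l) for p, l in zip(preds, labs)]
            scores = [s for s, _ in pairs]
            labs2 = [l for _, l in pairs]
            try:
                auc = auc_rank(scores, labs2)
            except ValueError:
                auc = None
            out[name][key] = MetricReport(
                **{
                    f.name: getattr(report, f.name)
                    for f in fields(MetricReport)
                    if f.name not in ("auc", "coverage")
                },
                auc=auc,
                coverage=coverage,
            )
    return out
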