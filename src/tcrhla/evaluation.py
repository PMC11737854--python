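"""Classifier performance metrics.

Confusion-matrix statistics (sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/total, precision = TP/(TP+FP)), ROC curves
with the AUC computed by the rank / Mann-Whitney U formulation (exact under
ties), precision-recall curves with average precision, and cross-allele
summaries correlating per-allele precision with the number of associated
clonotypes and with allele prevalence.

Undefined ratios (zero denominators) are reported as NaN with an explicit
flag, never silently as 0, so cross-allele averages stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .association import AssociationRecord
from .types import Cohort, HlaAllele

__all__ = [
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "pr_curve",
    "summarize_across_alleles",
]


@dataclass
class EvalReport:
    allele: Optional[HlaAllele]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    auc_roc: float = float("nan")
    auc_pr: float = float("nan")
    undefined: List[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int, name: str, undefined: List[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def confusion_metrics(
    calls: Sequence[int], truth: Sequence[int], allele: Optional[HlaAllele] = None
) -> EvalReport:
    """Confusion-matrix metrics from binary calls against binary truth."""
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} calls vs {truth.shape} truth")
    if calls.size == 0:
        raise ValueError("need at least one entry")
    tp = int(np.sum((calls == 1) & (truth == 1)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    undefined: List[str] = []
    return EvalReport(
        allele=allele,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn, "accuracy", undefined),
        precision=_ratio(tp, tp + fp, "precision", undefined),
        undefined=undefined,
    )


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> Tuple[pd.DataFrame, float]:
    """ROC curve points and AUC.

    The AUC is the normalized Mann-Whitney U statistic: the fraction of
    (positive, negative) pairs the score orders correctly, ties counted
    one half — exact even with tied scores.  1.0 for a perfect ranking,
    0.5 in expectation for label-independent scores.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(truth.sum())
    n_neg = int(truth.size - n_pos)
    if n_pos == 0:
        raise ValueError("no positive examples in truth")
    if n_neg == 0:
        raise ValueError("no negative examples in truth")
    ranks = rankdata(scores)  # average ranks handle ties
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(truth, scores)
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, float(auc)


def pr_curve(scores: Sequence[float], truth: Sequence[int]) -> Tuple[pd.DataFrame, float]:
    """Precision-recall curve and average precision."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if truth.sum() == 0:
        raise ValueError("no positive examples in truth")
    precision, recall, thresholds = precision_recall_curve(truth, scores)
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([thresholds, [np.inf]]),
            "recall": recall,
            "precision": precision,
        }
    )
    ap = float(average_precision_score(truth, scores))
    return curve, ap


def summarize_across_alleles(
    reports: Sequence[EvalReport],
    cohort: Cohort,
    associations: Sequence[AssociationRecord],
) -> Dict[str, object]:
    """Cross-allele summary: Pearson correlation of per-allele precision with
    (i) the number of associated clonotypes and (ii) allele prevalence.

    Alleles whose precision is undefined are dropped from the correlations;
    zero variance in precision yields a flagged undefined correlation.
    """
    if len(reports) < 3:
        raise ValueError("need reports for at least 3 alleles")
    n_assoc = {}
    for r in associations:
        n_assoc[r.allele] = n_assoc.get(r.allele, 0) + 1
    n_donors = len(cohort)
    rows = []
    for rep in reports:
        if rep.allele is None:
            raise ValueError("reports must carry their allele")
        prevalence = sum(1 for d in cohort if d.has_allele(rep.allele)) / n_donors
        rows.append(
            {
                "allele": rep.allele.code,
                "precision": rep.precision,
                "n_associations": n_assoc.get(rep.allele, 0),
                "prevalence": prevalence,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["precision"].notna()
    out: Dict[str, object] = {"table": df, "undefined": []}
    sub = df[ok]
    for key, col in (("precision_vs_n_associations", "n_associations"),
                     ("precision_vs_prevalence", "prevalence")):
        if len(sub) < 3 or sub["precision"].nunique() < 2 or sub[col].nunique() < 2:
            out[key] = (float("nan"), float("nan"))
            out["undefined"].append(key)
        else:
            r, p = pearsonr(sub["precision"], sub[col])
            out[key] = (float(r), float(p))
    return out


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Per-allele metrics table (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "allele": r.allele.code if r.allele else "",
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "auc_roc": r.auc_roc,
                "auc_pr": r.auc_pr,
                "undefined": ";".join(r.undefined),
            }
            for r in reports
        ]
    )
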