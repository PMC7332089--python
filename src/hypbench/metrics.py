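"""Site-centric evaluation: confusion counts, the six metrics, replica
aggregation, PR/ROC curves, and the random / consensus baselines.

Every modified and unmodified proline is an independent example.  The six
metrics — sensitivity, specificity, balanced accuracy (WACC), F1, precision
and Matthews correlation — use their standard definitions, with the 0/0
convention: any undefined ratio is reported as 0 (and logged) so replica
aggregation stays total.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from hypbench.assembly import ReplicaSet
from hypbench.io import PredictionRecord, SiteKey

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Sn", "Sp", "WACC", "F1", "PREC", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    Sn: float
    Sp: float
    WACC: float
    F1: float
    PREC: float
    MCC: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def calls_by_key(predictions: Iterable[PredictionRecord]) -> dict[SiteKey, int]:
    """Index prediction records by site key (single method/level expected)."""
    out: dict[SiteKey, int] = {}
    for p in predictions:
        if p.key in out:
            raise ValueError(f"multiple predictions for site {p.key}")
        out[p.key] = p.call
    return out


def confusion(calls: Mapping[SiteKey, int], replica: ReplicaSet,
              missing: str = "error") -> ConfusionCounts:
    """Confusion counts over exactly one replica's sites.

    ``calls`` maps site key → binary call (see :func:`calls_by_key`); sites
    outside the replica are ignored.  ``missing`` selects the policy for
    replica sites without a prediction: ``"error"`` (default) or
    ``"negative"`` (count the site as called unmodified, with a logged tally).
    """
    if missing not in ("error", "negative"):
        raise ValueError(f"unknown missing-prediction policy {missing!r}")
    n_missing = 0

    def call_for(key: SiteKey) -> int:
        nonlocal n_missing
        if key in calls:
            return calls[key]
        if missing == "error":
            raise KeyError(f"no prediction for replica site {key}")
        n_missing += 1
        return 0

    tp = sum(call_for(k) for k in replica.positives)
    fp = sum(call_for(k) for k in replica.negatives)
    if n_missing:
        logger.info("confusion: %d replica sites lacked predictions, counted as negative calls",
                    n_missing)
    return ConfusionCounts(TP=tp, FN=len(replica.positives) - tp,
                           FP=fp, TN=len(replica.negatives) - fp)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.debug("metric %s: 0/0 reported as 0 by convention", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The six standard metrics from one confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sn = _ratio(c.TP, c.TP + c.FN, "Sn")
    sp = _ratio(c.TN, c.TN + c.FP, "Sp")
    prec = _ratio(c.TP, c.TP + c.FP, "PREC")
    f1 = _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1")
    denom = math.sqrt(float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, denom, "MCC")
    return MetricSet(Sn=sn, Sp=sp, WACC=(sn + sp) / 2, F1=f1, PREC=prec, MCC=mcc)


def aggregate(metric_sets: Sequence[MetricSet]) -> dict[str, dict[str, float]]:
    """Per-metric mean and sample (n−1) standard deviation over replicas."""
    if len(metric_sets) < 2:
        raise ValueError("aggregation needs at least 2 replicas")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metric_sets])
        out[name] = {"mean": float(vals.mean()), "stdev": float(vals.std(ddof=1))}
    return out


@dataclass
class CurveResult:
    """PR and ROC curves over a score sweep, plus the trapezoidal ROC AUC."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def curves(scores: Mapping[SiteKey, float], truth: Mapping[SiteKey, int]) -> CurveResult:
    """Precision–recall and ROC curves for score-bearing predictions.

    Thresholds sweep the unique scores (ties grouped); AUC is the trapezoid
    area under the ROC.  If every score is identical the curve degenerates to
    a single point and AUC 0.5 is reported with a warning.
    """
    keys = sorted(truth)
    missing = [k for k in keys if k not in scores]
    if missing:
        raise KeyError(f"{len(missing)} evaluated sites lack scores, e.g. {missing[0]}")
    y = np.array([truth[k] for k in keys])
    s = np.array([scores[k] for k in keys], dtype=float)
    if np.ptp(s) == 0:
        warnings.warn("all scores identical: degenerate single-point curve, AUC 0.5",
                      stacklevel=2)
        pos = y.mean()
        return CurveResult(thresholds=np.array([s[0]]), recall=np.array([1.0]),
                           precision=np.array([pos]), fpr=np.array([1.0]),
                           tpr=np.array([1.0]), auc=0.5)
    prec, rec, pr_thr = precision_recall_curve(y, s)
    fpr, tpr, roc_thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return CurveResult(thresholds=roc_thr, recall=rec, precision=prec,
                       fpr=fpr, tpr=tpr, auc=auc)


def curves_to_tsv(result: CurveResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t, f, tp in zip(result.thresholds, result.fpr, result.tpr):
            fh.write(f"{t:g}\t{f:g}\t{tp:g}\n")


def random_baseline(sites: Iterable[SiteKey], p: float = 0.5, seed: int = 0,
                    method: str = "Random") -> list[PredictionRecord]:
    """The Bernoulli baseline: each site called modified with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    site_list = list(sites)
    calls = rng.random(len(site_list)) < p
    return [PredictionRecord(protein_id=k[0], position=k[1], call=int(c),
                             method=method, score=float(p))
            for k, c in zip(site_list, calls)]


def consensus(per_method_calls: Sequence[Mapping[SiteKey, int]],
              method: str = "Consensus") -> list[PredictionRecord]:
    """Majority vote across predictors; ties are resolved to not-modified.

    Every constituent method must cover every site covered by any of them.
    """
    if not per_method_calls:
        raise ValueError("consensus needs at least one method")
    all_keys = set().union(*(set(m) for m in per_method_calls))
    records = []
    for key in sorted(all_keys):
        votes = []
        for i, m in enumerate(per_method_calls):
            if key not in m:
                raise KeyError(f"method #{i} has no call for site {key}")
            votes.append(m[key])
        n_pos = sum(votes)
        call = int(n_pos * 2 > len(votes))  # strict majority; tie -> negative
        records.append(PredictionRecord(protein_id=key[0], position=key[1],
                                        call=call, method=method,
                                        score=n_pos / len(votes)))
    return records
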