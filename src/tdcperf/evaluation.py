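"""Voxelwise evaluation of predicted lesion masks against ground truth.

Quality factors are sensitivity, specificity and accuracy; accuracy is the
headline comparator because it reflects both trueness and precision while
counting true negatives (Sørensen–Dice is deliberately not offered — dropping
true negatives over-weights unspecific parameters; a Jaccard helper exists
for phantom QA only). ROC analysis uses the rank (Mann–Whitney) AUC estimator
with DeLong placement-value confidence intervals; the best-parameter question
is answered with a continuity-corrected odds-ratio test on per-case
"best accuracy" counts, reported as logarithmic quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm, rankdata

from .io import VolumeMask, ParameterMap


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class QualityFactors:
    """Fractions in [0, 1]; a factor whose denominator is empty is None
    (undefined), never 0."""

    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class OddsResult:
    log_odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple  # ((a, b), (c, d)) after any continuity correction


def confusion_counts(pred: VolumeMask, truth: VolumeMask, region: VolumeMask, excluded=None) -> ConfusionCounts:
    """TP/FP/TN/FN voxel counts inside the evaluation region.

    ``excluded`` (optional boolean volume) removes sentinel-excluded voxels
    from the region before counting.
    """
    if pred.values.shape != truth.values.shape or pred.values.shape != region.values.shape:
        raise ValueError("prediction, truth and region grids do not match")
    reg = region.values.copy()
    if excluded is not None:
        reg &= ~np.asarray(excluded, dtype=bool)
    if not reg.any():
        raise ValueError("evaluation region is empty")
    p = pred.values[reg]
    t = truth.values[reg]
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def quality_factors(c: ConfusionCounts) -> QualityFactors:
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total if c.total > 0 else None
    return QualityFactors(sensitivity=sens, specificity=spec, accuracy=acc)


def jaccard(pred: VolumeMask, truth: VolumeMask) -> float:
    """Intersection over union — phantom QA only, not a cohort quality factor."""
    inter = np.sum(pred.values & truth.values)
    union = np.sum(pred.values | truth.values)
    return float(inter / union) if union else np.nan


def roc_auc_delong(scores, truth, region=None) -> RocResult:
    """Rank-estimator AUC with a DeLong 95% confidence interval.

    ``scores`` may be a ParameterMap (evaluated at finite voxels inside
    ``region``) or a 1-D array paired with boolean ``truth`` labels. Tied
    score pairs get half credit. Both classes must be present.
    """
    if isinstance(scores, ParameterMap):
        if region is None:
            raise ValueError("region required with a map input")
        sel = region.values & scores.defined_mask
        x = scores.values[sel]
        y = truth.values[sel]
    else:
        x = np.asarray(scores, dtype=float)
        y = np.asarray(truth.values if isinstance(truth, VolumeMask) else truth, dtype=bool)
    pos = x[y]
    neg = x[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("ROC needs both classes in the evaluation region")
    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    # placement values (DeLong): V10_i = P(neg < pos_i) + .5 P(neg = pos_i)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.975)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n_pos=m,
        n_neg=n,
    )


def odds_ratio_best(best_flags, others_flags) -> OddsResult:
    """Odds-ratio test: does this parameter achieve the best accuracy per
    measurement more often than the pooled remaining parameters?

    Builds the 2x2 table (best / not best) x (parameter / others) with a 0.5
    continuity correction when any cell is zero; returns the log odds ratio,
    its normal-approximation 95% CI and a two-sided p-value.
    """
    bf = np.asarray(best_flags, dtype=bool)
    of = np.asarray(others_flags, dtype=bool)
    if bf.size == 0 or of.size == 0:
        raise ValueError("odds-ratio test needs at least one case per arm")
    a = float(np.sum(bf))
    b = float(bf.size - a)
    c = float(np.sum(of))
    d = float(of.size - c)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = norm.ppf(0.975)
    zstat = log_or / se
    p = float(2 * norm.sf(abs(zstat)))
    return OddsResult(
        log_odds_ratio=log_or,
        ci_low=log_or - z * se,
        ci_high=log_or + z * se,
        p_value=p,
        table=((a, b), (c, d)),
    )


@dataclass
class EvaluationReport:
    """Per-parameter voxelwise evaluation results plus run metadata."""

    results: dict  # parameter -> {counts, quality, roc, threshold}
    metadata: dict

    def to_json(self, path=None):
        def enc(o):
            if isinstance(o, (ConfusionCounts, QualityFactors, RocResult, OddsResult)):
                return asdict(o)
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        payload = {"results": self.results, "metadata": self.metadata}
        if path is None:
            return json.dumps(payload, indent=2, sort_keys=True, default=enc)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=enc)

    def to_csv(self, path):
        import pandas as pd

        rows = []
        for param, res in self.results.items():
            row = {"parameter": param}
            for key in ("counts", "quality", "roc"):
                obj = res.get(key)
                if obj is not None:
                    row.update({f"{key}_{k}": v for k, v in asdict(obj).items()})
            thr = res.get("threshold")
            if np.isscalar(thr):
                row["threshold"] = thr
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def evaluate_parameter(pmap: ParameterMap, threshold, truth: VolumeMask, region: VolumeMask):
    """Threshold a map, count, score and ROC it against truth in one go."""
    from .standardization import threshold_map

    pred = threshold_map(pmap, threshold)
    excluded = ~pmap.defined_mask
    counts = confusion_counts(pred, truth, region, excluded=excluded)
    qf = quality_factors(counts)
    roc = roc_auc_delong(pmap, truth, region)
    return {"counts": counts, "quality": qf, "roc": roc, "threshold": threshold, "pred": pred}
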