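"""Agreement metrics between continuous AI scores and discrete truth.

The continuous predictions are used directly for the mean absolute error;
for chance-corrected agreement (quadratic weighted Cohen's kappa) and the
support-weighted precision/recall/F1 they are first discretized by
round-half-up to the feature's score levels.  One report row per feature
and dataset, plus a NAS row built from the summed activity components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SLIDE_SCORE_MAX
from .scoring import NAS_COMPONENTS

REPORT_COLUMNS = [
    "feature",
    "dataset",
    "mae",
    "kappa_qw",
    "weighted_precision",
    "weighted_recall",
    "weighted_f1",
    "n",
]


def discretize(ai_score: float, s_max: int):
    """Round-half-up to the nearest score level, clipped to [0, s_max]."""
    arr = np.floor(np.asarray(ai_score, dtype=float) + 0.5)
    out = np.clip(arr, 0, s_max).astype(int)
    return out if out.ndim else int(out)


def mae(predictions, truth) -> float:
    """Mean absolute error of the continuous predictions."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(np.mean(np.abs(p - t)))


def quadratic_weighted_kappa(pred_discrete, truth, levels) -> float:
    """Cohen's kappa with quadratic disagreement weights.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with ``w_ij = (i - j)^2 / S^2``,
    O the observed confusion counts and E the outer product of the
    marginals scaled to n.  When both raters are constant and equal the
    expected-disagreement denominator vanishes and kappa is defined as 1.
    """
    levels = np.asarray(levels)
    p = np.asarray(pred_discrete)
    t = np.asarray(truth)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("need equal-length non-empty vectors")
    if not (np.isin(p, levels).all() and np.isin(t, levels).all()):
        raise ValueError("values outside the level set")
    k = len(levels)
    index = {v: i for i, v in enumerate(levels.tolist())}
    o = np.zeros((k, k))
    for ti, pi in zip(t, p):
        o[index[ti], index[pi]] += 1
    n = o.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    s = max(k - 1, 1)
    w = (ii - jj) ** 2 / s**2
    denom = (w * e).sum()
    if denom == 0:
        return 1.0
    return float(1.0 - (w * o).sum() / denom)


def weighted_prf(pred_discrete, truth, levels) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 over the score levels.

    Per-level metrics are averaged with weights equal to the level's
    support in the truth; levels absent from the truth get zero weight and
    per-level zero divisions resolve to 0.
    """
    p = np.asarray(pred_discrete)
    t = np.asarray(truth)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("need equal-length non-empty vectors")
    precisions, recalls, f1s, supports = [], [], [], []
    for level in levels:
        tp = np.sum((p == level) & (t == level))
        fp = np.sum((p == level) & (t != level))
        fn = np.sum((p != level) & (t == level))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
        supports.append(np.sum(t == level))
    supports = np.asarray(supports, dtype=float)
    total = supports.sum()
    wts = supports / total
    return (
        float(np.dot(wts, precisions)),
        float(np.dot(wts, recalls)),
        float(np.dot(wts, f1s)),
    )


def confusion_matrix(pred_discrete, truth, levels) -> np.ndarray:
    """Counts with rows = truth level, cols = predicted level."""
    k = len(levels)
    index = {v: i for i, v in enumerate(list(levels))}
    out = np.zeros((k, k), dtype=int)
    for ti, pi in zip(np.asarray(truth), np.asarray(pred_discrete)):
        out[index[ti], index[pi]] += 1
    return out


@dataclass
class EvalReport:
    """Table-style metrics of one feature on one dataset."""

    feature: str
    dataset: str
    mae: float
    kappa_qw: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    n: int
    confusion: np.ndarray

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "dataset": self.dataset,
            "mae": self.mae,
            "kappa_qw": self.kappa_qw,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "n": self.n,
        }


def _report(feature: str, dataset: str, truth: np.ndarray, ai: np.ndarray, s_max: int) -> EvalReport:
    levels = np.arange(s_max + 1)
    truth_int = np.rint(truth).astype(int)
    pred_int = np.asarray(discretize(ai, s_max))
    return EvalReport(
        feature=feature,
        dataset=dataset,
        mae=mae(ai, truth),
        kappa_qw=quadratic_weighted_kappa(pred_int, truth_int, levels),
        weighted_precision=weighted_prf(pred_int, truth_int, levels)[0],
        weighted_recall=weighted_prf(pred_int, truth_int, levels)[1],
        weighted_f1=weighted_prf(pred_int, truth_int, levels)[2],
        n=len(truth),
        confusion=confusion_matrix(pred_int, truth_int, levels),
    )


def evaluate_scores(records: pd.DataFrame, dataset: str = "synthetic", include_nas: bool = True) -> list[EvalReport]:
    """EvalReports per feature (plus NAS) from ScoreRecord rows.

    ``records`` needs columns slide_id, feature, truth, ai_score; rows with
    missing truth are excluded per feature.  The NAS row sums the discrete
    truths and the continuous AI activity components over slides that carry
    all three.
    """
    reports: list[EvalReport] = []
    for feature, s_max in SLIDE_SCORE_MAX.items():
        sub = records[(records["feature"] == feature) & records["truth"].notna()]
        if sub.empty:
            warnings.warn(f"no records for feature {feature!r}; omitted from the report", stacklevel=2)
            continue
        reports.append(_report(feature, dataset, sub["truth"].to_numpy(float), sub["ai_score"].to_numpy(float), s_max))
    if include_nas:
        wide_t = records.pivot_table(index="slide_id", columns="feature", values="truth")
        wide_p = records.pivot_table(index="slide_id", columns="feature", values="ai_score")
        have = [f for f in NAS_COMPONENTS if f in wide_t.columns]
        if len(have) == 3:
            complete = wide_t[list(NAS_COMPONENTS)].notna().all(axis=1) & wide_p[list(NAS_COMPONENTS)].notna().all(axis=1)
            if complete.sum() > 0:
                truth_nas = wide_t.loc[complete, list(NAS_COMPONENTS)].sum(axis=1).to_numpy(float)
                ai_nas = wide_p.loc[complete, list(NAS_COMPONENTS)].sum(axis=1).to_numpy(float)
                reports.append(_report("NAS", dataset, truth_nas, ai_nas, 8))
    return reports


def reports_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """Serialize reports in the standard column order."""
    return pd.DataFrame([r.to_row() for r in reports])[REPORT_COLUMNS]
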