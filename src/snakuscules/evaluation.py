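"""Detection scoring against ground-truth centers.

Detections and truths are matched one-to-one by a nearest-neighbor sweep:
candidate pairs closer than ``max_dist`` are accepted greedily in ascending
distance order.  Precision, recall, F-measure and Jaccard follow the usual
count-based formulas::

    Pr = TP / (TP + FP)        Re = TP / (TP + FN)
    F  = 2 Pr Re / (Pr + Re)   J  = Pr Re / (Pr + Re - Pr Re)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EvaluationReport",
    "match_centers",
    "compute_metrics",
    "metrics_from_precision_recall",
    "evaluate_detections",
]


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    jaccard: Optional[float]
    matches: List[Tuple[int, int, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "jaccard": self.jaccard,
        }


def match_centers(
    detected: np.ndarray, truth: np.ndarray, max_dist: float
) -> Tuple[int, int, int, List[Tuple[int, int, float]]]:
    """Greedy one-to-one matching within ``max_dist``.

    Returns ``(tp, fp, fn, matches)`` with matches as
    ``(detection_index, truth_index, distance)`` triples.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    detected = np.asarray(detected, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    n_det = detected.shape[0] if detected.ndim >= 1 else 0
    n_tru = truth.shape[0] if truth.ndim >= 1 else 0
    if n_det == 0 or n_tru == 0:
        return 0, n_det, n_tru, []
    detected = np.atleast_2d(detected)
    truth = np.atleast_2d(truth)

    tree = cKDTree(truth)
    pairs = []
    for di, point in enumerate(detected):
        for ti in tree.query_ball_point(point, max_dist):
            d = float(np.linalg.norm(point - truth[ti]))
            if d <= max_dist:
                pairs.append((d, di, ti))
    pairs.sort()
    det_used = np.zeros(n_det, dtype=bool)
    tru_used = np.zeros(n_tru, dtype=bool)
    matches: List[Tuple[int, int, float]] = []
    for d, di, ti in pairs:
        if det_used[di] or tru_used[ti]:
            continue
        det_used[di] = True
        tru_used[ti] = True
        matches.append((di, ti, d))
    tp = len(matches)
    return tp, n_det - tp, n_tru - tp, matches


def compute_metrics(
    tp: int, fp: int, fn: int, matches: Optional[list] = None
) -> EvaluationReport:
    """Report from raw counts; undefined ratios are reported as ``None``."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    pr = tp / (tp + fp) if tp + fp > 0 else None
    re = tp / (tp + fn) if tp + fn > 0 else None
    f = j = None
    if pr is not None and re is not None:
        if pr + re > 0:
            f = 2.0 * pr * re / (pr + re)
            j = pr * re / (pr + re - pr * re)
        else:
            f = 0.0
            j = 0.0
    return EvaluationReport(tp, fp, fn, pr, re, f, j, matches or [])


def metrics_from_precision_recall(precision: float, recall: float) -> dict:
    """F-measure and Jaccard directly from printed precision/recall values."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return {"f_measure": 0.0, "jaccard": 0.0}
    f = 2.0 * precision * recall / (precision + recall)
    j = precision * recall / (precision + recall - precision * recall)
    return {"f_measure": f, "jaccard": j}


def evaluate_detections(
    detected: np.ndarray, truth: np.ndarray, max_dist: float
) -> EvaluationReport:
    """Match centers then compute the metric report."""
    tp, fp, fn, matches = match_centers(detected, truth, max_dist)
    return compute_metrics(tp, fp, fn, matches)
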