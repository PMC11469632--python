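"""Segmentation accuracy and sensitivity metrics.

Sensitivity counts a ground-truth sound as a true positive when some predicted
sound of the same type has its midpoint bracketed by the truth interval
(half-open [start, end)); otherwise it is a false negative, and

    sensitivity = TP / (TP + FN).

Accuracy is the mean absolute distance between the midpoints of matched
truth/predicted sounds, matched greedily one-to-one by ascending midpoint
distance. Predictions wholly outside the truth-annotated span are disregarded:
the segmenter can find more cardiac cycles than the ground truth covers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import STATE_S1, STATE_S2, StateAnnotation
from .segment import Label, Segmentation


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fn: int
    sensitivity: float
    mean_midpoint_error_s1: float
    mean_midpoint_error_s2: float
    n_truth_s1: int
    n_truth_s2: int

    def __str__(self) -> str:  # pragma: no cover - presentation only
        sens = f"{100 * self.sensitivity:.2f}%" if np.isfinite(self.sensitivity) else "n/a"
        e1 = f"{1e3 * self.mean_midpoint_error_s1:.2f} ms" if np.isfinite(self.mean_midpoint_error_s1) else "n/a"
        e2 = f"{1e3 * self.mean_midpoint_error_s2:.2f} ms" if np.isfinite(self.mean_midpoint_error_s2) else "n/a"
        return (
            f"TP={self.tp} FN={self.fn} sensitivity={sens} "
            f"S1 midpoint error={e1} S2 midpoint error={e2}"
        )


def compute_sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); NaN when there are no ground-truth sounds."""
    total = tp + fn
    return tp / total if total > 0 else float("nan")


def _pred_midpoints(pred: Segmentation, label: Label, span: tuple[float, float]) -> np.ndarray:
    """Midpoints of predicted sounds whose extent overlaps the truth span."""
    lo, hi = span
    mids = [
        iv.midpoint_s
        for iv in pred.labeled(label)
        if iv.end_s > lo and iv.start_s < hi
    ]
    return np.asarray(mids)


def _truth_intervals(truth: StateAnnotation, state: int) -> np.ndarray:
    return truth.intervals_for(state)


def _bracket_counts(truth_iv: np.ndarray, pred_mid: np.ndarray) -> tuple[int, int]:
    """Count truth intervals bracketing at least one predicted midpoint."""
    tp = 0
    for on, off in truth_iv:
        if np.any((pred_mid >= on) & (pred_mid < off)):
            tp += 1
    return tp, truth_iv.shape[0] - tp


def sensitivity_eval(pred: Segmentation, truth: StateAnnotation) -> EvalReport:
    """Midpoint-bracketing sensitivity of predicted S1/S2 against the truth."""
    if len(truth) == 0:
        return EvalReport(0, 0, float("nan"), float("nan"), float("nan"), 0, 0)
    span = truth.span
    tp = fn = 0
    counts = {}
    for label, state in ((Label.S1, STATE_S1), (Label.S2, STATE_S2)):
        t_iv = _truth_intervals(truth, state)
        p_mid = _pred_midpoints(pred, label, span)
        t, f = _bracket_counts(t_iv, p_mid)
        tp += t
        fn += f
        counts[state] = t_iv.shape[0]
    err1, err2 = _midpoint_errors(pred, truth)
    return EvalReport(
        tp=tp,
        fn=fn,
        sensitivity=compute_sensitivity(tp, fn),
        mean_midpoint_error_s1=err1,
        mean_midpoint_error_s2=err2,
        n_truth_s1=counts[STATE_S1],
        n_truth_s2=counts[STATE_S2],
    )


def greedy_midpoint_matching(truth_mid: np.ndarray, pred_mid: np.ndarray) -> list[tuple[int, int]]:
    """One-to-one matching by ascending midpoint distance.

    Returns (truth index, pred index) pairs; each index is used at most once.
    """
    if truth_mid.size == 0 or pred_mid.size == 0:
        return []
    dist = np.abs(truth_mid[:, None] - pred_mid[None, :])
    order = np.argsort(dist, axis=None, kind="stable")
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        ti, pi = divmod(int(flat), pred_mid.size)
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        pairs.append((ti, pi))
        if len(used_t) == truth_mid.size or len(used_p) == pred_mid.size:
            break
    return pairs


def _midpoint_errors(pred: Segmentation, truth: StateAnnotation) -> tuple[float, float]:
    span = truth.span
    errs = []
    for label, state in ((Label.S1, STATE_S1), (Label.S2, STATE_S2)):
        t_iv = _truth_intervals(truth, state)
        t_mid = t_iv.mean(axis=1) if t_iv.size else np.empty(0)
        p_mid = _pred_midpoints(pred, label, span)
        pairs = greedy_midpoint_matching(t_mid, p_mid)
        if pairs:
            errs.append(float(np.mean([abs(t_mid[t] - p_mid[p]) for t, p in pairs])))
        else:
            errs.append(float("nan"))
    return errs[0], errs[1]


def accuracy_eval(pred: Segmentation, truth: StateAnnotation) -> EvalReport:
    """Mean midpoint-distance accuracy (S1 and S2 separately).

    Identical report structure to :func:`sensitivity_eval`; provided as a
    named entry point for the accuracy metric.
    """
    return sensitivity_eval(pred, truth)


def segmentation_success(
    pred: Segmentation,
    truth: StateAnnotation,
    exclude: list[tuple[float, float]] | None = None,
    pad_s: float = 0.15,
) -> bool:
    """Recording-level success: every available ground-truth sound was found.

    A recording is successfully segmented when every truth S1/S2 interval
    brackets the midpoint of a same-type predicted sound. Truth sounds within
    ``pad_s`` of an ``exclude`` window (e.g. a known noise region, which no
    segmenter is expected to label) are not counted as available.
    """
    exclude = exclude or []
    for label, state in ((Label.S1, STATE_S1), (Label.S2, STATE_S2)):
        t_iv = truth.intervals_for(state)
        mids = np.array([iv.midpoint_s for iv in pred.labeled(label)])
        for on, off in t_iv:
            if any(on < e1 + pad_s and off > e0 - pad_s for e0, e1 in exclude):
                continue
            if mids.size == 0 or not np.any((mids >= on) & (mids < off)):
                return False
    return True


def pooled_report(reports: list[EvalReport]) -> EvalReport:
    """Pool TP/FN across recordings; average the per-recording midpoint errors."""
    tp = sum(r.tp for r in reports)
    fn = sum(r.fn for r in reports)
    e1 = [r.mean_midpoint_error_s1 for r in reports if np.isfinite(r.mean_midpoint_error_s1)]
    e2 = [r.mean_midpoint_error_s2 for r in reports if np.isfinite(r.mean_midpoint_error_s2)]
    return EvalReport(
        tp=tp,
        fn=fn,
        sensitivity=compute_sensitivity(tp, fn),
        mean_midpoint_error_s1=float(np.mean(e1)) if e1 else float("nan"),
        mean_midpoint_error_s2=float(np.mean(e2)) if e2 else float("nan"),
        n_truth_s1=sum(r.n_truth_s1 for r in reports),
        n_truth_s2=sum(r.n_truth_s2 for r in reports),
    )
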