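"""Segmentation evaluation: IoU, Dice, FNR, FPR from pixel confusion counts.

For a binary prediction P and ground truth G on one slice with
TP = |P∩G|, FP = |P\\G|, FN = |G\\P| and TN the remaining pixels:

    IoU  = TP / (TP + FP + FN)
    Dice = 2·TP / (2·TP + FP + FN)
    FNR  = FN / (TP + FN)
    FPR  = FP / (FP + TN)

Degenerate slices (a zero denominator, e.g. empty ground truth) are resolved
by convention and flagged: two empty masks agree perfectly (IoU = Dice = 1),
false positives on an empty ground truth score 0, and FNR with nothing to
miss is 0. By default cohort aggregation includes only slices whose ground
truth contains at least one positive pixel; ``include_degenerate=True``
switches to all-slices mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import Cohort, ConfusionCounts, validate_mask

__all__ = [
    "confusion",
    "slice_metrics",
    "SliceEval",
    "aggregate",
    "evaluate_cohort",
]

METRIC_NAMES = ("iou", "dice", "fnr", "fpr")


def confusion(prediction: np.ndarray, ground_truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between a prediction and its ground truth.

    Raises
    ------
    ValueError
        If the two masks have different shapes.
    """
    p = validate_mask(prediction, name="prediction")
    g = validate_mask(ground_truth, name="ground_truth")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs ground truth {g.shape}")
    pb = p.astype(bool)
    gb = g.astype(bool)
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class SliceEval:
    """Per-slice metric values plus the counts they derive from.

    ``degenerate`` is True when any metric's denominator was zero and the
    value was fixed by convention rather than computed.
    """

    iou: float
    dice: float
    fnr: float
    fpr: float
    counts: ConfusionCounts
    degenerate: bool


def slice_metrics(counts: ConfusionCounts) -> SliceEval:
    """Compute IoU, Dice, FNR and FPR from confusion counts.

    Zero denominators never raise; they are resolved by the conventions in
    the module docstring and flagged ``degenerate``.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    degenerate = False

    union = tp + fp + fn
    if union == 0:  # both masks empty: perfect agreement
        iou, dice = 1.0, 1.0
        degenerate = True
    else:
        iou = tp / union
        dice = 2 * tp / (2 * tp + fp + fn)

    pos = tp + fn
    if pos == 0:  # empty ground truth: nothing to miss
        fnr = 0.0
        degenerate = True
    else:
        fnr = fn / pos

    neg = fp + tn
    if neg == 0:  # all-positive ground truth
        fpr = 0.0
        degenerate = True
    else:
        fpr = fp / neg

    return SliceEval(iou=iou, dice=dice, fnr=fnr, fpr=fpr, counts=counts, degenerate=degenerate)


def aggregate(
    evals: list[tuple[str, SliceEval]],
    scheme: str = "per_patient_then_cohort",
) -> dict:
    """Aggregate per-slice metrics into cohort means.

    Parameters
    ----------
    evals
        ``(patient_id, SliceEval)`` pairs, already filtered to the slices to
        include.
    scheme
        ``"per_patient_then_cohort"`` averages each metric within each
        patient first, then takes the unweighted mean over patients (each
        patient counts equally, the paper-style two-stage mean).
        ``"pooled_slices"`` is the flat unweighted mean over all slices.

    Returns
    -------
    dict
        Mean ``iou``/``dice``/``fnr``/``fpr`` plus ``scheme``, ``n_slices``
        and ``n_patients`` bookkeeping.
    """
    if scheme not in ("per_patient_then_cohort", "pooled_slices"):
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    if not evals:
        raise ValueError("no evaluable slices to aggregate")

    out: dict = {"scheme": scheme, "n_slices": len(evals)}
    if scheme == "pooled_slices":
        for name in METRIC_NAMES:
            out[name] = float(np.mean([getattr(e, name) for _, e in evals]))
        out["n_patients"] = len({pid for pid, _ in evals})
        return out

    per_patient: dict[str, list[SliceEval]] = {}
    for pid, e in evals:
        per_patient.setdefault(pid, []).append(e)
    for name in METRIC_NAMES:
        patient_means = [
            float(np.mean([getattr(e, name) for e in group]))
            for group in per_patient.values()
        ]
        out[name] = float(np.mean(patient_means))
    out["n_patients"] = len(per_patient)
    return out


def evaluate_masks(
    cohort: Cohort,
    fused: dict[tuple[str, str], np.ndarray],
    *,
    method: str = "method",
    include_degenerate: bool = False,
) -> pd.DataFrame:
    """Evaluate one fused mask per slice against the cohort's ground truth.

    ``fused`` maps ``(patient_id, slice_id)`` to a binary mask. Returns a
    per-slice table with one row per evaluated slice; by default slices with
    empty ground truth are excluded.
    """
    rows = []
    for s in cohort.slices:
        if not include_degenerate and s.ground_truth.sum() == 0:
            continue
        key = (s.patient_id, s.slice_id)
        if key not in fused:
            raise ValueError(f"method {method!r} missing a mask for slice {key}")
        ev = slice_metrics(confusion(fused[key], s.ground_truth))
        rows.append(
            {
                "patient_id": s.patient_id,
                "slice_id": s.slice_id,
                "method": method,
                "tp": ev.counts.tp,
                "fp": ev.counts.fp,
                "fn": ev.counts.fn,
                "tn": ev.counts.tn,
                "iou": ev.iou,
                "dice": ev.dice,
                "fnr": ev.fnr,
                "fpr": ev.fpr,
                "degenerate": ev.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "slice_id", "method",
            "tp", "fp", "fn", "tn",
            "iou", "dice", "fnr", "fpr", "degenerate",
        ],
    )


def evaluate_cohort(
    cohort: Cohort,
    fused: dict[tuple[str, str], np.ndarray],
    *,
    method: str = "method",
    include_degenerate: bool = False,
    scheme: str = "per_patient_then_cohort",
) -> tuple[pd.DataFrame, dict]:
    """Per-slice table plus aggregated summary for one method's masks."""
    table = evaluate_masks(
        cohort, fused, method=method, include_degenerate=include_degenerate
    )
    evals = [
        (row.patient_id, slice_metrics(ConfusionCounts(row.tp, row.fp, row.fn, row.tn)))
        for row in table.itertuples()
    ]
    summary = aggregate(evals, scheme=scheme)
    summary["method"] = method
    return table, summary
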