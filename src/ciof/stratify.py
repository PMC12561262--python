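"""Clot-burden stratification of slices by embolization ratio.

The embolization ratio of a slice is the fraction of its pixels labeled
embolus in ground truth. Slices are binned into three burden strata,
by default < 1e-4, [1e-4, 1e-3], and > 1e-3 (the middle bin closed on both
ends, matching the printed "<1e-4 / 1e-4~1e-3 / >1e-3" convention). On a
512x512 grid these edges correspond to lesion sizes of roughly <26, 26-262
and >262 pixels. Stratum assignment depends only on ground truth, never on
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import Cohort, validate_mask
from .metrics import confusion, slice_metrics

__all__ = ["StratumSpec", "embolization_ratio", "assign_stratum", "stratified_report"]


@dataclass(frozen=True)
class StratumSpec:
    """Two ratio edges defining three burden strata."""

    edges: tuple[float, float] = (1e-4, 1e-3)
    labels: tuple[str, str, str] = ("lt_1e-4", "1e-4_to_1e-3", "gt_1e-3")

    def __post_init__(self) -> None:
        lo, hi = self.edges
        if not 0 < lo < hi < 1:
            raise ValueError(f"stratum edges must satisfy 0 < lo < hi < 1, got {self.edges}")
        if len(self.labels) != 3:
            raise ValueError("exactly three stratum labels required")


def embolization_ratio(ground_truth: np.ndarray) -> float:
    """Fraction of a slice's pixels labeled embolus in ground truth."""
    gt = validate_mask(ground_truth, name="ground_truth")
    return float(gt.sum()) / gt.size


def assign_stratum(ratio: float, spec: StratumSpec = StratumSpec()) -> str:
    """Map an embolization ratio to its burden-stratum label.

    The middle stratum is closed: a ratio exactly equal to either edge
    belongs to it.
    """
    if not 0 <= ratio <= 1:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    lo, hi = spec.edges
    if ratio < lo:
        return spec.labels[0]
    if ratio <= hi:
        return spec.labels[1]
    return spec.labels[2]


def stratified_report(
    cohort: Cohort,
    methods: dict[str, dict[tuple[str, str], np.ndarray]],
    spec: StratumSpec = StratumSpec(),
    *,
    scheme: str = "per_patient_then_cohort",
) -> pd.DataFrame:
    """Per-stratum mean IoU and Dice for each fusion method.

    Parameters
    ----------
    cohort
        Evaluation cohort; only slices with ground-truth positives are
        evaluable (an all-empty slice has no defined burden stratum of
        interest and ratio 0).
    methods
        Maps method name -> {(patient_id, slice_id) -> fused mask}; every
        method must cover every evaluable slice.
    spec
        Stratum edges and labels.
    scheme
        Aggregation within each stratum: patient-first two-stage mean
        (default) or pooled slices.

    Returns
    -------
    pandas.DataFrame
        One row per (method, stratum) with mean IoU/Dice and the stratum
        slice count; empty strata appear with count 0 and NaN means.
    """
    evaluable = [s for s in cohort.slices if s.ground_truth.sum() > 0]
    if not evaluable:
        raise ValueError("no evaluable slices (no ground-truth positives)")
    for name, fused in methods.items():
        missing = [
            (s.patient_id, s.slice_id)
            for s in evaluable
            if (s.patient_id, s.slice_id) not in fused
        ]
        if missing:
            raise ValueError(f"method {name!r} missing masks for slices {missing[:5]}")

    strata_of = {
        (s.patient_id, s.slice_id): assign_stratum(embolization_ratio(s.ground_truth), spec)
        for s in evaluable
    }
    rows = []
    for name, fused in methods.items():
        per_stratum: dict[str, list[tuple[str, float, float]]] = {
            lab: [] for lab in spec.labels
        }
        for s in evaluable:
            key = (s.patient_id, s.slice_id)
            ev = slice_metrics(confusion(fused[key], s.ground_truth))
            per_stratum[strata_of[key]].append((s.patient_id, ev.iou, ev.dice))
        for lab in spec.labels:
            entries = per_stratum[lab]
            if not entries:
                rows.append({"method": name, "stratum": lab, "n_slices": 0,
                             "mean_iou": np.nan, "mean_dice": np.nan})
                continue
            if scheme == "pooled_slices":
                mean_iou = float(np.mean([e[1] for e in entries]))
                mean_dice = float(np.mean([e[2] for e in entries]))
            else:
                by_pat: dict[str, list[tuple[float, float]]] = {}
                for pid, iou, dice in entries:
                    by_pat.setdefault(pid, []).append((iou, dice))
                mean_iou = float(np.mean(
                    [np.mean([v[0] for v in vals]) for vals in by_pat.values()]))
                mean_dice = float(np.mean(
                    [np.mean([v[1] for v in vals]) for vals in by_pat.values()]))
            rows.append({"method": name, "stratum": lab, "n_slices": len(entries),
                         "mean_iou": mean_iou, "mean_dice": mean_dice})
    return pd.DataFrame(rows)
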