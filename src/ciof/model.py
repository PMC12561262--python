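"""IoU-optimized consensus-threshold selection, statsmodels-style.

:class:`ConsensusFusion` is built from a training :class:`~ciof.masks.Cohort`
and ``fit()`` sweeps every consensus threshold k = 1..M: each training slice
is fused at k, per-slice IoU is computed against ground truth, averaged
within each patient, and the patient means are averaged over the |D|
training patients to give IoU_k. The fitted
:class:`ConsensusFusionResults` carries the IoU_k curve and
K* = argmax_k IoU_k (smallest k on ties, favoring sensitivity), and applies
that frozen K* to held-out cohorts — refusing to evaluate any cohort that
shares a patient with the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import ciof_fuse
from .masks import Cohort, SliceRecord
from .metrics import (
    ConfusionCounts,
    aggregate,
    evaluate_cohort,
    slice_metrics,
)

__all__ = ["ConsensusFusion", "ConsensusFusionResults", "sweep_k", "apply_k"]


def _iou_per_k(record: SliceRecord) -> np.ndarray:
    """IoU of the fused mask at every k = 1..M for one slice.

    Uses the vote-count histogram: at threshold k the fused positives are the
    pixels with at least k votes, so TP(k)/FP(k) are suffix sums of the vote
    histogram inside/outside the ground truth.
    """
    m = record.predictions.m
    votes = record.predictions.sum_mask
    gt = record.ground_truth.astype(bool)
    pos = int(gt.sum())
    hist_in = np.bincount(votes[gt], minlength=m + 1)
    hist_out = np.bincount(votes[~gt], minlength=m + 1)
    # tp[k-1] = #{pixels in G with votes >= k}
    tp = np.cumsum(hist_in[::-1])[::-1][1:]
    fp = np.cumsum(hist_out[::-1])[::-1][1:]
    fn = pos - tp
    union = tp + fp + fn
    with np.errstate(invalid="ignore"):
        iou = np.where(union > 0, tp / np.maximum(union, 1), 1.0)
    return iou


@dataclass(frozen=True)
class KSweepResult:
    """Mean IoU per candidate threshold and the selected K*."""

    mean_iou_per_k: tuple[float, ...]
    k_star: int
    n_patients: int

    @property
    def m(self) -> int:
        return len(self.mean_iou_per_k)


class ConsensusFusion:
    """K-of-M consensus fusion model for a training cohort of mask ensembles.

    Parameters
    ----------
    train
        Training cohort; every slice must carry the same ensemble size M.
    include_degenerate
        Include slices with empty ground truth in the sweep (both-empty
        fusions then score IoU 1 by convention). Default False: only slices
        with at least one ground-truth positive pixel inform K*.
    """

    def __init__(self, train: Cohort, *, include_degenerate: bool = False):
        if train.n_slices == 0:
            raise ValueError("training cohort is empty")
        self.train = train
        self.m = train.m  # validates consistent ensemble size
        self.include_degenerate = include_degenerate
        self._evaluable = [
            s
            for s in train.slices
            if include_degenerate or s.ground_truth.sum() > 0
        ]
        if not self._evaluable:
            raise ValueError("training cohort has no evaluable slices "
                             "(no slice with ground-truth positives)")

    def fit(self) -> "ConsensusFusionResults":
        """Sweep k = 1..M and select K* maximizing patient-averaged IoU."""
        per_patient: dict[str, list[np.ndarray]] = {}
        for s in self._evaluable:
            per_patient.setdefault(s.patient_id, []).append(_iou_per_k(s))
        patient_curves = np.stack(
            [np.mean(curves, axis=0) for curves in per_patient.values()]
        )
        mean_iou_per_k = patient_curves.mean(axis=0)
        k_star = int(np.argmax(mean_iou_per_k)) + 1  # smallest k on ties
        sweep = KSweepResult(
            mean_iou_per_k=tuple(float(v) for v in mean_iou_per_k),
            k_star=k_star,
            n_patients=len(per_patient),
        )
        return ConsensusFusionResults(model=self, sweep=sweep)


@dataclass
class ConsensusFusionResults:
    """Fitted consensus threshold and everything needed to apply it."""

    model: ConsensusFusion
    sweep: KSweepResult
    _train_patients: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self._train_patients = set(self.model.train.patient_ids)

    @property
    def k_star(self) -> int:
        return self.sweep.k_star

    @property
    def mean_iou_per_k(self) -> tuple[float, ...]:
        return self.sweep.mean_iou_per_k

    def fuse(self, cohort: Cohort) -> dict[tuple[str, str], np.ndarray]:
        """Fused mask at the frozen K* for every slice of a cohort."""
        return {
            (s.patient_id, s.slice_id): ciof_fuse(s.predictions, self.k_star)
            for s in cohort.slices
        }

    def evaluate(
        self,
        test: Cohort,
        *,
        scheme: str = "per_patient_then_cohort",
        allow_train: bool = False,
    ) -> tuple[pd.DataFrame, dict]:
        """Fuse and score a held-out cohort at the frozen K*.

        Refuses any cohort sharing a patient with the training set unless
        ``allow_train=True`` (used for reporting training-set performance);
        K* is never re-optimized here.
        """
        overlap = self._train_patients & test.patient_ids
        if overlap and not allow_train:
            raise ValueError(
                "patient-level leakage: patients "
                f"{sorted(overlap)[:5]} appear in both the K*-selection "
                "cohort and the evaluation cohort"
            )
        return evaluate_cohort(
            test,
            self.fuse(test),
            method=f"ciof_k{self.k_star}",
            include_degenerate=self.model.include_degenerate,
            scheme=scheme,
        )

    def summary(self) -> str:
        """Human-readable fit summary: the IoU_k curve and the chosen K*."""
        lines = [
            "Consensus Intersection-Optimized Fusion",
            "=" * 44,
            f"Ensemble size M:        {self.sweep.m}",
            f"Training patients |D|:  {self.sweep.n_patients}",
            f"Evaluable slices:       {len(self.model._evaluable)}",
            f"Selected K*:            {self.k_star}",
            "",
            "  k   mean IoU_k",
            "  --  ----------",
        ]
        for k, iou in enumerate(self.mean_iou_per_k, start=1):
            marker = "  <- K*" if k == self.k_star else ""
            lines.append(f"  {k:<3} {iou:10.4f}{marker}")
        return "\n".join(lines)

    def plot_sweep(self, ax=None):
        """Plot the mean-IoU-versus-k curve with K* highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.arange(1, self.sweep.m + 1)
        ax.plot(ks, self.mean_iou_per_k, marker="o")
        ax.axvline(self.k_star, linestyle="--", color="tab:red",
                   label=f"K* = {self.k_star}")
        ax.set_xlabel("consensus threshold k")
        ax.set_ylabel("mean IoU on training patients")
        ax.set_xticks(ks)
        ax.legend()
        return ax


def sweep_k(train: Cohort, *, include_degenerate: bool = False) -> KSweepResult:
    """Functional wrapper: sweep k on a training cohort and select K*."""
    return ConsensusFusion(train, include_degenerate=include_degenerate).fit().sweep


def apply_k(
    test: Cohort,
    k_star: int,
    *,
    source_patients: set[str] | None = None,
    include_degenerate: bool = False,
    scheme: str = "per_patient_then_cohort",
) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame, dict]:
    """Fuse and evaluate a test cohort at a fixed, previously selected K*.

    ``source_patients`` is the patient set K* was selected on; any overlap
    with the test cohort raises a leakage error.
    """
    if source_patients is not None:
        overlap = set(source_patients) & test.patient_ids
        if overlap:
            raise ValueError(
                "patient-level leakage: patients "
                f"{sorted(overlap)[:5]} appear in both the K*-selection "
                "cohort and the test cohort"
            )
    if not 1 <= k_star <= test.m:
        raise ValueError(f"k_star={k_star} out of valid range [1, {test.m}]")
    fused = {
        (s.patient_id, s.slice_id): ciof_fuse(s.predictions, k_star)
        for s in test.slices
    }
    table, summary = evaluate_cohort(
        test,
        fused,
        method=f"ciof_k{k_star}",
        include_degenerate=include_degenerate,
        scheme=scheme,
    )
    return fused, table, summary
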