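"""Core data model: binary masks, ensemble stacks, slice records, cohorts.

Masks are plain ``numpy`` arrays of dtype ``uint8`` holding only 0/1, indexed
``(row, col)``. A *slice* is one 2-D image; a *patient* groups slices; a
*cohort* groups patients. Each slice carries one ground-truth mask and an
:class:`EnsembleStack` of M aligned model predictions whose pixel-wise vote
sum drives consensus fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "validate_mask",
    "EnsembleStack",
    "SliceRecord",
    "Cohort",
    "ConfusionCounts",
    "stack_predictions",
    "split_patients",
]


def validate_mask(mask: np.ndarray, *, name: str = "mask") -> np.ndarray:
    """Validate a 2-D binary mask and return it as a ``uint8`` array.

    Parameters
    ----------
    mask
        Array-like of shape ``(height, width)`` with values in {0, 1}.
    name
        Label used in error messages.

    Returns
    -------
    numpy.ndarray
        The same pixels as ``uint8``; a view where possible, else a copy.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one pixel")
    if not np.isin(arr, (0, 1)).all():
        bad = np.unique(arr[~np.isin(arr, (0, 1))])
        raise ValueError(f"{name} must be binary (0/1); found values {bad[:5]}")
    return arr.astype(np.uint8, copy=False)


def positive_count(mask: np.ndarray) -> int:
    """Number of 1-pixels in a binary mask."""
    return int(validate_mask(mask).sum())


@dataclass(frozen=True)
class EnsembleStack:
    """M aligned binary prediction masks for one slice plus their vote sum.

    ``sum_mask[p]`` counts how many of the M models label pixel ``p``
    positive; it is the quantity thresholded by consensus fusion.
    """

    masks: tuple[np.ndarray, ...]
    sum_mask: np.ndarray
    m: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.sum_mask.shape

    def __post_init__(self) -> None:
        if self.m != len(self.masks) or self.m < 1:
            raise ValueError("M must equal the number of masks and be >= 1")
        if self.sum_mask.shape != self.masks[0].shape:
            raise ValueError("sum_mask shape differs from mask shape")


def stack_predictions(masks: list[np.ndarray] | tuple[np.ndarray, ...]) -> EnsembleStack:
    """Stack M model masks for one slice and compute their pixel-wise sum.

    Raises
    ------
    ValueError
        If the list is empty, any mask is non-binary, or dimensions differ
        (the error names the offending list index).
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask to stack")
    validated = []
    ref_shape = None
    for i, m in enumerate(masks):
        arr = validate_mask(m, name=f"masks[{i}]")
        if ref_shape is None:
            ref_shape = arr.shape
        elif arr.shape != ref_shape:
            raise ValueError(
                f"masks[{i}] has shape {arr.shape}, expected {ref_shape}"
            )
        validated.append(arr)
    summed = np.sum(np.stack(validated, axis=0, dtype=np.int64), axis=0)
    return EnsembleStack(masks=tuple(validated), sum_mask=summed, m=len(validated))


@dataclass(frozen=True)
class SliceRecord:
    """One slice: its ids, ground-truth mask, and ensemble of predictions."""

    patient_id: str
    slice_id: str
    ground_truth: np.ndarray
    predictions: EnsembleStack

    def __post_init__(self) -> None:
        gt = validate_mask(self.ground_truth, name="ground_truth")
        object.__setattr__(self, "ground_truth", gt)
        if gt.shape != self.predictions.shape:
            raise ValueError(
                f"slice {self.patient_id}/{self.slice_id}: ground truth shape "
                f"{gt.shape} != prediction shape {self.predictions.shape}"
            )


@dataclass
class Cohort:
    """Patients -> slices -> (ground truth, per-model predictions)."""

    slices: list[SliceRecord] = field(default_factory=list)

    @property
    def patient_ids(self) -> set[str]:
        return {s.patient_id for s in self.slices}

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def m(self) -> int:
        """Ensemble size; raises if slices disagree on M."""
        ms = {s.predictions.m for s in self.slices}
        if len(ms) != 1:
            raise ValueError(f"cohort mixes ensemble sizes M={sorted(ms)}")
        return ms.pop()

    def by_patient(self) -> dict[str, list[SliceRecord]]:
        """Slices grouped by patient, preserving insertion order."""
        groups: dict[str, list[SliceRecord]] = {}
        for s in self.slices:
            groups.setdefault(s.patient_id, []).append(s)
        return groups

    def subset(self, patient_ids: set[str]) -> "Cohort":
        return Cohort(slices=[s for s in self.slices if s.patient_id in patient_ids])


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts for one (prediction, ground truth) pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def split_patients(cohort: Cohort, n_train: int, seed: int) -> tuple[Cohort, Cohort]:
    """Randomly partition a cohort by patient into train and test cohorts.

    Patients are drawn uniformly without replacement; no patient contributes
    slices to both sides, so there is no slice-level leakage. Deterministic
    for a fixed seed.

    Parameters
    ----------
    cohort
        Cohort to split.
    n_train
        Number of patients assigned to the training cohort.
    seed
        Seed for the permutation RNG.

    Returns
    -------
    (train, test)
        Two cohorts whose patient sets partition the input's.
    """
    n = cohort.n_patients
    if not 1 <= n_train < n:
        raise ValueError(
            f"n_train={n_train} out of valid range [1, {n - 1}] "
            f"for a cohort of {n} patients"
        )
    rng = np.random.default_rng(seed)
    ids = sorted(cohort.patient_ids)
    perm = rng.permutation(len(ids))
    train_ids = {ids[i] for i in perm[:n_train]}
    test_ids = set(ids) - train_ids
    return cohort.subset(train_ids), cohort.subset(test_ids)
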