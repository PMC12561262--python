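"""K-of-M consensus fusion of binary mask ensembles.

A pixel in the fused mask is labeled positive when at least ``k`` of the M
model masks vote positive (``sum_mask >= k``). ``k = 1`` is the pixel-wise
union of the ensemble, ``k = M`` the intersection, and strict majority
(``votes > floor(M/2)``, i.e. >= 6 of 10) is the Majority-Vote baseline.
"""

from __future__ import annotations

import numpy as np

from .masks import EnsembleStack
from .metrics import confusion, slice_metrics

__all__ = ["ciof_fuse", "majority_vote", "agreement_scores"]


def ciof_fuse(stack: EnsembleStack, k: int, *, strict: bool = False) -> np.ndarray:
    """Fuse an ensemble at consensus threshold ``k``.

    Parameters
    ----------
    stack
        Ensemble of M aligned binary masks.
    k
        Consensus threshold in ``[1, M]``; a pixel is positive when at
        least ``k`` models agree.
    strict
        Compatibility mode requiring strictly more than ``k`` votes instead
        of at least ``k``.

    Returns
    -------
    numpy.ndarray
        Fused ``uint8`` binary mask with the stack's dimensions.
    """
    if not 1 <= k <= stack.m:
        raise ValueError(f"k={k} out of valid range [1, {stack.m}]")
    if strict:
        return (stack.sum_mask > k).astype(np.uint8)
    return (stack.sum_mask >= k).astype(np.uint8)


def majority_vote(stack: EnsembleStack, *, inclusive: bool = False) -> np.ndarray:
    """Strict-majority baseline: positive where votes exceed ``floor(M/2)``.

    For M = 10 this requires >= 6 agreeing models. ``inclusive=True`` lowers
    the bar to ``votes >= ceil(M/2)`` (>= 5 of 10), the alternative reading
    of a half-ensemble threshold.
    """
    if inclusive:
        k = (stack.m + 1) // 2
        return (stack.sum_mask >= k).astype(np.uint8)
    return (stack.sum_mask > stack.m // 2).astype(np.uint8)


def agreement_scores(stack: EnsembleStack, fused: np.ndarray) -> list[float]:
    """Per-model agreement with the fused mask, as IoU(mask_i, fused).

    Higher values indicate a model whose votes align more closely with the
    consensus decision; returned in the stack's model order.
    """
    if fused.shape != stack.shape:
        raise ValueError(f"fused shape {fused.shape} != stack shape {stack.shape}")
    return [slice_metrics(confusion(m, fused)).iou for m in stack.masks]
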