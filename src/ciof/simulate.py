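"""Synthetic mask-ensemble cohorts with controlled error structure.

Emulates the structure of a CT-angiography embolism cohort: patients with
axial slices, elliptical ground-truth lesions spanning three clot-burden
strata (per-slice positive-pixel ratio < 1e-4, 1e-4..1e-3, > 1e-3), and M
model prediction masks degraded from ground truth by

* per-model lesion-pixel misses at rate ``beta_i`` (pixel sensitivity
  ``1 - beta_i``),
* spatially clustered background false alarms at rate ``alpha_i`` — small
  blobs, not i.i.d. salt noise, because consensus voting removes
  independent single-pixel noise too easily to be a fair test,
* morphological boundary jitter (random dilation/erosion up to a radius),
* optionally correlated mistakes: a shared standard-normal latent draw per
  lesion pixel is mixed into every model's miss decision with weight
  ``sqrt(rho)`` (Gaussian copula), so marginal miss rates stay exactly
  ``beta_i`` while misses co-occur across models; false-alarm blob
  placements are likewise shared with probability ``rho``.

Cohorts are bit-reproducible from the config seed, which expands into
per-patient / per-slice / per-model substreams so partial regeneration is
stable. Requested stratum mixes are met exactly by construction: each slice
is assigned a stratum and its lesions are rasterized to an exact pixel
count inside that stratum's ratio band.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from skimage.morphology import dilation, disk, erosion

from .masks import Cohort, SliceRecord, stack_predictions

__all__ = ["GeneratorConfig", "generate_cohort", "checksum_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe the package's reference simulation: a 10-patient,
    20-slice-per-patient cohort of 512x512 slices, lesion burdens mixed
    10/65/25% across the three strata (mirroring the skew of real embolism
    cohorts toward mid-burden slices), and a heterogeneous M=10 ensemble
    with miss rates evenly spread over 0.1-0.5 and clustered false alarms
    at rate 2e-3.
    """

    n_patients: int = 10
    slices_per_patient: int = 20
    image_size: tuple[int, int] = (512, 512)
    stratum_edges: tuple[float, float] = (1e-4, 1e-3)
    stratum_mix: tuple[float, float, float] = (0.10, 0.65, 0.25)
    m: int = 10
    miss_rates: tuple[float, ...] | None = None  # default: linspace(0.1, 0.5, M)
    false_alarm_rates: tuple[float, ...] | None = None  # default: 0.002 each
    boundary_jitter_radius: int = 1
    error_correlation: float = 0.0
    empty_fraction: float = 0.0  # fraction of slices with no lesion at all
    max_burden_ratio: float = 4e-3  # cap on top-stratum lesion load
    seed: int = 0

    def resolved_miss_rates(self) -> np.ndarray:
        if self.miss_rates is not None:
            return np.asarray(self.miss_rates, dtype=float)
        return np.linspace(0.1, 0.5, self.m)

    def resolved_false_alarm_rates(self) -> np.ndarray:
        if self.false_alarm_rates is not None:
            return np.asarray(self.false_alarm_rates, dtype=float)
        return np.full(self.m, 0.002)

    def validate(self) -> None:
        if self.n_patients < 1 or self.slices_per_patient < 1 or self.m < 1:
            raise ValueError("n_patients, slices_per_patient and M must be >= 1")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if abs(sum(self.stratum_mix) - 1.0) > 1e-9:
            raise ValueError(f"stratum_mix must sum to 1, got {self.stratum_mix}")
        if any(p < 0 for p in self.stratum_mix):
            raise ValueError("stratum_mix proportions must be non-negative")
        lo, hi = self.stratum_edges
        if not 0 < lo < hi < 1:
            raise ValueError("stratum_edges must satisfy 0 < lo < hi < 1")
        beta = self.resolved_miss_rates()
        alpha = self.resolved_false_alarm_rates()
        if len(beta) != self.m or len(alpha) != self.m:
            raise ValueError("need one miss rate and one false-alarm rate per model")
        if ((beta < 0) | (beta > 1)).any() or ((alpha < 0) | (alpha > 1)).any():
            raise ValueError("miss and false-alarm rates must lie in [0, 1]")
        if not 0 <= self.error_correlation < 1:
            raise ValueError("error_correlation must lie in [0, 1)")
        if self.boundary_jitter_radius < 0:
            raise ValueError("boundary_jitter_radius must be >= 0")
        if not 0 <= self.empty_fraction < 1:
            raise ValueError("empty_fraction must lie in [0, 1)")
        # every stratum with positive weight must admit at least one pixel count
        for idx, weight in enumerate(self.stratum_mix):
            if weight > 0:
                lo_px, hi_px = _stratum_pixel_bounds(self, idx)
                if lo_px > hi_px:
                    raise ValueError(
                        f"stratum {idx} infeasible: image {self.image_size} admits "
                        f"no integer lesion pixel count in its ratio band"
                    )


def _stratum_pixel_bounds(config: GeneratorConfig, stratum: int) -> tuple[int, int]:
    """Inclusive [lo, hi] lesion pixel counts whose ratio falls in a stratum."""
    h, w = config.image_size
    npix = h * w
    lo_edge, hi_edge = config.stratum_edges
    if stratum == 0:  # ratio < lo_edge
        return 1, int(np.ceil(lo_edge * npix)) - 1
    if stratum == 1:  # lo_edge <= ratio <= hi_edge
        return int(np.ceil(lo_edge * npix)), int(np.floor(hi_edge * npix))
    # ratio > hi_edge, capped so lesions stay small relative to the slice
    cap = max(int(np.floor(config.max_burden_ratio * npix)),
              int(np.floor(hi_edge * npix)) + 1)
    return int(np.floor(hi_edge * npix)) + 1, min(cap, npix)


def _stratum_labels(config: GeneratorConfig, n_slices: int) -> list[int]:
    """Exact per-slice stratum assignment (-1 = empty slice), largest remainder."""
    n_empty = int(round(config.empty_fraction * n_slices))
    n_lesion = n_slices - n_empty
    quotas = np.array(config.stratum_mix) * n_lesion
    counts = np.floor(quotas).astype(int)
    rem = n_lesion - counts.sum()
    order = np.argsort(-(quotas - counts))  # largest fractional part first
    for i in range(rem):
        counts[order[i % 3]] += 1
    labels: list[int] = []
    for stratum, c in enumerate(counts):
        labels.extend([stratum] * c)
    labels.extend([-1] * n_empty)
    return labels


def _rasterize_lesion(
    gt: np.ndarray, n_pixels: int, rng: np.random.Generator, margin: int
) -> bool:
    """Draw one elliptical blob of exactly ``n_pixels`` onto ``gt``.

    Picks the n_pixels smallest values of a rotated anisotropic quadratic
    form around a random center, which yields an exact-count ellipse.
    Returns False if no non-overlapping placement was found.
    """
    h, w = gt.shape
    r = int(np.ceil(np.sqrt(n_pixels))) + 2
    for _ in range(50):
        cy = int(rng.integers(margin + r, h - margin - r)) if h > 2 * (margin + r) else h // 2
        cx = int(rng.integers(margin + r, w - margin - r)) if w > 2 * (margin + r) else w // 2
        q = rng.uniform(0.4, 1.0)  # axis ratio
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        xr = xx * np.cos(theta) + yy * np.sin(theta)
        yr = -xx * np.sin(theta) + yy * np.cos(theta)
        dist = xr**2 + (yr / q) ** 2
        flat = np.argsort(dist, axis=None, kind="stable")[:n_pixels]
        ys = yy.ravel()[flat] + cy
        xs = xx.ravel()[flat] + cx
        inside = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[inside], xs[inside]
        if len(ys) < n_pixels:
            continue
        if gt[ys, xs].any():  # overlap with an existing lesion: retry
            continue
        gt[ys, xs] = 1
        return True
    return False


def _make_ground_truth(
    shape: tuple[int, int], stratum: int, config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ground truth for one slice with total burden inside the stratum band."""
    gt = np.zeros(shape, dtype=np.uint8)
    if stratum < 0:
        return gt
    lo_px, hi_px = _stratum_pixel_bounds(config, stratum)
    target = int(rng.integers(lo_px, hi_px + 1))
    n_lesions = 1 if target < 40 else int(rng.integers(1, 4))
    parts = _split_count(target, n_lesions, rng)
    placed = 0
    for part in parts:
        if _rasterize_lesion(gt, part, rng, margin=4):
            placed += part
    if placed < lo_px:  # placements failed (tiny image): one central lesion
        gt[:] = 0
        _rasterize_lesion(gt, target, rng, margin=0)
    return gt


def _split_count(total: int, n_parts: int, rng: np.random.Generator) -> list[int]:
    """Split a pixel budget into n_parts parts of at least 5 pixels each."""
    if n_parts == 1 or total < 5 * n_parts:
        return [total]
    budget = total - 5 * n_parts
    weights = rng.dirichlet(np.ones(n_parts))
    parts = [5 + int(np.floor(w * budget)) for w in weights]
    parts[0] += total - sum(parts)
    return parts


_DISKS = {rad: np.argwhere(disk(rad) > 0) - rad for rad in (1, 2, 3)}


def _clustered_false_alarms(
    pred: np.ndarray, gt: np.ndarray, n_target: int, rng: np.random.Generator,
    shared: list[tuple[int, int, int]], rho: float,
) -> None:
    """Add ~n_target background false-positive pixels as small blobs in place.

    With probability ``rho`` a blob reuses a shared (center, radius) drawn
    from the cohort-level latent list, inducing co-located false alarms
    across models.
    """
    h, w = pred.shape
    added = 0
    shared_idx = 0
    guard = 0
    while added < n_target and guard < 100 * (n_target + 1):
        guard += 1
        if rho > 0 and shared and rng.random() < rho:
            cy, cx, rad = shared[shared_idx % len(shared)]
            shared_idx += 1
        else:
            cy = int(rng.integers(0, h))
            cx = int(rng.integers(0, w))
            rad = int(rng.choice((1, 2, 3)))
        offs = _DISKS[rad]
        ys = offs[:, 0] + cy
        xs = offs[:, 1] + cx
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[ok], xs[ok]
        fresh = (gt[ys, xs] == 0) & (pred[ys, xs] == 0)
        ys, xs = ys[fresh], xs[fresh]
        take = min(len(ys), n_target - added)  # trim last blob to exact count
        if take == 0:
            continue
        pred[ys[:take], xs[:take]] = 1
        added += take


def _jitter(lesion: np.ndarray, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Random dilation/erosion of the lesion by up to ``radius`` pixels."""
    if radius == 0:
        return lesion.copy()
    j = int(rng.integers(-radius, radius + 1))
    if j == 0:
        return lesion.copy()
    # operate on the lesion bounding box for speed
    ys, xs = np.nonzero(lesion)
    if len(ys) == 0:
        return lesion.copy()
    pad = abs(j) + 1
    y0, y1 = max(0, ys.min() - pad), min(lesion.shape[0], ys.max() + pad + 1)
    x0, x1 = max(0, xs.min() - pad), min(lesion.shape[1], xs.max() + pad + 1)
    out = lesion.copy()
    window = lesion[y0:y1, x0:x1].astype(bool)
    fp = disk(abs(j))
    window = dilation(window, fp) if j > 0 else erosion(window, fp)
    out[y0:y1, x0:x1] = window.astype(np.uint8)
    return out


def _simulate_predictions(
    gt: np.ndarray, config: GeneratorConfig, rng_children: list[np.random.Generator],
    shared_rng: np.random.Generator,
) -> list[np.ndarray]:
    """M degraded prediction masks for one slice."""
    beta = config.resolved_miss_rates()
    alpha = config.resolved_false_alarm_rates()
    rho = config.error_correlation
    les_idx = np.nonzero(gt.ravel())[0]
    n_les = len(les_idx)
    z_shared = shared_rng.standard_normal(n_les) if (rho > 0 and n_les) else None
    shared_blobs: list[tuple[int, int, int]] = []
    if rho > 0:
        h, w = gt.shape
        n_shared = 200
        shared_blobs = [
            (int(shared_rng.integers(0, h)), int(shared_rng.integers(0, w)),
             int(shared_rng.choice((1, 2, 3))))
            for _ in range(n_shared)
        ]
    preds = []
    n_bg = gt.size - int(gt.sum())
    for i in range(config.m):
        rng = rng_children[i]
        pred = _jitter(gt, config.boundary_jitter_radius, rng)
        if n_les:
            eps = rng.standard_normal(n_les)
            if z_shared is not None:
                z = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * eps
            else:
                z = eps
            missed = norm.cdf(z) < beta[i]  # marginal rate exactly beta_i
            flat = pred.ravel()
            flat[les_idx[missed]] = 0
        n_fp = int(rng.binomial(n_bg, alpha[i]))
        _clustered_false_alarms(pred, gt, n_fp, rng, shared_blobs, rho)
        preds.append(pred)
    return preds


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort from a validated config.

    Deterministic for a fixed config (including its seed); stratum quotas
    are met exactly and each slice's ground-truth burden ratio lies inside
    its assigned stratum's band.
    """
    config.validate()
    n_slices = config.n_patients * config.slices_per_patient
    labels = _stratum_labels(config, n_slices)
    # deterministic interleave so every patient sees a mix of strata
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    label_order = assign_rng.permutation(n_slices)
    per_slice_label = [labels[i] for i in label_order]

    patient_seeds = root.spawn(config.n_patients)
    slices: list[SliceRecord] = []
    idx = 0
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        slice_seeds = patient_seeds[p].spawn(config.slices_per_patient)
        for s in range(config.slices_per_patient):
            stratum = per_slice_label[idx]
            idx += 1
            streams = slice_seeds[s].spawn(config.m + 2)
            gt_rng = np.random.default_rng(streams[0])
            shared_rng = np.random.default_rng(streams[1])
            model_rngs = [np.random.default_rng(st) for st in streams[2:]]
            gt = _make_ground_truth(config.image_size, stratum, config, gt_rng)
            preds = _simulate_predictions(gt, config, model_rngs, shared_rng)
            slices.append(
                SliceRecord(
                    patient_id=pid,
                    slice_id=f"S{s:04d}",
                    ground_truth=gt,
                    predictions=stack_predictions(preds),
                )
            )
    return Cohort(slices=slices)


def checksum_cohort(cohort: Cohort) -> str:
    """Platform-stable content digest of a cohort, for regression tests."""
    h = hashlib.sha256()
    for s in cohort.slices:
        h.update(s.patient_id.encode())
        h.update(s.slice_id.encode())
        h.update(np.asarray(s.ground_truth.shape, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(s.ground_truth, dtype=np.uint8).tobytes())
        for m in s.predictions.masks:
            h.update(np.ascontiguousarray(m, dtype=np.uint8).tobytes())
    return h.hexdigest()
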