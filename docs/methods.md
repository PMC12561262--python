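# Methods

## The fusion model

CIOF treats an ensemble of M binary segmentation masks as M pixel-wise
votes. The fused mask at consensus threshold k labels a pixel positive when
at least k models vote positive; the family is nested (`fused(k+1) ⊆
fused(k)`), so FNR is non-decreasing and FPR non-increasing in k on every
slice. The only fitted quantity is K*, selected by exhaustive sweep of
k = 1..M on the training patients with patient-averaged mean IoU as the
objective. This is deliberately unweighted voting: no per-model weights, no
probabilistic label fusion (STAPLE-style EM is an explicit non-goal); the
method trades those degrees of freedom for interpretability and a
one-parameter selection problem that cannot meaningfully overfit 10 choices
on dozens of patients.

Two pseudocode conventions for the vote comparison are in circulation
(`≥ k` versus strictly `> k`). The package uses `≥ k` everywhere — "at
least k of M" — and exposes a `strict=True` compatibility flag on
`ciof_fuse`. Similarly, "majority" is strict by default
(`votes > ⌊M/2⌋`, i.e. ≥ 6 of 10), with `inclusive=True` lowering the bar
to `⌈M/2⌉` (≥ 5 of 10).

### Aggregation and ties

Per-slice IoU is averaged within each patient, then unweighted across
patients (`per_patient_then_cohort`), so a patient with many slices does
not dominate the objective; `pooled_slices` (flat mean over slices) is
available as the bracketing alternative reading. Argmax ties break to the
smallest k, which favors sensitivity — the regime where consensus fusion
earns its keep is tiny lesions, where extra votes cost recall.

### Degenerate slices

Most slices in an embolism cohort contain no lesion, and IoU is undefined
on an empty ground truth. Default evaluation therefore includes only slices
with at least one ground-truth positive pixel. In the optional all-slices
mode (`include_degenerate=True`), two empty masks score IoU = Dice = 1,
any false positive on an empty ground truth scores 0, and FNR with an empty
ground truth is 0 (nothing to miss); such slices are flagged `degenerate`
in the per-slice table. Both modes are first-class because reported means
in the literature rarely state which convention they use.

### Burden stratification

The embolization ratio of a slice is its ground-truth positive-pixel
fraction; strata default to < 1e-4, [1e-4, 1e-3], > 1e-3, with the middle
bin closed on both ends (the outer bins are printed with strict
inequalities in the standard tabulation). Ratios are computed at the
resolution the ground-truth mask is stored at: the conventional pixel-count
bins (< 26, 26–262, > 262) correspond to these ratio edges on a 512×512
grid, indicating native-resolution ratios rather than ratios after any
model-input resizing. Stratum assignment uses ground truth only and
partitions the evaluable slices.

## The synthetic cohort generator

The generator emulates the *structure* of a CT-angiography embolism cohort
— patients × slices, small elliptical lesions spanning the three burden
strata, and M prediction masks with model-like error signatures — so that
the whole pipeline is exercisable without any imaging data. It does not
simulate CT intensities, vessels or anatomy, and its lesions are smooth
ellipses rather than irregular clots; passing tests therefore demonstrate
the correctness and the qualitative behavior of the fusion machinery
(union/intersection limits, the interior IoU maximum, majority's
conservatism), not clinical accuracy on real CTA.

Key parameters (defaults in `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_patients`, `slices_per_patient` | 10, 20 | cohort shape |
| `image_size` | 512×512 | native mask resolution (strata edges ↔ 26/262 px) |
| `stratum_mix` | 0.10/0.65/0.25 | exact share of slices per burden stratum, mirroring the skew of real embolism cohorts toward mid-burden slices |
| `miss_rates` β_i | linspace(0.1, 0.5, M) | per-model lesion-pixel miss probability (sensitivity 1−β_i); the spread makes the ensemble heterogeneous |
| `false_alarm_rates` α_i | 0.002 | expected background positive fraction per model |
| `boundary_jitter_radius` | 1 px | random dilation/erosion of the lesion per model, emulating boundary disagreement |
| `error_correlation` ρ | 0 | shared-latent mixing of errors across models |
| `empty_fraction` | 0 | share of lesion-free slices |
| `max_burden_ratio` | 4e-3 | cap on top-stratum lesion load |

Design choices worth noting:

* **Exact stratum quotas.** Slice counts per stratum come from a
  largest-remainder apportionment of `stratum_mix`, and each slice's lesion
  pixel count is drawn inside its stratum's integer band and rasterized to
  that exact count (lesions are the n smallest values of a rotated
  anisotropic quadratic form, i.e. exact-count ellipses). The mix is met
  exactly, not in expectation.
* **Clustered false alarms.** False positives are small disk-shaped blobs
  whose total pixel count is a Binomial(n_background, α_i) draw, trimmed to
  the exact count. Independent single-pixel salt noise would be erased by
  even k = 2 consensus and would flatter the method; clustered blobs can
  survive low thresholds, making the sweep non-trivial.
* **Exact marginal miss rates under correlation.** Misses use a Gaussian
  copula: pixel miss indicator is `Φ(√ρ·z_shared + √(1−ρ)·z_i) < β_i`, so
  the marginal rate is exactly β_i for any ρ while misses co-occur across
  models. False-alarm blob locations are shared across models with
  probability ρ.
* **Seed substreams.** One config seed expands through
  `numpy.random.SeedSequence.spawn` into per-patient / per-slice /
  per-model streams, so cohorts are bit-reproducible and stable under
  partial regeneration; `checksum_cohort` gives a platform-stable SHA-256
  digest for regression tests.

## Preprocessing

CT windowing is the standard linear ramp: `clamp((v − (level − width/2)) /
width, 0, 1)`. Named presets use conventional radiology settings — brain
L40/W80, lung L−600/W1500, bone L400/W1800 — because published window
choices for this pipeline are stated by name only and are internally
inconsistent (brain+lung in one place, bone+brain in another); presets make
either combination reproducible without guessing intent. The three-channel
composite is (window A, window B, their mean). Resizing is bilinear for
intensities and nearest-neighbor for masks, which provably preserves the
value set {0, 1}.

## Numerical notes

* The k-sweep is computed from each slice's vote-count histogram inside and
  outside the ground truth (suffix sums give TP(k), FP(k) for all k at
  once); tests verify equality with a from-scratch brute-force
  re-implementation that shares no intermediates.
* Masks are `uint8` throughout; vote sums are `int64`.
* Binarization on read: PNG pixels > 0 map to 1; NIfTI values are
  thresholded at 0.5 by default (configurable) to accommodate probability
  maps.
* The patient split draws uniformly without replacement from the sorted
  patient-id list under a stated seed; a particular historical partition of
  a real cohort is not reproducible without its (unpublished) RNG, only its
  18/17 patient counts.

## Problem sizes

The reference simulation used in tests and in `scripts/acceptance.py` is
10–20 patients × 20 slices at 512×512 with M = 10 — large enough that
per-model calibration is tight (≈1e5 lesion pixels, ≈1e8 background pixels)
and the IoU-versus-k curve has a clear interior maximum, while the full
suite runs in well under a minute of simulation time. Oracle-equivalence
checks run on hundreds of miniature cohorts (≤ 5 patients × ≤ 10 slices,
4×4–8×8 grids) where brute force is exact and instant.

## Known limitations

* Synthetic lesions are convex-ish ellipses; real emboli are irregular and
  vessel-following. Only pixel-count statistics enter any implemented
  quantity, so this does not bias the fusion math, but stratified results
  on synthetic data say nothing about boundary-accuracy behavior.
* The generator's error model (independent-or-copula misses, blob false
  alarms) is a caricature of FCN failure modes; correlated structured
  errors of real model families are richer.
* No surface-distance metrics (Hausdorff, ASSD) and no lesion-level
  detection analysis (FROC); evaluation is strictly pixel-wise.
* No DICOM ingestion or geometric registration: masks must already be
  aligned and equally sized.
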