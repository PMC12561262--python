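import numpy as np
import pytest

from ciof import (
    Cohort,
    GeneratorConfig,
    SliceRecord,
    generate_cohort,
    stack_predictions,
)


def make_slice(patient_id, slice_id, gt, masks):
    return SliceRecord(
        patient_id=patient_id,
        slice_id=slice_id,
        ground_truth=np.asarray(gt, dtype=np.uint8),
        predictions=stack_predictions([np.asarray(m, dtype=np.uint8) for m in masks]),
    )


def random_cohort(rng, n_patients, n_slices, m, shape=(8, 8), p_gt=0.3, p_pred=0.3):
    """Cohort of i.i.d. random masks; guarantees >=1 GT-positive per slice."""
    slices = []
    for p in range(n_patients):
        for s in range(n_slices):
            gt = (rng.random(shape) < p_gt).astype(np.uint8)
            if gt.sum() == 0:
                gt[rng.integers(shape[0]), rng.integers(shape[1])] = 1
            masks = [(rng.random(shape) < p_pred).astype(np.uint8) for _ in range(m)]
            slices.append(make_slice(f"P{p}", f"S{s}", gt, masks))
    return Cohort(slices=slices)


@pytest.fixture(scope="session")
def reference_config():
    """The package's reference simulation: heterogeneous M=10 ensemble,
    10 patients x 20 slices at 512x512, miss rates 0.1-0.5, clustered
    false alarms at 2e-3, independent errors, no boundary jitter."""
    return GeneratorConfig(seed=42, boundary_jitter_radius=0)


@pytest.fixture(scope="session")
def reference_cohort(reference_config):
    return generate_cohort(reference_config)


@pytest.fixture
def small_cohort():
    """Quick synthetic cohort on a 128x128 grid with widened strata edges."""
    cfg = GeneratorConfig(
        n_patients=3,
        slices_per_patient=4,
        image_size=(128, 128),
        stratum_edges=(2e-3, 2e-2),
        seed=7,
    )
    return generate_cohort(cfg)
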