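import numpy as np
import pytest

from ciof import (
    GeneratorConfig,
    StratumSpec,
    assign_stratum,
    checksum_cohort,
    embolization_ratio,
    generate_cohort,
)

FAST = dict(
    n_patients=2,
    slices_per_patient=5,
    image_size=(128, 128),
    stratum_edges=(2e-3, 2e-2),
)


class TestReproducibility:
    def test_same_config_same_checksum(self):
        cfg = GeneratorConfig(seed=5, **FAST)
        assert checksum_cohort(generate_cohort(cfg)) == checksum_cohort(
            generate_cohort(cfg)
        )

    def test_seed_changes_cohort(self):
        a = checksum_cohort(generate_cohort(GeneratorConfig(seed=5, **FAST)))
        b = checksum_cohort(generate_cohort(GeneratorConfig(seed=6, **FAST)))
        assert a != b

    def test_config_roundtrip_through_dict(self):
        from dataclasses import asdict

        cfg = GeneratorConfig(seed=5, **FAST)
        raw = asdict(cfg)
        for key in ("image_size", "stratum_edges", "stratum_mix"):
            raw[key] = tuple(raw[key])
        cfg2 = GeneratorConfig(**raw)
        assert checksum_cohort(generate_cohort(cfg)) == checksum_cohort(
            generate_cohort(cfg2)
        )


class TestGroundTruth:
    def test_stratum_quotas_matched_exactly(self):
        cfg = GeneratorConfig(
            seed=3, stratum_mix=(0.2, 0.5, 0.3), **FAST
        )
        cohort = generate_cohort(cfg)
        spec = StratumSpec(edges=cfg.stratum_edges,
                           labels=("low", "mid", "high"))
        counts = {"low": 0, "mid": 0, "high": 0}
        for s in cohort.slices:
            counts[assign_stratum(embolization_ratio(s.ground_truth), spec)] += 1
        assert counts == {"low": 2, "mid": 5, "high": 3}

    def test_single_stratum_mix_constrains_every_slice(self):
        cfg = GeneratorConfig(seed=3, stratum_mix=(1.0, 0.0, 0.0), **FAST)
        for s in generate_cohort(cfg).slices:
            ratio = embolization_ratio(s.ground_truth)
            assert 0 < ratio < cfg.stratum_edges[0]

    def test_empty_fraction_produces_lesion_free_slices(self):
        cfg = GeneratorConfig(seed=3, empty_fraction=0.4, **FAST)
        cohort = generate_cohort(cfg)
        n_empty = sum(1 for s in cohort.slices if s.ground_truth.sum() == 0)
        assert n_empty == 4  # 0.4 of 10 slices

    def test_infeasible_stratum_raises_configuration_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(
                n_patients=1, slices_per_patient=1, image_size=(16, 16),
                stratum_edges=(1e-4, 1e-3), stratum_mix=(1.0, 0.0, 0.0),
            ).validate()


class TestPredictions:
    def test_noise_free_limit_reproduces_ground_truth(self):
        cfg = GeneratorConfig(
            seed=4, m=3, miss_rates=(0.0, 0.0, 0.0),
            false_alarm_rates=(0.0, 0.0, 0.0), boundary_jitter_radius=0, **FAST
        )
        for s in generate_cohort(cfg).slices:
            for mask in s.predictions.masks:
                np.testing.assert_array_equal(mask, s.ground_truth)

    def test_miss_rate_calibration_within_three_standard_errors(self):
        cfg = GeneratorConfig(
            n_patients=4, slices_per_patient=10, image_size=(256, 256),
            stratum_edges=(1e-3, 1e-2), stratum_mix=(0.0, 0.3, 0.7),
            m=3, miss_rates=(0.3, 0.3, 0.3), false_alarm_rates=(0.0, 0.0, 0.0),
            boundary_jitter_radius=0, seed=13,
        )
        cohort = generate_cohort(cfg)
        n_lesion = sum(int(s.ground_truth.sum()) for s in cohort.slices)
        for i in range(3):
            missed = sum(
                int(np.count_nonzero((s.ground_truth == 1)
                                     & (s.predictions.masks[i] == 0)))
                for s in cohort.slices
            )
            rate = missed / n_lesion
            se = np.sqrt(0.3 * 0.7 / n_lesion)
            assert abs(rate - 0.3) < 3 * se

    def test_false_alarm_calibration_within_three_standard_errors(self):
        cfg = GeneratorConfig(
            n_patients=2, slices_per_patient=10, image_size=(256, 256),
            stratum_edges=(1e-3, 1e-2), stratum_mix=(0.0, 1.0, 0.0),
            m=2, miss_rates=(0.0, 0.0), false_alarm_rates=(0.01, 0.01),
            boundary_jitter_radius=0, seed=14,
        )
        cohort = generate_cohort(cfg)
        n_bg = sum(int(s.ground_truth.size - s.ground_truth.sum())
                   for s in cohort.slices)
        for i in range(2):
            fp = sum(
                int(np.count_nonzero((s.ground_truth == 0)
                                     & (s.predictions.masks[i] == 1)))
                for s in cohort.slices
            )
            rate = fp / n_bg
            se = np.sqrt(0.01 * 0.99 / n_bg)
            assert abs(rate - 0.01) < 3 * se

    def test_correlated_errors_share_misses_across_models(self):
        base = dict(
            n_patients=2, slices_per_patient=10, image_size=(256, 256),
            stratum_edges=(1e-3, 1e-2), stratum_mix=(0.0, 0.0, 1.0),
            m=2, miss_rates=(0.4, 0.4), false_alarm_rates=(0.0, 0.0),
            boundary_jitter_radius=0, seed=15,
        )

        def joint_miss_rate(rho):
            cohort = generate_cohort(GeneratorConfig(error_correlation=rho, **base))
            both = total = 0
            for s in cohort.slices:
                lesion = s.ground_truth == 1
                m0 = s.predictions.masks[0][lesion] == 0
                m1 = s.predictions.masks[1][lesion] == 0
                both += int(np.count_nonzero(m0 & m1))
                total += int(lesion.sum())
            return both / total

        independent = joint_miss_rate(0.0)
        correlated = joint_miss_rate(0.8)
        assert correlated > independent + 0.05  # well above 0.4**2

    def test_jitter_perturbs_only_the_boundary_region(self):
        cfg = GeneratorConfig(
            seed=4, m=2, miss_rates=(0.0, 0.0), false_alarm_rates=(0.0, 0.0),
            boundary_jitter_radius=2, **FAST
        )
        from skimage.morphology import dilation, disk

        for s in generate_cohort(cfg).slices:
            halo = dilation(s.ground_truth.astype(bool), disk(2))
            for mask in s.predictions.masks:
                assert not np.any(mask.astype(bool) & ~halo)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(stratum_mix=(0.5, 0.5, 0.5)), "sum to 1"),
            (dict(error_correlation=1.0), "correlation"),
            (dict(boundary_jitter_radius=-1), "jitter"),
            (dict(m=2, miss_rates=(0.1,)), "per model"),
            (dict(stratum_edges=(0.5, 0.1)), "edges"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        base = {**FAST, **kwargs}
        with pytest.raises(ValueError, match=match):
            GeneratorConfig(**base).validate()
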