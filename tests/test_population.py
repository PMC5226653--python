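import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vestfit as vf
from conftest import make_params


def brute_force_ptt(params, stim, kinds=None, with_baseline=True, rectify=True,
                    step=1.0):
    """Independent dense-grid oracle for the direction-maximized modulation."""
    az = np.deg2rad(np.arange(0.0, 360.0, step))
    el = np.deg2rad(np.arange(-90.0, 90.0 + 1e-9, step))
    AZ, EL = np.meshgrid(az, el)
    U = np.column_stack(
        [
            (np.cos(AZ) * np.cos(EL)).ravel(),
            (np.sin(AZ) * np.cos(EL)).ravel(),
            np.sin(EL).ravel(),
        ]
    )
    profiles = vf.temporal_profiles(stim, params.delay)
    total = np.full((U.shape[0], len(stim.time_grid)),
                    params.baseline if with_baseline else 0.0)
    for c in params.components:
        if kinds is not None and c.kind not in kinds:
            continue
        g = U @ vf.direction_to_unit_vector(c.tuning.pd)
        y = c.tuning.offset + (1 - abs(c.tuning.offset)) * np.clip(g, -1, 1)
        total += c.weight * np.outer(y, profiles.by_kind(c.kind))
    if rectify:
        total = np.maximum(total, 0.0)
    return float((total.max(axis=1) - total.min(axis=1)).max())


class TestModulation:
    def test_zero_weights_give_zero_modulation(self, stim):
        p = make_params("V", [("velocity", 0.0, 0, 0, 0.0)], baseline=30.0)
        assert vf.peak_to_trough_modulation(p, stim) == pytest.approx(0.0, abs=1e-9)

    def test_single_component_modulation_equals_weight(self, stim):
        p = make_params("A", [("acceleration", 35.0, 120, 30, 0.0)], baseline=200.0)
        assert vf.peak_to_trough_modulation(p, stim) == pytest.approx(35.0, rel=1e-3)

    def test_matches_dense_grid_oracle(self, stim):
        rng = np.random.default_rng(0)
        for _ in range(3):
            p = vf.sample_neuron_params(
                vf.ModelSpec.from_string("VAJ"), vf.GeneratorConfig(), rng
            )
            ours = vf.peak_to_trough_modulation(p, stim)
            oracle = brute_force_ptt(p, stim, step=1.0)
            assert ours == pytest.approx(oracle, rel=0.01)


class TestPositionRatio:
    def test_pure_position_generator(self, stim):
        p = make_params("PV", [("position", 30.0, 45, 10, 0.2),
                               ("velocity", 0.0, 0, 0, 0.0)], baseline=100.0)
        assert vf.position_ratio(p, stim) == pytest.approx(1.0, abs=0.01)

    def test_zero_position_weight(self, stim):
        p = make_params("PV", [("position", 0.0, 0, 0, 0.0),
                               ("velocity", 40.0, 90, 0, 0.3)], baseline=60.0)
        assert vf.position_ratio(p, stim) == 0.0

    def test_mixed_neuron_matches_oracle(self, stim):
        p = make_params(
            "PVAJ",
            [("position", 20.0, 10, -20, 0.1), ("velocity", 35.0, 80, 10, 0.4),
             ("acceleration", 25.0, 200, 40, 0.0), ("jerk", 15.0, 300, -40, 0.2)],
            baseline=50.0,
        )
        num = brute_force_ptt(p, stim, kinds=("position",), with_baseline=False,
                              rectify=False)
        den = brute_force_ptt(p, stim)
        assert vf.position_ratio(p, stim) == pytest.approx(num / den, rel=0.01)

    def test_requires_position_component(self, stim, pure_a_params):
        with pytest.raises(ValueError, match="position"):
            vf.position_ratio(pure_a_params, stim)


class TestOffsetCosineDecomposition:
    @pytest.mark.parametrize(
        "w, o, expected",
        [(0.7, 0.0, (0.7, 0.0)), (0.4, 1.0, (0.0, 0.4)), (0.5, -0.6, (0.2, -0.3))],
    )
    def test_decomposition_arithmetic(self, w, o, expected):
        out = vf.offset_cosine_decomposition({"velocity": w}, {"velocity": o})
        assert out["velocity"] == pytest.approx(expected)


class TestAngleDistributions:
    def make_pop(self, rows):
        return pd.DataFrame(rows)

    def test_inclusion_requires_both_components_in_best_model(self):
        pop = self.make_pop(
            [
                {"neuron_id": "a", "best_model": "VA", "pd_v_az": 0, "pd_v_el": 0,
                 "pd_a_az": 90, "pd_a_el": 0, "pd_j_az": 0, "pd_j_el": 0},
                {"neuron_id": "b", "best_model": "A", "pd_v_az": 0, "pd_v_el": 0,
                 "pd_a_az": 0, "pd_a_el": 0, "pd_j_az": 0, "pd_j_el": 0},
            ]
        )
        dist = vf.pd_angle_distribution(pop, "V-A")
        assert dist.neuron_ids == ("a",)
        assert dist.angles[0] == pytest.approx(90.0)

    def test_identical_pds_give_zero_angle(self):
        pop = self.make_pop(
            [{"neuron_id": "a", "best_model": "VAJ", "pd_v_az": 33, "pd_v_el": -12,
              "pd_a_az": 33, "pd_a_el": -12, "pd_j_az": 0, "pd_j_el": 0}]
        )
        assert vf.pd_angle_distribution(pop, "V-A").angles[0] == pytest.approx(
            0.0, abs=1e-5
        )

    def test_aligned_population_ks_rejects_chance(self):
        rng = np.random.default_rng(0)
        angles = np.abs(rng.normal(0, 5, 200))  # concentrated near 0
        p = vf.ks_test_vs_null(angles, vf.h1_null(10_000, rng))
        assert p < 1e-10

    def test_independent_pds_match_chance(self):
        rng = np.random.default_rng(1)
        angles = vf.h1_null(300, rng)
        p = vf.ks_test_vs_null(angles, vf.h1_null(50_000, rng))
        assert p > 0.01


class TestH1Null:
    def test_closed_form_cdf(self):
        angles = vf.h1_null(100_000, np.random.default_rng(0))
        # CDF(theta) = (1 - cos theta) / 2; at 60 deg -> 0.25; median 90 deg
        assert np.mean(angles <= 60) == pytest.approx(0.25, abs=0.01)
        assert np.median(angles) == pytest.approx(90.0, abs=1.0)
        grid = np.linspace(0, 180, 361)
        ecdf = np.searchsorted(np.sort(angles), grid) / angles.size
        sup = np.abs(ecdf - (1 - np.cos(np.deg2rad(grid))) / 2).max()
        assert sup < 0.01

    def test_h2_null_is_degenerate_aligned(self):
        assert np.all(vf.h2_null(10) == 0.0)

    def test_identical_samples_ks_p_one(self):
        x = vf.h1_null(100, np.random.default_rng(0))
        assert vf.ks_test_vs_null(x, x) == pytest.approx(1.0)


class TestRayleigh:
    def test_identical_pds_full_resultant(self):
        pds = [vf.Direction(40, 20)] * 20
        R, p = vf.rayleigh_uniformity(pds, rng=np.random.default_rng(0))
        assert R == pytest.approx(1.0)
        assert p == 0.0

    def test_antipodal_pairs_cancel(self):
        pds = [vf.Direction(0, 0), vf.Direction(180, 0)] * 5
        R, _ = vf.rayleigh_uniformity(pds, rng=np.random.default_rng(0))
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_uniform_population_not_rejected(self):
        rng = np.random.default_rng(2)
        pds = [vf.sample_uniform_direction(rng) for _ in range(500)]
        R, p = vf.rayleigh_uniformity(pds, rng=np.random.default_rng(3))
        assert R < 0.15 and p > 0.05

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            vf.rayleigh_uniformity([vf.Direction(0, 0)] * 3)


class TestBootstrap:
    def test_constant_sample(self):
        med, lo, hi = vf.bootstrap_median_ci([4.0] * 10)
        assert med == lo == hi == 4.0

    def test_ci_contains_sample_median(self):
        x = np.random.default_rng(0).normal(10, 2, 41)
        med, lo, hi = vf.bootstrap_median_ci(x, rng=np.random.default_rng(1))
        assert lo <= med <= hi
        assert med == np.median(x)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(0.0, 1.0, 30)
            _, lo, hi = vf.bootstrap_median_ci(x, n_boot=500, rng=rng)
            hits += lo <= 0.0 <= hi
        # percentile bootstrap of the median is approximately calibrated
        assert 0.88 <= hits / n_rep <= 0.99

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            vf.bootstrap_median_ci([1.0, 2.0])


class TestTernary:
    def test_corners_and_centroid(self):
        c0 = vf.ternary_coordinates([1, 0, 0])
        c1 = vf.ternary_coordinates([0, 1, 0])
        c2 = vf.ternary_coordinates([0, 0, 1])
        np.testing.assert_allclose(c0, [0, 0])
        np.testing.assert_allclose(c1, [1, 0])
        np.testing.assert_allclose(c2, [0.5, np.sqrt(3) / 2])
        np.testing.assert_allclose(
            vf.ternary_coordinates([1 / 3, 1 / 3, 1 / 3]),
            (c0 + c1 + c2) / 3,
        )

    def test_rescaling_before_normalization_is_invariant(self):
        w = np.array([2.0, 3.0, 5.0])
        a = vf.ternary_coordinates(w / w.sum())
        b = vf.ternary_coordinates((10 * w) / (10 * w).sum())
        np.testing.assert_allclose(a, b)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            vf.ternary_coordinates([1.0, 1.0, 1.0])
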