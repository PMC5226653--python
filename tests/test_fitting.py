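import numpy as np
import pytest

import vestfit as vf
from conftest import make_params, noiseless_psth


class TestInformationCriteria:
    def test_bic_log_one_is_penalty_only(self):
        assert vf.bic(rss=260.0, n_effective=260, p=6) == pytest.approx(
            6 * np.log(260)
        )

    def test_bic_penalty_monotone_in_p(self):
        assert vf.bic(100.0, 260, 6) < vf.bic(100.0, 260, 14)

    def test_perfect_fit_sentinel(self):
        assert vf.bic(0.0, 260, 6) == float("-inf")

    def test_effective_n_default_protocol(self, grid, stim, pure_a_params):
        psth = noiseless_psth(pure_a_params, grid, stim)
        assert vf.effective_n(psth) == 260

    def test_effective_n_scales_with_directions_and_kernel(self, stim,
                                                           pure_a_params):
        one_dir = vf.DirectionGrid((vf.Direction(0, 0),))
        rates = vf.predict_firing_rate(pure_a_params, one_dir, stim)
        assert vf.effective_n(vf.PSTHMatrix(rates=rates, grid=one_dir)) == 10
        grid26 = vf.make_direction_grid()
        rates26 = vf.predict_firing_rate(pure_a_params, grid26, stim)
        psth = vf.PSTHMatrix(rates=rates26, grid=grid26, smoothing_sigma=0.05)
        assert vf.effective_n(psth) == 520


class TestNormalizedWeights:
    def test_example_ratios(self):
        p = make_params(
            "VAJ",
            [("velocity", 1.0, 0, 0, 0), ("acceleration", 1.0, 0, 0, 0),
             ("jerk", 2.0, 0, 0, 0)],
        )
        nw = vf.normalized_weights(p)
        assert nw == pytest.approx(
            {"velocity": 0.25, "acceleration": 0.25, "jerk": 0.5}
        )
        assert sum(nw.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_nonzero_weight(self):
        p = make_params(
            "VA", [("velocity", 0.0, 0, 0, 0), ("acceleration", 7.0, 0, 0, 0)]
        )
        assert vf.normalized_weights(p)["acceleration"] == 1.0

    def test_all_zero_rejected(self):
        p = make_params("V", [("velocity", 0.0, 0, 0, 0)])
        with pytest.raises(ValueError):
            vf.normalized_weights(p)


class TestFit:
    def test_noiseless_single_component_recovery(self, grid, stim, pure_a_params):
        model = vf.SpatioTemporalTuningModel(noiseless_psth(pure_a_params, grid, stim))
        res = model.fit("A")
        c = res.params.component("acceleration")
        truth = pure_a_params.component("acceleration")
        assert vf.angular_difference(c.tuning.pd, truth.tuning.pd) < 2.0
        assert c.weight == pytest.approx(truth.weight, rel=0.01)
        assert c.tuning.offset == pytest.approx(truth.tuning.offset, abs=0.02)
        assert res.params.delay == pytest.approx(pure_a_params.delay, abs=0.01)
        assert res.r2 > 0.999

    def test_nested_models_never_fit_worse(self, poisson_vaj_neuron):
        _, spikes = poisson_vaj_neuron
        fam = vf.SpatioTemporalTuningModel.from_spike_trains(spikes).fit_family()
        f = fam.fits
        for sub, sup in [("V", "VA"), ("A", "VA"), ("V", "VJ"), ("J", "VJ"),
                         ("A", "AJ"), ("J", "AJ"), ("VA", "VAJ"), ("VJ", "VAJ"),
                         ("AJ", "VAJ"), ("SepVAJ", "VAJ")]:
            assert f[sup].r2 >= f[sub].r2 - 1e-9

    def test_fit_invariant_to_rate_rescaling(self, grid, stim, poisson_vaj_neuron):
        _, spikes = poisson_vaj_neuron
        psth = vf.build_psth(spikes)
        m1 = vf.SpatioTemporalTuningModel(psth)
        scaled = vf.PSTHMatrix(rates=psth.rates * 3.0, grid=psth.grid)
        m2 = vf.SpatioTemporalTuningModel(scaled)
        r1, r2 = m1.fit("VA", seed=0), m2.fit("VA", seed=0)
        assert r2.r2 == pytest.approx(r1.r2, abs=1e-4)
        assert r2.params.baseline == pytest.approx(3 * r1.params.baseline, rel=0.01)
        w1 = r1.params.component("velocity").weight
        w2 = r2.params.component("velocity").weight
        assert w2 == pytest.approx(3 * w1, rel=0.02)

    def test_flat_psth_rejected(self, grid):
        psth = vf.PSTHMatrix(rates=np.full((26, 80), 10.0), grid=grid)
        with pytest.raises(ValueError, match="flat|variance"):
            vf.SpatioTemporalTuningModel(psth)

    def test_summary_mentions_fit_quality(self, grid, stim, pure_a_params):
        model = vf.SpatioTemporalTuningModel(noiseless_psth(pure_a_params, grid, stim))
        text = model.fit("A").summary()
        assert "R2" in text and "BIC" in text and "acceleration" in text


@pytest.fixture(scope="module")
def pure_a_family(grid, stim, pure_a_params):
    # near-noiseless: a touch of rate noise keeps reduced-model R2 below 1
    rates = vf.predict_firing_rate(pure_a_params, grid, stim)
    rates = np.maximum(
        rates + np.random.default_rng(0).normal(0, 0.5, rates.shape), 0.0
    )
    model = vf.SpatioTemporalTuningModel(vf.PSTHMatrix(rates=rates, grid=grid))
    return model.fit_family()


class TestFamilySummaries:

    def test_partials_identify_the_generating_component(self, pure_a_family):
        pr = pure_a_family.partial_r2()
        assert pr["acceleration"] > 0.95
        assert pr["velocity"] < 0.05 and pr["jerk"] < 0.05

    def test_best_model_is_the_generator(self, pure_a_family):
        assert pure_a_family.best_spec.name == "A"

    def test_single_component_generator_is_separable(self, pure_a_family):
        assert pure_a_family.separability_index() >= 0.99

    def test_partial_r2_formula_consistency(self, pure_a_family):
        f = pure_a_family.fits
        expect = (f["VAJ"].r2 - f["VJ"].r2) / (1 - f["VJ"].r2)
        assert pure_a_family.partial_r2()["acceleration"] == pytest.approx(
            max(0.0, expect)
        )

    def test_summary_table_lists_all_models(self, pure_a_family):
        text = pure_a_family.summary()
        for name in ("V", "A", "J", "VA", "VJ", "AJ", "VAJ", "SepVAJ"):
            assert name in text

    def test_to_row_schema(self, pure_a_family):
        row = pure_a_family.to_row("cell1")
        for col in ("neuron_id", "best_model", "r2_vaj", "w_v", "w_a", "w_j",
                    "o_a", "pd_a_az", "pd_a_el", "tau0", "fr0", "sep_index",
                    "partial_r2_a"):
            assert col in row


class TestSelection:
    def test_bic_tie_broken_toward_fewer_parameters(self, grid, stim,
                                                    pure_a_params):
        model = vf.SpatioTemporalTuningModel(noiseless_psth(pure_a_params, grid, stim))
        fam = model.fit_family()
        fits = dict(fam.fits)
        import dataclasses

        # force an exact BIC tie between A and VAJ: smaller p must win
        fits["VAJ"] = dataclasses.replace(fits["VAJ"], bic=fits["A"].bic)
        assert vf.select_best_model(fits).name == "A"

    def test_poisson_single_component_generator_selected(self, grid, stim):
        truth = make_params(
            "A", [("acceleration", 70.0, 200.0, -20.0, 0.1)], baseline=50.0
        )
        picks = []
        for s in range(5):
            spikes = vf.simulate_spikes(truth, grid, stim, 5,
                                        np.random.default_rng(20 + s),
                                        trial_jitter_sd=5.0)
            fam = vf.SpatioTemporalTuningModel.from_spike_trains(spikes).fit_family()
            picks.append(fam.best_spec.name)
        assert sum(p == "A" for p in picks) >= 3
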