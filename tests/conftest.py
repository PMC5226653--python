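import numpy as np
import pytest

import vestfit as vf


@pytest.fixture(scope="session")
def grid():
    return vf.make_direction_grid()


@pytest.fixture(scope="session")
def stim():
    return vf.MotionStimulus()


def make_params(spec, comps, delay=0.05, baseline=40.0):
    """comps: list of (kind, weight, az, el, offset)."""
    return vf.ModelParams(
        spec=vf.ModelSpec.from_string(spec),
        components=tuple(
            vf.Component(k, w, vf.SpatialTuning(vf.Direction(az, el), o))
            for k, w, az, el, o in comps
        ),
        delay=delay,
        baseline=baseline,
    )


def noiseless_psth(params, grid, stim):
    """A PSTHMatrix holding the exact model rates (no trials, no noise)."""
    return vf.PSTHMatrix(
        rates=vf.predict_firing_rate(params, grid, stim), grid=grid
    )


@pytest.fixture(scope="session")
def pure_a_params():
    return make_params(
        "A", [("acceleration", 40.0, 120.0, 30.0, 0.2)], delay=0.06, baseline=50.0
    )


@pytest.fixture(scope="session")
def poisson_vaj_neuron(grid, stim):
    """One Poisson-spiking three-component neuron at protocol scale."""
    rng = np.random.default_rng(7)
    truth = make_params(
        "VAJ",
        [
            ("velocity", 60.0, 250.0, -50.0, 0.5),
            ("acceleration", 50.0, 280.0, -45.0, 0.0),
            ("jerk", 40.0, 330.0, 15.0, 0.3),
        ],
        delay=0.05,
        baseline=45.0,
    )
    spikes = vf.simulate_spikes(truth, grid=grid, stim=stim, n_reps=5, rng=rng,
                                trial_jitter_sd=5.0)
    return truth, spikes
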