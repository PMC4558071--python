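import numpy as np
import pytest

import sacpupil as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def run_cfg():
    return sp.RunConfig(decimate=10)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny experiment config for module-level tests (fast, deterministic)."""
    return sp.SimConfig(n_participants=4, n_trials_per_cell=2, part1_trials=10,
                        seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return sp.simulate_experiment(small_sim)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset, run_cfg):
    pres = sp.preprocess(small_dataset.trials, run_cfg)
    report = sp.apply_part2_filter(small_dataset.trials,
                                   [p.event for p in pres], run_cfg)
    return pres, report


def make_trial_meta(direction="right", condition="no_percept", cue_onset=1000.0,
                    participant="p00", trial_id=0, ecc=8.5, sf=None):
    along = {"left": (-1.0, 0.0), "right": (1.0, 0.0),
             "up": (0.0, 1.0), "down": (0.0, -1.0)}[direction]
    fix = (-ecc * along[0], -ecc * along[1])
    targ = (ecc * along[0], ecc * along[1])
    return sp.TrialMeta(participant=participant, trial_id=trial_id,
                        direction=direction, condition=condition,
                        cue_onset=cue_onset, fixation_pos=fix,
                        target_pos=targ, spatial_frequency=sf)
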