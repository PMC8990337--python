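import numpy as np
import pytest

import modeswitch as ms


def make_unit(unit_id="u0", spike_times=(), width=0.8, **kw):
    defaults = dict(
        area_label="ALM", depth_um=500.0, spike_width_ms=width,
        amplitude_uv=200.0, isi_violation=0.1, amplitude_cutoff=0.05,
        snr=5.0, presence_ratio=0.99, coordinates_um=(100.0, 100.0),
    )
    defaults.update(kw)
    return ms.Unit(unit_id=unit_id, spike_times=np.asarray(spike_times, float), **defaults)


def make_trial(i=0, type="lick_right", outcome="correct", t_go=10.0, **kw):
    defaults = dict(t_sample_on=t_go - 2.6, t_delay_on=t_go - 1.2, perturbation="none")
    defaults.update(kw)
    return ms.Trial(trial_index=i, type=type, outcome=outcome, t_go=t_go, **defaults)


def make_session(units, trials, animal_id="a0", session_id="s0"):
    return ms.SessionData(animal_id=animal_id, session_id=session_id,
                          units=list(units), trials=list(trials))


@pytest.fixture(scope="session")
def rank2_session():
    """One 100-unit session with planted rank-2 selectivity, shared by the
    mode-recovery tests."""
    cfg = ms.rank2_recovery_config(seed=0)
    sess, gt = ms.simulate_session(cfg, "a0", "s0", seed=101)
    return cfg, sess, gt


@pytest.fixture(scope="session")
def small_session():
    """A small simulated session for structural tests."""
    cfg = ms.SimConfig(n_animals=1, sessions_per_animal=1, neurons_per_session=12,
                       n_trials_per_type=20, seed=7)
    sess, gt = ms.simulate_session(cfg, "a0", "s0", seed=7)
    return cfg, sess, gt
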