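import numpy as np
import pytest

import rivalsamp as rs


@pytest.fixture(scope="session")
def montage():
    return rs.standard_montage()


@pytest.fixture(scope="session")
def study_config():
    return rs.StudyConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mismatched_cohort_first_switches(freq, rep, n_subjects=34, n_blocks=8,
                                     depth=0.9):
    """First-switch times of mismatched attended-low trials for one cohort.

    Runs the full rivalry forward model with the cue-locked hazard modulation
    injected at ``freq``; ~24 mismatched trials per subject arise from
    ``n_blocks`` attended blocks (6 low-frequency cues each, roughly half
    mismatched at onset).
    """
    cfg = rs.StudyConfig(blocks_per_session=n_blocks)
    dyn = rs.RivalryDynamics(modulation_freq_mismatch=freq,
                             modulation_depth=depth)
    times = []
    for s in range(n_subjects):
        trials = []
        for b in range(n_blocks):
            sched = rs.generate_cue_schedule(
                cfg, b, rng_seed=rep * 10_000 + s * 100 + b)
            trace = rs.simulate_rivalry_block(
                sched, dyn, cfg, rng_seed=rep * 10_000 + s * 100 + b + 50)
            trials += [t for t in rs.epoch_trials(trace, sched, subject_id=s)
                       if t.condition_label == "attended_low"
                       and t.congruence == "mismatched"]
        times.append(rs.first_switch_times(trials))
    return times
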