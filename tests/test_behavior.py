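"""Behavioral epoching, congruence, time-courses, PSI, FDR, CDFs."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

import rivalsamp as rs
from rivalsamp import behavior as bhv
from rivalsamp.synthgen import (ButtonTrace, CueEvent, STATE_HIGH, STATE_LOW,
                                STATE_NONE)


def make_trial(states, onset_index=120, cue_frequency="low_4p5",
               subject_id=0, attended=True):
    return bhv.Trial(subject_id=subject_id, block=0, attended=attended,
                     cue_frequency=cue_frequency,
                     modality="auditory" if cue_frequency != "none"
                     else "visual_only",
                     states=np.asarray(states, dtype=np.int8),
                     onset_index=onset_index)


def flat_trial(state, cue="low_4p5", n=540, **kw):
    return make_trial(np.full(n, state, dtype=np.int8), cue_frequency=cue, **kw)


# ---------------------------------------------------------------------------
# epoching and congruence
# ---------------------------------------------------------------------------

def test_congruence_classification():
    assert flat_trial(STATE_LOW, "low_4p5").congruence == "matched"
    assert flat_trial(STATE_HIGH, "low_4p5").congruence == "mismatched"
    assert flat_trial(STATE_HIGH, "high_20").congruence == "matched"
    # left-button convention for visual-only periods
    assert flat_trial(STATE_LOW, "none").congruence == "matched"
    assert flat_trial(STATE_NONE, "low_4p5").congruence == "undefined"


def test_congruence_partition_counts(study_config):
    sched = rs.generate_cue_schedule(study_config, 0, rng_seed=0)
    trace = rs.simulate_rivalry_block(sched, rs.RivalryDynamics(),
                                      study_config, rng_seed=1)
    trials = rs.epoch_trials(trace, sched)
    cross = [t for t in trials if t.cue_frequency != "none"]
    tally = sum(t.congruence in ("matched", "mismatched", "undefined")
                for t in cross)
    assert tally == len(cross) == 12


def test_out_of_bounds_epoch_dropped(study_config, caplog):
    sched = [CueEvent(onset=179.0, duration=2.0, modality="auditory",
                      cue_frequency="low_4p5", attended=True)]
    trace = ButtonTrace(states=np.zeros(10800, dtype=np.int8))
    with caplog.at_level("WARNING"):
        trials = rs.epoch_trials(trace, sched)
    assert trials == []
    assert "outside trace bounds" in caplog.text


def test_first_switch_time_conventions():
    states = np.zeros(540, dtype=np.int8)
    states[120 + 45:] = STATE_HIGH          # first change 45 samples post-onset
    assert make_trial(states).first_switch_time == pytest.approx(45 / 60)
    assert flat_trial(STATE_LOW).first_switch_time != \
        flat_trial(STATE_LOW).first_switch_time  # NaN (censored)


# ---------------------------------------------------------------------------
# probability time-courses
# ---------------------------------------------------------------------------

def test_probability_timecourse_trivial_cases():
    t1 = flat_trial(STATE_LOW, "low_4p5")
    tc = bhv.congruent_probability_timecourse([t1, t1])
    assert np.all(tc.mean == 1.0)
    t2 = flat_trial(STATE_HIGH, "low_4p5")
    tc = bhv.congruent_probability_timecourse([t1, t2])
    assert np.all(tc.per_subject == 0.5)


def test_timecourse_excludes_undefined_onsets():
    good = flat_trial(STATE_LOW, "low_4p5")
    bad = flat_trial(STATE_NONE, "low_4p5")
    tc = bhv.congruent_probability_timecourse([good, bad])
    assert np.all(tc.mean == 1.0)


def test_effect_separates_attended_low_condition(study_config):
    """Hazard gain > 1 for attended-low mismatched cues raises the congruent
    probability in the 1-4 s window relative to ignored cues."""
    dyn = rs.RivalryDynamics()       # mismatch gain 2, match gain 0.5
    att, ign = [], []
    for s in range(6):
        for b in range(3):
            for attended, sink in ((True, att), (False, ign)):
                sched = rs.generate_cue_schedule(study_config, b,
                                                 rng_seed=s * 10 + b,
                                                 attended=attended)
                trace = rs.simulate_rivalry_block(
                    sched, dyn, study_config,
                    rng_seed=5000 + s * 100 + b * 2 + attended)
                sink += [t for t in rs.epoch_trials(trace, sched, subject_id=s)
                         if t.cue_frequency == "low_4p5"]
    tca = bhv.congruent_probability_timecourse(att)
    tci = bhv.congruent_probability_timecourse(ign)
    win = (tca.times >= 1.0) & (tca.times < 4.0)
    assert tca.mean[win].mean() > tci.mean[win].mean() + 0.05


# ---------------------------------------------------------------------------
# per-bin statistics
# ---------------------------------------------------------------------------

def test_rm_anova_matches_pingouin_oracle(rng):
    data = rng.random((6, 10, 3))
    f, p = bhv.rm_anova_f(data)
    for b in range(3):
        long = []
        for c in range(6):
            for s in range(10):
                long.append({"cond": c, "subj": s, "y": data[c, s, b]})
        import pandas as pd
        res = pg.rm_anova(data=pd.DataFrame(long), dv="y", within="cond",
                          subject="subj")
        assert f[b] == pytest.approx(res["F"].iloc[0], rel=1e-9)
        assert p[b] == pytest.approx(res["p_unc"].iloc[0], rel=1e-9)


def test_identical_conditions_give_zero_f():
    base = np.random.default_rng(0).random((1, 8, 5))
    data = np.repeat(base, 6, axis=0)
    f, p = bhv.rm_anova_f(data)
    assert np.all(f == 0.0)
    assert np.all(p == 1.0)


def test_bh_stepup_thresholds():
    reject = bhv.bh_fdr(np.array([0.001, 0.02, 0.03, 0.5]), q=0.05)
    assert reject.tolist() == [True, True, True, False]


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(1e-6, 1.0), min_size=4, max_size=40),
       st.randoms(use_true_random=False))
def test_bh_rejections_invariant_to_input_order(pvals, rnd):
    pvals = np.asarray(pvals)
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    perm = np.asarray(perm)
    direct = bhv.bh_fdr(pvals)
    shuffled = bhv.bh_fdr(pvals[perm])
    assert np.array_equal(direct[perm], shuffled)


def test_per_bin_condition_test_requires_equal_shapes():
    tcs = {c: np.zeros((5, 4)) for c in bhv.SIX_CONDITIONS}
    tcs["attended_low"] = np.zeros((4, 4))
    with pytest.raises(ValueError):
        bhv.per_bin_condition_test(tcs)


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def test_psi_hand_arithmetic():
    times = np.arange(540) / 60 - 2.0
    mats = {"attended_low": np.full((1, 540), 0.6),
            "a": np.full((1, 540), 0.5), "b": np.full((1, 540), 0.5),
            "c": np.full((1, 540), 0.4), "d": np.full((1, 540), 0.4)}
    psi = bhv.compute_psi(mats, times, target="attended_low")
    assert psi[0] == pytest.approx(0.15)
    same = {k: np.full((1, 540), 0.7) for k in mats}
    assert bhv.compute_psi(same, times)[0] == pytest.approx(0.0)
    bounds = {"attended_low": np.ones((1, 540)),
              "x": np.zeros((1, 540))}
    assert bhv.compute_psi(bounds, times)[0] == pytest.approx(1.0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_psi_antisymmetry(seed):
    """Swapping target and comparison sets negates the PSI."""
    r = np.random.default_rng(seed)
    times = np.arange(540) / 60 - 2.0
    a, b = r.random((3, 540)), r.random((3, 540))
    fwd = bhv.compute_psi({"t": a, "o": b}, times, target="t")
    rev = bhv.compute_psi({"t": a, "o": b}, times, target="o")
    assert np.allclose(fwd, -rev)


def test_psi_empty_window_rejected():
    times = np.arange(540) / 60 - 2.0
    with pytest.raises(ValueError):
        bhv.compute_psi({"t": np.zeros((1, 540)), "o": np.zeros((1, 540))},
                        times, target="t", window=(4.0, 1.0))


# ---------------------------------------------------------------------------
# attention index
# ---------------------------------------------------------------------------

def test_attention_index_cases(rng):
    actual = rng.integers(0, 12, 24)
    assert rs.attention_index(actual, actual) == pytest.approx(1.0)
    assert np.isnan(rs.attention_index(np.full(24, 5), actual))
    with pytest.raises(ValueError):
        rs.attention_index(actual[:-1], actual)


def test_attention_index_permutation_null(rng):
    actual = rng.integers(0, 12, 24).astype(float)
    rs_ = [rs.attention_index(rng.permutation(actual), actual)
           for _ in range(1000)]
    rs_ = np.asarray(rs_)
    se = rs_.std(ddof=1) / np.sqrt(rs_.size)
    assert abs(rs_.mean()) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# first switches and CDFs
# ---------------------------------------------------------------------------

def test_switch_cdf_counts_and_censoring():
    grid = bhv.default_grid()
    times = [np.array([0.6, 0.6, 1.0, np.nan])]
    cdf = bhv.switch_cdf(times, grid)
    assert cdf[0, np.searchsorted(grid, 0.6)] == pytest.approx(0.5)
    assert cdf[0, -1] == pytest.approx(0.75)   # censored trial never counted
    assert np.all(np.diff(cdf[0]) >= 0)


@pytest.mark.parametrize("seed", range(20))
def test_cdf_monotone_and_bounded_on_simulated_data(seed):
    rng = np.random.default_rng(seed)
    times = [rs.sample_first_switch_times(30, 0.5, rng) for _ in range(4)]
    cdf = bhv.switch_cdf(times, bhv.default_grid())
    assert np.all(cdf >= 0) and np.all(cdf <= 1)
    assert np.all(np.diff(cdf, axis=1) >= 0)


def test_cdf_difference_test_flags_shifted_condition(rng):
    grid = bhv.default_grid()
    fast = bhv.switch_cdf([rs.sample_first_switch_times(200, 1.2, rng)
                           for _ in range(10)], grid)
    slow = bhv.switch_cdf([rs.sample_first_switch_times(200, 0.3, rng)
                           for _ in range(10)], grid)
    table = bhv.cdf_difference_test(fast, slow)
    assert table["fdr_significant"].any()
    null = bhv.cdf_difference_test(fast, fast)
    assert not null["fdr_significant"].any()
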