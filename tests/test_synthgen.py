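"""Generator contracts: schedules, rivalry traces, reports, montage, EEG."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import i0, i1

import rivalsamp as rs
from rivalsamp.behavior import first_switch_times, epoch_trials
from rivalsamp.eeg_itpc import POST_WINDOW, PRE_WINDOW, itpc, window_phase


# ---------------------------------------------------------------------------
# cue schedules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(100))
def test_schedule_counts_durations_and_isi_bounds(study_config, seed):
    sched = rs.generate_cue_schedule(study_config, block_index=0, rng_seed=seed)
    cross = [e for e in sched if e.is_crossmodal]
    nulls = [e for e in sched if not e.is_crossmodal]
    assert len(cross) == 12 and len(nulls) == 3
    low = sorted(e.duration for e in cross if e.cue_frequency == "low_4p5")
    high = sorted(e.duration for e in cross if e.cue_frequency == "high_20")
    assert low == high == [2.0, 2.0, 2.0, 3.1, 3.1, 4.0]
    assert all(e.duration == 2.6 for e in nulls)
    gaps = [sched[0].onset] + [b.onset - a.offset
                               for a, b in zip(sched, sched[1:])]
    assert all(7.0 <= g <= 10.0 for g in gaps)
    assert sched[-1].offset <= study_config.block_duration


def test_schedule_deterministic_given_seed(study_config):
    a = rs.generate_cue_schedule(study_config, 3, rng_seed=42)
    b = rs.generate_cue_schedule(study_config, 3, rng_seed=42)
    assert a == b
    c = rs.generate_cue_schedule(study_config, 3, rng_seed=43)
    assert a != c


def test_infeasible_block_raises():
    with pytest.raises(rs.ScheduleInfeasibleError):
        rs.StudyConfig(block_duration=60.0)


# ---------------------------------------------------------------------------
# rivalry traces
# ---------------------------------------------------------------------------

def test_trace_length_and_state_codes(study_config):
    sched = rs.generate_cue_schedule(study_config, 0, rng_seed=0)
    trace = rs.simulate_rivalry_block(sched, rs.RivalryDynamics(),
                                      study_config, rng_seed=1)
    assert trace.states.size == int(study_config.block_duration * 60)
    assert set(np.unique(trace.states)) <= {0, 1}


def test_trace_deterministic_and_empty_schedule_ok(study_config):
    dyn = rs.RivalryDynamics()
    a = rs.simulate_rivalry_block([], dyn, study_config, rng_seed=5)
    b = rs.simulate_rivalry_block([], dyn, study_config, rng_seed=5)
    assert np.array_equal(a.states, b.states)
    assert np.unique(a.states).size == 2  # switches do occur


def test_optional_no_press_state(study_config):
    dyn = rs.RivalryDynamics(no_press_prob=1.0)
    sched = rs.generate_cue_schedule(study_config, 0, rng_seed=0)
    trace = rs.simulate_rivalry_block(sched, dyn, study_config, rng_seed=1)
    assert 2 in np.unique(trace.states)


def test_unmodulated_first_switches_match_renewal_oracle(study_config):
    """With depth 0 and unit gains, cue-locked first-switch times are the
    residual life of the stationary gamma renewal process."""
    dyn = rs.RivalryDynamics(modulation_depth=0.0, hazard_gain_mismatch=1.0,
                             hazard_gain_match=1.0)
    sim_times = []
    for b in range(70):
        sched = rs.generate_cue_schedule(study_config, b, rng_seed=b)
        trace = rs.simulate_rivalry_block(sched, dyn, study_config,
                                          rng_seed=1000 + b)
        sim_times.append(first_switch_times(epoch_trials(trace, sched)))
    sim = np.concatenate(sim_times)
    sim = sim[~np.isnan(sim)]
    assert sim.size >= 1000
    oracle = rs.sample_renewal_residual_times(5000, dyn,
                                              np.random.default_rng(2))
    oracle = oracle[~np.isnan(oracle)]
    _, p = stats.ks_2samp(sim, oracle)
    assert p > 0.01


def test_injected_modulation_peaks_spectrum_at_target_bin():
    """Depth-0.9 modulation at 3.5 Hz dominates the first-switch spectrum
    (>=800 pooled trials), excluding the 0-1 Hz bins."""
    rng = np.random.default_rng(7)
    times = [rs.sample_first_switch_times(850, 0.8, rng, depth=0.9, freq=3.5)]
    tc = rs.switch_timecourse(times)
    spec = rs.amplitude_spectrum(tc)
    sel = spec.freqs > 1.0
    peak = spec.freqs[sel][np.argmax(spec.amps[sel])]
    grid_target = spec.freqs[np.argmin(np.abs(spec.freqs - 3.5))]
    assert peak == pytest.approx(grid_target)


def test_first_switch_sampler_matches_constant_hazard_cdf(rng):
    """The gridded sampler reproduces the exponential first-switch law."""
    lam = 0.7
    t = rs.sample_first_switch_times(40_000, lam, rng)
    switched = t[~np.isnan(t)]
    # censoring fraction and conditional CDF at 1 s
    assert np.mean(np.isnan(t)) == pytest.approx(np.exp(-lam * 7.0), abs=0.01)
    expected = (1 - np.exp(-lam * 1.0)) / (1 - np.exp(-lam * 7.0))
    assert np.mean(switched <= 1.0) == pytest.approx(expected, abs=0.02)


# ---------------------------------------------------------------------------
# attention reports
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def attended_blocks(study_config):
    scheds, traces = [], []
    for b in range(24):
        sched = rs.generate_cue_schedule(study_config, b, rng_seed=b)
        scheds.append(sched)
        traces.append(rs.simulate_rivalry_block(sched, rs.RivalryDynamics(),
                                                study_config, rng_seed=100 + b))
    return traces, scheds


def test_perfect_reports_reproduce_truth_and_unit_index(attended_blocks):
    traces, scheds = attended_blocks
    df = rs.simulate_attention_reports(traces, scheds, 1.0, rng_seed=0)
    assert (df["reported"] == df["actual"]).all()
    assert rs.attention_index(df["reported"], df["actual"]) == pytest.approx(1.0)


def test_zero_accuracy_reports_are_uninformative(attended_blocks):
    """Monte-Carlo under independence: the attention index is centred on 0."""
    traces, scheds = attended_blocks
    vals = []
    for rep in range(100):
        df = rs.simulate_attention_reports(traces, scheds, 0.0, rng_seed=rep)
        r = rs.attention_index(df["reported"], df["actual"])
        if np.isfinite(r):
            vals.append(r)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean()) < 3 * se + 1e-12


def test_report_accuracy_validated(attended_blocks):
    traces, scheds = attended_blocks
    with pytest.raises(ValueError):
        rs.simulate_attention_reports(traces, scheds, 1.5, rng_seed=0)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def test_montage_cluster_pairs_are_adjacent(montage):
    assert len(montage.ch_names) == 64
    assert montage.distance("FT8", "C6") <= 3.5
    assert montage.distance("P6", "PO8") <= 3.5
    assert montage.distance("Fp1", "O2") > 3.5


def test_montage_adjacency_is_sparse_and_symmetric(montage):
    adj = montage.adjacency(3.5)
    assert np.array_equal(adj, adj.T)
    assert not adj.diagonal().any()
    degrees = adj.sum(axis=1)
    assert degrees.max() <= 10  # near-neighbour graph, not a clique


def test_montage_json_roundtrip(tmp_path, montage):
    montage.to_json(tmp_path / "m.json")
    back = rs.Montage.from_json(tmp_path / "m.json")
    assert back.ch_names == montage.ch_names
    assert np.allclose(back.positions_cm, montage.positions_cm)


# ---------------------------------------------------------------------------
# synthetic EEG
# ---------------------------------------------------------------------------

def test_eeg_epoch_geometry_and_determinism(montage):
    truth = rs.EEGGroundTruth(kappa=2.0)
    a = rs.simulate_eeg_epochs(5, truth, montage, rng_seed=9)
    b = rs.simulate_eeg_epochs(5, truth, montage, rng_seed=9)
    assert a.data.shape == (5, 64, 1000)
    assert np.array_equal(a.data, b.data)
    assert a.times[0] == pytest.approx(-2.0)


def test_negative_kappa_rejected():
    with pytest.raises(ValueError):
        rs.EEGGroundTruth(kappa=-1.0)


def test_perfect_phase_locking_saturates_itpc(montage):
    truth = rs.EEGGroundTruth(kappa=1e6, noise_sd=0.05)
    ep = rs.simulate_eeg_epochs(48, truth, montage, rng_seed=3)
    post = itpc(window_phase(ep, POST_WINDOW, 3.5), axis=0)
    assert post.mean() > 0.98


def test_unlocked_eeg_has_zero_mean_evoked_itpc(montage):
    """kappa = 0 everywhere: evoked ITPC averages to 0 within Monte-Carlo
    error (replicates x 64 electrodes as independent draws)."""
    vals = []
    for rep in range(8):
        ep = rs.simulate_eeg_epochs(
            16, rs.EEGGroundTruth(kappa=0.0, noise_sd=0.3), montage,
            rng_seed=rep)
        post = itpc(window_phase(ep, POST_WINDOW, 3.5), axis=0)
        pre = itpc(window_phase(ep, PRE_WINDOW, 3.5), axis=0)
        vals.append(post - pre)
    vals = np.concatenate(vals)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean()) < 3 * se + 1e-12


def test_evoked_itpc_monotone_in_kappa(montage):
    means = []
    for kappa in (0.0, 1.0, 4.0, 16.0):
        ep = rs.simulate_eeg_epochs(
            24, rs.EEGGroundTruth(kappa=kappa, noise_sd=0.2), montage,
            rng_seed=11)
        post = itpc(window_phase(ep, POST_WINDOW, 3.5), axis=0)
        pre = itpc(window_phase(ep, PRE_WINDOW, 3.5), axis=0)
        means.append((post - pre).mean())
    assert np.all(np.diff(means) > 0)


def test_itpc_converges_to_von_mises_resultant(montage):
    """ITPC at large N approaches I1(kappa)/I0(kappa)."""
    kappa = 4.0
    ep = rs.simulate_eeg_epochs(
        500, rs.EEGGroundTruth(kappa=kappa, noise_sd=0.1), montage, rng_seed=3)
    post = itpc(window_phase(ep, POST_WINDOW, 3.5), axis=0)
    assert post.mean() == pytest.approx(i1(kappa) / i0(kappa), abs=0.05)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def test_schedule_and_trace_tsv_roundtrip(tmp_path, study_config):
    scheds = [rs.generate_cue_schedule(study_config, b, rng_seed=b)
              for b in range(2)]
    traces = [rs.simulate_rivalry_block(s, rs.RivalryDynamics(), study_config,
                                        rng_seed=i)
              for i, s in enumerate(scheds)]
    from rivalsamp import synthgen as sg
    sg.write_schedules_tsv(scheds, tmp_path / "s.tsv")
    sg.write_traces_tsv(traces, tmp_path / "t.tsv")
    back_s = sg.read_schedules_tsv(tmp_path / "s.tsv")
    back_t = sg.read_traces_tsv(tmp_path / "t.tsv")
    assert back_s == scheds
    assert all(np.array_equal(a.states, b.states)
               for a, b in zip(back_t, traces))
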