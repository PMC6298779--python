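"""Synthetic study generator for crossmodal binocular-rivalry experiments.

Emulates the design of a dense-sampling rivalry study: 3-minute blocks of
continuous binocular rivalry report (60 Hz button state) during which brief
auditory/tactile cues, amplitude-modulated at the flicker frequency of one of
the two rivaling images (4.5 or 20 Hz), are interleaved with "visual-only"
null periods.  The generator provides full ground-truth control over

* the cue schedule (12 crossmodal + 3 null cues per block, jittered ISIs),
* rivalry dynamics (gamma renewal of dominance durations, with an optional
  cue-locked oscillatory modulation of the first-switch hazard),
* per-block subjective tally reports used for the attention-on-task index,
* a 64-channel electrode montage, and
* cue-locked EEG epochs with von Mises phase-locked oscillatory components
  on a 1/f noise floor.

All randomness flows through one global seed expanded into per-block /
per-subject child seeds by an explicit spawn-key scheme (`child_rng`), so any
block or subject is regenerable in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# state codes for the 60 Hz button trace
# ---------------------------------------------------------------------------

STATE_LOW = 0    # low-frequency (4.5 Hz) image dominant; "left button"
STATE_HIGH = 1   # high-frequency (20 Hz) image dominant; "right button"
STATE_NONE = 2   # optional piecemeal / no-press state

STATE_NAMES = {STATE_LOW: "low_percept", STATE_HIGH: "high_percept",
               STATE_NONE: "no_press"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

MODALITIES = ("auditory", "tactile", "combined")
FREQ_LOW = "low_4p5"
FREQ_HIGH = "high_20"
FREQ_NONE = "none"


class ScheduleInfeasibleError(ValueError):
    """Raised when the requested cues + minimal ISIs do not fit in a block."""


def child_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, *indices).

    Uses numpy's SeedSequence spawn-key mechanism, so e.g.
    ``child_rng(seed, subject, block)`` always yields the same stream
    regardless of what else has been generated.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Design parameters of one recording session."""

    n_subjects: int = 34
    blocks_per_session: int = 24
    block_duration: float = 180.0          # seconds
    sample_rate_behavior: int = 60         # Hz, button state
    sample_rate_eeg: int = 250             # Hz, analysis rate
    #: crossmodal cue durations per frequency (3 x 2 s, 2 x 3.1 s, 1 x 4 s)
    cue_durations: tuple = (2.0, 2.0, 2.0, 3.1, 3.1, 4.0)
    null_cue_duration: float = 2.6         # seconds ("visual-only" periods)
    n_null_cues: int = 3
    isi_range: tuple = (7.0, 10.0)         # uniform jitter between cue periods
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.cue_durations) or self.null_cue_duration <= 0:
            raise ValueError("all cue durations must be positive")
        if not self.isi_range[0] <= self.isi_range[1]:
            raise ValueError("isi_range must be ordered")
        n_events = 2 * len(self.cue_durations) + self.n_null_cues
        min_total = (2 * sum(self.cue_durations)
                     + self.n_null_cues * self.null_cue_duration
                     + n_events * self.isi_range[0])
        if self.block_duration < min_total:
            raise ScheduleInfeasibleError(
                f"block of {self.block_duration} s cannot fit {n_events} cues "
                f"with minimal ISIs (needs >= {min_total:.1f} s)")


@dataclass
class CueEvent:
    """One timed cue period within a block."""

    onset: float               # seconds from block start
    duration: float
    modality: str              # auditory | tactile | combined | visual_only
    cue_frequency: str         # low_4p5 | high_20 | none
    attended: bool             # session-level attention instruction

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def is_crossmodal(self) -> bool:
        return self.modality != "visual_only"


@dataclass
class RivalryDynamics:
    """Forward model of rivalry report dynamics.

    Dominance durations outside cue influence are gamma(shape, mean/shape)
    renewals.  After an *attended low-frequency* cue onset the hazard of the
    first switch is multiplicatively modulated,

        h(t) = h0(u) * g * (1 + m * cos(2*pi*f*t + phi)),

    with t the time since cue onset, u the time since the last switch, and
    (g, f) selected by the congruence of the cue with the percept at onset:
    mismatched cues promote switching (g > 1) at ``modulation_freq_mismatch``
    and matched cues delay it (g < 1) at ``modulation_freq_match``.
    Unattended, high-frequency and null cues leave the hazard unmodulated.
    """

    dominance_shape: float = 3.5
    dominance_mean: float = 2.5            # seconds
    hazard_gain_mismatch: float = 2.0
    hazard_gain_match: float = 0.5
    modulation_freq_mismatch: float = 3.5  # Hz
    modulation_freq_match: float = 8.0     # Hz
    modulation_depth: float = 0.9
    modulation_phase: float = 0.0          # radians
    #: optional third (piecemeal / no-press) state; default off
    no_press_prob: float = 0.0
    no_press_duration: float = 0.15        # seconds

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.hazard_gain_mismatch < 0 or self.hazard_gain_match < 0:
            raise ValueError("hazard gains must be >= 0")
        if self.dominance_mean <= 0 or self.dominance_shape <= 0:
            raise ValueError("dominance duration parameters must be positive")
        if not 0.0 <= self.no_press_prob <= 1.0:
            raise ValueError("no_press_prob must lie in [0, 1]")


@dataclass
class ButtonTrace:
    """60 Hz perceptual-report state sequence for one block."""

    states: np.ndarray                     # int8 codes, STATE_* values
    sample_rate: int = 60
    block_index: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = set(np.unique(self.states)) - set(STATE_NAMES)
        if bad:
            raise ValueError(f"unknown state codes in trace: {bad}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.size) / self.sample_rate


# ---------------------------------------------------------------------------
# cue schedules
# ---------------------------------------------------------------------------

def generate_cue_schedule(config: StudyConfig, block_index: int,
                          rng_seed: int | None = None,
                          attended: bool = True,
                          modality: str | None = None) -> list[CueEvent]:
    """Randomized cue schedule for one block.

    12 crossmodal cues (6 low-, 6 high-frequency, with the duration multiset
    of ``config.cue_durations`` per frequency) plus ``n_null_cues`` visual-only
    periods, in seed-determined random order, separated by ISIs drawn
    uniformly from ``config.isi_range`` (the gap before the first cue is drawn
    the same way).  ISI sets whose total overruns the block are redrawn.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = child_rng(seed, block_index)
    if modality is None:
        modality = MODALITIES[block_index % len(MODALITIES)]

    events = ([(d, modality, FREQ_LOW) for d in config.cue_durations]
              + [(d, modality, FREQ_HIGH) for d in config.cue_durations]
              + [(config.null_cue_duration, "visual_only", FREQ_NONE)]
              * config.n_null_cues)
    order = rng.permutation(len(events))
    events = [events[i] for i in order]

    durations = np.array([e[0] for e in events])
    lo, hi = config.isi_range
    for _ in range(10_000):
        isis = rng.uniform(lo, hi, size=len(events))
        if isis.sum() + durations.sum() <= config.block_duration:
            break
    else:  # pragma: no cover - astronomically unlikely with a feasible config
        raise ScheduleInfeasibleError("could not place cues within the block")

    schedule, t = [], 0.0
    for (dur, mod, freq), isi in zip(events, isis):
        t += isi
        schedule.append(CueEvent(onset=float(t), duration=float(dur),
                                 modality=mod, cue_frequency=freq,
                                 attended=attended))
        t += dur
    return schedule


# ---------------------------------------------------------------------------
# rivalry simulation
# ---------------------------------------------------------------------------

def _gamma_hazard_table(dynamics: RivalryDynamics, sr: int,
                        max_seconds: float = 60.0) -> np.ndarray:
    """Discrete baseline hazard h0 for the gamma renewal process.

    Entry k is the hazard evaluated at time-since-switch (k + 0.5)/sr; beyond
    the table the (asymptotically constant) last value is reused.
    """
    shape = dynamics.dominance_shape
    scale = dynamics.dominance_mean / shape
    u = (np.arange(int(max_seconds * sr)) + 0.5) / sr
    sf = stats.gamma.sf(u, shape, scale=scale)
    pdf = stats.gamma.pdf(u, shape, scale=scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(sf > 1e-12, pdf / sf, 1.0 / scale)
    return h


def simulate_rivalry_block(schedule: Sequence[CueEvent],
                           dynamics: RivalryDynamics,
                           config: StudyConfig,
                           rng_seed: int,
                           modulation_horizon: float = 7.0) -> ButtonTrace:
    """Simulate one block's 60 Hz button trace under the hazard model.

    The percept alternates as a gamma renewal process; after an attended
    low-frequency cue onset the first-switch hazard is modulated as described
    in :class:`RivalryDynamics` until that first switch occurs (or until
    ``modulation_horizon`` seconds elapse).  An empty schedule yields a plain
    renewal trace.
    """
    sr = config.sample_rate_behavior
    dt = 1.0 / sr
    n = int(round(config.block_duration * sr))
    h0 = _gamma_hazard_table(dynamics, sr)
    rng = child_rng(rng_seed)

    # pre-compute cue arming info: (onset_sample, freq string)
    cue_onsets = {}
    for ev in schedule:
        if ev.attended and ev.cue_frequency == FREQ_LOW:
            cue_onsets[int(round(ev.onset * sr))] = ev

    m = dynamics.modulation_depth
    phi = dynamics.modulation_phase
    horizon = int(round(modulation_horizon * sr))

    randoms = rng.random(n)
    np_draws = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    state = int(rng.integers(2))
    u = 0                      # samples since last switch
    active = None              # (onset_sample, gain, freq) of armed modulation
    no_press_left = 0
    np_len = max(1, int(round(dynamics.no_press_duration * sr)))

    for i in range(n):
        ev = cue_onsets.get(i)
        if ev is not None and state in (STATE_LOW, STATE_HIGH):
            if state == STATE_LOW:       # percept matches the low-freq cue
                active = (i, dynamics.hazard_gain_match,
                          dynamics.modulation_freq_match)
            else:                        # mismatched at onset
                active = (i, dynamics.hazard_gain_mismatch,
                          dynamics.modulation_freq_mismatch)
        h = h0[u] if u < h0.size else h0[-1]
        if active is not None:
            t0, gain, f = active
            if i - t0 >= horizon:
                active = None
            else:
                h *= gain * (1.0 + m * np.cos(2 * np.pi * f * (i - t0) * dt + phi))
        if randoms[i] < -np.expm1(-max(h, 0.0) * dt):
            state ^= 1
            u = 0
            active = None
            if dynamics.no_press_prob > 0 and np_draws[i] < dynamics.no_press_prob:
                no_press_left = np_len
        else:
            u += 1
        if no_press_left > 0:
            states[i] = STATE_NONE
            no_press_left -= 1
        else:
            states[i] = state
    return ButtonTrace(states=states, sample_rate=sr, block_index=0)


def sample_renewal_residual_times(n: int, dynamics: RivalryDynamics,
                                  rng: np.random.Generator,
                                  horizon: float = 7.0) -> np.ndarray:
    """Direct sampler of cue-locked first-switch times under pure renewal.

    Simulates a long stationary gamma renewal sequence, probes it at random
    times, and returns the residual life (time to the next switch), censored
    at ``horizon`` (NaN).  Serves as an independent oracle for the
    unmodulated trace simulator.
    """
    shape = dynamics.dominance_shape
    scale = dynamics.dominance_mean / shape
    total = n * dynamics.dominance_mean * 4 + 100.0
    durations = rng.gamma(shape, scale, size=int(total / dynamics.dominance_mean * 2))
    edges = np.cumsum(durations)
    probes = rng.uniform(edges[0], edges[-2], size=n)
    nxt = edges[np.searchsorted(edges, probes)]
    res = nxt - probes
    res[res > horizon] = np.nan
    return res


def sample_first_switch_times(n_trials: int, base_hazard: float,
                              rng: np.random.Generator,
                              gain: float = 1.0, depth: float = 0.0,
                              freq: float = 0.0, phase: float = 0.0,
                              horizon: float = 7.0, sr: int = 60) -> np.ndarray:
    """Cue-locked first-switch sampler with a sinusoidally modulated hazard.

    Draws first-switch times on the 1/sr grid from the discrete-time hazard
    h(t) = base_hazard * gain * (1 + depth*cos(2*pi*freq*t + phase)); trials
    with no switch before ``horizon`` are censored (NaN).  This abstracts the
    full rivalry trace away and is the generator used for null-calibration
    and frequency-recovery cohorts.
    """
    k = np.arange(1, int(round(horizon * sr)) + 1)
    t = k / sr
    h = base_hazard * gain * (1.0 + depth * np.cos(2 * np.pi * freq * t + phase))
    h = np.clip(h, 0.0, None)
    p = -np.expm1(-h / sr)
    surv = np.cumprod(1.0 - p)
    cdf = 1.0 - surv
    u = rng.random(n_trials)
    idx = np.searchsorted(cdf, u)
    times = np.where(idx < k.size, (idx + 1) / sr, np.nan)
    return times


# ---------------------------------------------------------------------------
# attention-on-task reports
# ---------------------------------------------------------------------------

def true_congruent_tally(trace: ButtonTrace, schedule: Sequence[CueEvent]) -> int:
    """Number of crossmodal cues whose frequency matches the percept at offset."""
    sr = trace.sample_rate
    count = 0
    for ev in schedule:
        if not ev.is_crossmodal:
            continue
        i = min(int(round(ev.offset * sr)), trace.states.size - 1)
        s = trace.states[i]
        if (ev.cue_frequency == FREQ_LOW and s == STATE_LOW) or \
           (ev.cue_frequency == FREQ_HIGH and s == STATE_HIGH):
            count += 1
    return count


def simulate_attention_reports(traces: Sequence[ButtonTrace],
                               schedules: Sequence[Sequence[CueEvent]],
                               report_accuracy: float,
                               rng_seed: int) -> pd.DataFrame:
    """Per-block subjective tallies of frequency-congruent cue offsets.

    The true tally is computed from the trace; the report mixes it with a
    uniform random tally in proportion (1 - report_accuracy) and rounds to an
    integer, so accuracy 1 reproduces the truth exactly and accuracy 0 yields
    reports independent of the truth.
    """
    if not 0.0 <= report_accuracy <= 1.0:
        raise ValueError("report_accuracy must lie in [0, 1]")
    rng = child_rng(rng_seed)
    rows = []
    for b, (trace, schedule) in enumerate(zip(traces, schedules)):
        n_cross = sum(ev.is_crossmodal for ev in schedule)
        actual = true_congruent_tally(trace, schedule)
        noise = rng.uniform(0, n_cross)
        reported = int(round(report_accuracy * actual
                             + (1.0 - report_accuracy) * noise))
        rows.append({"block": b, "actual": actual,
                     "reported": int(np.clip(reported, 0, n_cross))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# electrode montage
# ---------------------------------------------------------------------------

#: 64-channel ActiCap-style 10-10 label set (ground AFz / reference FCz absent)
ACTICAP_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
]

#: sphere radius (cm) for montage positions.  Chosen so that first-order
#: 10-10 neighbours -- including the fronto-temporal pair FT8/C6 -- fall
#: within the 3.5 cm cluster-adjacency criterion while more distant sites
#: do not.
HEAD_RADIUS_CM = 6.8


@dataclass
class Montage:
    ch_names: list
    positions_cm: np.ndarray   # (n_channels, 3)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def distance(self, a: str, b: str) -> float:
        pa = self.positions_cm[self.index(a)]
        pb = self.positions_cm[self.index(b)]
        return float(np.linalg.norm(pa - pb))

    def adjacency(self, max_dist_cm: float = 3.5) -> np.ndarray:
        """Boolean adjacency matrix under a pairwise-distance cut."""
        d = np.linalg.norm(self.positions_cm[:, None] - self.positions_cm[None], axis=-1)
        adj = d <= max_dist_cm
        np.fill_diagonal(adj, False)
        return adj

    def to_json(self, path: str | Path) -> None:
        payload = {"ch_names": list(self.ch_names),
                   "positions_cm": self.positions_cm.tolist()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(ch_names=payload["ch_names"],
                   positions_cm=np.asarray(payload["positions_cm"], float))


def standard_montage() -> Montage:
    """64-channel 10-10 montage on a sphere of HEAD_RADIUS_CM.

    Directions come from the mne 'easycap-M1' template; each electrode is
    projected radially onto the sphere so that pairwise distances scale
    uniformly.
    """
    from mne.channels import make_standard_montage

    tpl = make_standard_montage("easycap-M1").get_positions()["ch_pos"]
    pos = np.array([tpl[name] for name in ACTICAP_64], dtype=float)
    pos = HEAD_RADIUS_CM * pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(ch_names=list(ACTICAP_64), positions_cm=pos)


# ---------------------------------------------------------------------------
# synthetic EEG
# ---------------------------------------------------------------------------

@dataclass
class EEGGroundTruth:
    """Ground truth for the phase-locked EEG generator.

    ``kappa`` is the von Mises concentration of the post-onset phase of each
    oscillatory component, broadcastable to (n_freqs, n_channels); kappa = 0
    means no phase locking (uniform phases), large kappa approaches perfect
    locking.  Pre-onset phases are always uniform.
    """

    component_freqs: tuple = (3.5, 8.0)     # Hz
    amplitudes: tuple = (1.0, 1.0)          # uV
    kappa: float | np.ndarray = 0.0
    phase_mu: tuple = (0.0, 0.0)            # radians, per component
    noise_exponent: float = 1.0             # 1/f^alpha slope
    noise_sd: float = 1.0                   # uV

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.kappa) < 0):
            raise ValueError("kappa must be >= 0")
        if np.any(np.asarray(self.amplitudes) < 0):
            raise ValueError("amplitudes must be >= 0")


@dataclass
class EEGEpochs:
    """Cue-locked epochs: trials x electrodes x samples, -2 to +2 s."""

    data: np.ndarray
    sfreq: float = 250.0
    t_start: float = -2.0
    ch_names: list = field(default_factory=list)
    subject_id: int = 0
    condition: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[-1]) / self.sfreq

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _one_over_f_noise(shape: tuple, n_samples: int, exponent: float,
                      sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise, unit-free, scaled to standard deviation `sd`."""
    freqs = np.fft.rfftfreq(n_samples)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape + (freqs.size,))
            + 1j * rng.standard_normal(shape + (freqs.size,))) * w
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return sd * x / s


def simulate_eeg_epochs(n_trials: int, truth: EEGGroundTruth, montage: Montage,
                        rng_seed: int, sfreq: float = 250.0,
                        t_start: float = -2.0, t_stop: float = 2.0,
                        subject_id: int = 0, condition: str = "") -> EEGEpochs:
    """Generate cue-locked epochs with controllable phase locking.

    Each trial/electrode is a sum of cosines at ``truth.component_freqs``
    riding on 1/f noise.  In the post-onset half of the epoch (t >= 0) the
    phase of component k at electrode c is drawn from a von Mises with
    concentration kappa[k, c]; in the pre-onset half the phase is uniform.
    """
    rng = child_rng(rng_seed, subject_id)
    n_ch = len(montage.ch_names)
    n_samp = int(round((t_stop - t_start) * sfreq))
    t = t_start + np.arange(n_samp) / sfreq
    post = t >= 0

    freqs = np.asarray(truth.component_freqs, float)
    amps = np.asarray(truth.amplitudes, float)
    kappa = np.broadcast_to(np.asarray(truth.kappa, float),
                            (freqs.size, n_ch)).copy()
    mu = np.asarray(truth.phase_mu, float)

    data = _one_over_f_noise((n_trials, n_ch), n_samp,
                             truth.noise_exponent, truth.noise_sd, rng)
    for k, (f, a) in enumerate(zip(freqs, amps)):
        phi_pre = rng.uniform(-np.pi, np.pi, size=(n_trials, n_ch))
        phi_post = rng.vonmises(mu[k], np.maximum(kappa[k], 1e-12),
                                size=(n_trials, n_ch))
        # kappa exactly 0 -> uniform phases (vonmises(kappa->0) is uniform)
        arg = 2 * np.pi * f * t
        data += a * np.where(post, np.cos(arg + phi_post[..., None]),
                             np.cos(arg + phi_pre[..., None]))
    return EEGEpochs(data=data.astype(np.float64), sfreq=sfreq, t_start=t_start,
                     ch_names=list(montage.ch_names), subject_id=subject_id,
                     condition=condition)


# ---------------------------------------------------------------------------
# tabular / array I/O (TSV dialect shared with the analysis modules)
# ---------------------------------------------------------------------------

def schedules_to_frame(schedules: Iterable[Sequence[CueEvent]]) -> pd.DataFrame:
    rows = []
    for b, schedule in enumerate(schedules):
        for ev in schedule:
            rows.append({"block": b, "onset_s": ev.onset, "duration_s": ev.duration,
                         "modality": ev.modality, "cue_frequency": ev.cue_frequency,
                         "attended": ev.attended})
    return pd.DataFrame(rows)


def frame_to_schedules(df: pd.DataFrame) -> list[list[CueEvent]]:
    out = []
    for _, g in df.groupby("block", sort=True):
        out.append([CueEvent(onset=r.onset_s, duration=r.duration_s,
                             modality=r.modality, cue_frequency=r.cue_frequency,
                             attended=bool(r.attended))
                    for r in g.itertuples()])
    return out


def write_schedules_tsv(schedules, path: str | Path) -> None:
    schedules_to_frame(schedules).to_csv(path, sep="\t", index=False,
                                         float_format="%.17g")


def read_schedules_tsv(path: str | Path) -> list[list[CueEvent]]:
    return frame_to_schedules(pd.read_csv(path, sep="\t",
                                          float_precision="round_trip"))


def traces_to_frame(traces: Iterable[ButtonTrace]) -> pd.DataFrame:
    frames = []
    for b, trace in enumerate(traces):
        n = trace.states.size
        frames.append(pd.DataFrame({
            "block": b, "sample_index": np.arange(n),
            "time_s": np.arange(n) / trace.sample_rate,
            "state": [STATE_NAMES[s] for s in trace.states]}))
    return pd.concat(frames, ignore_index=True)


def write_traces_tsv(traces, path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path: str | Path) -> list[ButtonTrace]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for b, g in df.groupby("block", sort=True):
        sr = int(round(1.0 / np.diff(g["time_s"].to_numpy()[:2])[0]))
        codes = np.array([STATE_CODES[s] for s in g["state"]], dtype=np.int8)
        out.append(ButtonTrace(states=codes, sample_rate=sr, block_index=int(b)))
    return out


def write_eeg_epochs(epochs: EEGEpochs, montage: Montage, out_dir: str | Path,
                     stem: str) -> None:
    """Float32 array container plus a JSON sidecar with geometry metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / f"{stem}.npy", epochs.data.astype("<f4"))
    sidecar = {"n_trials": int(epochs.data.shape[0]),
               "n_channels": int(epochs.data.shape[1]),
               "n_samples": int(epochs.data.shape[2]),
               "sfreq": epochs.sfreq, "t0": epochs.t_start,
               "ch_names": list(epochs.ch_names),
               "positions_cm": montage.positions_cm.tolist(),
               "subject_id": epochs.subject_id, "condition": epochs.condition}
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))


def read_eeg_epochs(out_dir: str | Path, stem: str) -> EEGEpochs:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.json").read_text())
    data = np.load(out_dir / f"{stem}.npy").astype(np.float64)
    return EEGEpochs(data=data, sfreq=meta["sfreq"], t_start=meta["t0"],
                     ch_names=meta["ch_names"], subject_id=meta["subject_id"],
                     condition=meta["condition"])
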