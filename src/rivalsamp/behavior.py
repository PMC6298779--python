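"""Cue-locked behavioral analysis of binocular-rivalry button traces.

Epochs the 60 Hz button-state trace around every cue, classifies each trial's
congruence at onset (does the cue's modulation frequency agree with the
flicker frequency of the currently dominant image?), and computes

* probability time-courses of a reference percept on the 16.7 ms grid,
* per-bin six-condition repeated-measures statistics with BH-FDR correction,
* the perceptual switch index (PSI),
* the attention-on-task index (tally correlation),
* first-switch times, their cumulative density functions, and per-bin CDF
  difference tests.

Bin convention: bin k covers [k/60, (k+1)/60) s, 0-based, with cue onset at
t = 0; each 60 Hz sample belongs to exactly one bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthgen import (ButtonTrace, CueEvent, FREQ_HIGH, FREQ_LOW, FREQ_NONE,
                       STATE_HIGH, STATE_LOW, STATE_NONE)

logger = logging.getLogger(__name__)

EPOCH_START = -2.0     # seconds relative to cue onset
EPOCH_STOP = 7.0       # censoring horizon = minimum ISI
MATCHED = "matched"
MISMATCHED = "mismatched"
UNDEFINED = "undefined"

#: canonical six-condition labels of the within-subject design
SIX_CONDITIONS = ("visual_only_attend", "visual_only_ignore",
                  "attended_low", "attended_high",
                  "ignored_low", "ignored_high")


@dataclass
class Trial:
    """One cue-locked behavioral epoch."""

    subject_id: int
    block: int
    attended: bool
    cue_frequency: str           # low_4p5 | high_20 | none
    modality: str
    states: np.ndarray           # int8, 60 Hz, [EPOCH_START, EPOCH_STOP)
    onset_index: int             # index of the t = 0 sample within `states`
    sample_rate: int = 60

    @property
    def onset_state(self) -> int:
        return int(self.states[self.onset_index])

    @property
    def congruence(self) -> str:
        """Congruence of the percept at cue onset with the cue frequency.

        Visual-only periods use the left-button convention: the low-frequency
        (left-eye) percept is arbitrarily the congruent one.
        """
        s = self.onset_state
        if s == STATE_NONE:
            return UNDEFINED
        if self.cue_frequency == FREQ_LOW or self.cue_frequency == FREQ_NONE:
            return MATCHED if s == STATE_LOW else MISMATCHED
        return MATCHED if s == STATE_HIGH else MISMATCHED

    @property
    def congruent_state(self) -> int:
        """Percept state congruent with the cue frequency (left button for
        visual-only periods)."""
        return STATE_HIGH if self.cue_frequency == FREQ_HIGH else STATE_LOW

    @property
    def first_switch_time(self) -> float:
        """Time of the first post-onset change in button state (s), NaN if
        censored (no change before the epoch end) or onset undefined."""
        if self.onset_state == STATE_NONE:
            return np.nan
        post = self.states[self.onset_index + 1:]
        hits = np.nonzero(post != self.onset_state)[0]
        if hits.size == 0:
            return np.nan
        return float((hits[0] + 1) / self.sample_rate)

    @property
    def condition_label(self) -> str:
        if self.cue_frequency == FREQ_NONE:
            return "visual_only_attend" if self.attended else "visual_only_ignore"
        band = "low" if self.cue_frequency == FREQ_LOW else "high"
        return f"{'attended' if self.attended else 'ignored'}_{band}"


def epoch_trials(trace: ButtonTrace, schedule: Sequence[CueEvent],
                 subject_id: int = 0, block: int = 0) -> list[Trial]:
    """One Trial per cue event; epochs exceeding the trace are dropped."""
    sr = trace.sample_rate
    pre = int(round(-EPOCH_START * sr))
    post = int(round(EPOCH_STOP * sr))
    trials = []
    for ev in schedule:
        onset = int(round(ev.onset * sr))
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > trace.states.size:
            logger.warning("dropping trial at %.2f s (block %d): epoch window "
                           "outside trace bounds", ev.onset, block)
            continue
        trials.append(Trial(subject_id=subject_id, block=block,
                            attended=ev.attended, cue_frequency=ev.cue_frequency,
                            modality=ev.modality,
                            states=trace.states[lo:hi].copy(),
                            onset_index=pre, sample_rate=sr))
    return trials


# ---------------------------------------------------------------------------
# probability time-courses
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityTimecourse:
    """Per-subject probability of a reference state on the 16.7 ms grid."""

    times: np.ndarray                  # bin left edges, s relative to onset
    per_subject: np.ndarray            # (n_subjects, n_bins)
    subject_ids: list = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        return self.per_subject.std(axis=0, ddof=1) / np.sqrt(self.n_subjects)

    @property
    def n_subjects(self) -> int:
        return self.per_subject.shape[0]


def _trial_indicator(trial: Trial, reference: str) -> np.ndarray:
    if reference == "congruent":
        return (trial.states == trial.congruent_state).astype(float)
    if reference == "switched":
        return (trial.states != trial.onset_state).astype(float)
    if reference == "mismatched_flicker":
        valid = trial.states != STATE_NONE
        return np.where(valid, trial.states != trial.congruent_state, 0.0)
    raise ValueError(f"unknown reference {reference!r}")


def congruent_probability_timecourse(trials: Sequence[Trial],
                                     reference: str = "congruent"
                                     ) -> ProbabilityTimecourse:
    """Fraction of trials in the reference state per bin, per subject.

    ``reference`` selects the scored state: 'congruent' (state agrees with
    the cue frequency; left button for visual-only periods), 'switched'
    (state differs from the onset state), or 'mismatched_flicker'.  Trials
    with an undefined (no-press) onset state are excluded.  The group curve
    is the unweighted mean over subjects.
    """
    usable = [t for t in trials if t.onset_state != STATE_NONE]
    if not usable:
        raise ValueError("no usable trials (all onsets undefined)")
    sr = usable[0].sample_rate
    n_bins = usable[0].states.size
    subject_ids = sorted({t.subject_id for t in usable})
    per_subject = []
    kept = []
    for sid in subject_ids:
        own = [t for t in usable if t.subject_id == sid]
        if not own:
            logger.warning("subject %s has zero usable trials; excluded", sid)
            continue
        per_subject.append(np.mean([_trial_indicator(t, reference) for t in own],
                                   axis=0))
        kept.append(sid)
    times = EPOCH_START + np.arange(n_bins) / sr
    return ProbabilityTimecourse(times=times, per_subject=np.array(per_subject),
                                 subject_ids=kept)


# ---------------------------------------------------------------------------
# per-bin six-condition statistics
# ---------------------------------------------------------------------------

def rm_anova_f(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical one-way repeated-measures F over axis 0 (conditions).

    ``data`` has shape (n_conditions, n_subjects, ...); subjects are the
    blocking factor.  Returns (F, p) with trailing shape.  Uses the
    univariate decomposition SS_total = SS_cond + SS_subj + SS_error without
    sphericity correction.  Bins with zero condition variance get F = 0,
    p = 1.
    """
    c, s = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    cond_mean = data.mean(axis=1)
    subj_mean = data.mean(axis=0)
    ss_cond = s * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = c * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.clip(ss_tot - ss_cond - ss_subj, 0.0, None)
    df1, df2 = c - 1, (c - 1) * (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    # zero condition variance (up to float error) -> F = 0, p = 1
    degenerate = ss_cond <= 1e-12 * np.maximum(ss_tot, 1e-300)
    f = np.where(degenerate, 0.0, f)
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0),
                                            df1, df2), 0.0)
    p = np.where(f == 0.0, 1.0, p)
    return f, p


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    pvals = np.asarray(pvals, float)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def per_bin_condition_test(timecourses: Mapping[str, np.ndarray],
                           baseline: str = "visual_only_attend",
                           q: float = 0.05) -> pd.DataFrame:
    """Per-bin RM-ANOVA over the six conditions plus planned comparisons.

    ``timecourses`` maps condition label -> (n_subjects, n_bins) per-subject
    probabilities, with identical subject sets (within-subject design).
    Returns a frame with per-bin F, p, BH-FDR mask, and for every non-baseline
    condition a paired-t planned comparison against the visual-only baseline,
    BH-corrected across bins.
    """
    labels = list(timecourses)
    shapes = {timecourses[k].shape for k in labels}
    if len(shapes) != 1:
        raise ValueError("all conditions must share the same subjects and bins")
    data = np.stack([timecourses[k] for k in labels])
    f, p = rm_anova_f(data)
    out = pd.DataFrame({"bin": np.arange(f.size), "F": f, "p": p,
                        "fdr_significant": bh_fdr(p, q)})
    base = timecourses[baseline]
    for k in labels:
        if k == baseline:
            continue
        t, pt = stats.ttest_rel(timecourses[k], base, axis=0)
        pt = np.where(np.isnan(pt), 1.0, pt)
        out[f"t_{k}"] = t
        out[f"sig_{k}"] = bh_fdr(pt, q)
    return out


# ---------------------------------------------------------------------------
# perceptual switch index and attention index
# ---------------------------------------------------------------------------

def compute_psi(timecourses: Mapping[str, np.ndarray], times: np.ndarray,
                target: str = "attended_low",
                window: tuple = (1.0, 4.0),
                others: Sequence[str] | None = None) -> np.ndarray:
    """Per-subject perceptual switch index.

    PSI = mean over the (half-open) window of (P_target - mean of P_others).
    The canonical windows are 1-4 s for the congruent-probability index and
    2-4 s for the mismatched/matched switch indices.
    """
    if window[1] <= window[0]:
        raise ValueError("empty PSI window")
    if others is None:
        others = [k for k in timecourses if k != target]
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise ValueError("PSI window does not overlap the epoch")
    p_target = timecourses[target][:, mask]
    p_others = np.mean([timecourses[k][:, mask] for k in others], axis=0)
    return (p_target - p_others).mean(axis=1)


def attention_index(reported: Sequence[float], actual: Sequence[float]) -> float:
    """Pearson correlation between reported and actual per-block tallies.

    Returns NaN (an explicit undefined flag, never silently 0) when either
    series has zero variance.
    """
    reported = np.asarray(reported, float)
    actual = np.asarray(actual, float)
    if reported.shape != actual.shape:
        raise ValueError("reported and actual tallies differ in length")
    if reported.std() == 0 or actual.std() == 0:
        return np.nan
    return float(np.corrcoef(reported, actual)[0, 1])


# ---------------------------------------------------------------------------
# first switches and CDFs
# ---------------------------------------------------------------------------

def first_switch_times(trials: Sequence[Trial]) -> np.ndarray:
    """First-switch times (s) for every trial with a defined onset state;
    censored trials yield NaN."""
    return np.array([t.first_switch_time for t in trials
                     if t.onset_state != STATE_NONE])


def switch_cdf(times_by_subject: Sequence[np.ndarray],
               grid: np.ndarray) -> np.ndarray:
    """Per-subject cumulative proportion of trials switched by each grid time.

    Censored trials (NaN) stay in the denominator but contribute to no bin,
    so every CDF is bounded by the subject's switch fraction.
    """
    out = np.zeros((len(times_by_subject), grid.size))
    for i, times in enumerate(times_by_subject):
        times = np.asarray(times, float)
        n = times.size
        if n == 0:
            raise ValueError("subject with zero trials in switch_cdf")
        valid = times[~np.isnan(times)]
        out[i] = np.searchsorted(np.sort(valid), grid, side="right") / n
    return out


def cdf_difference_test(cdf_a: np.ndarray, cdf_b: np.ndarray,
                        q: float = 0.05) -> pd.DataFrame:
    """Paired t per bin between two per-subject CDF matrices, BH-corrected."""
    t, p = stats.ttest_rel(cdf_a, cdf_b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"bin": np.arange(t.size), "t": t, "p": p,
                         "fdr_significant": bh_fdr(p, q)})


def default_grid(sr: int = 60, horizon: float = EPOCH_STOP) -> np.ndarray:
    """0-7 s bin left edges at 16.7 ms."""
    return np.arange(int(round(horizon * sr))) / sr
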