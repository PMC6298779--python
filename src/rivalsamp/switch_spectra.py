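"""Spectral analysis of cue-locked first-switch timing.

The proportion of first switches per 16.7 ms bin is computed per subject,
averaged (unweighted) across subjects, and the 0.5-2 s post-onset segment of
the group curve is Fourier-analyzed with a single Slepian (DPSS) taper of
time-bandwidth product 1 (half bandwidth 1/1.5 ~ 0.67 Hz on the 1.5 s
window).  Inference uses a two-stage surrogate procedure:

1. per-frequency thresholds: switch times are redrawn uniformly on the 60 Hz
   grid inside the analysis window, per subject and count-preserving; a bin
   is flagged when the observed amplitude exceeds the top (1 - p_first)
   fraction of the surrogate amplitudes at that frequency;
2. cluster correction: runs of >= 2 contiguous flagged bins are kept and the
   sum of their amplitudes compared against the per-surrogate distribution
   of the maximum amplitude (excluding 0-1 Hz and its nearest neighbour)
   plus that maximum's largest neighbour.

Frequencies at or below 1 Hz and the next bin up are excluded from
inference so the DC/onset-transient leakage cannot form clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import windows

logger = logging.getLogger(__name__)

SAMPLE_RATE = 60
ANALYSIS_WINDOW = (0.5, 2.0)   # s after cue onset, half-open


@dataclass
class SwitchTimecourse:
    """Group proportion of first switches per 16.7 ms bin."""

    times: np.ndarray              # bin left edges, s after onset
    per_subject: np.ndarray        # (n_subjects, n_bins)

    @property
    def mean(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)


@dataclass
class AmplitudeSpectrum:
    freqs: np.ndarray              # Hz, spacing 1/window-length
    amps: np.ndarray               # 2/N-normalized DFT amplitudes
    window: tuple = ANALYSIS_WINDOW
    taper: str = "dpss NW=1"


@dataclass
class SurrogateNull:
    """Count-preserving surrogate distribution for the switch spectrum."""

    freqs: np.ndarray
    amps: np.ndarray               # (n_surrogates, n_freqs)
    max_cluster_stats: np.ndarray  # (n_surrogates,)
    n_surrogates: int
    seed: int
    switch_counts: np.ndarray      # per-subject in-window counts


@dataclass
class ClusterResult:
    member_bins: np.ndarray        # indices into the frequency grid
    member_freqs: np.ndarray       # Hz
    statistic: float               # sum of member amplitudes
    p_cluster: float
    significant: bool
    critical_value: float          # 95th percentile of the null
    n_surrogates: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"member_bins": self.member_bins.tolist(),
                "member_freqs": self.member_freqs.tolist(),
                "statistic": self.statistic, "p_cluster": self.p_cluster,
                "significant": bool(self.significant),
                "critical_value": self.critical_value,
                "n_surrogates": self.n_surrogates, "seed": self.seed}


# ---------------------------------------------------------------------------
# time-course and spectrum
# ---------------------------------------------------------------------------

def switch_timecourse(times_by_subject: Sequence[np.ndarray],
                      grid: np.ndarray | None = None,
                      sr: int = SAMPLE_RATE) -> SwitchTimecourse:
    """Per-subject proportion of first switches per bin, then group mean.

    Each subject's histogram is normalized by that subject's trial count
    (censored NaN trials included in the denominator), so the per-subject
    curve sums to the subject's switch fraction.  Subjects with zero trials
    are excluded with a warning.
    """
    if grid is None:
        grid = np.arange(int(round(7.0 * sr))) / sr
    n_bins = grid.size
    rows = []
    for i, times in enumerate(times_by_subject):
        times = np.asarray(times, float)
        if times.size == 0:
            logger.warning("subject %d has zero trials; excluded from "
                           "switch time-course", i)
            continue
        valid = times[~np.isnan(times)]
        idx = np.rint(valid * sr).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        rows.append(np.bincount(idx, minlength=n_bins) / times.size)
    if not rows:
        raise ValueError("no subjects with trials")
    return SwitchTimecourse(times=grid, per_subject=np.array(rows))


def _window_slice(times: np.ndarray, window: tuple, sr: int) -> slice:
    i0 = int(round(window[0] * sr))
    i1 = int(round(window[1] * sr))
    if i0 < 0 or i1 > times.size + int(round(times[0] * sr)) + times.size:
        raise ValueError("analysis window outside the epoch")
    return slice(i0, i1)


def single_taper(n: int) -> np.ndarray:
    """Single DPSS taper, time-bandwidth product 1."""
    return windows.dpss(n, NW=1)


def amplitude_spectrum(tc: SwitchTimecourse | np.ndarray,
                       window: tuple = ANALYSIS_WINDOW,
                       sr: int = SAMPLE_RATE) -> AmplitudeSpectrum:
    """Single-taper amplitude spectrum of the group curve on the window.

    The half-open window [0.5, 2.0) s holds exactly 90 samples at 60 Hz,
    giving a frequency grid with 1/1.5 Hz spacing up to the 30 Hz Nyquist.
    Amplitudes carry the conventional 2/N normalization (it cancels between
    observed data and surrogates).
    """
    if isinstance(tc, SwitchTimecourse):
        series = tc.mean
        if window[0] < tc.times[0] or window[1] > tc.times[-1] + 1.0 / sr:
            raise ValueError("analysis window outside the time-course")
        i0 = int(round((window[0] - tc.times[0]) * sr))
    else:
        series = np.asarray(tc, float)
        i0 = int(round(window[0] * sr))
    n = int(round((window[1] - window[0]) * sr))
    if i0 < 0 or i0 + n > series.size:
        raise ValueError("analysis window outside the epoch")
    x = series[i0:i0 + n] * single_taper(n)
    amps = 2.0 / n * np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, window=window)


def excluded_low_bins(freqs: np.ndarray) -> np.ndarray:
    """Mask of bins excluded from inference: f <= 1 Hz plus the next bin."""
    mask = freqs <= 1.0
    edge = np.nonzero(mask)[0]
    if edge.size and edge[-1] + 1 < freqs.size:
        mask = mask.copy()
        mask[edge[-1] + 1] = True
    return mask


# ---------------------------------------------------------------------------
# surrogate null
# ---------------------------------------------------------------------------

def _max_cluster_stats(amps: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Per-surrogate max amplitude + its largest neighbour, on allowed bins.

    The allowed bins form one contiguous run (everything above the excluded
    low-frequency edge), so neighbours are adjacent columns.
    """
    a = amps[:, allowed]
    j = np.argmax(a, axis=1)
    peak = np.take_along_axis(a, j[:, None], axis=1)[:, 0]
    left = np.take_along_axis(a, np.maximum(j - 1, 0)[:, None], axis=1)[:, 0]
    right = np.take_along_axis(a, np.minimum(j + 1, a.shape[1] - 1)[:, None],
                               axis=1)[:, 0]
    left = np.where(j == 0, -np.inf, left)
    right = np.where(j == a.shape[1] - 1, -np.inf, right)
    nb = np.maximum(left, right)
    nb = np.where(np.isfinite(nb), nb, 0.0)
    return peak + nb


def surrogate_null(times_by_subject: Sequence[np.ndarray],
                   n_trials_by_subject: Sequence[int] | None = None,
                   n_surrogates: int = 5000, seed: int = 0,
                   window: tuple = ANALYSIS_WINDOW,
                   sr: int = SAMPLE_RATE) -> SurrogateNull:
    """Count-preserving surrogate spectra of the first-switch time-course.

    Every switch falling inside the analysis window is redrawn uniformly on
    the 60 Hz grid within the window, per subject (the per-subject in-window
    switch count is preserved by construction); the group curve and its
    single-taper spectrum are recomputed for each surrogate.
    """
    if n_surrogates < 100:
        logger.warning("n_surrogates=%d < 100: tail quantiles of the "
                       "surrogate null will be unstable", n_surrogates)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_trials_by_subject is None:
        n_trials_by_subject = [np.asarray(t).size for t in times_by_subject]
    n_subj = len(times_by_subject)
    n_win = int(round((window[1] - window[0]) * sr))

    # weight of one switch in the group curve: 1/(subject trials * n_subjects)
    weights, counts = [], []
    for times, n_tr in zip(times_by_subject, n_trials_by_subject):
        times = np.asarray(times, float)
        c = int(np.sum((times >= window[0]) & (times < window[1])))
        counts.append(c)
        weights.extend([1.0 / (n_tr * n_subj)] * c)
    weights = np.asarray(weights)
    n_switch = weights.size

    taper = single_taper(n_win)
    freqs = np.fft.rfftfreq(n_win, 1.0 / sr)
    if n_switch == 0:
        amps = np.zeros((n_surrogates, freqs.size))
    else:
        bins = rng.integers(0, n_win, size=(n_surrogates, n_switch))
        flat = (np.arange(n_surrogates)[:, None] * n_win + bins).ravel()
        series = np.bincount(flat, weights=np.tile(weights, n_surrogates),
                             minlength=n_surrogates * n_win)
        series = series.reshape(n_surrogates, n_win)
        amps = 2.0 / n_win * np.abs(np.fft.rfft(series * taper, axis=1))
    allowed = ~excluded_low_bins(freqs)
    stats_ = _max_cluster_stats(amps, allowed)
    return SurrogateNull(freqs=freqs, amps=amps, max_cluster_stats=stats_,
                         n_surrogates=n_surrogates, seed=seed,
                         switch_counts=np.asarray(counts))


# ---------------------------------------------------------------------------
# two-stage frequency-cluster test
# ---------------------------------------------------------------------------

def frequency_cluster_test(observed: AmplitudeSpectrum, null: SurrogateNull,
                           p_first: float = 0.005,
                           p_cluster: float = 0.05) -> list[ClusterResult]:
    """Two-stage surrogate / cluster permutation test on the spectrum.

    Stage 1 flags bins whose observed amplitude exceeds the per-frequency
    (1 - p_first) surrogate quantile; stage 2 keeps runs of >= 2 contiguous
    flagged bins, sums their amplitudes, and compares each sum against the
    per-surrogate max-cluster statistic.  Isolated single-bin exceedances
    form no cluster.
    """
    if observed.freqs.size != null.freqs.size or \
            not np.allclose(observed.freqs, null.freqs):
        raise ValueError("observed and null spectra use different grids")
    thresh = np.quantile(null.amps, 1.0 - p_first, axis=0)
    allowed = ~excluded_low_bins(observed.freqs)
    flags = (observed.amps > thresh) & allowed

    crit = float(np.quantile(null.max_cluster_stats, 1.0 - p_cluster))
    results = []
    i = 0
    n = flags.size
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        if j > i:  # >= 2 contiguous bins
            members = np.arange(i, j + 1)
            stat = float(observed.amps[members].sum())
            exceed = int(np.sum(null.max_cluster_stats >= stat))
            p = (1 + exceed) / (1 + null.n_surrogates)
            results.append(ClusterResult(
                member_bins=members, member_freqs=observed.freqs[members],
                statistic=stat, p_cluster=p, significant=stat > crit,
                critical_value=crit, n_surrogates=null.n_surrogates,
                seed=null.seed))
        i = j + 1
    return results


def analyze_switch_spectrum(times_by_subject: Sequence[np.ndarray],
                            n_trials_by_subject: Sequence[int] | None = None,
                            n_surrogates: int = 5000, seed: int = 0,
                            p_first: float = 0.005, p_cluster: float = 0.05,
                            window: tuple = ANALYSIS_WINDOW,
                            sr: int = SAMPLE_RATE):
    """Full first-switch spectral pipeline for one condition.

    Returns (timecourse, spectrum, surrogate null, clusters).
    """
    tc = switch_timecourse(times_by_subject, sr=sr)
    spec = amplitude_spectrum(tc, window=window, sr=sr)
    null = surrogate_null(times_by_subject, n_trials_by_subject,
                          n_surrogates=n_surrogates, seed=seed,
                          window=window, sr=sr)
    clusters = frequency_cluster_test(spec, null, p_first=p_first,
                                      p_cluster=p_cluster)
    return tc, spec, null, clusters


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum_tsv(spec: AmplitudeSpectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": spec.freqs, "amplitude": spec.amps}).to_csv(
        path, sep="\t", index=False)


def write_clusters_json(clusters: Sequence[ClusterResult],
                        path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in clusters], indent=1))
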