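# Methods

This note documents the forward model, the statistical procedures, the
defaults and the design choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

Each session has 24 three-minute blocks of continuous binocular rivalry
report (button state sampled at 60 Hz).  Per block the generator places 12
crossmodal cues — six low-frequency (4.5 Hz) and six high-frequency (20 Hz),
with the duration multiset {3×2 s, 2×3.1 s, 1×4 s} per frequency — plus
three 2.6 s visual-only (null) periods, in seed-determined random order,
separated by ISIs drawn uniformly from 7–10 s (the gap before the first cue
included).  ISI draws whose total would overrun the block are redrawn; a
configuration whose minimum total cannot fit raises a schedule-infeasible
error.  The 2.6 s null duration is taken as the design's stated "average
cue duration" even though the arithmetic mean of the duration multiset is
2.7 s; the printed value is used as-is.

One global seed expands into child streams through numpy `SeedSequence`
spawn keys (`child_rng(seed, *indices)`), so any subject, block or resample
is regenerable in isolation and every run is bit-reproducible.

## Rivalry forward model

Outside cue influence the percept alternates as a gamma renewal process
(shape 3.5, mean dominance 2.5 s — standard rivalry phenomenology).  The
simulator runs in discrete 1/60 s steps with the renewal hazard
h0(u) = pdf(u)/sf(u) tabulated over time-since-switch u.  After an
*attended low-frequency* cue onset, the hazard of the first switch becomes

    h(t) = h0(u) · g · (1 + m · cos(2π f t + φ)),   t = time since onset,

with (g, f) chosen by congruence at onset: mismatched cues promote switching
(default g = 2) at 3.5 Hz, matched cues delay it (default g = 0.5) at 8 Hz;
modulation depth m defaults to 0.9 and the phase resets to φ = 0 at onset.
The modulation disarms at the first switch or 7 s after onset, whichever
comes first.  Unattended, high-frequency and null cues never modulate.
This multiplicative-hazard mechanism is the simplest that yields cue-locked
oscillatory first-switch probability; it is a phenomenological stand-in, not
a biophysical rivalry model (no mutual inhibition or adaptation).

A vectorized companion, `sample_first_switch_times`, draws cue-locked
first-switch times directly from a (optionally modulated) constant hazard on
the 60 Hz grid; it is the generator for null-calibration cohorts, where the
baseline hazard is 0.4 s⁻¹ (the reciprocal of the 2.5 s mean dominance).
Trials with no switch by the 7 s horizon (the minimum ISI, so no epoch
overlaps the next cue) are censored.

An optional third "no-press" state (default off) can be injected after
switches so the degenerate-input paths of the behavioral module are
testable.

## Behavioral analysis

Epochs span −2 to +7 s around cue onset with the bin convention
[k/60, (k+1)/60), onset at t = 0.  Congruence at onset is defined by the
percept state at the onset sample; visual-only periods use the left-button
convention (the low-frequency/left-eye percept is arbitrarily congruent).
Trials with an undefined (no-press) onset are excluded rather than imputed,
since congruence requires an onset percept.

Probability time-courses are per-subject trial fractions per bin; group
curves are unweighted subject means.  The six-condition per-bin test is a
classical univariate repeated-measures F (condition factor, subject
blocking) without sphericity correction — the per-bin masks are
descriptive — with Benjamini–Hochberg FDR at q = 0.05 across bins, and
paired-t planned comparisons against the visual-only baseline corrected the
same way.  Bins with zero condition variance report F = 0, p = 1.

PSI is the windowed mean of (P_target − mean of the other conditions), with
window 1–4 s for the congruent-probability index and 2–4 s for the
mismatched/matched switch indices.  The attention index is the Pearson
correlation between reported and actual per-block congruent-cue tallies; it
returns an explicit NaN (never a silent 0) when either series has zero
variance.  Simulated reports mix the true tally with a uniform random tally
in proportion (1 − report_accuracy), so accuracy 1 reproduces the truth and
accuracy 0 is uninformative.

## Switch spectra and the two-stage test

The group first-switch time-course on the half-open window [0.5, 2.0) s
(exactly 90 samples) is tapered with a single discrete prolate spheroidal
sequence of time-bandwidth product 1 — matching the stated half-bandwidth
1/1.5 ≈ 0.67 Hz — and Fourier transformed; amplitudes carry a 2/N
normalization that cancels between observed and surrogate data.  The group
curve is not demeaned; instead the DC bin, every bin at or below 1 Hz, and
the next bin up are excluded from inference.

Surrogates preserve each subject's in-window switch count and redraw those
switch times uniformly on the 60 Hz grid within the window (the measurement
resolution).  Only in-window switches are redrawn: moving out-of-window
switches into the window would inflate the surrogate spectral mass relative
to the observed window and mis-calibrate the test.  Stage 1 flags bins whose
observed amplitude exceeds the per-frequency 99.5th surrogate percentile;
stage 2 keeps runs of ≥ 2 contiguous flagged bins, sums their amplitudes,
and compares the sum against the per-surrogate distribution of the maximum
amplitude (over allowed bins) plus that maximum's larger neighbour.  The
composition of this null statistic is ambiguous in the source description
("maximum spectral amplitude … and nearest neighbor"); the
one-bin-plus-one-neighbour reading mirrors the minimum two-bin observed
cluster and is the default here.  Default counts are 5000 surrogates,
p_first = 0.005, p_cluster = 0.05.

## EEG generation and ITPC

Synthetic epochs span −2..+2 s at 250 Hz.  Each trial/electrode is a sum of
cosines (default 3.5 and 8 Hz, 1 µV) on 1/f noise; post-onset phases are von
Mises with concentration κ (per frequency and electrode), pre-onset phases
uniform.  As n_trials grows the post-window ITPC approaches the von Mises
mean resultant length I₁(κ)/I₀(κ), which the tests verify at n = 500.

The preprocessing contract re-references to the channel average, detrends
each epoch linearly, applies a zero-phase Hamming-window FIR band-pass
(0.1–60 Hz; filter order bounded by a third of the epoch length, so very
short epochs are rejected) and decimates to 250 Hz.  The contract is
quantitative: 10 Hz passes with gain 1 ± 0.05 and 80 Hz is attenuated by at
least 20 dB.  With 4 s epochs the achievable high-pass transition is far
wider than 0.1 Hz; the low edge mainly removes DC/drift, which the detrend
already handles.

Phases come from a single DPSS taper (NW = 1) over the 2 s pre- or
post-onset window, so W = 1/T = 0.5 Hz and frequencies must sit on the
0.5 Hz grid (3.5 Hz is thereby resolvable from the 4.5 Hz stimulus
frequency).  ITPC is the length of the mean unit phase vector; for pure
noise its expectation is √π/(2√N), so trial counts are equalized before any
comparison: the minimum count over subjects and conditions defines N_min,
subjects above it are resampled with replacement to N_min and the ITPC
averaged over 100 resamples (a subject already at N_min contributes their
own trials unchanged).  Resampling with replacement leaves a small residual
positive bias from duplicated trials, of order (1 − ITPC²)/(2·ITPC·N); at
the study's trial counts this is below 0.01 ITPC units and inside the 0.02
equivalence band the tests enforce.  Evoked ITPC is post minus pre.

## Spatial cluster permutation

The electrode adjacency graph links sites at most 3.5 cm apart.  Standard
10-10 positions on a 9.5 cm-radius head place FT8 and C6 about 4.7 cm apart,
which would disconnect exactly the fronto-temporal pair the analysis is
meant to resolve; the montage therefore projects the 64 ActiCap-template
directions onto a 6.8 cm sphere — the largest radius at which first-order
10-10 neighbours (including FT8–C6 and P6–PO8) fall inside the 3.5 cm cut
while non-neighbours (e.g. Fp1–O2) remain far outside it.  The adjacency
graph is built once from these positions.

Stage 1 keeps electrodes with uncorrected paired-t p < 0.05 that form
connected, same-polarity groups of ≥ 2 under the graph; the observed
statistic is |Σ member t|.  The null shuffles condition labels independently
per electrode within each subject (equivalently, flips the sign of that
subject-electrode difference) — exactly as described in the source
procedure, although it breaks spatial coherence and is therefore
conservative for cluster extent — recomputes the t-map, and retains the
maximum-|t| electrode plus the largest |t| among its neighbours, 2000 times
by default.  Observed clusters larger than two electrodes are compared
against the same two-electrode null; the run log notes when this happens.
Paired (not independent) t is used throughout because both conditions come
from the same subjects.

## Brain–behavior coupling

nITPC = evoked ITPC of the attended low-frequency condition minus the mean
over the other cue conditions, averaged over the cluster region, per subject
and frequency.  "Other conditions" defaults to the non-target crossmodal
cue types; visual-only periods are excluded (they have no crossmodal onset
to phase-lock to) but the set is configurable.  Correlations are Pearson r
with two-tailed p from the t transform, df = n − 2.  In the joint synthetic
cohort a single latent per-subject effect scales both the hazard gains and
κ, which is what produces a positive nITPC–PSI correlation for the detector
to find.

## Problem sizes used in the checked runs

The suite and the acceptance script run the detectors at reduced but
honestly calibrated sizes chosen for a desktop-class machine: 200 null
cohorts with 500 surrogates each for the family-wise calibration of the
frequency-cluster test; 50 replicates of the full forward model (34
subjects, ~24 mismatched trials each from 8 attended blocks) for 3.5 and
8 Hz recovery; 16 subjects × 16 trials of full synthetic EEG for the
spatial-cluster locus recovery and 100 phase-level null cohorts at 500
permutations for its type-I rate.  Defaults in the library remain the full
values (5000 surrogates, 2000 permutations, 100 resamples).

## Known limitations

* The forward model is phenomenological: no mutual-inhibition/adaptation
  dynamics, no piecemeal texture beyond the optional third state, no
  report-latency model.  Passing recovery tests show the *detectors* work
  under the assumed generative structure, not that real rivalry obeys it.
* Synthetic EEG has stationary 1/f noise and phase-locked cosines only — no
  artifacts, no evoked amplitude changes, no spatial correlation of noise —
  so the spatial permutation test faces an easier null than real data.
* The exactly-on-grid 8 Hz injection concentrates its energy in one
  frequency bin; the ≥ 2-bin cluster rule then relies on taper mainlobe
  leakage into the neighbouring bin, which makes 8 Hz recovery harder than
  the off-grid 3.5 Hz case at equal depth.
* The two-electrode permutation null applied to larger observed clusters
  (and the per-electrode label shuffle) follow the stated procedure
  literally; both choices are conservative and are logged rather than
  altered.
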