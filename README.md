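# rivalsamp

Analyses of **rhythmic attentional sampling during binocular rivalry**, built
around a fully controllable synthetic-data generator.

During binocular rivalry, each eye views an incompatible image and conscious
perception alternates between them.  When an observer attends to a brief
auditory/tactile cue amplitude-modulated at the flicker frequency of one of
the images, the timing of the *first perceptual switch* after cue onset can
become rhythmic: roughly 8 Hz when the cue matches the dominant image, and
roughly 3.5 Hz when it mismatches, consistent with focused versus divided
attentional sampling.  `rivalsamp` implements, end to end and with tests, the
statistical machinery used to detect such rhythms in dense-sampled behavior
(60 Hz button state) and in cue-locked EEG — exercised against a forward
model with known ground truth, so every detector can be checked for
calibration and recovery.

## What is implemented

**Synthetic study generator** (`rivalsamp.synthgen`) — 3-minute blocks with
12 crossmodal cues (six low-, six high-frequency; durations 3×2 s, 2×3.1 s,
1×4 s) plus three 2.6 s visual-only periods, ISIs jittered uniformly in
7–10 s; rivalry reports as a gamma-renewal process (shape 3.5, mean
dominance 2.5 s) whose first-switch hazard after an attended low-frequency
cue is multiplicatively modulated,

```
h(t) = h0(u) · g · (1 + m · cos(2π f t + φ)),
```

with gain `g` and frequency `f` selected by cue–percept congruence at onset;
per-block tally reports with controllable accuracy; a 64-channel 10-10
montage; and cue-locked EEG epochs (−2..+2 s at 250 Hz) whose oscillatory
components have von Mises-distributed post-onset phases (concentration κ)
on a 1/f noise floor.

**Behavioral analysis** (`rivalsamp.behavior`) — cue-locked epoching and
congruence labels, probability time-courses on the 16.7 ms grid, per-bin
six-condition repeated-measures ANOVA with Benjamini–Hochberg FDR and
planned comparisons against the visual-only baseline, the perceptual switch
index (PSI = windowed probability difference, attended-low vs the other cue
types), the attention-on-task index (Pearson r between reported and actual
congruent-cue tallies), first-switch times with censoring, and CDF
difference tests.

**Switch spectra** (`rivalsamp.switch_spectra`) — the group first-switch
time-course on 0.5–2.0 s after onset (90 samples), a single-Slepian-taper
(time-bandwidth 1) amplitude spectrum on the 1/1.5 Hz grid, and a two-stage
test: per-frequency thresholds from count-preserving surrogates (switch
times redrawn uniformly within the window per subject; first-stage
p < 0.005), then clusters of ≥ 2 contiguous supra-threshold bins compared
against the per-surrogate maximum-plus-neighbour null (cluster p < 0.05).

**EEG ITPC** (`rivalsamp.eeg_itpc`) — preprocessing contract (average
reference, linear detrend, 0.1–60 Hz zero-phase FIR, 250 Hz), single-taper
phase estimation on 2 s windows (half-bandwidth W = 0.5 Hz), inter-trial
phase coherence

```
ITPC(t, f) = | (1/N) Σ_n exp(i θ(t, f, n)) |,
```

trial-count equalization by resampling with replacement to the cohort
minimum (×100) to cancel the √π/(2√N) small-sample bias, evoked ITPC
(post − pre window), per-electrode paired t-maps, and a spatial cluster
permutation test on the ≤ 3.5 cm electrode adjacency graph (2000 label
permutations, maximum-electrode-plus-neighbour null).

**Brain–behavior coupling** (`rivalsamp.brain_behavior`) — normalized ITPC
(nITPC = evoked ITPC of the target condition minus the mean of the other cue
conditions, averaged over a cluster region) correlated with PSI across
subjects (Pearson r, df = n − 2).

**Pipeline + CLI** (`rivalsamp.pipeline`, `python -m rivalsamp`) — a
YAML-configured, seed-deterministic run of all stages with TSV/JSON outputs
and a manifest; subcommands `simulate`, `behavior`, `spectra`, `itpc`,
`correlate`, `all`.

## Worked example

Detect an injected 3.5 Hz switch rhythm in a synthetic cohort of 34 subjects
with 24 cue-locked trials each:

```python
import numpy as np
import rivalsamp as rs

rng = np.random.default_rng(0)
times = [rs.sample_first_switch_times(24, 0.8, rng, depth=0.9, freq=3.5)
         for _ in range(34)]
tc, spec, null, clusters = rs.analyze_switch_spectrum(
    times, n_surrogates=1000, seed=0)
for c in clusters:
    print(f"cluster {np.round(c.member_freqs, 2)} Hz  "
          f"statistic={c.statistic:.4f}  p_cluster={c.p_cluster:.4f}  "
          f"significant={c.significant}")

print("ITPC of phases {0, pi/2}:", round(rs.itpc(np.array([0.0, np.pi/2])), 5))
```

Output:

```
cluster [3.33 4.  ] Hz  statistic=0.0056  p_cluster=0.0010  significant=True
ITPC of phases {0, pi/2}: 0.70711
```

The significant cluster brackets the injected 3.5 Hz frequency on the
1/1.5 Hz grid (bins 3.33 and 4.0 Hz); its statistic is the summed spectral
amplitude of the member bins and `p_cluster` its permutation p-value against
1000 count-preserving surrogates.  The ITPC of two phases 90° apart is
|1 + i|/2 = √2/2 ≈ 0.70711.

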