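# Methods

`salieeg` re-implements, as a tested pipeline over a synthetic-data
generator, an EEG analysis of the competition between top-down attention
(to a rhythmic tone stream) and bottom-up attention (to salient events in
an ignored natural soundscape). This note documents the model behind the
generator, the analysis procedures, the numerical choices, and what the
desk-scale studies in the test suite do and do not demonstrate.

## The simulated study

Subjects attend a 440 Hz tone stream presented at 2.6 Hz (300 ms tones)
and count rare amplitude-modulated targets (64 Hz AM, 3–5 per scene, at
least 1.5 s from any salient event), while a natural scene plays in the
background. Background salience is represented by a behavioral salience
curve per scene; peaks in its smoothed derivative define salient events,
whose *strength* is `0.5·z(slope) + 0.5·z(peak in the 4 s window after
the event)` and whose tertiles define high/mid/low tiers (counts equal to
within one). The default configuration mirrors the full study: 20 scenes
× 120 s, 12 subjects, 128 channels, 351 events (117 per tier).

### Generator components

Per subject and scene the EEG (channels × samples, µV) is the sum of:

- **1/f noise** (default exponent 1, 5 µV RMS per channel) plus a 60 Hz
  line component (2 µV, random phase per channel).
- **Steady-state response (SSR):** a 2.6 Hz sinusoid (1 µV in the
  central/frontal groups, ×0.3 elsewhere) with one *stimulus-locked*
  phase for the whole experiment. Because tone onsets sit on the rate
  grid, every six-tone segment then starts at the same phase and
  concatenated segments stay coherent; a per-scene random phase would
  destroy exactly the coherence the tone-locking statistic measures.
  Optional per-scene phase jitter is available (`ssr_phase_jitter`).
  The SSR amplitude is multiplied by `ssr_target_gain` (default 1.3) for
  the six tones starting at a target and by `ssr_event_gain[tier]`
  (defaults 0.6/0.8/1.0) for the six tones starting at the tone nearest
  an event. The low tier defaults to 1.0, mirroring the observation that
  the weakest events produce no measurable suppression.
- **High gamma:** 70–110 Hz band-limited noise (3.5 µV RMS in-group)
  whose power receives a dB offset (`gamma_target_gain` +3 dB;
  `gamma_event_gain` −3/−1.5/0 dB) in the window 0.5–3.5 s after the
  onset. The burst covers the full +1.5 to +3.5 s measurement window;
  a shorter burst would make the injected dB offset unrecoverable by
  construction.
- **Envelope-following response (EFR):** the scene envelope (≤4 Hz,
  z-scored), delayed by 100 ms, added at 1 µV; its gain is multiplied by
  `efr_gain_high` for 1.5 s after each high-tier event.
- **Artifacts (optional):** bad channels (broadband 10× noise) and eye
  blinks — 0.4 s squared-Hann transients coupled mainly into frontal
  channels, with a dedicated virtual EOG channel so automated removal is
  testable.

Scene envelopes, salience curves, and the five acoustic-feature tracks
(loudness, brightness, harmonicity, pitch, scale, plus 440 Hz ERB-band
energy) are smooth seeded noise processes; feature values at events are
drawn from the background distribution (Bhattacharyya overlap → 1 as the
event count grows) unless `event_feature_shift` is set.

Every stream is keyed on `(seed, stream-id, scene, subject)`, so outputs
are bit-reproducible and independent across streams.

### What the generator does not emulate

Real auditory scenes, cochlear processing, realistic head geometry and
volume conduction, non-stationary noise, subject-specific anatomy, or
correlated artifacts. Passing recovery tests therefore demonstrates that
the *analysis code* recovers effects of known size under realistic noise
and geometry — not that the effects exist in any real recording.

## Preprocessing

Demean/detrend → 0.5 Hz 3rd-order Butterworth high-pass (zero-phase) →
resample to 256 Hz → 59–61 Hz zero-phase notch (a narrow band-stop, used
in place of a multi-taper line-regression tool; it sits safely below the
70–110 Hz analysis band). Channels whose 20–40 Hz band energy exceeds the
across-channel mean by 2.5 SD are rejected — once per subject, pooling
band energies over scenes, so all scenes keep one montage. Data are then
re-referenced to the common average, and the EOG channel is regressed out
of every EEG channel (an automated stand-in for manual ICA component
rejection; blinks couple linearly, so regression removes ≥80% of blink
variance while changing the 2.6 Hz statistic by <5%, both tested).

Epochs are ±5 s around targets, the tone nearest each event, and random
control tones. The control exclusion half-width is configurable (default
5 s = the full epoch; the pipeline uses 3.6 s, which still keeps every
analysis window — six-tone segments and both gamma windows — clear of
targets and events, because at realistic event densities a fully clear
±5 s epoch almost never exists). Epoch rejection uses an amplitude
joint-probability criterion per condition pool: per channel, each epoch's
mean negative log-probability under the pooled amplitude histogram is
z-scored *leave-one-out* across epochs (with self-inclusive scoring an
outlier among n epochs can never exceed (n−1)/√n SD, so a 6 SD local
threshold would be unreachable at desk scale); thresholds are 6 SD local
(single channel) and 2 SD global (channel average). Pools smaller than 8
epochs skip rejection.

## Tone locking

Six-tone (2.3077 s, 591 samples at 256 Hz) segments are cut before and
after each onset, concatenated across trials per condition, zero-padded
to a fixed 260-window length (so all conditions share one frequency
grid), and Fourier transformed. The statistic is the energy at the 2.6 Hz
bin divided by the mean energy between 2.55 and 2.65 Hz (excluding that
bin); the change is post minus pre, computed per electrode of the
central∪frontal union, then averaged. No taper is applied.

Two numerical properties matter. The ratio is invariant to amplitude
scaling, so amplitude changes are detectable only through the noise floor
in the normalization band: the concatenation must be long enough that its
spectral main lobe (width ≈ fs/N) is narrower than the ±0.05 Hz band,
which at 256 Hz requires ≳20 segments per pool. This motivates the
dense-event desk preset below. Second, group statistics are computed
across subjects (n = 12, paired t on per-subject changes); per-electrode
values remain available but electrodes within a subject are not treated
as independent samples.

## High gamma

The change statistic is 10·log₁₀ of trial-averaged 70–110 Hz power in the
2 s window [+1.5, +3.5] s over that in [−2.5, −0.5] s (Hann taper), per
electrode, averaged over the group union; the spectrogram normalization
(divide by the across-window mean per frequency/electrode after trial
averaging, then dB) cancels in this difference, making it scale
invariant. Sensor spectrograms use 2 s windows at 200 ms steps. Behavior
splits group epochs by scene-level signed error (detected − actual
targets), with an absolute-error variant.

Because the pre-window reaches 2.5 s back and bursts extend 3.5 s
forward, any other onset 1–6 s before an analyzed tone leaks its burst
into that tone's baseline window. Unbiased dB recovery therefore needs
sparse events (the gamma desk preset spaces events ≥15 s and targets
≥6 s from events); dense sessions still *detect* the effects but
over/under-estimate the dB offsets.

## Envelope decoding

The scene envelope is the Hilbert magnitude of the audio, low-passed at
8 Hz (4th-order Butterworth), resampled to the EEG rate and z-scored.
(The reversed order — low-pass before Hilbert — is available as an
option, but for any carrier above 8 Hz it removes the signal before an
envelope can be formed, so the conventional order is the default.) EEG is
band-passed 2–8 Hz and expanded with 0–250 ms lags (65 taps at 256 Hz;
the pipeline decodes at 64 Hz → 17 taps, a desk-scale choice). The
decoder is the closed-form ridge solution W = (XᵀX + λI)⁻¹XᵀY with
λ = 2²⁰, trained leave-one-scene-out by accumulating the normal equations
once and subtracting the held-out scene. Accuracy is the Pearson
correlation in a 1 s sliding window (step one sample); each event
contributes the window just before ([−1, 0] s) and just after ([0, +1] s)
its time. Pairs are averaged across subjects before the paired t-test —
all subjects share each scene's envelope and events, so subject×event
pairs are strongly correlated and pooling them would be anticonservative
(simulated null false-positive rates near 40%).

## Source imaging and network overlap

sLORETA: J = Lᵀ(LLᵀ + αI)⁻¹v with each source standardized by the square
root of the corresponding diagonal of the resolution operator
Lᵀ(LLᵀ+αI)⁻¹L; α defaults to trace(LLᵀ)/n_channels × 10⁻². On noiseless
single-source data the standardized power peaks exactly at the true
source (tested for every source of a 32×200 synthetic leadfield). Source
gamma is 70–110 Hz power in 500 ms windows at 200 ms steps, z-scored
across windows per voxel and trial. Voxels not uniquely active versus
control (paired t across matched trials, p < 0.005, Bonferroni over
voxels per lag) are zeroed.

Sparse CCA follows the penalized-matrix-decomposition family: alternating
power iterations on the cross-covariance with non-negative
soft-thresholding (threshold = penalty × the largest weight magnitude,
which vectorizes across permutations; increasing the penalty never
increases the support) and L2 normalization; within-set covariances are
treated as identity during the maximization, and the reported q is the
Pearson correlation of the projections. Penalties are chosen by
permutation: rows of one matrix are permuted (identity excluded), each
penalty's observed q is z-scored against its permutation distribution,
and the best-z penalty is selected. Significance accounts for that
selection with a max-over-penalties permutation null (each permutation is
reduced to its own maximum z), giving p = (1 + #{max-z ≥ observed}) /
(1 + n_perm) — positive and conservative by construction; the naive
selected-penalty p-value was measurably anticonservative. The lag grid
evaluates every (τ_S, τ_T) pair (default 0–2 s, 200 ms source-step grid)
with 200 permutations per cell (resolution 1/201 < 0.005); the region
center is the q-weighted centroid of significant cells, robust when q
saturates over a plateau.

The network-overlap recovery studies run on generator-produced
subject×voxel activation maps with a planted shared voxel set whose
bottom-up time course leads the top-down one by 0.5 s — emulating the
post-localization stage directly; the EEG→sLORETA→source-gamma chain is
validated separately.

## Salience prediction

Tones starting 1–2.5 s before an event are labeled *before*, 1–2.5 s
after an event *after*; tones qualifying for both are dropped. Features
per tone and subject: 2.6 Hz energy in a 5 s centered window normalized
by the 2.5–2.7 Hz neighborhood (the window is zero-padded ×8 because at
0.2 Hz native resolution that neighborhood contains no other bin), and
mean 70–110 Hz energy in a 2 s window — each averaged over the
central∪frontal electrodes, giving 2 × n_subjects features. The
classifier is a small feed-forward network (hidden layers 16 → 8, ReLU,
softmax readout, lbfgs) under 10-fold cross-validation grouped by event,
so a tone pair never straddles the train/test split; AUCs are averaged
per fold (pooled AUC also reported). The noise floor retrains on
event-level label shuffles. Interaction information
I(F1,F2;S) − I(F1;S) − I(F2;S) is the plug-in estimate in bits on
8-quantile bins (exact when a finite joint distribution is supplied);
positive values mean the gamma and tone-locking features carry synergistic
information about event proximity.

## Behavior and statistics

Simulated subjects detect each target with probability 0.754 (the easy
task's accuracy) at 250–650 ms latency plus occasional false alarms.
Scoring matches each target to at most one response 200–800 ms after
onset (earliest wins); signed error = reported − actual count. Targets
are grouped near-event (0.25–1.25 s post) versus far (>4 s after every
event, including targets preceding all events). The statistics toolkit
wraps paired/two-sample t, one-way ANOVA with Tukey HSD, and the JZS
Bayes factor (Cauchy prior, scale 0.707; BF₁₀ < 1/3 flagged as null
support), cross-checked in the tests against a numerical-integration
oracle.

## Desk-scale study designs

The recovery studies in `tests/test_acceptance.py` use 20 seeded
sessions per question with a pass threshold of 18 (90%), and null
calibrations allow at most 3 significant results in 20 runs (the 95%
binomial bound for a 5%-rate event) or 10 in 100 datasets for the sparse
CCA null. Problem sizes per study:

- **Tone locking:** 5 scenes × 120 s, 12 subjects, 8 channels, 105
  events (35/tier) — dense, because the statistic needs ≥~20 segments
  per pool (see above). Gamma/EFR components off (they do not enter the
  statistic).
- **Gamma:** 6 scenes × 60 s, 12 subjects, 8 channels, 12 events ≥15 s
  apart, targets ≥6 s from events — sparse, for unbiased dB recovery.
- **Decoding:** 10 scenes × 60 s, 4 subjects, 54 events (18/tier), EFR
  1.5 µV with post-high-event gain 2.5 — the 1 s sliding correlation is
  an intrinsically noisy per-event measure, and these settings give the
  event-level paired contrast adequate power.
- **Network overlap:** 12 subjects × 60 voxels, 10 shared, amplitude 4×
  voxel noise, 9×9 lag grid, 200 permutations per cell.
- **End-to-end pipeline** (and `scripts/acceptance.py`): 6 scenes × 40 s,
  12 subjects, 16 channels, 24 events — a compromise exercising every
  stage in a few minutes; its per-tier gamma estimates carry the
  burst-spillover bias discussed above, which the report shows alongside
  the injected values.

## Known limitations

- The tone-locking ratio is resolution-limited: with few segments it
  saturates on its own spectral leakage and loses amplitude sensitivity;
  condition pools should hold ≥20 segments.
- Burst spillover between nearby onsets biases gamma dB estimates at
  high event density (an inherent property of the fixed analysis
  windows, not of this implementation).
- The sparse CCA treats within-set covariances as identity (standard for
  p ≫ n); its q equals the full canonical correlation only for whitened
  inputs.
- Stage outputs are not cached between runs; desk-scale reruns are cheap
  and a content-addressed cache was judged not worth its complexity.
- Blink removal by EOG regression assumes linear coupling and a
  reasonably clean EOG; it is not a general ICA replacement.
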