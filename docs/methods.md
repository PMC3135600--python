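# Methods

`vicfreeze` re-implements, as a tested library, the computational chain of a
rat vicarious-fear ("empathy") paradigm: detecting 22-kHz alarm
vocalizations in cage audio, synthesizing playback stimuli from them,
scoring freezing/locomotion/zone behavior on the experiment's bin
schedules, and running the split-plot statistics that relate the groups.
Real recordings and scored videos are not distributed with the paradigm,
so every pipeline stage is exercised against synthetic data with known
ground truth; this note records the models, the defaults, and what the
synthetic route does and does not establish.

## Call detection

Audio is 16-bit PCM WAV at 96 kHz. The detection substrate is a short-time
FFT power spectrogram with a 256-sample window, 75% overlap (hop 64
samples, 0.667 ms) and a Hann taper (configurable; a rectangular window is
also available), with
frequencies outside 15–30 kHz discarded (41 retained bins at 375 Hz
spacing, both edges inclusive). Frame times are window centers; all
intervals downstream are half-open `[start, end)` seconds.

Frames are classified call vs. noise by the spread of their power spectrum
across the retained bins: a constant-frequency call concentrates power in
two or three bins, broadband cage noise spreads it over all 41. Three
numerical scales for that spread were evaluated:

* **dB-scale SD** — the SD across bins of the dB spectrum. For white-noise
  frames this statistic sits near 5.4 dB with ~1 dB spread (the log of
  exponential periodogram noise has large dispersion of its own), while a
  20-dB-SNR call frame reaches only ~10 dB: the two distributions overlap
  in the tails and hundreds of noise frames per minute cross any
  threshold. Kept as an option (`sd_scale="db"`), not the default.
* **linear SD** — separates calls from stationary noise by orders of
  magnitude but scales with frame power, so a loud *flat* transient (cage
  clatter) is indistinguishable from a call.
* **coefficient of variation** (default, `sd_scale="linear_cv"`) — the SD
  of linear bin powers divided by the frame's mean power. Scale-invariant:
  flat frames sit near the CV of exponential noise (~1) at any loudness,
  tonal frames near the concentration bound (~√(n_bins/k) ≈ 4). This is
  the spread statistic used everywhere below.

The classification threshold is chosen by Otsu's method on the frame-CV
distribution, with a valley guard: the Otsu split is accepted only if the
histogram density at the threshold is below 5% of the peak density.
Without the guard a call-free recording (unimodal CV distribution) would
be bisected through its mode and roughly half its frames flagged; with it,
call-free audio yields zero detections. Within a flat criterion plateau
(an empty valley) the threshold is placed at the plateau center.
Alternatives: a fixed threshold, or median + k·MAD (k = 4 default), both
recorded in the result's provenance.

Noise frames are then silenced — their contribution to the summed-power
envelope is set to exactly zero rather than to unit power (0 dB): only
under the zero convention does the subsequent nonzero-run rule define
call segments at all.
Per-frame power is summed across the band and smoothed with a centered,
edge-truncated 100-frame moving average (≈66.67 ms at the default hop).
Maximal runs of strictly positive smoothed envelope are calls; runs
shorter than `min_call_duration` (10 ms default; 0 restores the literal
rule) are dropped. Consequences of the smoothing, accepted as faithful
behavior: call onsets move ~33 ms earlier and durations grow by one
smoothing span (~67 ms), and two calls separated by less than the span
fuse into one. Calls are attributed to an analysis bin by onset.

## Playback stimuli

The stimulus track is the recording band-passed to 17–25 kHz with a
linear-phase FIR filter (1025 taps, ≥40 dB stop-band, applied with
centered convolution so group delay is zero and call timing is
untouched). The control track pitches every component down 35 semitones
(factor 2^(−35/12) ≈ 0.1326), moving 20–30 kHz content into the 2.6–4.0
kHz range. (Note an arithmetic tension in the paradigm's constants: the 17–25 kHz
*filter* band maps to ≈2.25–3.31 kHz, while the 2.6–4 kHz target range
corresponds to a 20–30 kHz source band; the package implements the stated
filter band and shift and verifies the mapping on the 20 and 30 kHz
edges.)

The pitch shift is a phase vocoder that rebins magnitudes in the frequency
domain at an unchanged time base: per 512-sample frame (hop 128), each
analysis bin's magnitude is routed to the bin nearest `factor ×` its
*instantaneous* frequency (estimated from heterodyned phase increments),
output phase is accumulated from the magnitude-weighted scaled
instantaneous frequency, plus the structural cross-bin phase ramp
`(ω_j − ω_component)(N−1)/2` that a windowed tone requires for coherent
overlap-add. Two properties drove this design over the usual
stretch-then-resample vocoder: routing by instantaneous frequency keeps a
component whose mainlobe straddles a target-bin boundary in a single
output bin (index-based rounding splits it into two half-components that
beat, ~80% amplitude modulation at 22 kHz); and the fixed time base bounds
transient smear by one analysis window (~5 ms), whereas resampling a
stretched signal smears onsets by `window/factor` ≈ 160 ms. Measured on
pure tones, output peaks land within ~3 Hz of `f × 2^(−35/12)`; envelope
events of USV and control tracks coincide within one 50-ms envelope
window and their envelopes correlate at ≥0.99. With
`preserve_envelope=True` (default) the control track is rescaled to the
stimulus track's overall RMS.

## Behavioral scoring

Freezing arrives as per-animal bout intervals (video scoring is upstream).
The 40-min witness/demonstrator session is scored over 14 minutes in six
bins: 2 minutes before the first shock onset, then one bin per shock
trial. Inter-shock gaps are 2 or 3 minutes; the five post-shock bins must
form the multiset {2, 2, 2, 3, 3} min, and the length of the bin after the
fifth shock — not fixed by the session itself — is defined as the value
completing that multiset, so the schedule always totals 840 s. Percent
freezing per bin is interval overlap over bin length; a bout straddling a
boundary contributes its overlap to each side. The shock-period summary is
the unweighted mean of the five post-shock bins. The pre-exposure test
scores the last 3 minutes of a 5-minute session. Locomotion is consumed as
per-5-min-bin distances with percent change referenced to bin 1 (0 by
definition). Position tracks use x measured from the divider; the window
zone is `[0, 12.5)` cm of the 25-cm compartment, the boundary sample
belonging to the far zone.

## Statistics

The central test is the classical two-way mixed (split-plot) ANOVA — group
between subjects, time bin within — computed from cell means: the group
effect is tested against subjects-within-group, time and group×time
against the within-subject residual. With equal group sizes this is the
exact classical decomposition (total SS additive to 1e−8; verified against
an independent projection-based least-squares oracle and against
`pingouin`); with unequal sizes (the emulated design has n = 11–15 per
group) effect SS use unweighted cell means with the harmonic mean group
size (unweighted-means analysis) and the result is flagged `balanced=False`.
No sphericity correction is applied, and no REML machinery is involved —
the design is fully crossed and complete, with listwise deletion of
incomplete animals only behind an explicit flag. Planned comparisons are
ordinary pooled-variance (unpaired) and paired t-tests; Bonferroni
adjustment takes the family size m as an explicit input. Associations are
Pearson correlations with the t-based p-value. The proportion of pairs
emitting any call is compared between shock groups by a two-sample t-test
on the binary emit indicator.

## Synthetic data

**Audio.** White (optionally pink) background noise at −40 dB RMS re full
scale, plus Poisson cage-clatter transients (default 2/min, 5–45 ms, flat
spectrum, 6–12 dB above background — rejected by the CV statistic by
construction) and constant-frequency calls: 22 kHz ± 300 Hz jitter,
lognormal durations (median 0.8 s, σ = 0.35, literature-typical for
22-kHz alarm calls, and configurable), 5-ms cosine ramps, placed uniformly at random with a
minimum gap. Call amplitude is set from the per-call SNR against the
background power inside the 15–30 kHz analysis band. Frequency-modulated
sweeps are deliberately absent — the 22-kHz repertoire is near constant
frequency, and the band logic of the detector is the object under test.

**Cohorts.** Per-animal, per-bin freezing percentages are truncated
normals around group targets with SD = SEM·√n. The pre-exposure generator
defaults to group parameters of 36.6 ± 5.2% (experienced) vs
1.2 ± 0.7% (naive), the paradigm's reference effect size. The six-bin
test defaults encode the qualitative structure of the paradigm's expected results —
witness controls flat-low, shock witnesses elevated only with prior shock
experience, demonstrators escalating over trials — with magnitudes chosen
once as realistic for the paradigm (no
numeric reference values exist for them). Each animal's percentages are realized as actual bout
intervals (≥1-s bouts, random non-overlapping placement, exact to ≤0.5
percentage points per bin), so the scoring code runs on the same data type
it would see in production. Pair call counts follow a negative binomial
(per-group mean/size chosen to give realistic overdispersion and
non-emitting pairs) coupled to demonstrator shock-period freezing through
a Gaussian copula at ρ = 0.6; freezing is standardized within group so the
copula preserves the count marginals. All randomness flows through one
seeded generator; every artifact records its seed.

Passing tests on this synthetic route establish that the algorithms
recover known structure under the stated noise models. They do not
establish performance on real cage audio (reverberation, overlapping
vocalizations, nonstationary noise) or real scoring (observer error,
bout-boundary ambiguity), and no claim about animal behavior follows from
them.

## Problem sizes and tolerances

The closed-loop detector check uses a 600-s recording with 100 injected
calls at 20 dB SNR (exact count recovery); recall/precision are measured
on 200-s fixtures of 40 calls per SNR level with onset matching within
0.2 s. ANOVA oracle agreement is required to 1e−6 relative F on 20 random
balanced designs (observed ~1e−13). Replicate counts for generator
recovery are 200 (pre-exposure significance, coupling correlation).
Spectrograms of long recordings are computed in 65,536-frame chunks to
bound peak memory. Degenerate inputs: zero-variance ANOVA cells flag the
result rather than raising; zero-variance t-tests return a degenerate
flag; zero-variance correlations raise.

## Known limitations

* The detector cannot attribute calls to an individual animal (single
  microphone), and 50-kHz call types are out of scope.
* Smoothing-induced call fusion below ~67 ms gaps is inherent to the
  algorithm; a pre-smoothing segmentation mode exists for comparison via
  `min_call_duration=0` with `smoothing_frames=1`.
* The unweighted-means path for unbalanced designs is an approximation to
  a full Type-III analysis; for the mild imbalance of this design the
  difference is negligible, and the flag makes the path auditable.
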