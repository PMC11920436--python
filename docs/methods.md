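# Methods

This note documents the models, algorithms and numerical choices behind
`clsleep`, in the spirit of a methods section: what is simulated, how
the closed loop works, what the statistics compute, and what the
synthetic benchmarks do and do not establish about real data.

## Synthetic sleep EEG

**Slow oscillations.** A planted SO is one biphasic cycle: a
raised-cosine negative half-wave (trough) followed by a raised-cosine
positive half-wave (peak), each lasting half a period. Trough and peak
amplitudes are independently scalable, matching the trough/peak
decomposition used by the detectors. Defaults: trough −110…−80 µV,
trough-to-peak 150…200 µV, frequency 0.8–1.3 Hz. These ranges keep every
planted event well inside the offline detector's acceptance windows with
margin for noise: at 0.8–1.3 Hz each half-wave lasts 0.38–0.63 s, safely
inside the 0.3–1.5 s (negative) and 0.1–1 s (positive) duration
criteria even when background noise perturbs the zero crossings. SOs can
be planted in back-to-back trains (`so_train_length`), emulating the
quasi-rhythmic recurrence of SOs in deep NREM; `placement="regular"`
places events on a jittered grid rather than a Poisson process, which
equalizes event counts between stimulation intervals.

**Spindles.** Hann-windowed sinusoids at 11–16 Hz, default duration
0.8–2 s and envelope amplitude 25–40 µV. The lower duration bound is
deliberately above the detector's 0.3-s minimum because a Hann envelope
concentrates the oscillation in the middle of the nominal duration: a
0.5-s Hann burst has a supra-threshold core shorter than 0.3 s and is
not a detectable spindle under the stated criteria.

**Background.** Gaussian noise with power ∝ 1/f^1.6 above a 1-Hz knee
(flat below), broadband SD 15 µV, independent across channels; planted
events are shared across channels with fronto-central gain weighting.
The source protocol does not report background noise levels, so these
defaults are the package's own and were chosen to satisfy two
constraints that pull in opposite directions: (i) the background's
relative sigma power (8–18 Hz over 1–30 Hz) must sit below the spindle
detector's 0.2 threshold — a pure 1/f spectrum fails this, with a ratio
of 0.24, so noise alone would be "spindle-like"; (ii) slow-band
(0.3–2 Hz) noise must be small enough that zero-crossing jitter does not
push compliant SOs outside the positive-half-wave duration window —
which rules out steep exponents without a knee. The 1-Hz knee mirrors
the low-frequency flattening of real aperiodic EEG spectra. With these
defaults the planted-event benchmarks hold: SO and spindle recall
≥ 95% with ≤ 0.05 false positives/min at an event-amplitude-to-noise
ratio of ≥ 5, and noise-only recordings yield zero events.

**Auditory cues.** Three 100-ms sounds with 10-ms linear ramps: a
harmonic complex at f0 = 543 Hz with 11 harmonics of linearly
*decreasing* amplitude (1 → 0.1), white noise band-passed 100–1000 Hz,
and a complex at f0 = 1480 Hz with linearly *increasing* harmonic
amplitudes (0.1 → 1).

**Behavior.** Per-keypress SRTT tables. Within the pre-night session,
block-mean RT decays exponentially from ~420 ms to a per-subject,
per-condition plateau near 300 ms; the post-night session starts at the
plateau scaled by the planted overnight gain. Gains are
`mean + subject intercept + condition noise` with defaults
(up, down, not) = (8, 2, 7)% — up ≈ not > down, the ordering the method
is designed to resolve — subject SD 5%, condition SD 2%, keypress jitter
SD 30 ms, error rate 5%.

## The closed loop

The loop consumes the detection channel (Fpz) at 500 Hz. Detection
operates on a causal 50-sample moving-average trace; a *down* event arms
when the trace first drops below the sex-specific trough threshold
(−41 µV F / −39.5 µV M; the male value is taken as negative by symmetry
— troughs are negative), and an *up* event arms when, after a
qualifying trough, the running peak-to-peak amplitude reaches the
sex-specific threshold (77 / 74 µV) *and* the trace is positive. The
positivity requirement prevents a monophasic negative deflection from
counting its return to baseline as an up-state.

**Phase estimation (ecHT).** On a sliding 2-s causal buffer, the
analytic signal is formed from the one-sided FFT spectrum and a causal
2nd-order Butterworth band-pass (0.1–4.5 Hz) is applied in the frequency
domain; the endpoint sample's angle is the phase estimate (0° = rising
zero crossing, 90° = peak, 270° = trough). Because the filter is causal,
its edge distortion lands at the buffer's start, not at the endpoint.
Two numerical refinements: the filter's *steady-state* phase response at
the endpoint's instantaneous frequency (median phase increment over the
last 100 ms, clipped to the pass-band) is subtracted, and that
compensation is scaled by a convergence weight — the analytic amplitude
one period ago relative to now — because during an oscillation's onset
the filter has not yet built up its steady-state lag and the raw
endpoint phase is already accurate. On sustained oscillations the
estimate is within ~1° of truth; on isolated one-cycle transients the
first cycle carries a lead of up to ~25°, an inherent limit of causal
estimation on broadband transients.

**Firing, lockout, gating, balancing.** Within an up (down) interval the
cue fires when the ecHT phase crosses 90° (270°) after arming; if the
estimate is already within 45° past the target at arming (possible under
noise plus the moving-average delay), the cue fires immediately rather
than skipping the oscillation. After each cue the loop locks out until
the next positive-to-negative zero crossing of the moving-average trace.
Intervals alternate up/down (3 min) with 1-min rests, scheduled in wall
time from the first N2/N3 epoch; cue delivery is suppressed outside
N2/N3 (the experimenter's manual gating is modeled at 30-s epoch
granularity). Each cue is validated online on a delay-compensated causal
FIR trace (order 500, 0.1–4.5 Hz): the cue's SO cycle — bounded by
positive-to-negative zero crossings — must contain a trough ≤ −40 µV
followed by a peak giving PTP ≥ 75 µV; cues in the filter's edge
transient are indeterminate and counted invalid. Validation results
settle before the next interval decision, where a down interval is
silenced iff validated down cues outnumber validated up cues (a
silenced down interval yields the 1 + 3 + 1 = 5-min no-stimulation
span). The session ends 3 h after the first cue. The balancing rule can
only throttle the *down* side, so the two-sided count-imbalance bound is
guaranteed under conditions where down-detection propensity is at least
that of up-detection — with regularly recurring planted SOs the bound
holds comfortably.

The simulation is event-driven over causally filtered traces rather
than a literal per-sample loop, which is deterministic-equivalent and
keeps hour-long nights under a few seconds; causality is preserved
(truncating the recording reproduces the cue prefix exactly), and the
per-sample reference state machine (`SOCandidateDetector`) is tested
for equivalence against an offline scan of the same trace.

## Offline validation and sham cues

Offline phase is the non-causal reference: zero-phase FIR band-pass
0.1–4.5 Hz plus Hilbert analytic signal. A cue is *accurate* iff it lies
within a true SO (trough ≤ −41 µV F / −39.5 µV M, PTP ≥ 77 / 74 µV on
the filtered trace) and within the 180° half-plane around its
condition's target: up gets [0°, 180°], down gets (180°, 360°). The
half-plane boundary assignment is not specified by the protocol; it is
assigned to the up window here and is configurable. Each non-stimulated
SO receives one up-sham and one down-sham time at a phase drawn with
replacement from the corresponding true-positive phase list, converted
to a time by linear interpolation of the SO's own unwrapped analytic
phase within its cycle (the unique unwrapped branch starting a quarter
cycle before the trough's phase value), which reproduces the drawn
phase to a fraction of a degree.

## Event detection

The SO detector band-passes 0.3–2 Hz (linear-phase FIR with 0.2-Hz
transition width, applied centered so events are not shifted), picks
negative peaks in [−200, −40] µV and positive peaks in [10, 150] µV,
pairs each negative peak with the next positive peak before the
subsequent negative peak, and applies the five logical thresholds
(negative half-wave 0.3–1.5 s, positive half-wave 0.1–1 s, negative
magnitude 40–300 µV, positive 10–200 µV, PTP 75–500 µV). The two
amplitude clauses are kept as a literal two-stage procedure (picking
windows, then logical thresholds); their intersection makes the
effective negative-peak magnitude range 40–200 µV. A post-hoc audit
function independently re-checks every returned event.

The spindle detector computes, per channel: relative sigma power
(8–18 Hz over 1–30 Hz) from a short-time Fourier transform with 2-s
Hann windows every 200 ms; the moving RMS of the sigma-filtered signal
in 300-ms windows every 100 ms, thresholded at its recording-wide
mean + 1.5 SD; and the Pearson moving correlation between the broadband
(1–30 Hz) and sigma-filtered signals on the same 300-ms grid,
thresholded at 0.65. Samples passing all three form candidate runs;
each run is shrunk by half the RMS window on each side (the
moving-window tracks smear boundaries by exactly that much), and events
outside 0.3–3 s are discarded. Detections on different channels with
onsets within 500 ms are merged transitively (one physiological spindle)
into a single event spanning the earliest onset to the latest offset.
RMS baseline statistics are computed per channel over the whole
recording (whether the original procedure used per-interval baselines
is unstated; per-recording is adopted).

## ERP and time–frequency analysis

Analyses run on 0.1–30 Hz zero-phase band-passed data polyphase-resampled
to 100 Hz. Trough-locked epochs span [−2, 2] s (401 samples), cue-locked
[−2.5, 2] s; epochs touching the recording edge or a rejected-mask
sample are dropped and counted. Power uses a Hann taper with an
adaptive five-cycle window (Δt = 5/f) on a 5–30 Hz grid every 20 ms,
computed per epoch and then averaged (induced + evoked), scaled as
one-sided spectral density so that integrating over the grid
approximates band power (verified to 5% against a Welch estimate).
Baseline normalization is relative change (P − B)/B with B the mean
power over [−2.5, −2] s for cue-locked data or the whole epoch for
trough-locked data; the trough-locked baseline is taken on the
epoch-averaged power (per-average rather than per-epoch — the original
is ambiguous). The time grid is common across frequencies (restricted
to centers valid for the longest, 1-s, window), so statistics windows
such as [−1.5, 1.5] s contain finite values everywhere.

## Cluster-based permutation statistics

For two paired conditions (subject × channel × [frequency ×] time), a
pointwise paired t statistic is thresholded two-sided at the
cluster-forming alpha 0.01; suprathreshold samples are clustered by
flood-fill over temporal, spectral and montage adjacency (default
neighbor graph over {Fz, Cz, Pz, Oz, C3, C4}; positive and negative
clusters separate; no minimum-neighbor constraint), and cluster mass is
the sum of t values. The null is built by randomly sign-flipping each
subject's condition difference (the standard within-subject relabeling
for paired designs; epoch-level exchange is the alternative reading and
is not implemented), taking the maximum cluster mass per permutation
(500 by default), and p = (r + 1)/(n + 1). Cohen's d for a cluster is
mean/SD of the subject-level mean differences within the cluster.
Bonferroni across the three condition contrasts (α = 0.05/3) is exposed
as a constant. Type-I calibration on null simulations lands in the
[0.02, 0.09] band, and the implementation is cross-checked against an
independent cluster-permutation implementation (MNE) and, on a
two-subject toy, against exhaustive enumeration of all sign
assignments.

## Behavioral statistics

Per block, performance is the median RT of correct, non-outlier presses
(Tukey fences at 1.5×IQR per subject × session × condition, computed
over correct trials only; no fence constant is stated in the protocol so
the conventional 1.5 is used) and accuracy the percent of correct
presses. Offline change per condition is
`100·(pre − post)/pre` with `pre` the mean of the three pre-night test
block medians and `post` the mean of the first three post-night block
medians — positive means faster after sleep. Medians-of-blocks are
averaged (pooling all trials is the unstated alternative). The TMR
index is the reactivated minus the not-reactivated condition's change.
The one-way repeated-measures ANOVA computes the standard
sums-of-squares F with df (k−1, (k−1)(n−1)), Greenhouse–Geisser epsilon
from the double-centered covariance (corrected p reported alongside the
uncorrected one), partial η², and all pairwise paired t tests with
Benjamini–Hochberg FDR and paired Cohen's d. Identical condition columns
return F = 0, p = 1 rather than 0/0. The power benchmark plants the
condition effect in the repeated-measures power-analysis convention
(Cohen f on the total within-cell SD with correlation 0.5 among
repeated measures — the convention of the G*Power-style calculation used
to size such studies), i.e. total within-cell SD 6.8% with half the
variance shared across conditions, which gives partial η² ≈ 0.13 and
analytic power ≈ 99% at n = 28.

## Problem sizes

The test suite and the acceptance script run hour-long, single-channel
nights at 500 Hz for the closed-loop and detector benchmarks, 20-minute
multichannel recordings for offline validation, 150–500 Monte-Carlo
replicates for the estimator-recovery and calibration checks, and
28-subject behavioral datasets — sizes at which every benchmarked
property is stable across seeds.

## What passing these benchmarks does not show

The generator omits EMG/ocular/cardiac artifacts, REM microstructure,
scalp topography beyond fixed channel gains, non-stationary stage
transitions within epochs, and any coupling between spindles and SO
phase. Detector recall and closed-loop accuracy on this synthetic data
are therefore upper bounds on real-data performance; conversely the
causal-phase lead on isolated transients is a real phenomenon that any
online system shares. The behavioral generator plants gains directly at
the session level, so the recovery benchmarks validate the estimator
arithmetic and the statistics, not any theory of consolidation.
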