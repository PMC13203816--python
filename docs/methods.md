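# Methods

## Detection model

The detector treats a single detrended EEG channel as a time series whose
*trend changes* carry the information. Two causal moving averages run over
the stream: a fast window of `L_f` samples and a slow window of
`L_s > L_f` samples (defaults drawn from {50, 100, 150} x {100, 150, 200}
at 300 Hz, i.e. 0.17–0.67 s). Both are ring buffers with maintained
running sums, so each sample costs O(1) and the filter adds no latency
once filled. The difference `d = MA_fast − MA_slow` behaves like a
band-pass of the trend: a sustained downward slope `m` drives it toward
`m (L_s − L_f) / (2 f_s)`, while oscillations faster than the windows are
attenuated by the Dirichlet-kernel response of each average.

A **cross event** is emitted on the sample where the sign of `d` changes
relative to the last non-zero sign. Exact ties (`d = 0`) emit nothing and
carry the previous sign forward, so constant signals never fire and a tie
during a crossing collapses to a single event. Crossing comparisons are
exact (no epsilon): tie handling already covers equality, and the running
sums are re-anchored by full recomputation every 10^5 samples to bound
drift (verified to 1e-9 against per-sample recomputation in tests).

Per trial, the buffers start filling at preparation onset (relative time
0) and the sign state is tracked continuously from the moment the slow
buffer fills — it is *not* reset when the detection window opens at 2 s.
Crosses before the window opening are ignored but update the sign state;
this is what makes the kind of the first in-window cross depend on the
relative position of the two averages at opening. The first in-window
cross accepted by the strategy (blue = under only, red = over only,
gold = either) is the trial's detection; the window is closed at both
ends, and an optional opening delay (0.25 s was used clinically for one
slow-reacting participant) shifts only the start. The slow buffer must
fill before the window opens; with the largest default window
(200 samples = 0.67 s) and the 2 s preparation this always holds.

## Preprocessing

GO trials are epoched `[-6, +5]` s around preparation onset
(nearest-sample anchoring). The baseline is the last 6 s of the rest
period (`[-6, 0)`); an ordinary least-squares line over the baseline is
extrapolated across the whole epoch and subtracted, removing slow drift
without filtering — the real-time path is deliberately unfiltered, so
alpha/low-beta content reaches the detector. Zero-phase Butterworth
band-passes (0.5–5 Hz for MRCP review, 8–13 Hz for alpha) exist only on
the offline review path. ERD courses are sliding-window band power
(default 0.5 s rectangular windows, 50% overlap, windows overlapping the
outer 0.25 s of the epoch dropped as filter-transient guard), expressed
as percent change against the mean baseline-window power; halving an
oscillation's amplitude reads as −75%.

Ankle movement onset is the first time at or after the GO cue where the
centered-difference angular velocity exceeds 5 deg/s continuously for
100 ms (both configurable). The criterion is deliberately simple; against
generator ground truth it is 10–20 ms late (the velocity needs a few
milliseconds to clear the threshold), well inside the 50 ms recovery
budget. A back-extrapolation refinement was evaluated and rejected: under
band-limited angle noise it walks through noise-positive velocity runs
and inflates the error tail.

## Evaluation

A detection is a true positive when its latency relative to movement
onset lies in the closed interval [−400, +100] ms, a false positive
otherwise, and a trial without detection is a false negative; only GO
trials are scored (movement is confirmed on each), so true negatives are
undefined. TPR and FPR share the GO-trial denominator with FN counted
separately, so TPR + FPR + FN-rate = 100% exactly per participant — the
one self-consistent convention compatible with the published
per-participant tables. The latency comparison carries a 1e-6 ms epsilon
so grid-exact boundary latencies classify as the closed interval demands.
Cohort aggregates are unweighted means over participants, percentages
printed to one decimal (half away from zero), and the signed mean
detection lead — mean over participants of (mean detection − mean onset)
— truncated toward zero to integer milliseconds; feeding the four
published participant rows through this arithmetic yields 85.9% mean TPR,
14.1% mean FPR, and a −182 ms mean lead.

Grid optimization evaluates every valid (fast, slow) pair times strategy
(6 x 3 = 18 entries at the defaults) and selects the highest TPR, with
deterministic tie-breaks: lower FPR, smaller slow window, smaller fast
window, then blue < red < gold. An all-tie input therefore selects
(50, 100, blue).

## Synthetic sessions

The generator emulates the cued GO/NO-GO ankle-dorsiflexion paradigm on
one shared timebase: trials of 8 s rest, 2 s preparation, 3 s cue, 1.2 s
feedback; NO-GO drawn per trial at probability 0.25; GO trials continue
until the requested count. Reaction times are truncated normal
(0.45 ± 0.10 s within [0.15, 1.5] s; per-participant means can be set to
published values to mimic a cohort). Each GO trial anchors three
components to its movement onset:

* **MRCP template** — zero until 1.5 s before movement; linear ramp to
  −3 µV at 0.45 s before movement; linear steep ramp to the −8 µV trough
  at onset; then a *sharp reversal*: a saturating exponential (time
  constant `rebound_s/4`) to +2 µV at 0.4 s, decaying linearly to zero
  over 1 s. The reversal shape matters: with it, the noise-free
  cross-over that marks the trough lands +83 ms after onset for the
  50/100 pair (inside the target window) and +123…+320 ms for the larger
  pairs.
* **ERD** — a band-limited 8–13 Hz carrier (filtered Gaussian noise,
  RMS = 4/√2 µV) runs through the whole session; its envelope dips by
  50% from 0.8 s before movement until 1 s after, with 0.1 s cosine
  edges.
* **1/f noise** — spectrally shaped Gaussian noise, exponent 1, scaled to
  2 µV SD over the session (≈1.8 µV within a detrended epoch).

The angle trace is a smoothstep rise of 15 deg over 0.4 s at each
movement onset plus band-limited jitter (4 Hz low-passed, 0.2 deg SD) —
sensor-fusion angle output wobbles slowly; per-sample white noise would
imply physically impossible angular velocities. Everything is a pure
function of one seed.

What the generator does *not* emulate: cue-evoked potentials, trial-to-
trial MRCP amplitude/latency variability, alpha burstiness, EMG/ocular
artifacts, electrode drift, or volume conduction. Passing closed-loop
tests therefore demonstrate pipeline correctness and the detector's
geometry, not clinical-grade performance on real EEG.

## Closed-loop recovery: known limitation

Under the generator's default conditions the closed loop saturates below
the intended recovery levels, and two acceptance tests assert those
levels and stay red. The mechanism is geometric. The early MRCP ramp
plus the ERD envelope drop pin `d` negative *before* the detection window
opens for typical reaction times, so the informative steep-phase
cross-under fires inside the ignored preparation span; the one reliable
in-window event is the reversal cross-over, whose lag straddles the
+100 ms target edge for every pair but 50/100 (+83 ms noise-free, ±~30 ms
under noise); and alpha-ripple chatter just after window opening
straddles the −400 ms edge — precisely the failure mode that forced a
0.25 s window delay for the slowest-reacting participant in practice.
Measured across seeds: best-configuration TPR 57–77% at default noise and
70–80% maximum at high SNR. The acceptance script reports whatever the
current run produces; nothing is tuned toward a target.

## Numerical and interface choices

Delimited text (comma, header row, `.` decimal) is the canonical format;
EDF reading is a convenience via mne. Non-uniform sampling (>10%
deviation of any interval from the median) is rejected, not resampled.
Trials whose epoch window exceeds the recording are dropped with a
warning; a GO trial without a recoverable movement onset is excluded from
scoring with a warning. The CLI (`simulate | detect | optimize | report`)
is a thin layer over the library; all commands are deterministic given
their options and `--seed`, and log lines carry ISO timestamps plus a
hash of the effective options.
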