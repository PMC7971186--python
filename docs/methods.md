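# Methods

This note documents the models, parameter choices and numerical conventions
behind `frandr`, and what the synthetic studies do and do not establish.

## Signal model and preprocessing

Recordings are multichannel iEEG in microvolts. The analysis operates on a
**bipolar montage**: each channel is the difference of two adjacent contacts
on one depth-electrode shank, which cancels spatially extended background
and line noise — essential because HFO amplitudes are small. `to_bipolar`
emits `contact_i − contact_{i+1}` per shank in depth order; a bipolar channel
is labelled SOZ if *either* contact is inside the seizure onset zone
(clinically conservative), and inherits the region of the deeper contact
when a pair straddles a boundary (deterministic, and consistent with
depth-electrode geometry where the deeper contact sits in the target
structure). Resampling to the analysis rate (2 kHz) uses polyphase FIR
filtering with a Kaiser anti-aliasing design — no FFT-edge ringing across
long recordings. Only downsampling is supported; nothing in the pipeline
needs upsampling, and refusing it avoids silently inventing bandwidth.
Channels with known hardware problems are excluded by an explicit label
list; no automatic noise heuristic is applied (any such heuristic would
itself need validation, and exclusion decisions should be auditable).

Time is in seconds from recording start; all intervals are half-open
`[start, end)`, which makes window membership unambiguous at boundaries.

## HFO detector

Per channel and band (ripple 80–250 Hz, FR 250–500 Hz), two stages:

**Baseline segmentation.** Consecutive 1-s windows are scored by the
magnitude-squared Stockwell transform restricted to the band (frequency rows
every 5 Hz; the S-transform's Gaussian window scales inversely with
frequency, standard definition). Per time sample the Shannon entropy of the
frequency-normalised power, divided by `log n_bins`, lies in [0, 1]; columns
with zero power map to 1 (featureless ≈ baseline-like). A window is baseline
iff the **median** of its entropy track is ≥ 0.9. Two numerical notes:

* The *median* (not the minimum) is the window summary. Even for pure white
  noise the pointwise entropy minimum within a second dips to ≈ 0.74 —
  envelope statistics guarantee occasional near-deterministic columns — so a
  minimum-based rule leaves no baseline at any threshold that still rejects
  oscillations. The window median separates cleanly: ≈ 0.92–0.95 for white
  or 1/f noise, ≈ 0.77 under a sustained band-limited oscillation.
* The threshold is an *absolute* fraction (0.9) of the entropy ceiling, not
  of the recording's own maximum: a recording dominated by oscillation has a
  low maximum, and a relative rule would then classify oscillation as
  baseline.
* The entropy track is evaluated on every 4th sample (2 ms at 2 kHz) by
  alias-folding the spectrum before the inverse FFT — exact strided samples
  of the transform; the S-transform's own time resolution in these bands is
  several ms, so nothing is lost.

If total baseline falls below 5 s the channel is flagged and threshold
statistics fall back to the whole recording.

**Detection.** The band-pass filter is a linear-phase Kaiser-window FIR
(≥ 40 dB stop-band, 20 Hz transition) applied by centred FFT convolution —
exactly zero-phase, so event timestamps are unbiased. The envelope is the
magnitude of the analytic (Hilbert) signal; evaluating the duration rule on
the envelope rather than the rectified trace keeps sub-cycle zero crossings
from splitting events. The amplitude threshold is

```
threshold = mean + k · SD        (population SD, baseline envelope samples)
```

with default `k = 3.5`. Maximal envelope excursions above threshold are
merged when separated by < 10 ms, then kept if they last ≥ 20 ms (ripple) or
≥ 10 ms (FR). FRandR events are intersections of overlapping ripple and FR
intervals (≥ 1 sample; chained overlaps merge; an optional tolerance can
bridge half-open boundary contact, default 0).

*Why k = 3.5:* the choice is pinned by the detector's operating point, which
was mapped by simulation (Hann-enveloped bursts at SNR 5 over 1/f
background). For Rayleigh-distributed baseline envelopes the threshold sits
at `(1.253 + 0.655·k)·σ_band`. At `k = 3` the FR band produces ≈ 2–4 false
events/min on pure noise — pairs of short noise excursions fused by the
10 ms merge gap pass the 10 ms duration rule — an unacceptable floor next to
FRandR rates of interest (~0.07–2/min). At `k = 4`, burst sensitivity at
SNR 5 drops below 90%. `k = 3.5` yields, at the standard operating point
(20 channels × 10 min, SNR 5), sensitivity 0.97/0.94/0.94 and spurious
fractions 0.00/0.05/0.01 for ripple/FR/FRandR. Event counts are monotone
non-increasing in `k` throughout this regime (they need not be at thresholds
below the envelope bulk, where runs merge into few giant events).

The detector runs on the continuous recording — no epoching before
detection, so threshold statistics are not biased by trial selection.
Detection is deterministic; scaling a channel by any positive constant
leaves the event list unchanged (entropy is scale-free, the threshold is
linear in amplitude).

## Tasks, trials and rates

Three task schedules are modelled: verbal working memory (50 trials/session:
fixation 1 s, encoding 2 s, maintenance 3 s, probe; set size 4 = control,
6/8 = task), visual working memory (192 trials: fixation uniform 2–5 s
carried per trial, encoding 0.8 s, maintenance 0.9 s; set size 1/2 =
control, 4/6 = task), and fearful faces (17 alternating 24-s blocks, 9
landscape-control + 8 fearful-task, each preceded by a 2-s landscape
baseline that belongs to neither condition). Only correct trials enter the
rate tables (incorrect trials do not guarantee task engagement); the faces
task is passive viewing, so all its blocks count.

An event belongs to a trial iff its envelope-peak timestamp falls in the
trial's analysis window — one unambiguous timestamp per event, so no event
is double-counted and window-edge events resolve deterministically.
Rates are `count / window × 60` (events/min). Pooled channel rates
(`Σ count / Σ window`) summarise a channel's whole-task behaviour.

## Statistics

**Per-channel test**: two-sided Wilcoxon rank-sum on per-trial task vs.
control rates. Exact enumeration when the pooled sample has ≤ 20
observations without ties; otherwise the normal approximation with mid-ranks,
tie-corrected variance and continuity correction (pinned against scipy to
machine precision, and against exhaustive enumeration on small instances).
A degenerate comparison (zero variance, e.g. all-zero rates) reports p = 1.
No per-channel multiple-testing correction is applied — family-wise control
happens at the count level.

**Channel-count permutation test**: the statistic is the number of channels
significant at α = 0.05 (both directions by default; either direction alone
is available). Null: trial condition labels are permuted *jointly* for all
channels of a session — each task condition is one unbreakable unit per
trial — preserving the inter-channel correlation that makes the count
statistic over-dispersed relative to binomial; an independent per-channel
shuffle is available as a config switch for comparison. `n_perm ≥ 200` is
enforced and `p = (1 + #{null ≥ obs})/(n_perm + 1)`, so p can never be 0 and
its floor is `1/(n_perm+1)` (= 1/201 at the default). Inside the permutation
engine, observed and null counts both use the asymptotic rank-sum (the two
sides of a permutation comparison must be computed identically to be
exchangeable; with per-trial count data the exact branch would essentially
never trigger anyway). The engine is vectorised: per channel the data are
ranked once and each permutation only re-sums ranks.

**SOZ contrast**: pooled whole-task rates per channel, split by the SOZ
flag, compared by rank-sum with the channel as the statistical unit.

### Calibration

Because per-trial rates are small Poisson counts, rank-sum p-values are
discrete. At the verbal-WM window (3 s) the asymptotic test holds its
nominal size for the ripple stream (λ ≈ 0.21 events/trial → type-I rate
≈ 0.043 at α = 0.05) but is conservative for sparser streams (FR ≈ 0.033,
FRandR at 2/min ≈ 0.032) — conservatism, not inflation, so it cannot
manufacture false positives. Calibration checks are therefore evaluated on
the ripple stream. The permutation p-values are valid by construction
(exact conditional on the data) for every stream; under the null their
sub-0.05 mass stays below the binomial bound in 200-study batches.

## Synthetic studies

`gen_study` synthesises what the analysis assumes: per channel, 1/f^β
background noise (β = 1 default; spectrum shaped in the frequency domain,
unit RMS, scaled to a per-channel RMS around 50 µV) plus Poisson-timed
oscillatory bursts. Bursts are Hann-enveloped sinusoids — ripple events
140 Hz with 50 ms effective duration, FR events 350 Hz/20 ms, FRandR events
both co-centred. The `duration` of a burst is the **FWHM of its envelope**
(the Hann support is twice that): the nominal duration then matches the
length of visible oscillation, which is what the detector's duration rule
measures. Burst amplitude is `snr ×` the channel's background RMS in the
corresponding band. Default base rates are the field-typical awake-MTL
medians (ripple 4.14, FR 2.38, FRandR 0.07 events/min); power and recovery
studies raise FRandR to 2/min, since at 0.07/min a session contains too few
events for any rate statistic (hours of signal per channel would be needed).
SOZ channels (assigned per shank, matching the spatial granularity of
clinical SOZ labels) have rates multiplied by `soz_multiplier`; inside
task-condition analysis windows rates are multiplied by
`condition_multiplier` (1.0 = the null). Event times are drawn from the
corresponding piecewise-constant-intensity Poisson process and kept clear of
the recording edges.

`gen_rate_table` draws the same per-trial Poisson counts *without* waveform
synthesis — statistically a perfect-sensitivity detection of a `gen_study`
recording — and assigns SOZ per channel exactly. Calibration batches
(thousands of channels, hundreds of studies) use this path; everything that
claims to test the detector uses full waveforms.

Everything is a deterministic function of (config, seed); one generator
drives all draws, and the pipeline derives its permutation seed from the run
seed via a seed sequence.

**What the synthetic studies do not show.** The background has no spikes,
sharp transients, sleep architecture or artifacts, and bursts are clean
tones — so passing recovery tests demonstrates the detector's threshold and
duration logic, not robustness to real-world artifact morphology. Rates are
homogeneous within condition (no slow drifts), inter-channel noise is
independent (real recordings share reference noise; the joint-shuffle
permutation design matters more there than here), and effect sizes enter
only as rate multipliers, not amplitude or morphology changes.

## Known limitations

* The entropy baseline can misclassify long continuous oscillatory artifacts
  as "signal" everywhere, triggering the whole-recording threshold fallback
  (flagged per channel in the detector's quality output).
* Detected event counts at very low SNR (< ~4) degrade gracefully but are
  not calibrated; the operating point is SNR ≥ 5.
* Multi-session studies shuffle labels within each session; rate tables
  without a session column are treated as one session.
* The fixture signal format is plain text and bulky; it is meant for tests
  and synthetic studies, not archival storage of long recordings.
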