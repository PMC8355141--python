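# Methods

This note documents the models, conventions, parameter choices and known
limitations of `thetaseq`, in the order of the analysis chain.

## Data model and conventions

Time is seconds from session start. Sequence positions and iteration
indices are 0-based. Every event window is half-open, `[onset, offset)`,
so a spike exactly on a boundary belongs to the next window; this removes
all ambiguity from spike-to-event assignment. Sessions are stored as two
CSVs (events, spikes), raw little-endian float32 LFP (channel-major), and
one JSON sidecar — a deliberately plain, language-agnostic format that
round-trips bit-exactly except for the float32 quantisation of the LFP.
The LFP trace is stored as given; no re-referencing is applied or assumed.

## LFP preprocessing and spectra

Traces are polyphase-resampled to 1 kHz (the resampler's FIR low-pass is
the anti-alias filter) and notch filtered at 45–55 and 98–102 Hz with
second-order Butterworth band-stops applied forward–backward. Power
spectra use consecutive non-overlapping 2 s Hanning epochs over the whole
recording (no trial epoching; a trailing partial epoch is discarded),
giving a 0.5 Hz grid of 79 frequencies between 1 and 40 Hz. Each
channel's spectrum receives its own least-squares log–log fit of
`P(f) = c·f^(−α)`; the dB ratio `10·log₁₀(P/fit)` is averaged across
channels and tested per frequency with a two-sided one-sample t-test,
Bonferroni-corrected for the 79 frequencies. (Whether the original
procedure's t-test was one- or two-sided is not documented; two-sided is
the conservative choice.) The fit deliberately includes the oscillatory
peak regions — no peak exclusion is attempted — so on traces containing
strong oscillations the fitted exponent is biased upward (≈ +0.3 for the
generator's default theta+beta amplitudes). The exponent-recovery tests
therefore evaluate the generator/fitter pair on aperiodic traces, where
the configured α = 1.98 is recovered to within 0.05 on average.

Spike-triggered power extracts a 1 s Hanning-tapered segment centred on
each spike with full context (≥ 10 usable spikes required), averages the
per-segment power spectra, and applies the same 1/f-relative machinery.

## Phase extraction

Band-pass filtering for phase is a second-order Butterworth applied
forward–backward. Zero-phase filtering matters: any one-pass filter would
add a frequency-dependent delay and bias every spike phase, contradicting
the convention that 0° is the oscillation peak and ±180° the trough (the
angle of the analytic signal of a cosine). Spike phases are looked up at
the nearest 1 kHz sample; against a 10 kHz reference this differs by
< 3° for content up to 8 Hz.

## Circular statistics

Implemented in `thetaseq.circstats` following the standard directional
statistics literature (Fisher 1993; Zar ch. 26–27): mean direction as the
angle of the mean resultant vector; angular deviation `√(2(1−R̄))`;
Rayleigh test with the finite-n corrected p approximation;
Watson–Williams high-concentration F test with the `1 + 3/(8κ̂)`
correction and df `(k−1, N−k)`, warning when the pooled resultant falls
below 0.45; and a sign/binomial test of the circular median against a
fixed direction. All statistics operate on unit vectors and are invariant
under adding full turns (property-tested). The sliding-window display
masks time bins where the textbook confidence interval for a mean
direction does not exist (`n·R̄² ≤ χ²(0.95,1)/2`); the confidence level is
exposed as a parameter.

## Stimulus preference and reliability

Counts are taken in `[onset, onset + 2 s)` — the full stimulus + ISI
trial. The counting window is not documented in the original procedure;
the full trial is the default because anticipatory and ISI firing carry
stimulus information, and the window is a parameter for users who prefer
the 1.5 s stimulus period alone. Probe presentations are excluded from
counting (the stimulus was not shown).

Split-half consistency: halves of size ⌊n/2⌋/⌈n/2⌉ drawn at random; the
preference is the argmax of summed counts on the training half (ties
broken uniformly at random); it is confirmed on the held-out half when
the preferred stimulus's median response exceeds the median of the other
stimuli's medians. This confirmation rule makes the no-preference chance
level exactly 50% for continuous responses — a value exceeds the median
of its 5 exchangeable competitors with probability 3/6 — and exact median
ties (common for small integer counts) are scored ½ so the discrete null
stays centred on 50%. The binomial test of the confirmation count is
one-sided (greater than ½), matching the directional hypothesis. An
`exact=True` mode enumerates every half-split for small tables and is the
oracle for the randomised estimator. The default split count is 10⁵; the
pipeline exposes it because 10³ splits already estimate the proportion to
±1.6 percentage points and suffice for screening synthetic populations.

## Phase precession statistics

Only sequence iterations where the preceding, preferred and following
items occurred consecutively with no probe among them enter the triplet
analysis. Under the generator's independent 20% probe flags the expected
inclusion is `0.8³ × 60 ≈ 31` iterations per cell; published figures from
comparable paradigms are somewhat lower, which would require correlated
probe placement that is not documented — the generator models the stated
rate, nothing more.

The population summary averages per-cell circular means, weighting cells
equally rather than pooling spikes (pooling would overweight
high-rate cells; a pooled mode is available). Sign conventions: the
*consecutive phase difference* is the circular mean of the two signed
steps `μ₀−μ₋₁` and `μ₊₁−μ₀`, negative under precession; the *phase lag*
`wrap(μ_prec − μ_foll)/2` is the positive-magnitude form of the same
quantity. Per-cell lags (≥ 5 spikes at both offsets) are aggregated with
a circular median and tested against 0 with a sign test.

## Controls

* **Spike-count matching** keeps iterations where the preceding and
  following counts differ by ≤ 1 spike and recomputes the comparison.
* **Inter-trial coherence** uses 32 log-spaced frequencies (1.7–98.7 Hz)
  on a −0.5…1.5 s × 50 ms grid. The time–frequency window is 2 cycles per
  frequency; with so short a window only one taper is usable, so a single
  Hanning taper is applied (the standard low-frequency configuration of
  multitaper toolboxes). Trial counts are equalised across stimulus types
  by seeded random subsampling, as no specific method is documented.
* **Phase-reset spike removal** drops spikes within a ±100 ms window
  (configurable; no published value exists) of the theta-band ITC peak
  latency within each trial.
* **Theta-power median split** labels each spike by the theta envelope at
  spike time relative to the session median and summarises each half.
* **Spiking vs LFP frequency**: the binned spike train's 1/f-relative
  spectrum is compared with the LFP theta peak; precession predicts a
  slightly faster spiking rhythm. A peak is called "clear" above 2 dB;
  partially coupled units often stay below this, so the pipeline reports
  raw peak sizes alongside the detected subset.

## Synthetic generator

The generator exists to make the pipeline falsifiable: it produces data
with known ground truth under the study's conditions — 6 stimuli × 60
iterations, 1.5 s stimulus + 0.5 s ISI, 20% probes (independent Bernoulli
flags by default; a deterministic every-5th mode gives exact counts).

* **LFP**: spectrally shaped Gaussian noise (`f^(−α/2)` amplitude
  shaping, α = 1.98) normalised so the 1–40 Hz content has 15 µV RMS,
  plus narrow-band filtered-noise oscillations — theta 4–8 Hz at 10 µV
  RMS (fragmented into alternating high/low-power bouts, emulating the
  fragmented theta typical of primate recordings) and beta 10–18 Hz at
  6 µV RMS. These amplitudes put the band peaks ≈ +4–6 dB above the
  aperiodic fit, comparable to visible band peaks in human MTL spectra.
* **Spikes**: an inhomogeneous Poisson process drawn by thinning.
  The rate is `base × rate_by_offset × ramp × exp(κ cos(θ−μ))/I₀(κ)`,
  where θ is the analytic phase of the generated theta component, so the
  von Mises factor has unit time-average and mean rates are preserved.
  Defaults: base 0.8 Hz, multipliers 3.0 / 1.5 at the preferred /
  neighbouring items. The base rate was set so that the spike-count
  matching control retains ≈ 60% of iterations (the published retention)
  and rates stay in the typical human-MTL range; with two neighbour
  counts at mean 2.4/trial, `P(|ΔN| ≤ 1) ≈ 0.52`. The anticipatory ramp
  is a mean-preserving linear rate increase across the preceding trial
  (±50% by default; no published slope exists).
* **Phase coupling**: per-offset population mean phases 233° / 181° /
  117° at offsets −1/0/+1, with per-cell means drawn from wrapped normals
  with the across-cell SDs 35° / 16° / 9°. The within-cell concentration
  κ is a free parameter (default 2, moderate locking); no published value
  constrains it. During probe events the unit falls back to its baseline,
  uncoupled rate (no stimulus, no stimulus-locked response).

All randomness flows from one seed through named `SeedSequence`
substreams; a fixed seed reproduces sessions bit-exactly.

### What the generator does not emulate

Learning dynamics (tuning is stationary), within-theta-cycle coordination
between cells, genuine stimulus-evoked phase reset, spike-sorting noise
or multi-unit contamination, electrode heterogeneity, and non-stationary
firing rates beyond the anticipatory ramp. Passing the recovery tests
therefore shows that the pipeline measures what it claims to measure on
data satisfying its assumptions — not that real recordings satisfy them.

## Numerical choices and degenerate inputs

Ties in preference argmax go to the lowest stimulus index in the
deterministic path (flagged), and are randomised inside the split-half
resampling where determinism would bias the null. A perfectly
concentrated sample (R̄ → 1) maps to a huge κ in the Watson–Williams
correction rather than a division error; all-equal counts classify as
*weak* with a warning (the F statistic is undefined); an all-tied lag
sample flags the sign test as undefined instead of raising. ITC of a
single trial is exactly 1 by construction — the statistic is reported,
with trial counts, never interpreted alone.

## Problem sizes

Default test and acceptance runs use one 452-cell session (four LFP
channels, 720 s at 1 kHz, ≈ 12 min of simulated recording), 10³
consistency splits per cell, and 20 seeds for exponent recovery; these
sizes keep a full end-to-end run in tens of seconds while leaving the
population standard error of each recovered mean phase below 2°.
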