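# Methods

This note documents the models and procedures implemented in `sabr`, the
defaults they ship with, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Signal model

A recording is an epoch matrix `x(t, i)` in µV: `t` indexes samples at
20 000 Hz (a 10 ms pre-stimulus baseline precedes onset), `i` indexes
epochs. Epochs alternate between the two stimulus polarities (labels
0/1, balanced within one). The simulator composes four parts:

1. **Evoked template.** Each landmark (V, A, D, E, F, O) is a Gaussian
   deflection `s·a·exp(−(t−µ)²/2σ²)` with sign `s` (+1 for V, −1 for the
   troughs), amplitude `a` (µV), latency `µ` (ms) and width `2σ` (ms).
   A positive deflection of half the trough amplitude is placed 3 ms before
   each of D, E, F, O; real speech-ABRs oscillate, and this gives the
   peak-to-trough amplitude convention a well-defined reference on the
   synthetic waveform. Defaults (quiet): V 6.6 ms/0.35 µV, A 7.9/0.25,
   D 22.5/0.15, E 31.5/0.15, F 39.5/0.15, and an offset trough O at
   48 ms (40 ms CV), 53 ms (50 ms CV) or 72 ms (170 ms CV). These defaults
   are configuration, not normative claims; every test compares against the
   configured truth.
2. **FFR** (long stimulus only): a 100 Hz sinusoid of 0.15 µV spanning
   54.5–178 ms with 10 % linear tapers. The start is chosen so that an FFR
   trough falls exactly at 72 ms: peak O of the long template is literally
   an early FFR trough, and the latency ground truth stays exact.
3. **Background EEG**: Gaussian noise shaped to 30–3000 Hz with power ∝ 1/f
   (amplitude ∝ f^−1/2), per-epoch RMS `sd_uV` (default 2.5 µV). The band
   and tilt give EEG-like spectra without modelling real EEG. The default
   RMS was set from the F_SP scaling law `E[F_SP] ≈ 1 + n·Var_t[template]/σ²`
   so that a 12 000-epoch quiet recording lands in the upper single digits
   and the 3.1 criterion is crossed near 4–5 k epochs — the regime the
   method is designed for.
4. **Artifacts**: with probability `artifact_rate` an epoch receives a 5 ms
   Gaussian transient of `artifact_amp_uV` (> 20 µV, so it is rejectable);
   a stimulus-following sinusoid of `cm_artifact_uV` inverts with the
   polarity label, emulating stimulus artifact / cochlear microphonic, and
   cancels exactly in the alternating-polarity average.

The **noise background condition** is modelled as a +0.91 ms latency shift
and a ×0.70 amplitude scale applied to every template peak (0.70 = 1 −
0.12 µV / 0.40 µV typical peak-to-trough). The FFR is left unchanged:
at the +10 dB SNR the protocol models, phase locking at F0 is not
measurably degraded, and the package's paired ITPC comparison is expected
to be null on matched synthetic conditions.

The stimulus synthesizer renders CVs by additive harmonic synthesis —
harmonics of F0 (default 100 Hz) weighted by Gaussian formant envelopes
(80 Hz bandwidth, 1/k source roll-off) along linear formant transitions
over the first 50 ms, with a deterministic noise burst cross-faded over the
onset. It reproduces the features the analysis depends on (F0 periodicity,
formant energy, F2 contrast between [ba]/[da]/[ga], polarity inversion,
Hamming-ramp clipping of long CVs to 50 ms) and makes no claim to
synthesizer-grade fidelity.

## Preprocessing

Rejection drops any epoch with |x| strictly above 20 µV at any sample
(peak-to-zero, matching online-rejection semantics; exactly 20.0 µV
survives). The two polarities are averaged separately and each average is
band-passed 70–2000 Hz with a 1201-tap Hamming-window FIR applied
forward–backward (`filtfilt`): zero phase by construction, stopband
attenuation doubled, ≥ 20 dB one octave outside the passband. The
alternating average is the mean of the two filtered polarity averages,
then de-meaned. The high-pass default is 70 Hz for every stimulus and
configurable per run.

## Detection

`compute_fsp` uses sample variances (n−1 denominators) and operates on the
epoch matrix as given — no internal filtering — so the generator's band is
the analysis band in null simulations. The duration-specific windows are
5–60 ms (40 ms CV) and 8–70 ms (50/170 ms CVs) with the single point at the
window midpoint (32.5/39 ms). Presence rules: quiet ⇒ F_SP ≥ 3.1
(inclusive); noise ⇒ F_SP strictly above the subject's no-sound F_SP.

`bootstrap_bands` resamples epochs with replacement within polarity strata
and negates each drawn epoch with probability ½, then takes per-sample
quantiles of the resulting alternating averages (default 1000 resamples,
95 % level; fewer than 200 resamples is refused). Sign-flipping preserves
the noise spectrum and second moments while destroying the phase-locked
component; an exhaustive-enumeration test on a 2+2-epoch instance confirms
the resampled quantiles against the exact null. Peak detection requires
strict exceedance of a band; values exactly on a bound count as absent.
Band construction uses unfiltered epochs while peak values come from the
filtered average; the filter's passband gain is ≈ 1 where the peaks live,
so the comparison is slightly conservative (out-of-band noise widens the
bands).

## Peaks

Each landmark is assigned the extremum of the correct sign (V: positive
local maximum; troughs: negative local minima) within ±2 ms of its expected
latency, constrained to preserve the temporal order V<A<D<E<F<O; ties
resolve to the earlier sample. Corrected latency = raw − 0.8 ms (earphone
tube delay); the correction is a pure shift and never touches amplitudes.
V's amplitude is V-to-A. For D, E, F, O the reference is the *largest*
positive local maximum between the previously assigned landmark and the
trough — the prominence-based reading of "the preceding positive peak";
a nearest-maximum rule would latch onto sub-sample noise ripples on
band-limited averages. When no positive maximum precedes a trough the
amplitude is left unassigned with a flag.

Note that the zero-phase band-pass can move the extremum of *overlapping*
deflections by one or two samples even though it preserves an isolated
symmetric pulse exactly; recovery tests therefore compare picked latencies
to the extrema of the band-limited template (the picker's actual input) at
one-sample tolerance, and to the configured latencies at 0.2 ms.

## Phase locking

Phase is extracted by convolution with a complex Morlet wavelet at F0
(7 cycles, temporal σ ≈ 11 ms at 100 Hz); ITPC(t) is the modulus of the
mean unit phase vector across epochs, clipped to [0, 1] against rounding.
The FFR summary is the ITPC maximum over 70–190 ms, excluding points within
one wavelet transient (2σ_t) of the window edges; windows shorter than two
F0 cycles are refused. Fisher-Z = atanh(max), with a maximum of exactly 1
clipped just below 1 (warning issued). The quiet-vs-noise comparison is a
classical two-tailed paired t test on per-subject Fisher-Z maxima; all-zero
difference vectors return (t, p) = (0, 1) and constant non-zero differences
raise a degenerate-variance error rather than reporting an infinite t.

## Epoch-count sweep

Subsets are cumulative prefixes in acquisition order after rejection,
balanced n/2 per polarity — modelling incremental clinical recording rather
than re-randomized subsampling. The default schedule is 800 to 12 000 in
steps of 800 (15 counts); counts unsatisfiable after rejection truncate the
schedule with a warning. At each count the full preprocessing chain, F_SP,
bootstrap bands and peak picking run; the bootstrap seed is derived per
count from the sweep seed, so the whole sweep is reproducible. The two
reported minima are the first count meeting the condition-specific presence
rule, and the first count at or after it where every peak detected at the
maximum count is again bootstrap-detected; `None` marks criteria never
reached.

## Problem sizes and checks

The reproduction script (`scripts/acceptance.py`) uses 20 replicates of
2000 noise-only epochs with 1000 resamples for the band-coverage check and
12 recordings of 12 000 epochs for the no-sound F_SP ceiling; the test
suite runs the same sizes plus smaller property fixtures, and hypothesis
property tests run derandomized. Null-calibration checks treat the
"F_SP = 3.1 ⇔ 99 % confidence" mapping as approximate: the statistic's
effective degrees of freedom depend on the noise bandwidth inside the
analysis window.

## Known limitations

- The generator's noise is stationary, Gaussian and epoch-independent; real
  EEG is none of these (drowsiness drifts, myogenic bursts, line noise).
  Passing tests demonstrate correctness of the *analysis* under the stated
  model, not robustness to every real-world artifact.
- The evoked template is identical across epochs; genuine latency jitter
  between epochs (which differentially attenuates averaged high frequencies)
  is not modelled.
- The CV synthesizer is a simplified harmonic source–filter; it is adequate
  for driving the analysis and for F2-contrast bookkeeping, not for
  perceptual use.
- Group-level mixed-model analyses of latency/amplitude effects are out of
  scope; the reported fixed-effect sizes appear only as the generator's
  default condition contrast.
- Bands from unfiltered epochs are conservative for peaks measured on
  filtered averages (see Detection above).
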