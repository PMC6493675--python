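"""Synthetic consonant-vowel stimuli and simulated speech-ABR epoch matrices.

The generator provides everything the downstream analysis assumes about real
recordings without requiring any:

* a simplified harmonic source-filter rendering of consonant-vowel (CV)
  syllables with configurable fundamental (F0) and formant tracks, where the
  second formant (F2) onset is what distinguishes [ba]/[da]/[ga];
* a deterministic evoked-response template with the conventional speech-ABR
  landmarks -- positive onset peak V, troughs A, D, E, F, O -- plus an
  F0-locked frequency-following response (FFR) for long-duration stimuli;
* additive band-limited background EEG noise (Gaussian, 30-3000 Hz,
  power ~ 1/f), occasional large transients that exceed the +/-20 uV online
  rejection threshold, and a polarity-inverting stimulus-following component
  emulating stimulus artifact / cochlear microphonic;
* a "noise background" condition realized as a configurable latency increase
  and amplitude reduction applied to every peak of the template.

Everything is seeded and reproducible: identical seeds give bit-identical
epoch matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "StimulusSpec",
    "Stimulus",
    "PeakShape",
    "FfrParams",
    "ResponseTemplate",
    "NoiseModel",
    "EpochMatrix",
    "cv_spec",
    "synthesize_cv",
    "clip_stimulus",
    "make_template",
    "simulate_epochs",
    "DEFAULT_PEAKS",
    "DEFAULT_BACKGROUND_EFFECT",
    "DURATION_CLASSES",
    "PEAK_ORDER",
]

PEAK_ORDER = ("V", "A", "D", "E", "F", "O")
DURATION_CLASSES = ("short40", "short50", "long170")

#: Stimulus duration in ms per duration class.
STIMULUS_MS = {"short40": 40.0, "short50": 50.0, "long170": 170.0}

#: Default post-stimulus analysis window (ms) per duration class.
EPOCH_MS = {"short40": 75.0, "short50": 80.0, "long170": 210.0}


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a synthesized CV syllable.

    ``formant_tracks`` is a list of ``(start_hz, end_hz, transition_end_ms)``
    triples, one per formant.  Each formant sweeps linearly from ``start_hz``
    to ``end_hz`` over ``[0, transition_end_ms]`` and stays constant after.
    """

    duration_ms: float
    f0_hz: float = 100.0
    formant_tracks: tuple[tuple[float, float, float], ...] = ()
    onset_burst_ms: float = 5.0
    sample_rate_hz: float = 20_000.0
    polarity: str = "original"

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise InvalidParameterError("duration_ms must be positive")
        nyq = self.sample_rate_hz / 2.0
        if not (0 < self.f0_hz < nyq):
            raise InvalidParameterError(f"f0_hz must lie in (0, {nyq}) Hz")
        for start, end, trans in self.formant_tracks:
            if start >= nyq or end >= nyq:
                raise InvalidParameterError(
                    f"formant track ({start}, {end}) Hz reaches the Nyquist "
                    f"frequency ({nyq} Hz); lower the formant or raise the "
                    "sample rate"
                )
            if trans > self.duration_ms:
                raise InvalidParameterError(
                    "transition_end_ms must not exceed duration_ms"
                )
        if self.polarity not in ("original", "inverted"):
            raise InvalidParameterError("polarity must be 'original' or 'inverted'")


@dataclass(frozen=True)
class Stimulus:
    """A rendered stimulus waveform together with its generating spec."""

    waveform: np.ndarray
    spec: StimulusSpec

    @property
    def duration_ms(self) -> float:
        return self.spec.duration_ms

    @property
    def sample_rate_hz(self) -> float:
        return self.spec.sample_rate_hz


#: Formant tracks (start_hz, end_hz, transition_end_ms) for the three CVs.
#: F2 onset is the distinguishing feature; all other tracks are shared and
#: converge on common vowel-/a/-like targets by 50 ms.
_CV_F2_START = {"ba": 900.0, "da": 1700.0, "ga": 2480.0}
_SHARED_TRACKS = (
    (400.0, 720.0, 50.0),     # F1
    None,                     # F2, filled per CV
    (2580.0, 2500.0, 50.0),   # F3
    (3300.0, 3300.0, 50.0),   # F4
    (3750.0, 3750.0, 50.0),   # F5
    (4900.0, 4900.0, 50.0),   # F6
)


def cv_spec(
    cv: str,
    duration_ms: float = 170.0,
    *,
    f0_hz: float = 100.0,
    sample_rate_hz: float = 20_000.0,
    onset_burst_ms: float = 5.0,
    polarity: str = "original",
) -> StimulusSpec:
    """Build the spec for one of the study CVs ([ba], [da], [ga])."""
    if cv not in _CV_F2_START:
        raise InvalidParameterError(f"unknown CV {cv!r}; expected ba, da or ga")
    tracks = []
    for i, track in enumerate(_SHARED_TRACKS):
        if i == 1:
            track = (_CV_F2_START[cv], 1240.0, 50.0)
        start, end, trans = track
        tracks.append((start, end, min(trans, duration_ms)))
    return StimulusSpec(
        duration_ms=duration_ms,
        f0_hz=f0_hz,
        formant_tracks=tuple(tracks),
        onset_burst_ms=onset_burst_ms,
        sample_rate_hz=sample_rate_hz,
        polarity=polarity,
    )


def synthesize_cv(spec: StimulusSpec) -> Stimulus:
    """Render a CV waveform from its spec by additive harmonic synthesis.

    The voiced portion is a sum of harmonics of F0 whose amplitudes follow
    Gaussian formant envelopes around each (possibly sweeping) formant track,
    with a 1/k source roll-off; it is therefore exactly periodic at F0 once
    the formant transitions have ended.  The first ``onset_burst_ms`` are
    cross-faded with a deterministic aperiodic noise burst (the plosive
    release).  Peak amplitude is normalized to 1; the ``inverted`` polarity
    is the sample-wise negation of the ``original`` rendering.
    """
    fs = spec.sample_rate_hz
    n = int(spec.duration_ms * fs / 1000.0)
    t = np.arange(n) / fs
    t_ms = t * 1000.0

    nyq = fs / 2.0
    kmax = max(1, int((nyq - 1.0) // spec.f0_hz))
    k = np.arange(1, kmax + 1)
    harm_hz = k * spec.f0_hz

    # time-varying harmonic amplitudes: source roll-off plus formant humps
    bw = 80.0  # formant bandwidth (Hz)
    gains = np.full((n, kmax), 0.08)
    for start, end, trans_ms in spec.formant_tracks:
        f_track = np.where(
            t_ms < trans_ms,
            start + (end - start) * t_ms / max(trans_ms, 1e-9),
            end,
        )
        gains += np.exp(-0.5 * ((harm_hz[None, :] - f_track[:, None]) / bw) ** 2)
    gains /= k[None, :]

    x = np.sum(gains * np.sin(2.0 * np.pi * harm_hz[None, :] * t[:, None]), axis=1)

    nb = int(spec.onset_burst_ms * fs / 1000.0)
    if nb > 0:
        # deterministic aperiodic burst; fixed stream so rendering is pure
        rng = np.random.default_rng(772200)
        burst = rng.standard_normal(nb)
        burst *= np.hanning(max(nb, 2))[:nb]
        seg = x[nb : 2 * nb]
        scale = np.sqrt(np.mean(seg**2)) / max(np.sqrt(np.mean(burst**2)), 1e-12)
        fade = np.linspace(0.0, 1.0, nb)
        x[:nb] = fade * x[:nb] + (1.0 - fade) * burst * scale

    x /= np.max(np.abs(x))
    if spec.polarity == "inverted":
        x = -x
    return Stimulus(waveform=x, spec=spec)


def clip_stimulus(stim: Stimulus, keep_ms: float, ramp_ms: float) -> Stimulus:
    """Clip a stimulus to ``keep_ms`` with a falling Hamming ramp at the end.

    The first ``keep_ms - ramp_ms`` are bit-identical to the input; over the
    final ``ramp_ms`` the falling half of a Hamming window is applied, which
    ends at a gain of 0.08 (>90 % amplitude reduction).
    """
    if keep_ms > stim.duration_ms:
        raise InvalidParameterError(
            f"keep_ms={keep_ms} exceeds stimulus duration {stim.duration_ms} ms"
        )
    if ramp_ms >= keep_ms:
        raise InvalidParameterError("ramp_ms must be shorter than keep_ms")
    fs = stim.sample_rate_hz
    n_keep = int(round(keep_ms * fs / 1000.0))
    out = stim.waveform[:n_keep].copy()
    n_ramp = int(round(ramp_ms * fs / 1000.0))
    if n_ramp > 1:
        i = np.arange(n_ramp)
        out[n_keep - n_ramp :] *= 0.54 + 0.46 * np.cos(np.pi * i / (n_ramp - 1))
    tracks = tuple(
        (s, e, min(tr, keep_ms)) for (s, e, tr) in stim.spec.formant_tracks
    )
    new_spec = dataclasses.replace(
        stim.spec, duration_ms=keep_ms, formant_tracks=tracks
    )
    return Stimulus(waveform=out, spec=new_spec)


# ---------------------------------------------------------------------------
# evoked-response templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakShape:
    """One labeled deflection: a Gaussian bump of the given sign."""

    latency_ms: float
    amplitude_uV: float  # magnitude, always positive
    width_ms: float      # approximately 2 sigma of the Gaussian
    sign: int            # +1 for V, -1 for the troughs

    def __post_init__(self) -> None:
        if self.amplitude_uV <= 0 or self.width_ms <= 0:
            raise InvalidParameterError("amplitude_uV and width_ms must be > 0")
        if self.sign not in (-1, 1):
            raise InvalidParameterError("sign must be +1 or -1")


@dataclass(frozen=True)
class FfrParams:
    f0_hz: float = 100.0
    amplitude_uV: float = 0.15
    start_ms: float = 54.5
    end_ms: float = 178.0


#: Offset (ms) of the small positive deflection preceding each trough after A,
#: giving the peak-to-trough amplitude rule a well-defined reference.
_PRECEDING_POS_MS = 3.0
_PRECEDING_POS_FRAC = 0.5

DEFAULT_PEAKS: dict[str, dict[str, PeakShape]] = {
    "short40": {
        "V": PeakShape(6.6, 0.35, 1.0, +1),
        "A": PeakShape(7.9, 0.25, 1.0, -1),
        "D": PeakShape(22.5, 0.15, 2.0, -1),
        "E": PeakShape(31.5, 0.15, 2.0, -1),
        "F": PeakShape(39.5, 0.15, 2.0, -1),
        "O": PeakShape(48.0, 0.20, 2.0, -1),
    },
}
DEFAULT_PEAKS["short50"] = dict(DEFAULT_PEAKS["short40"], O=PeakShape(53.0, 0.20, 2.0, -1))
# For the long CV, O is an early FFR trough: its latency coincides with a
# trough of the default FFR (start 54.5 ms, F0 100 Hz -> troughs at 62, 72 ...).
DEFAULT_PEAKS["long170"] = dict(DEFAULT_PEAKS["short40"], O=PeakShape(72.0, 0.20, 2.0, -1))

#: Default quiet-vs-noise background effect: +0.91 ms latency shift and a
#: multiplicative amplitude scale of 0.70 (= 1 - 0.12 uV / 0.40 uV typical
#: peak-to-trough amplitude).
DEFAULT_BACKGROUND_EFFECT = (0.91, 0.70)


@dataclass(frozen=True)
class ResponseTemplate:
    """Deterministic evoked waveform description for the simulator.

    ``peak_params`` already has any background effect applied; the configured
    effect is retained in ``background_effect`` for provenance.
    """

    peak_params: Mapping[str, PeakShape]
    ffr: FfrParams | None = None
    background_effect: tuple[float, float] = DEFAULT_BACKGROUND_EFFECT
    duration_class: str = "short50"
    condition: str = "quiet"

    def __post_init__(self) -> None:
        shift, scale = self.background_effect
        if not (0.0 < scale <= 1.0):
            raise InvalidParameterError("amplitude_scale must lie in (0, 1]")
        if self.duration_class not in DURATION_CLASSES:
            raise InvalidParameterError(f"unknown duration_class {self.duration_class!r}")
        labels = [lab for lab in PEAK_ORDER if lab in self.peak_params]
        if set(self.peak_params) - set(PEAK_ORDER):
            raise InvalidParameterError("peak labels must be among V, A, D, E, F, O")
        if "V" in self.peak_params and self.peak_params["V"].sign != 1:
            raise InvalidParameterError("peak V must have positive sign")
        for lab in labels:
            if lab != "V" and self.peak_params[lab].sign != -1:
                raise InvalidParameterError(f"peak {lab} must have negative sign")
        lats = [self.peak_params[lab].latency_ms for lab in labels]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise InvalidParameterError(
                "peak latencies must be strictly increasing in V<A<D<E<F<O order"
            )
        if self.ffr is not None and self.duration_class != "long170":
            raise InvalidParameterError("FFR is only defined for long-duration templates")

    def render(
        self, n_samples: int, sample_rate_hz: float, pre_stim_ms: float = 0.0
    ) -> np.ndarray:
        """Render the noiseless evoked waveform (uV) on the epoch time axis."""
        t_ms = np.arange(n_samples) / sample_rate_hz * 1000.0 - pre_stim_ms
        y = np.zeros(n_samples)
        for lab, p in self.peak_params.items():
            sig = p.width_ms / 2.0
            y += p.sign * p.amplitude_uV * np.exp(-0.5 * ((t_ms - p.latency_ms) / sig) ** 2)
            if lab in ("D", "E", "F", "O"):
                mu = p.latency_ms - _PRECEDING_POS_MS
                y += (
                    _PRECEDING_POS_FRAC
                    * p.amplitude_uV
                    * np.exp(-0.5 * ((t_ms - mu) / sig) ** 2)
                )
        if self.ffr is not None:
            f = self.ffr
            span = f.end_ms - f.start_ms
            u = (t_ms - f.start_ms) / span
            env = np.clip(np.minimum(u, 1.0 - u) / 0.1, 0.0, 1.0)  # 10% linear taper
            y += (
                f.amplitude_uV
                * env
                * np.sin(2.0 * np.pi * f.f0_hz * (t_ms - f.start_ms) / 1000.0)
                * ((u >= 0) & (u <= 1))
            )
        return y

    def expected_peak_to_trough(self) -> dict[str, float]:
        """Configured peak-to-trough amplitudes implied by the construction.

        V is measured V-to-A; each later trough against its preceding
        positivity; troughs inside the FFR span gain one FFR amplitude on
        each side (construction aligns peak O with an FFR trough).
        """
        out: dict[str, float] = {}
        if "V" in self.peak_params and "A" in self.peak_params:
            out["V"] = (
                self.peak_params["V"].amplitude_uV + self.peak_params["A"].amplitude_uV
            )
        for lab in ("D", "E", "F", "O"):
            if lab not in self.peak_params:
                continue
            p = self.peak_params[lab]
            amp = (1.0 + _PRECEDING_POS_FRAC) * p.amplitude_uV
            if self.ffr is not None and self.ffr.start_ms <= p.latency_ms <= self.ffr.end_ms:
                amp += 2.0 * self.ffr.amplitude_uV
            out[lab] = amp
        return out


def make_template(
    duration_class: str,
    condition: str = "quiet",
    overrides: Mapping[str, PeakShape] | None = None,
    *,
    background_effect: tuple[float, float] = DEFAULT_BACKGROUND_EFFECT,
    ffr: FfrParams | None = None,
) -> ResponseTemplate:
    """Build the default evoked template for a duration class and condition.

    Short templates end with the offset trough O and carry no FFR; the long
    template adds an F0-locked FFR spanning the sustained vowel period.  The
    ``noise`` condition shifts every peak later by the configured latency
    shift and scales every peak amplitude down; the FFR is left unchanged
    (background noise at the study's +10 dB SNR does not measurably alter
    FFR phase locking).
    """
    if duration_class not in DURATION_CLASSES:
        raise InvalidParameterError(f"unknown duration_class {duration_class!r}")
    if condition not in ("quiet", "noise"):
        raise InvalidParameterError("condition must be 'quiet' or 'noise'")
    peaks = dict(DEFAULT_PEAKS[duration_class])
    if overrides:
        peaks.update(overrides)
    if ffr is None and duration_class == "long170":
        ffr = FfrParams()
    if condition == "noise":
        shift, scale = background_effect
        peaks = {
            lab: dataclasses.replace(
                p, latency_ms=p.latency_ms + shift, amplitude_uV=p.amplitude_uV * scale
            )
            for lab, p in peaks.items()
        }
    return ResponseTemplate(
        peak_params=peaks,
        ffr=ffr,
        background_effect=background_effect,
        duration_class=duration_class,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Statistical model of the background EEG and recording artifacts."""

    sd_uV: float = 2.5
    band_hz: tuple[float, float] = (30.0, 3000.0)
    artifact_rate: float = 0.0
    artifact_amp_uV: float = 60.0
    cm_artifact_uV: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_uV < 0:
            raise InvalidParameterError("sd_uV must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise InvalidParameterError("artifact_rate must lie in [0, 1]")
        if self.artifact_rate > 0 and self.artifact_amp_uV <= 20.0:
            raise InvalidParameterError(
                "artifact_amp_uV must exceed the 20 uV rejection threshold"
            )
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise InvalidParameterError("band_hz must satisfy 0 < low < high")


@dataclass
class EpochMatrix:
    """Time x epoch voltage matrix (uV) -- the pipeline's central object.

    Rows are samples (the time axis starts ``pre_stim_ms`` before stimulus
    onset), columns are epochs.  ``polarity`` labels each epoch 0/1 for the
    original/inverted stimulus polarity.
    """

    data: np.ndarray
    sample_rate_hz: float
    pre_stim_ms: float
    polarity: np.ndarray
    condition: str = "quiet"
    seed_provenance: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise InvalidParameterError("data must be 2-D with at least one epoch")
        self.polarity = np.asarray(self.polarity, dtype=np.int8)
        if self.polarity.shape != (self.data.shape[1],):
            raise InvalidParameterError("polarity labels must match the epoch count")
        if self.condition not in ("quiet", "noise", "no_sound"):
            raise InvalidParameterError(
                "condition must be 'quiet', 'noise' or 'no_sound'"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sample_rate_hz * 1000.0 - self.pre_stim_ms

    def index_of(self, time_ms: float) -> int:
        """Sample index of a post-onset time (ms)."""
        idx = int(round((time_ms + self.pre_stim_ms) * self.sample_rate_hz / 1000.0))
        if not (0 <= idx < self.n_samples):
            raise InvalidParameterError(
                f"time {time_ms} ms lies outside the epoch span"
            )
        return idx

    def select(self, columns: np.ndarray) -> "EpochMatrix":
        """A new EpochMatrix restricted to the given epoch columns."""
        columns = np.asarray(columns)
        return EpochMatrix(
            data=self.data[:, columns],
            sample_rate_hz=self.sample_rate_hz,
            pre_stim_ms=self.pre_stim_ms,
            polarity=self.polarity[columns],
            condition=self.condition,
            seed_provenance=self.seed_provenance,
        )

    def subset_balanced(self, n: int) -> "EpochMatrix":
        """First ``n`` epochs in acquisition order, n/2 from each polarity."""
        if n % 2:
            raise InvalidParameterError("balanced subsets need an even epoch count")
        half = n // 2
        cols: list[int] = []
        for pol in (0, 1):
            idx = np.flatnonzero(self.polarity == pol)[:half]
            if idx.size < half:
                raise InvalidParameterError(
                    f"polarity {pol} has only {idx.size} epochs; {half} needed"
                )
            cols.extend(idx.tolist())
        return self.select(np.sort(np.asarray(cols)))


def _shaped_noise(
    rng: np.random.Generator,
    n_samples: int,
    n_epochs: int,
    sample_rate_hz: float,
    band_hz: tuple[float, float],
    sd_uV: float,
) -> np.ndarray:
    """Band-limited Gaussian noise with 1/f power tilt, global RMS = sd_uV."""
    white = rng.standard_normal((n_samples, n_epochs))
    if sd_uV == 0.0:
        return np.zeros((n_samples, n_epochs))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate_hz)
    lo, hi = band_hz
    mask = np.zeros_like(freqs)
    inband = (freqs >= lo) & (freqs <= hi)
    mask[inband] = freqs[inband] ** -0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    # soften the band edges over 10% to avoid ringing
    edge = (freqs > lo * 0.9) & (freqs < lo)
    mask[edge] = (freqs[edge] / lo) ** 8 * lo**-0.5
    x = np.fft.irfft(spec * mask[:, None], n=n_samples, axis=0)
    x *= sd_uV / x.std()
    return x


def simulate_epochs(
    template: ResponseTemplate | None,
    n_epochs: int,
    noise: NoiseModel,
    *,
    seed: int | np.random.SeedSequence,
    sample_rate_hz: float = 20_000.0,
    pre_stim_ms: float = 10.0,
    epoch_ms: float | None = None,
) -> EpochMatrix:
    """Simulate an epoch matrix: evoked template + EEG noise + artifacts.

    ``template=None`` produces a pure-noise ``no_sound`` recording.  The
    evoked component is identical across epochs; the stimulus-following
    component (``cm_artifact_uV``) inverts with the polarity label, so it
    cancels in the alternating-polarity average; transients of magnitude
    ``artifact_amp_uV`` are added to a Bernoulli(``artifact_rate``) subset
    of epochs.  Polarity labels alternate 0,1,0,1,... (balanced within one).
    """
    if n_epochs < 2:
        raise InvalidParameterError("n_epochs must be >= 2 (variance undefined below)")
    rng = np.random.default_rng(seed)
    if epoch_ms is None:
        epoch_ms = EPOCH_MS[template.duration_class] if template is not None else 80.0
    n_samples = int(round((pre_stim_ms + epoch_ms) * sample_rate_hz / 1000.0))
    t_ms = np.arange(n_samples) / sample_rate_hz * 1000.0 - pre_stim_ms

    evoked = (
        template.render(n_samples, sample_rate_hz, pre_stim_ms)
        if template is not None
        else np.zeros(n_samples)
    )
    polarity = (np.arange(n_epochs) % 2).astype(np.int8)

    data = _shaped_noise(rng, n_samples, n_epochs, sample_rate_hz, noise.band_hz, noise.sd_uV)
    data += evoked[:, None]

    if template is not None and noise.cm_artifact_uV > 0.0:
        stim_ms = STIMULUS_MS[template.duration_class]
        f0 = template.ffr.f0_hz if template.ffr is not None else 100.0
        cm = np.where(
            (t_ms >= 0.0) & (t_ms <= stim_ms),
            noise.cm_artifact_uV * np.sin(2.0 * np.pi * f0 * t_ms / 1000.0),
            0.0,
        )
        data += cm[:, None] * (1.0 - 2.0 * polarity[None, :])

    if noise.artifact_rate > 0.0:
        hit = rng.random(n_epochs) < noise.artifact_rate
        width = 5.0  # ms
        for j in np.flatnonzero(hit):
            center = rng.uniform(t_ms[0] + width, t_ms[-1] - width)
            sign = rng.choice((-1.0, 1.0))
            data[:, j] += (
                sign * noise.artifact_amp_uV * np.exp(-0.5 * ((t_ms - center) / (width / 2)) ** 2)
            )

    condition = template.condition if template is not None else "no_sound"
    return EpochMatrix(
        data=data,
        sample_rate_hz=sample_rate_hz,
        pre_stim_ms=pre_stim_ms,
        polarity=polarity,
        condition=condition,
        seed_provenance=str(seed),
    )
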