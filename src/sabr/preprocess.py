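"""Epoch preprocessing: rejection, polarity averaging, filtering, de-meaning.

The stages compose into the standard speech-ABR processing chain: reject
epochs with any activity above +/-20 uV, average each stimulus polarity
separately, band-pass each polarity average (70-2000 Hz by default) with a
zero-phase FIR, average the two polarities into the final alternating
response, and baseline-correct by de-meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    AllEpochsRejectedError,
    InvalidParameterError,
    MissingPolarityError,
)
from .synth import EpochMatrix

__all__ = [
    "AveragedResponse",
    "reject_artifacts",
    "average_polarities",
    "filter_response",
    "alternating_average",
    "demean",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_REJECTION_UV = 20.0
DEFAULT_HP_HZ = 70.0
DEFAULT_LP_HZ = 2000.0
DEFAULT_NUMTAPS = 1201


@dataclass
class AveragedResponse:
    """Final averaged alternating-polarity waveform with provenance."""

    samples: np.ndarray
    sample_rate_hz: float
    pre_stim_ms: float
    n_epochs_used: dict[int, int]
    filters_applied: tuple[float, float] | None = None
    demeaned: bool = False

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz * 1000.0 - self.pre_stim_ms

    def index_of(self, time_ms: float) -> int:
        idx = int(round((time_ms + self.pre_stim_ms) * self.sample_rate_hz / 1000.0))
        if not (0 <= idx < self.samples.size):
            raise InvalidParameterError(f"time {time_ms} ms outside the response span")
        return idx

    @property
    def n_epochs_total(self) -> int:
        return int(sum(self.n_epochs_used.values()))


def reject_artifacts(
    epochs: EpochMatrix, threshold_uV: float = DEFAULT_REJECTION_UV
) -> EpochMatrix:
    """Drop every epoch containing any activity strictly above the threshold.

    Retained epochs keep their acquisition order and are returned unaltered.
    """
    if threshold_uV <= 0:
        raise InvalidParameterError("threshold_uV must be positive")
    peak = np.max(np.abs(epochs.data), axis=0)
    keep = peak <= threshold_uV
    n_rej = int(np.sum(~keep))
    if not np.any(keep):
        raise AllEpochsRejectedError(
            f"all {epochs.n_epochs} epochs exceeded the {threshold_uV} uV "
            "rejection threshold"
        )
    logger.info(
        "artifact rejection: kept %d / %d epochs (threshold %.1f uV)",
        epochs.n_epochs - n_rej,
        epochs.n_epochs,
        threshold_uV,
    )
    return epochs.select(np.flatnonzero(keep))


def average_polarities(epochs: EpochMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of each polarity's epochs, separately (unweighted)."""
    out = []
    for pol in (0, 1):
        cols = epochs.polarity == pol
        if not np.any(cols):
            raise MissingPolarityError(f"no epochs with polarity {pol}")
        out.append(epochs.data[:, cols].mean(axis=1))
    return out[0], out[1]


def filter_response(
    series: np.ndarray,
    hp_hz: float = DEFAULT_HP_HZ,
    lp_hz: float = DEFAULT_LP_HZ,
    sample_rate_hz: float = 20_000.0,
    numtaps: int = DEFAULT_NUMTAPS,
) -> np.ndarray:
    """Zero-phase band-pass: linear-phase FIR applied forward and backward.

    The forward-backward application cancels the group delay exactly (a
    symmetric pulse keeps its extremum sample) and doubles the stopband
    attenuation of the underlying Hamming-window FIR.
    """
    series = np.asarray(series, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not (0 < hp_hz < lp_hz < nyq):
        raise InvalidParameterError(
            f"need 0 < hp ({hp_hz}) < lp ({lp_hz}) < Nyquist ({nyq})"
        )
    taps = signal.firwin(
        numtaps, [hp_hz, lp_hz], fs=sample_rate_hz, pass_zero=False, window="hamming"
    )
    padlen = min(3 * numtaps, series.shape[-1] - 1)
    return signal.filtfilt(taps, 1.0, series, padlen=padlen)


def alternating_average(avg_a: np.ndarray, avg_b: np.ndarray) -> np.ndarray:
    """Mean of the two polarity averages: (A + B) / 2."""
    avg_a = np.asarray(avg_a, dtype=float)
    avg_b = np.asarray(avg_b, dtype=float)
    if avg_a.shape != avg_b.shape:
        raise InvalidParameterError("polarity averages must have equal length")
    return 0.5 * (avg_a + avg_b)


def demean(series: np.ndarray) -> np.ndarray:
    """Baseline-correct a series by removing its mean."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InvalidParameterError("cannot de-mean an empty series")
    return series - series.mean()


def preprocess_pipeline(
    epochs: EpochMatrix,
    *,
    rejection_uV: float | None = DEFAULT_REJECTION_UV,
    hp_hz: float = DEFAULT_HP_HZ,
    lp_hz: float = DEFAULT_LP_HZ,
    numtaps: int = DEFAULT_NUMTAPS,
) -> AveragedResponse:
    """Full chain: reject -> per-polarity average -> filter -> alternate -> demean.

    ``rejection_uV=None`` skips rejection (for pre-screened subsets).
    """
    if rejection_uV is not None:
        epochs = reject_artifacts(epochs, rejection_uV)
    avg_a, avg_b = average_polarities(epochs)
    fs = epochs.sample_rate_hz
    avg_a = filter_response(avg_a, hp_hz, lp_hz, fs, numtaps)
    avg_b = filter_response(avg_b, hp_hz, lp_hz, fs, numtaps)
    final = demean(alternating_average(avg_a, avg_b))
    counts = {
        0: int(np.sum(epochs.polarity == 0)),
        1: int(np.sum(epochs.polarity == 1)),
    }
    return AveragedResponse(
        samples=final,
        sample_rate_hz=fs,
        pre_stim_ms=epochs.pre_stim_ms,
        n_epochs_used=counts,
        filters_applied=(hp_hz, lp_hz),
        demeaned=True,
    )
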