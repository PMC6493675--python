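"""Intertrial phase clustering (ITPC) at F0 over the FFR period.

ITPC at a time point is the length of the mean unit phase vector across
epochs at a target frequency: 1 for perfectly repeatable phase, 0 for
uniformly random phase.  Phase is extracted from the raw (unaveraged) epochs
by convolution with a complex Morlet wavelet centered at F0 -- a standard
realization of narrow-band phase estimation.  The FFR summary is the maximum
ITPC over the sustained-response window (70-190 ms by default), Fisher-Z
transformed (atanh) for group statistics, compared across conditions with a
classical two-tailed paired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import DegenerateInputError, InvalidParameterError
from .synth import EpochMatrix

__all__ = [
    "PhaseLockingResult",
    "DEFAULT_FFR_WINDOW_MS",
    "compute_itpc",
    "summarize_ffr",
    "compare_phase_locking",
]

DEFAULT_FFR_WINDOW_MS = (70.0, 190.0)
DEFAULT_N_CYCLES = 7.0


@dataclass
class PhaseLockingResult:
    """Per-time-point ITPC and its windowed summary."""

    itpc_series: np.ndarray
    times_ms: np.ndarray
    window_ms: tuple[float, float]
    max_itpc: float
    fisher_z: float
    f0_hz: float
    n_epochs: int
    edge_ms: float

    def __post_init__(self) -> None:
        if np.any(self.itpc_series < -1e-9) or np.any(self.itpc_series > 1.0 + 1e-9):
            raise InvalidParameterError("ITPC must lie in [0, 1]")


def _morlet_phases(
    data: np.ndarray, sample_rate_hz: float, f0_hz: float, n_cycles: float
) -> np.ndarray:
    """Unit phase vectors (complex) per sample and epoch at f0."""
    sigma_t = n_cycles / (2.0 * np.pi * f0_hz)
    half = int(np.ceil(4.0 * sigma_t * sample_rate_hz))
    t = np.arange(-half, half + 1) / sample_rate_hz
    wavelet = np.exp(2j * np.pi * f0_hz * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    z = signal.fftconvolve(data, wavelet[:, None], mode="same", axes=0)
    mag = np.abs(z)
    mag[mag == 0.0] = 1.0
    return z / mag


def compute_itpc(
    epochs: EpochMatrix,
    f0_hz: float = 100.0,
    window_ms: tuple[float, float] = DEFAULT_FFR_WINDOW_MS,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> PhaseLockingResult:
    """ITPC(t) at f0 across raw epochs, summarized over the given window.

    The window must span at least two cycles of f0.  Points within one
    wavelet transient (2 sigma_t) of the window edges are excluded from the
    windowed maximum; the full per-sample series is returned untouched.
    """
    if epochs.n_epochs < 2:
        raise InvalidParameterError("ITPC needs at least 2 epochs")
    lo, hi = window_ms
    if (hi - lo) < 2.0 * 1000.0 / f0_hz:
        raise InvalidParameterError(
            f"window ({lo}, {hi}) ms is shorter than 2 cycles of {f0_hz} Hz"
        )
    unit = _morlet_phases(epochs.data, epochs.sample_rate_hz, f0_hz, n_cycles)
    # rounding can push |mean of unit vectors| a few ulp above 1
    series = np.minimum(np.abs(unit.mean(axis=1)), 1.0)
    times = epochs.times_ms
    edge_ms = 2.0 * 1000.0 * n_cycles / (2.0 * np.pi * f0_hz)
    max_itpc, fisher_z = _window_summary(series, times, (lo, hi), edge_ms)
    return PhaseLockingResult(
        itpc_series=series,
        times_ms=times,
        window_ms=(lo, hi),
        max_itpc=max_itpc,
        fisher_z=fisher_z,
        f0_hz=f0_hz,
        n_epochs=epochs.n_epochs,
        edge_ms=edge_ms,
    )


def _window_summary(
    series: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    edge_ms: float,
) -> tuple[float, float]:
    lo, hi = window_ms
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise InvalidParameterError(
            f"window ({lo}, {hi}) ms lies outside the data span "
            f"({times_ms[0]:.1f}, {times_ms[-1]:.1f})"
        )
    inner = (times_ms >= lo + edge_ms) & (times_ms <= hi - edge_ms)
    if not np.any(inner):  # window too short for edge exclusion: use it whole
        inner = (times_ms >= lo) & (times_ms <= hi)
    max_itpc = float(series[inner].max())
    if max_itpc >= 1.0:
        warnings.warn("ITPC reached 1; clipping below 1 for the Fisher-Z transform")
        max_itpc = np.nextafter(1.0, 0.0)
    return max_itpc, float(np.arctanh(max_itpc))


def summarize_ffr(
    result: PhaseLockingResult,
    window_ms: tuple[float, float] = DEFAULT_FFR_WINDOW_MS,
) -> tuple[float, float]:
    """(max ITPC, Fisher-Z) over a window of an existing ITPC series."""
    return _window_summary(result.itpc_series, result.times_ms, window_ms, result.edge_ms)


def compare_phase_locking(
    z_quiet: np.ndarray, z_noise: np.ndarray
) -> tuple[float, float]:
    """Two-tailed paired t test on per-subject Fisher-Z phase-locking maxima.

    Returns (t, p) for quiet minus noise differences.  Identical vectors give
    (0, 1); constant non-zero differences have no variance and raise.
    """
    a = np.asarray(z_quiet, dtype=float)
    b = np.asarray(z_noise, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be 1-D of equal length")
    if a.size < 2:
        raise InvalidParameterError("paired t test needs at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        if np.all(d == 0.0):
            return 0.0, 1.0
        raise DegenerateInputError(
            "paired differences have zero variance; t statistic undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
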