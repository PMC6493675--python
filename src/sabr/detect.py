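"""Objective response detection: the F_SP statistic and bootstrap bands.

F_SP is a variance-ratio statistic: the variance over time of the averaged
waveform within a response window, divided by an estimate of the residual
noise variance of the average, obtained from the across-epoch variance of the
voltage at a single time point.  Values near 1 indicate noise only; the
conventional presence criterion for responses in quiet is F_SP >= 3.1
(~99 % confidence on click-ABR calibrations).

The bootstrap builds per-sample 95 % confidence bands for the noise floor of
the alternating-polarity average: epochs are resampled with replacement
within each polarity stratum and each drawn epoch is randomly negated, which
destroys the phase-locked evoked component while preserving the noise
spectrum.  Samples of the observed average lying outside the bands are, with
the stated confidence, above the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError
from .synth import EpochMatrix

__all__ = [
    "FspResult",
    "ConfidenceBands",
    "PresenceVerdict",
    "FSP_WINDOWS",
    "FSP_CRITERION",
    "fsp_window_for",
    "compute_fsp",
    "bootstrap_bands",
    "response_present",
    "peak_detected",
]

FSP_CRITERION = 3.1

#: Duration-class specific analysis windows (ms post onset); the single point
#: sits at the midpoint of each window.
FSP_WINDOWS: dict[str, tuple[tuple[float, float], float]] = {
    "short40": ((5.0, 60.0), 32.5),
    "short50": ((8.0, 70.0), 39.0),
    "long170": ((8.0, 70.0), 39.0),
}


@dataclass(frozen=True)
class FspResult:
    value: float
    window_ms: tuple[float, float]
    single_point_ms: float
    n_epochs: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidParameterError("F_SP cannot be negative")
        lo, hi = self.window_ms
        if not (lo <= self.single_point_ms <= hi):
            raise InvalidParameterError("single point must lie inside the window")


@dataclass(frozen=True)
class ConfidenceBands:
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise InvalidParameterError("level must lie in (0, 1)")
        if np.any(self.lower > self.upper):
            raise InvalidParameterError("lower band exceeds upper band")


@dataclass(frozen=True)
class PresenceVerdict:
    present: bool
    rule: str
    fsp_value: float
    condition: str


def fsp_window_for(duration_class: str) -> tuple[tuple[float, float], float]:
    """Analysis window and single-point position for a duration class."""
    try:
        return FSP_WINDOWS[duration_class]
    except KeyError:
        raise InvalidParameterError(
            f"unknown duration class {duration_class!r}; "
            f"expected one of {sorted(FSP_WINDOWS)}"
        ) from None


def compute_fsp(
    epochs: EpochMatrix,
    window_ms: tuple[float, float] | None = None,
    single_point_ms: float | None = None,
    *,
    duration_class: str | None = None,
) -> FspResult:
    """F_SP of an epoch matrix.

    value = Var_time[average over window] / (Var_epochs[x(single point)] / n)

    Both variances use the n-1 sample denominator.  Either pass the window
    and single point explicitly or give a ``duration_class``.
    """
    if window_ms is None or single_point_ms is None:
        if duration_class is None:
            raise InvalidParameterError(
                "provide window_ms and single_point_ms, or a duration_class"
            )
        window_ms, single_point_ms = fsp_window_for(duration_class)
    if epochs.n_epochs < 2:
        raise InvalidParameterError("F_SP needs at least 2 epochs")
    lo, hi = window_ms
    if not (lo <= single_point_ms <= hi):
        raise InvalidParameterError("single point must lie inside the window")
    i0, i1 = epochs.index_of(lo), epochs.index_of(hi)
    isp = epochs.index_of(single_point_ms)

    avg = epochs.data.mean(axis=1)
    num = float(np.var(avg[i0 : i1 + 1], ddof=1))
    sp = epochs.data[isp, :]
    var_sp = float(np.var(sp, ddof=1))
    if var_sp == 0.0:
        raise DegenerateInputError(
            "zero across-epoch variance at the single point; F_SP undefined"
        )
    value = num / (var_sp / epochs.n_epochs)
    return FspResult(
        value=value,
        window_ms=(lo, hi),
        single_point_ms=single_point_ms,
        n_epochs=epochs.n_epochs,
    )


def _null_averages(
    epochs: EpochMatrix,
    n_boot: int,
    rng: np.random.Generator,
    chunk: int = 250,
) -> np.ndarray:
    """(n_samples, n_boot) matrix of sign-flipped resampled alternating averages."""
    strata = [np.flatnonzero(epochs.polarity == p) for p in np.unique(epochs.polarity)]
    n_epochs = epochs.n_epochs
    out = np.empty((epochs.n_samples, n_boot))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        w = np.zeros((n_epochs, b))
        for col in range(b):
            for idx in strata:
                draws = rng.integers(0, idx.size, size=idx.size)
                signs = rng.choice((-1.0, 1.0), size=idx.size)
                w[:, col] += np.bincount(
                    idx[draws], weights=signs, minlength=n_epochs
                ) / (idx.size * len(strata))
        out[:, done : done + b] = epochs.data @ w
        done += b
    return out


def bootstrap_bands(
    epochs: EpochMatrix,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> ConfidenceBands:
    """Per-sample noise-floor confidence bands of the alternating average.

    Deterministic given ``seed``.  Requires at least 2 epochs per polarity
    stratum and ``n_boot >= 200`` (quantiles are unstable below that).
    """
    if n_boot < 200:
        raise InvalidParameterError("n_boot must be >= 200 for stable quantiles")
    if not (0.0 < level < 1.0):
        raise InvalidParameterError("level must lie in (0, 1)")
    for p in np.unique(epochs.polarity):
        if np.sum(epochs.polarity == p) < 2:
            raise InvalidParameterError(
                f"polarity {p} has fewer than 2 epochs; cannot resample"
            )
    rng = np.random.default_rng(seed)
    null = _null_averages(epochs, n_boot, rng)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(null, alpha, axis=1)
    upper = np.quantile(null, 1.0 - alpha, axis=1)
    return ConfidenceBands(
        lower=lower,
        upper=upper,
        level=level,
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
    )


def response_present(
    fsp: FspResult,
    condition: str,
    no_sound_fsp: float | None = None,
    criterion: float = FSP_CRITERION,
) -> PresenceVerdict:
    """Presence verdict under the condition-specific rule.

    Quiet responses are present when F_SP >= criterion (inclusive at 3.1);
    responses in noise are present when F_SP exceeds the same participant's
    no-sound F_SP (the absolute criterion is not calibrated for noise).
    """
    if condition == "quiet":
        return PresenceVerdict(
            present=fsp.value >= criterion,
            rule=f"quiet: F_SP >= {criterion}",
            fsp_value=fsp.value,
            condition=condition,
        )
    if condition == "noise":
        if no_sound_fsp is None:
            raise InvalidParameterError(
                "the noise-condition rule requires the participant's no-sound F_SP"
            )
        return PresenceVerdict(
            present=fsp.value > no_sound_fsp,
            rule=f"noise: F_SP > no-sound F_SP ({no_sound_fsp:g})",
            fsp_value=fsp.value,
            condition=condition,
        )
    raise InvalidParameterError("condition must be 'quiet' or 'noise'")


def peak_detected(
    value_uV: float, bands: ConfidenceBands, sample_index: int
) -> bool:
    """True iff the value lies strictly outside the bands at that sample."""
    if not (0 <= sample_index < bands.lower.size):
        raise InvalidParameterError("sample_index outside the band span")
    return bool(
        value_uV < bands.lower[sample_index] or value_uV > bands.upper[sample_index]
    )
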