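"""Minimum-epoch-count sweep: F_SP and bootstrap peak detection on nested
epoch subsets.

The procedure evaluates the full detection chain on cumulative prefixes of
the recording (balanced across polarities) at an ascending schedule of epoch
counts -- by default 800, 1600, ..., 12,000 (15 iterations).  Two minima are
reported: the smallest count at which the condition-specific presence
criterion is met (F_SP >= 3.1 in quiet; F_SP above the no-sound F_SP in
noise), and the smallest count at or above it at which every peak detected
at the maximum count is again detected with 95 % confidence via bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detect import (
    FSP_CRITERION,
    bootstrap_bands,
    compute_fsp,
    fsp_window_for,
    peak_detected,
    response_present,
)
from .errors import InvalidParameterError
from .peaks import DEFAULT_HALF_WINDOW_MS, measure_amplitudes, pick_peaks
from .preprocess import (
    DEFAULT_HP_HZ,
    DEFAULT_LP_HZ,
    DEFAULT_REJECTION_UV,
    preprocess_pipeline,
    reject_artifacts,
)
from .synth import EpochMatrix

__all__ = ["SweepIteration", "SweepResult", "epoch_schedule", "run_sweep", "minimum_epochs"]

DEFAULT_STEP = 800
DEFAULT_MAX = 12_000


@dataclass(frozen=True)
class SweepIteration:
    n_epochs: int
    fsp_value: float
    peaks_detected: frozenset[str]


@dataclass
class SweepResult:
    schedule: list[int]
    iterations: list[SweepIteration]
    reference_peaks: frozenset[str] = field(default_factory=frozenset)
    condition: str = "quiet"
    min_epochs_fsp: int | None = None
    min_epochs_all_peaks: int | None = None

    def fsp_trace(self) -> list[float]:
        return [it.fsp_value for it in self.iterations]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "schedule": self.schedule,
            "fsp_trace": self.fsp_trace(),
            "peaks_detected": [sorted(it.peaks_detected) for it in self.iterations],
            "reference_peaks": sorted(self.reference_peaks),
            "min_epochs_fsp": self.min_epochs_fsp,
            "min_epochs_all_peaks": self.min_epochs_all_peaks,
        }


def epoch_schedule(step: int = DEFAULT_STEP, maximum: int = DEFAULT_MAX) -> list[int]:
    """Ascending multiples of ``step`` up to ``maximum``."""
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    if maximum < step:
        raise InvalidParameterError("maximum must be at least one step")
    return list(range(step, maximum + 1, step))


def run_sweep(
    epochs: EpochMatrix,
    *,
    duration_class: str,
    condition: str | None = None,
    no_sound_fsp: float | None = None,
    schedule: list[int] | None = None,
    step: int = DEFAULT_STEP,
    maximum: int = DEFAULT_MAX,
    rejection_uV: float = DEFAULT_REJECTION_UV,
    hp_hz: float = DEFAULT_HP_HZ,
    lp_hz: float = DEFAULT_LP_HZ,
    expected_latencies: dict[str, float] | None = None,
    half_window_ms: float = DEFAULT_HALF_WINDOW_MS,
    level: float = 0.95,
    n_boot: int = 1000,
    fsp_criterion: float = FSP_CRITERION,
    seed: int = 0,
) -> SweepResult:
    """Run the epoch-count sweep on one recording.

    Subsets are cumulative prefixes in acquisition order after artifact
    rejection, balanced n/2 per polarity.  At each count the preprocessing
    pipeline, F_SP, bootstrap bands and peak picking are applied; the
    bootstrap seed is fixed per count so the sweep is reproducible.
    ``expected_latencies`` default to the generator's template latencies via
    the caller; they must be supplied here.
    """
    if expected_latencies is None:
        raise InvalidParameterError("expected_latencies are required for peak picking")
    condition = condition or (epochs.condition if epochs.condition != "no_sound" else "quiet")
    if schedule is None:
        schedule = epoch_schedule(step, maximum)
    retained = reject_artifacts(epochs, rejection_uV)
    per_pol = min(
        int(np.sum(retained.polarity == 0)), int(np.sum(retained.polarity == 1))
    )
    if per_pol == 0:
        raise InvalidParameterError("both polarities are required for the sweep")
    usable = [n for n in schedule if n // 2 <= per_pol]
    if len(usable) < len(schedule):
        warnings.warn(
            f"schedule truncated to {usable[-1] if usable else 0} epochs: only "
            f"{per_pol} artifact-free epochs per polarity available"
        )
    if not usable:
        raise InvalidParameterError("no schedule count is satisfiable after rejection")

    window_ms, single_point_ms = fsp_window_for(duration_class)
    root = np.random.SeedSequence(seed)
    iterations: list[SweepIteration] = []
    for i, n in enumerate(usable):
        sub = retained.subset_balanced(n)
        fsp = compute_fsp(sub, window_ms, single_point_ms)
        avg = preprocess_pipeline(sub, rejection_uV=None, hp_hz=hp_hz, lp_hz=lp_hz)
        bands = bootstrap_bands(
            sub, level=level, n_boot=n_boot, seed=np.random.SeedSequence(seed, spawn_key=(i,))
        )
        picked = measure_amplitudes(avg, pick_peaks(avg, expected_latencies, half_window_ms))
        detected = frozenset(
            lab
            for lab, p in picked.peaks.items()
            if p.detected and peak_detected(p.value_uV, bands, p.index)
        )
        iterations.append(SweepIteration(n, fsp.value, detected))

    result = SweepResult(
        schedule=usable,
        iterations=iterations,
        reference_peaks=iterations[-1].peaks_detected,
        condition=condition,
    )
    result.min_epochs_fsp, result.min_epochs_all_peaks = minimum_epochs(
        result, condition, no_sound_fsp, fsp_criterion=fsp_criterion,
        duration_class=duration_class,
    )
    return result


def minimum_epochs(
    sweep: SweepResult,
    condition: str,
    no_sound_fsp: float | None = None,
    *,
    fsp_criterion: float = FSP_CRITERION,
    duration_class: str = "short50",
) -> tuple[int | None, int | None]:
    """(min epochs to the F_SP criterion, min epochs for all reference peaks).

    The all-peaks search starts at the F_SP minimum; ``None`` marks a
    criterion never reached within the sweep.
    """
    window_ms, single_point_ms = fsp_window_for(duration_class)
    min_fsp: int | None = None
    fsp_index: int | None = None
    for i, it in enumerate(sweep.iterations):
        fake = _fsp_stub(it.fsp_value, window_ms, single_point_ms, it.n_epochs)
        if response_present(fake, condition, no_sound_fsp, criterion=fsp_criterion).present:
            min_fsp, fsp_index = it.n_epochs, i
            break
    if min_fsp is None:
        return None, None
    reference = sweep.reference_peaks
    for it in sweep.iterations[fsp_index:]:
        if reference <= it.peaks_detected:
            return min_fsp, it.n_epochs
    return min_fsp, None


def _fsp_stub(value, window_ms, single_point_ms, n):
    from .detect import FspResult

    return FspResult(
        value=value, window_ms=window_ms, single_point_ms=single_point_ms, n_epochs=n
    )
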