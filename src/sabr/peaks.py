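"""Peak picking, tube-delay latency correction, and amplitude measurement.

An automated stand-in for visual peak identification: each labeled landmark
(V, A, D, E, F, O) is assigned to the extremum of the correct sign within a
window around its expected latency, subject to the conventional temporal
order V < A < D < E < F < O.  Latencies are corrected for the insert-earphone
tube delay (0.8 ms subtracted).  Amplitudes follow the peak-to-trough
convention: V is measured against trough A, and each later trough against
the positive peak immediately preceding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidParameterError
from .preprocess import AveragedResponse
from .synth import PEAK_ORDER

__all__ = [
    "PeakMeasure",
    "PeakSet",
    "TUBE_DELAY_MS",
    "pick_peaks",
    "correct_latency",
    "measure_amplitudes",
]

TUBE_DELAY_MS = 0.8
DEFAULT_HALF_WINDOW_MS = 2.0

PEAK_SIGNS = {"V": +1, "A": -1, "D": -1, "E": -1, "F": -1, "O": -1}


@dataclass
class PeakMeasure:
    label: str
    detected: bool = False
    latency_ms_raw: float | None = None
    latency_ms_corrected: float | None = None
    value_uV: float | None = None
    amplitude_uV: float | None = None
    amplitude_flag: str | None = None
    search_window_ms: tuple[float, float] | None = None
    index: int | None = None


@dataclass
class PeakSet:
    """Measured landmarks keyed by label, in temporal order."""

    peaks: dict[str, PeakMeasure] = field(default_factory=dict)

    def __getitem__(self, label: str) -> PeakMeasure:
        return self.peaks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.peaks

    def labels_detected(self) -> frozenset[str]:
        return frozenset(l for l, p in self.peaks.items() if p.detected)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": p.label,
                "raw_ms": p.latency_ms_raw,
                "corrected_ms": p.latency_ms_corrected,
                "amplitude_uV": p.amplitude_uV,
                "detected": p.detected,
            }
            for p in self.peaks.values()
        ]
        return pd.DataFrame(rows, columns=["label", "raw_ms", "corrected_ms", "amplitude_uV", "detected"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def correct_latency(latency_ms_raw, tube_delay_ms: float = TUBE_DELAY_MS):
    """Subtract the insert-earphone tube delay from raw latencies.

    Accepts a scalar or array; errors if any raw latency is below the delay.
    """
    arr = np.asarray(latency_ms_raw, dtype=float)
    if np.any(arr < tube_delay_ms):
        raise InvalidParameterError(
            f"raw latency below the {tube_delay_ms} ms tube delay"
        )
    out = arr - tube_delay_ms
    return float(out) if np.isscalar(latency_ms_raw) else out


def _local_extrema(x: np.ndarray, sign: int) -> np.ndarray:
    """Indices of strict local extrema of the given sign (value on that side of 0)."""
    idx, _ = find_peaks(sign * x)
    return idx[sign * x[idx] > 0]


def pick_peaks(
    avg: AveragedResponse,
    expected_latencies: dict[str, float],
    half_window_ms: float = DEFAULT_HALF_WINDOW_MS,
) -> PeakSet:
    """Assign each label to the extremum of the correct sign near its
    expected latency.

    V is only assigned at a positive local maximum, the troughs only at
    negative local minima.  A label is left unassigned when no such extremum
    exists in its window.  Assigned latencies preserve the label order: each
    search is constrained to start after the previously assigned peak.  Ties
    between equal extrema resolve to the earlier sample.
    """
    labels = [lab for lab in PEAK_ORDER if lab in expected_latencies]
    if not labels:
        raise InvalidParameterError("expected_latencies is empty")
    exp = [expected_latencies[lab] for lab in labels]
    if any(b <= a for a, b in zip(exp, exp[1:])):
        raise InvalidParameterError("expected latencies must be strictly increasing")
    if half_window_ms <= 0:
        raise InvalidParameterError("half_window_ms must be positive")

    x = np.asarray(avg.samples, dtype=float)
    result = PeakSet()
    prev_idx = -1
    for lab, mu in zip(labels, exp):
        lo_ms, hi_ms = mu - half_window_ms, mu + half_window_ms
        i0 = max(avg.index_of(max(lo_ms, avg.times_ms[0])), 0)
        i1 = avg.index_of(min(hi_ms, avg.times_ms[-1]))
        i0 = max(i0, prev_idx + 1)
        meas = PeakMeasure(label=lab, search_window_ms=(lo_ms, hi_ms))
        if i1 > i0:
            # pad by one sample so window-edge extrema are visible to find_peaks
            a, b = max(i0 - 1, 0), min(i1 + 2, x.size)
            cand = _local_extrema(x[a:b], PEAK_SIGNS[lab]) + a
            cand = cand[(cand >= i0) & (cand <= i1)]
            if cand.size:
                best = cand[np.argmax(PEAK_SIGNS[lab] * x[cand])]
                raw = avg.times_ms[best]
                meas.detected = True
                meas.index = int(best)
                meas.latency_ms_raw = float(raw)
                meas.latency_ms_corrected = correct_latency(float(raw))
                meas.value_uV = float(x[best])
                prev_idx = int(best)
        result.peaks[lab] = meas
    return result


def measure_amplitudes(avg: AveragedResponse, peakset: PeakSet) -> PeakSet:
    """Fill in peak-to-trough amplitudes in place and return the PeakSet.

    V's amplitude is value(V) - value(A).  For D, E, F, O the reference is
    the positive peak preceding the trough: the largest positive local
    maximum between the previously assigned landmark (or the response start)
    and the trough -- what a human picker would call "the" preceding
    positivity, robust to sub-sample noise ripples.  When no positive
    maximum exists the amplitude stays unassigned and a flag records why.
    """
    x = np.asarray(avg.samples, dtype=float)
    pos_max = _local_extrema(x, +1)

    if "V" in peakset and "A" in peakset:
        v, a = peakset["V"], peakset["A"]
        if v.detected and a.detected:
            v.amplitude_uV = float(v.value_uV - a.value_uV)

    assigned = sorted(p.index for p in peakset.peaks.values() if p.detected)
    for lab in ("D", "E", "F", "O"):
        if lab not in peakset:
            continue
        p = peakset[lab]
        if not p.detected:
            continue
        earlier = [i for i in assigned if i < p.index]
        seg_start = earlier[-1] + 1 if earlier else 0
        preceding = pos_max[(pos_max >= seg_start) & (pos_max < p.index)]
        if preceding.size == 0:
            p.amplitude_flag = "no preceding positive peak"
            continue
        ref = int(preceding[np.argmax(x[preceding])])
        p.amplitude_uV = float(x[ref] - x[p.index])
    return peakset
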