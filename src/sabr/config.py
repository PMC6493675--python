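"""Run configuration: acquisition plan, filters, detection, peaks, phase, sweep.

Configurations are plain dataclasses with study-protocol defaults; a TOML
file with matching section names ([acquisition], [filters], [detection],
[peaks], [phase], [sweep]) overrides individual keys.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidParameterError
from .synth import DEFAULT_PEAKS

__all__ = [
    "AcquisitionConfig",
    "FilterConfig",
    "DetectionConfig",
    "PeaksConfig",
    "PhaseConfig",
    "SweepSectionConfig",
    "RunConfig",
    "default_expected_latencies",
]


def default_expected_latencies(duration_class: str = "short50") -> dict[str, float]:
    """Template-truth expected latencies for peak picking (ms, raw)."""
    return {lab: p.latency_ms for lab, p in DEFAULT_PEAKS[duration_class].items()}


@dataclass
class AcquisitionConfig:
    sample_rate_hz: float = 20_000.0
    rejection_uV: float = 20.0
    blocks: int = 2
    epochs_per_block: int = 3000
    polarities: int = 2
    speech_level_dbA: float = 80.0
    babble_level_dbA: float = 70.0

    @property
    def snr_db(self) -> float:
        """Signal-to-noise ratio: speech level minus masker level (dB)."""
        return self.speech_level_dbA - self.babble_level_dbA

    @property
    def total_epochs(self) -> int:
        """Planned artifact-free epochs per stimulus."""
        return self.blocks * self.epochs_per_block * self.polarities


@dataclass
class FilterConfig:
    hp_hz: float = 70.0
    lp_hz: float = 2000.0


@dataclass
class DetectionConfig:
    level: float = 0.95
    n_boot: int = 1000
    fsp_criterion: float = 3.1
    duration_class: str = "short50"


@dataclass
class PeaksConfig:
    expected_latencies: dict[str, float] = field(
        default_factory=lambda: default_expected_latencies("short50")
    )
    half_window_ms: float = 2.0


@dataclass
class PhaseConfig:
    f0_hz: float = 100.0
    window_ms: tuple[float, float] = (70.0, 190.0)


@dataclass
class SweepSectionConfig:
    step: int = 800
    max: int = 12_000


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    sweep: SweepSectionConfig = field(default_factory=SweepSectionConfig)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(seed=raw.get("seed", 0))
        for section in ("acquisition", "filters", "detection", "peaks", "phase", "sweep"):
            if section not in raw:
                continue
            target = getattr(cfg, section)
            names = {f.name for f in dataclasses.fields(target)}
            for key, value in raw[section].items():
                if key not in names:
                    raise InvalidParameterError(
                        f"unknown key {key!r} in config section [{section}]"
                    )
                if key == "window_ms":
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    def echo(self) -> dict:
        """JSON-serializable echo of the full configuration."""
        d = dataclasses.asdict(self)
        d["acquisition"]["snr_db"] = self.acquisition.snr_db
        d["acquisition"]["total_epochs"] = self.acquisition.total_epochs
        d["phase"]["window_ms"] = list(self.phase.window_ms)
        return d
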