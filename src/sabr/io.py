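"""Epoch archives, CSV fixtures, WAV stimuli, and run reports.

The canonical on-disk form of an :class:`~sabr.synth.EpochMatrix` is a pair
of files sharing a base path: ``<base>.f32`` holds the voltage matrix as
little-endian 32-bit floats in row-major (sample-major) order, and
``<base>.json`` is a sidecar with the shape, sampling metadata and per-epoch
polarity labels.  Small fixtures can also be read from CSV (header row:
``sample_ms`` then one column per epoch).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import CorruptArchiveError, InvalidParameterError
from .synth import EpochMatrix, Stimulus

__all__ = [
    "write_archive",
    "read_archive",
    "read_csv_epochs",
    "write_wav",
    "emit_report",
    "render_summary",
]

FORMAT_VERSION = 1


def _paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    if base.suffix in (".f32", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".f32"), base.with_suffix(".json")


def write_archive(epochs: EpochMatrix, base: str | Path) -> tuple[Path, Path]:
    """Write payload + sidecar; returns the two paths."""
    payload_path, meta_path = _paths(base)
    payload = np.ascontiguousarray(epochs.data, dtype="<f4")
    payload_path.write_bytes(payload.tobytes())
    meta = {
        "format_version": FORMAT_VERSION,
        "n_samples": epochs.n_samples,
        "n_epochs": epochs.n_epochs,
        "sample_rate_hz": epochs.sample_rate_hz,
        "pre_stim_ms": epochs.pre_stim_ms,
        "polarity": epochs.polarity.astype(int).tolist(),
        "condition": epochs.condition,
        "units": "uV",
        "seed_provenance": epochs.seed_provenance,
    }
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    return payload_path, meta_path


def read_archive(base: str | Path) -> EpochMatrix:
    """Read an archive back; bit-exact for float32 payloads."""
    payload_path, meta_path = _paths(base)
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise CorruptArchiveError(
            f"unknown archive format_version {meta.get('format_version')!r}"
        )
    n_samples, n_epochs = meta["n_samples"], meta["n_epochs"]
    blob = payload_path.read_bytes()
    expected = n_samples * n_epochs * 4
    if len(blob) != expected:
        raise CorruptArchiveError(
            f"payload is {len(blob)} bytes; sidecar declares {expected} "
            f"({n_samples} samples x {n_epochs} epochs x 4)"
        )
    if len(meta["polarity"]) != n_epochs:
        raise CorruptArchiveError("polarity array length does not match n_epochs")
    data = np.frombuffer(blob, dtype="<f4").reshape(n_samples, n_epochs)
    return EpochMatrix(
        data=data.astype(float),
        sample_rate_hz=meta["sample_rate_hz"],
        pre_stim_ms=meta["pre_stim_ms"],
        polarity=np.asarray(meta["polarity"], dtype=np.int8),
        condition=meta["condition"],
        seed_provenance=meta.get("seed_provenance"),
    )


def read_csv_epochs(
    path: str | Path,
    *,
    polarity: np.ndarray | None = None,
    condition: str = "quiet",
) -> EpochMatrix:
    """Read a small CSV fixture: ``sample_ms`` column then one column per epoch.

    The sample rate is inferred from the time axis; negative leading times
    define the pre-stimulus baseline.  Polarity labels default to
    alternating 0,1,0,1,...
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InvalidParameterError("CSV needs a sample_ms column plus epochs")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.median(np.diff(t))
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    n_epochs = data.shape[1]
    if polarity is None:
        polarity = (np.arange(n_epochs) % 2).astype(np.int8)
    return EpochMatrix(
        data=data,
        sample_rate_hz=1000.0 / dt,
        pre_stim_ms=max(0.0, -t[0]),
        polarity=polarity,
        condition=condition,
        seed_provenance=str(path),
    )


def write_wav(stimulus: Stimulus, path: str | Path) -> Path:
    """Write a rendered stimulus as 16-bit WAV."""
    path = Path(path)
    x = stimulus.waveform / max(np.max(np.abs(stimulus.waveform)), 1e-12)
    wavfile.write(path, int(stimulus.sample_rate_hz), (x * 32767).astype(np.int16))
    return path


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def emit_report(
    path: str | Path | None = None,
    *,
    fsp=None,
    presence=None,
    peaks=None,
    itpc=None,
    sweep=None,
    config=None,
    seed: int | None = None,
) -> dict:
    """Combine stage results into one stable JSON report.

    Only blocks for stages that actually ran appear; key order is stable so
    identical runs serialize byte-identically.
    """
    if all(x is None for x in (fsp, presence, peaks, itpc, sweep)):
        raise InvalidParameterError("emit_report needs at least one stage result")
    report: dict = {"schema": "sabr-report-1"}
    if seed is not None:
        report["seed"] = seed
    if config is not None:
        report["config"] = config.echo() if hasattr(config, "echo") else config
    if fsp is not None:
        report["fsp"] = {
            "value": fsp.value,
            "window_ms": list(fsp.window_ms),
            "single_point_ms": fsp.single_point_ms,
            "n_epochs": fsp.n_epochs,
        }
    if presence is not None:
        report["presence"] = {
            "present": presence.present,
            "rule": presence.rule,
            "fsp_value": presence.fsp_value,
            "condition": presence.condition,
        }
    if peaks is not None:
        report["peaks"] = json.loads(
            peaks.to_frame().to_json(orient="records")
        )
    if itpc is not None:
        report["itpc"] = {
            "max_itpc": itpc.max_itpc,
            "fisher_z": itpc.fisher_z,
            "f0_hz": itpc.f0_hz,
            "window_ms": list(itpc.window_ms),
            "n_epochs": itpc.n_epochs,
        }
    if sweep is not None:
        report["sweep"] = sweep.to_dict()
    if path is not None:
        Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report


def render_summary(report: dict) -> str:
    """Short human-readable summary of a report dict."""
    lines = ["sabr run summary", "----------------"]
    if "seed" in report:
        lines.append(f"seed: {report['seed']}")
    if "config" in report and "acquisition" in report["config"]:
        acq = report["config"]["acquisition"]
        lines.append(
            f"acquisition: {acq.get('total_epochs')} epochs planned, "
            f"SNR {acq.get('snr_db')} dB"
        )
    if "fsp" in report:
        f = report["fsp"]
        lines.append(
            f"F_SP = {f['value']:.3f} (window {f['window_ms'][0]}-"
            f"{f['window_ms'][1]} ms, {f['n_epochs']} epochs)"
        )
    if "presence" in report:
        p = report["presence"]
        verdict = "PRESENT" if p["present"] else "ABSENT"
        lines.append(f"response {verdict} by rule: {p['rule']}")
    if "peaks" in report:
        det = [row["label"] for row in report["peaks"] if row["detected"]]
        lines.append(f"peaks detected: {', '.join(det) if det else 'none'}")
    if "itpc" in report:
        i = report["itpc"]
        lines.append(
            f"FFR ITPC max = {i['max_itpc']:.3f} (Fisher-Z {i['fisher_z']:.3f}) "
            f"at {i['f0_hz']} Hz"
        )
    if "sweep" in report:
        s = report["sweep"]
        lines.append(
            f"sweep: min epochs for F_SP criterion = {s['min_epochs_fsp']}, "
            f"for all reference peaks = {s['min_epochs_all_peaks']}"
        )
    return "\n".join(lines)
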