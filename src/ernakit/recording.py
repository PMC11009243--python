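"""Recording container: voltage trace + pulse times + spike times.

The common currency between the synthetic microelectrode generator and
the waveform/spiking analysis.  On disk a recording is a directory of
plain-text files — ``trace.csv`` (one voltage column), ``pulses.csv``,
``spikes.csv`` (one time column each, seconds) and a ``meta.yaml``
sidecar with the sampling rate and site metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ProtocolError


@dataclass
class Recording:
    fs: float                      # sampling rate (Hz), >= 10 kHz for MER-like data
    voltage: np.ndarray            # regularly sampled trace (µV or normalized units)
    pulse_times: np.ndarray        # stimulus onsets (s)
    spike_times: np.ndarray        # action-potential timestamps (s)
    metadata: dict = field(default_factory=dict)  # site, intensity_ua, frequency_hz, ...

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.pulse_times) > 1:
            diffs = np.diff(self.pulse_times)
            if np.any(diffs <= 0):
                raise ProtocolError("pulse_times must be strictly increasing")
            freq = self.metadata.get("frequency_hz")
            if freq:
                if abs(np.median(diffs) - 1.0 / freq) > 0.01 / freq:
                    raise ProtocolError(
                        f"pulse spacing inconsistent with stated {freq} Hz"
                    )

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.fs

    @property
    def prestim_window(self) -> float:
        """Seconds of baseline before the first pulse (whole trace if none)."""
        return float(self.pulse_times[0]) if len(self.pulse_times) else self.duration

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.fs

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "trace.csv", self.voltage, header="voltage", comments="")
        np.savetxt(d / "pulses.csv", self.pulse_times, header="time_s", comments="")
        np.savetxt(d / "spikes.csv", self.spike_times, header="time_s", comments="")
        with open(d / "meta.yaml", "w") as fh:
            yaml.safe_dump({"fs": float(self.fs), "metadata": _plain(self.metadata)}, fh)
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "Recording":
        d = Path(directory)
        with open(d / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            fs=float(meta["fs"]),
            voltage=np.loadtxt(d / "trace.csv", skiprows=1, ndmin=1),
            pulse_times=np.loadtxt(d / "pulses.csv", skiprows=1, ndmin=1),
            spike_times=np.loadtxt(d / "spikes.csv", skiprows=1, ndmin=1),
            metadata=meta.get("metadata", {}),
        )


def _plain(obj):
    """Recursively coerce numpy scalars so YAML stays human-readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
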