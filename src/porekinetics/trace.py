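"""Single-channel current traces and their on-disk dialects.

A recording is a uniformly sampled current time series (pA) with its
sampling rate. Two interchange formats are supported:

* two-column UTF-8 text, one header line ``time_s,current_pa``;
* a little-endian binary dialect: an 8-byte magic ``PKTRACE1``, one
  float64 sampling rate (Hz), then float32 samples (pA).

Vendor acquisition formats (e.g. ABF) are deliberately not parsed here;
:func:`read_trace` is the extension point for adding a reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAGIC = b"PKTRACE1"
TEXT_HEADER = "time_s,current_pa"


@dataclass
class CurrentTrace:
    """A uniformly sampled single-channel current recording.

    Parameters
    ----------
    samples:
        Current samples in pA.
    sampling_rate_hz:
        Sampling frequency in Hz (uniform sampling assumed).
    metadata:
        Free-form recording metadata (e.g. holding voltage in mV, label).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples in one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


def write_trace_text(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace as two-column text with one header line."""
    data = np.column_stack([trace.times_s, trace.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter=",", header=TEXT_HEADER, comments="")


def read_trace_text(path: str | Path) -> CurrentTrace:
    """Read the two-column text dialect; the sampling rate is inferred
    from the first two timestamps."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected two columns (time_s,current_pa)")
    dt = data[1, 0] - data[0, 0]
    if dt <= 0:
        raise ValueError(f"{path}: timestamps are not increasing")
    return CurrentTrace(samples=data[:, 1], sampling_rate_hz=1.0 / dt)


def write_trace_binary(trace: CurrentTrace, path: str | Path) -> None:
    """Write the documented binary dialect (magic, f64 rate, f32 samples)."""
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(np.float64(trace.sampling_rate_hz).tobytes())
        fh.write(trace.samples.astype("<f4").tobytes())


def read_trace_binary(path: str | Path) -> CurrentTrace:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != MAGIC:
            raise ValueError(f"{path}: bad magic {magic!r}, not a {MAGIC.decode()} file")
        rate = np.frombuffer(fh.read(8), dtype="<f8")[0]
        samples = np.frombuffer(fh.read(), dtype="<f4").astype(float)
    return CurrentTrace(samples=samples, sampling_rate_hz=float(rate))


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace, sniffing the dialect from the file's first bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head == MAGIC:
        return read_trace_binary(path)
    return read_trace_text(path)
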