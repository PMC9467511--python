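"""Uniformly sampled single-channel time series container and plain-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TimeSeries", "read_time_series", "write_time_series"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        1-D array of signal samples (arbitrary units).
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray = field(repr=False)
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs


def read_time_series(path, fs: float | None = None) -> TimeSeries:
    """Read a single-column TSV signal with a ``# fs=...`` header line.

    The sampling rate may alternatively be supplied with ``fs``; an
    explicit argument overrides the header. NaN or infinite samples are
    rejected with the offending row indices listed.
    """
    path = Path(path)
    header_fs = None
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs"):
                    header_fs = float(body.split("=", 1)[1])
                continue
            values.append(float(line.split("\t")[0]))
    if fs is None:
        fs = header_fs
    if fs is None:
        raise ValueError(f"{path}: no sampling rate: add a '# fs=...' header or pass fs")
    samples = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"{path}: non-finite samples at rows {shown}"
                         + (" ..." if bad.size > 10 else ""))
    return TimeSeries(samples, fs)


def write_time_series(ts: TimeSeries, path) -> None:
    """Write a signal as single-column TSV with a ``# fs=...`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={ts.fs:g}\n")
        for v in ts.samples:
            fh.write(f"{v:.17g}\n")
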