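"""Spectrogram front-ends: Hann-windowed STFT with n-window averaging and a
complex Morlet wavelet comparator with optional temporal smoothing.

Power is one-sided PSD density (power per Hz), Welch convention: each
windowed segment is normalized by fs * sum(w^2) and non-DC/Nyquist bins are
doubled. A pure cosine of amplitude A at an exact bin frequency therefore
integrates to total power A^2/2 across its bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = ["StftOptions", "Spectrogram", "stft_spectrogram",
           "morlet_spectrogram", "temporal_smooth"]


@dataclass(frozen=True)
class StftOptions:
    """Short-time Fourier settings.

    window_length is the sliding Hann window in seconds (default 1 s),
    overlap_fraction the overlap between neighbours (default 50%),
    n_average the odd number of consecutive windows whose power is averaged
    per time bin (default 5), and freq_range the emitted band in Hz.
    """

    window_length: float = 1.0
    overlap_fraction: float = 0.5
    n_average: int = 5
    freq_range: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.n_average < 1 or self.n_average % 2 == 0:
            raise ValueError("n_average must be odd and >= 1")
        if self.freq_range[0] < 0 or self.freq_range[1] <= self.freq_range[0]:
            raise ValueError("freq_range must be ordered and non-negative")

    @property
    def step(self) -> float:
        """Bin spacing in seconds."""
        return self.window_length * (1 - self.overlap_fraction)


@dataclass(frozen=True)
class Spectrogram:
    """Frequency x time matrix of linear power with axis vectors."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray = field(repr=False)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        times = np.asarray(self.times, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if power.shape != (freqs.size, times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(power)) or np.any(power < 0):
            raise ValueError("power must be finite and non-negative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "power", power)

    def crop_freqs(self, lo: float, hi: float) -> "Spectrogram":
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return Spectrogram(self.freqs[sel], self.times, self.power[sel])

    def to_long_frame(self):
        """Long-format DataFrame with columns time, freq, power."""
        import pandas as pd
        t, f = np.meshgrid(self.times, self.freqs)
        return pd.DataFrame({"time": t.ravel(), "freq": f.ravel(),
                             "power": self.power.ravel()})

    def to_dict(self) -> dict:
        """Compact JSON-ready form: axis vectors + row-major matrix."""
        return {"freqs": self.freqs.tolist(), "times": self.times.tolist(),
                "power": self.power.ravel().tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Spectrogram":
        freqs = np.asarray(d["freqs"], dtype=float)
        times = np.asarray(d["times"], dtype=float)
        power = np.asarray(d["power"], dtype=float).reshape(freqs.size, times.size)
        return cls(freqs, times, power)


def stft_spectrogram(ts: TimeSeries, opts: StftOptions | None = None) -> Spectrogram:
    """Hann-tapered sliding-window PSD spectrogram with n-window averaging.

    Per window the one-sided PSD is computed; each emitted time bin is the
    mean power of ``n_average`` consecutive windows centred on it. Only
    bins with a full complement of windows are kept, so the time axis is
    cropped by (n_average - 1) / 2 windows at each end.
    """
    opts = opts or StftOptions()
    fs = ts.fs
    nperseg = int(round(opts.window_length * fs))
    noverlap = int(round(nperseg * opts.overlap_fraction))
    n_windows = 1 + (ts.n_samples - nperseg) // (nperseg - noverlap) \
        if ts.n_samples >= nperseg else 0
    if n_windows < opts.n_average:
        raise ValueError(
            f"series too short: {n_windows} windows available, "
            f"n_average={opts.n_average} required")
    freqs, times, power = sps.spectrogram(
        ts.samples, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density", mode="psd")
    n = opts.n_average
    if n > 1:
        kernel = np.ones(n) / n
        # centred moving mean, valid bins only
        power = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="valid"), 1, power)
        half = (n - 1) // 2
        times = times[half:len(times) - half]
    sel = (freqs >= opts.freq_range[0]) & (freqs <= opts.freq_range[1])
    return Spectrogram(freqs[sel], times, power[sel])


def morlet_spectrogram(ts: TimeSeries, freqs, central_frequency: float = 3.0,
                       fwhm: float = 1.0, decimate: int = 1) -> Spectrogram:
    """Complex Morlet wavelet power spectrogram.

    The mother wavelet has a Gaussian temporal envelope of full width at
    half maximum ``fwhm`` (seconds) at ``central_frequency``; at frequency
    f the envelope scales by central_frequency / f. The wavelet is
    normalized so a unit-amplitude sinusoid at f yields power 1/2 on the
    ridge. The time grid is the sample grid, optionally decimated.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= ts.fs / 2):
        raise ValueError("freqs must lie within (0, fs/2)")
    fs = ts.fs
    x = ts.samples
    sigma_c = fwhm / (2 * np.sqrt(2 * np.log(2)))
    power = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        sigma_t = sigma_c * central_frequency / f
        half = int(np.ceil(4 * sigma_t * fs))
        tt = np.arange(-half, half + 1) / fs
        env = np.exp(-tt ** 2 / (2 * sigma_t ** 2))
        wavelet = env * np.exp(2j * np.pi * f * tt)
        # response to unit cosine at f: (1/2) * sum(env); normalize to sqrt(1/2)
        wavelet *= np.sqrt(2) / env.sum()
        conv = sps.fftconvolve(x, wavelet, mode="same")
        power[i] = np.abs(conv) ** 2
    times = ts.times
    if decimate > 1:
        power = power[:, ::decimate]
        times = times[::decimate]
    return Spectrogram(freqs, times, power)


def temporal_smooth(spec: Spectrogram, kernel_sd: float,
                    kernel_span: float) -> Spectrogram:
    """Per-frequency Gaussian smoothing along time with edge cropping.

    The kernel is a truncated, renormalized Gaussian of SD ``kernel_sd``
    seconds spanning ``kernel_span`` seconds in total; output bins are
    cropped to the range where the kernel lies fully inside the input
    (kernel_span / 2 removed from each end).
    """
    if kernel_span < 2 * kernel_sd:
        raise ValueError("kernel_span must be >= 2 * kernel_sd")
    dt = float(np.median(np.diff(spec.times)))
    half = int(round(kernel_span / 2 / dt))
    tt = np.arange(-half, half + 1) * dt
    kernel = np.exp(-tt ** 2 / (2 * kernel_sd ** 2))
    kernel /= kernel.sum()
    if spec.times.size < kernel.size:
        raise ValueError("spectrogram shorter than smoothing kernel")
    power = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, spec.power)
    times = spec.times[half:spec.times.size - half]
    return Spectrogram(spec.freqs, times, power)
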