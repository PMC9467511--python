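"""Naturalistic synthetic neural time series with prescribed, time-varying
aperiodic and periodic spectral content, plus their ground truth.

A trial is defined by a target log10-power spectrogram

    S(f, t) = A(f, t) + sum_k env_k(t) * a_k * exp(-(f - cf_k(t))^2 / (2 sd_k^2))

where A is a piecewise-linear-in-time aperiodic trajectory (offset,
exponent, optional constant knee) and each periodic event contributes a
Gaussian in frequency whose amplitude is tapered in time by a Tukey window
(cosine fraction 0.4 by default). The signal is synthesized as a bank of
cosines on the Fourier grid of the trial (frequency spacing 1/duration),

    x(t) = sum_f a_f(t) * cos(2 pi f t + phi_f),
    a_f(t) = sqrt(2 * 10^S(f, t) * df) * |W(f)| / sqrt(E|W|^2),

with independent uniform phases and per-frequency magnitudes drawn from
the Fourier modulus of a white-noise seed series, so the expected PSD of
the signal equals 10^S at every (f, t).

The expensive double sum is evaluated exactly through inverse FFTs on
stationary segments, an exact power-series factorization of the aperiodic
ramp (fixed mode), and dense evaluation restricted to peak patches and
knee-mode ramp columns; the result is numerically identical to the naive
cosine bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "AperiodicTrajectory", "PeakEvent", "GroundTruth", "SimulatedTrial",
    "SimulationError", "build_ground_truth", "synthesize_time_series",
    "make_challenge1", "sample_challenge2", "sample_knee_challenge",
    "draw_challenge2_design", "draw_knee_design",
]

_LN10 = np.log(10.0)


class SimulationError(RuntimeError):
    """Raised when constrained trial sampling cannot satisfy its bounds."""


@dataclass(frozen=True)
class AperiodicTrajectory:
    """Piecewise-linear aperiodic parameter trajectory.

    ``times`` are strictly increasing breakpoints in seconds; ``offsets``
    (log10-power a.u.) and ``exponents`` (Hz^-1) are linearly interpolated
    between them and held constant beyond the ends. ``knee`` is a constant
    per-trial knee parameter (a.u.); None selects the fixed (knee-free)
    aperiodic form.
    """

    times: tuple[float, ...]
    offsets: tuple[float, ...]
    exponents: tuple[float, ...]
    knee: float | None = None

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        offsets = tuple(float(v) for v in self.offsets)
        exponents = tuple(float(v) for v in self.exponents)
        if not len(times) == len(offsets) == len(exponents):
            raise ValueError("times, offsets, exponents must share length")
        if len(times) < 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-empty and strictly increasing")
        if not np.all(np.isfinite(offsets)) or not np.all(np.isfinite(exponents)):
            raise ValueError("trajectory values must be finite")
        if self.knee is not None and self.knee < 0:
            raise ValueError("knee must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "exponents", exponents)

    @classmethod
    def constant(cls, offset: float, exponent: float, knee: float | None = None):
        return cls(times=(0.0,), offsets=(offset,), exponents=(exponent,),
                   knee=knee)

    @classmethod
    def ramp(cls, offset: tuple[float, float], exponent: tuple[float, float],
             interval: tuple[float, float], knee: float | None = None):
        """Single linear shift of offset and exponent over ``interval``."""
        t0, t1 = interval
        return cls(times=(0.0, t0, t1),
                   offsets=(offset[0], offset[0], offset[1]),
                   exponents=(exponent[0], exponent[0], exponent[1]),
                   knee=knee)

    def offset_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.offsets)

    def exponent_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.exponents)

    def value(self, freqs, times) -> np.ndarray:
        """Aperiodic log10 power on the (freqs x times) grid."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        if np.any(freqs <= 0):
            raise ValueError("aperiodic value undefined at f <= 0")
        off = self.offset_at(times)[None, :]
        expo = self.exponent_at(times)[None, :]
        f = freqs[:, None]
        if self.knee is None:
            return off - expo * np.log10(f)
        # f ** expo via exp(expo * ln f): much faster on broadcast grids
        return off - np.log10(self.knee + np.exp(expo * np.log(f)))


@dataclass(frozen=True)
class PeakEvent:
    """A transient periodic component.

    The centre frequency is constant, or chirps linearly from ``cf`` to
    ``cf_end`` inside ``chirp_interval`` (constant on either side of it).
    ``amplitude`` is the log10-power height above the aperiodic curve at
    the envelope plateau; the envelope is a Tukey window over
    [onset, offset_time) with the given cosine fraction.
    """

    cf: float
    amplitude: float
    sd: float
    onset: float
    offset_time: float
    cf_end: float | None = None
    chirp_interval: tuple[float, float] | None = None
    taper_fraction: float = 0.4

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if not self.onset < self.offset_time:
            raise ValueError("onset must precede offset_time")
        if not 0 <= self.taper_fraction <= 1:
            raise ValueError("taper_fraction must be in [0, 1]")
        if (self.cf_end is None) != (self.chirp_interval is None):
            raise ValueError("cf_end and chirp_interval must be given together")

    def cf_at(self, t) -> np.ndarray:
        """Centre frequency across time (linear chirp inside its interval)."""
        t = np.asarray(t, dtype=float)
        if self.cf_end is None:
            return np.full_like(t, self.cf, dtype=float)
        t0, t1 = self.chirp_interval
        s = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        return self.cf + s * (self.cf_end - self.cf)

    def cf_range(self) -> tuple[float, float]:
        cfs = (self.cf,) if self.cf_end is None else (self.cf, self.cf_end)
        return min(cfs), max(cfs)

    def envelope(self, t) -> np.ndarray:
        """Tukey amplitude envelope; zero outside [onset, offset_time)."""
        t = np.asarray(t, dtype=float)
        dur = self.offset_time - self.onset
        x = (t - self.onset) / dur
        env = np.zeros_like(x)
        inside = (x >= 0) & (x < 1)
        r = self.taper_fraction
        xi = x[inside]
        e = np.ones_like(xi)
        if r > 0:
            rise = xi < r / 2
            e[rise] = 0.5 * (1 + np.cos(np.pi * (2 * xi[rise] / r - 1)))
            fall = xi > 1 - r / 2
            e[fall] = 0.5 * (1 + np.cos(np.pi * (2 * (1 - xi[fall]) / r - 1)))
        env[inside] = e
        return env

    def plateau_interval(self) -> tuple[float, float]:
        """Time interval where the envelope equals 1 (Tukey flat top)."""
        dur = self.offset_time - self.onset
        r = self.taper_fraction
        return (self.onset + r / 2 * dur, self.onset + (1 - r / 2) * dur)

    def is_active(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.onset) & (t < self.offset_time)

    def contribution(self, freqs, times) -> np.ndarray:
        """Gaussian log10-power contribution on the (freqs x times) grid."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        times = np.atleast_1d(np.asarray(times, dtype=float))
        env = self.envelope(times)
        cf = self.cf_at(times)
        g = np.exp(-((freqs[:, None] - cf[None, :]) ** 2) / (2 * self.sd ** 2))
        return self.amplitude * env[None, :] * g


@dataclass(frozen=True)
class GroundTruth:
    """A trial's generative description and its target spectrogram.

    The native target grid has frequency spacing 1/duration (the Fourier
    grid of the trial, DC and Nyquist excluded) and time spacing 1/fs. The
    target spectrogram is evaluated lazily via :meth:`spectrogram`, which
    is the exact additive model at every grid point.
    """

    aperiodic: AperiodicTrajectory
    peaks: tuple[PeakEvent, ...]
    duration: float
    fs: float

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def freq_grid(self) -> np.ndarray:
        n = self.n_samples
        return np.arange(1, (n + 1) // 2 if n % 2 else n // 2) / self.duration

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def spectrogram(self, freqs=None, times=None, component: str = "full"):
        """Target log10-power spectrogram on the given (or native) grids."""
        freqs = self.freq_grid if freqs is None else np.asarray(freqs, float)
        times = self.time_grid if times is None else np.asarray(times, float)
        if component not in ("full", "aperiodic", "periodic"):
            raise ValueError(f"unknown component {component!r}")
        if component == "aperiodic":
            return self.aperiodic.value(freqs, times)
        per = np.zeros((freqs.size, times.size))
        for pk in self.peaks:
            per += pk.contribution(freqs, times)
        if component == "periodic":
            return per
        return self.aperiodic.value(freqs, times) + per


@dataclass(frozen=True)
class SimulatedTrial:
    """A synthesized time series with its ground truth and seed."""

    series: TimeSeries
    truth: GroundTruth
    seed: int | None = None


def build_ground_truth(aperiodic: AperiodicTrajectory, peaks, duration: float,
                       fs: float) -> GroundTruth:
    """Assemble and validate a trial's generative description."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    peaks = tuple(peaks)
    for i, pk in enumerate(peaks):
        lo, hi = pk.cf_range()
        if not (0 < lo and hi < fs / 2):
            raise ValueError(
                f"peak event {i} (cf {lo:g}-{hi:g} Hz) outside (0, {fs / 2:g}) Hz")
        if pk.onset < 0 or pk.offset_time > duration:
            raise ValueError(
                f"peak event {i} ([{pk.onset:g}, {pk.offset_time:g}] s) "
                f"outside [0, {duration:g}] s")
    return GroundTruth(aperiodic=aperiodic, peaks=peaks,
                       duration=float(duration), fs=float(fs))


# ---------------------------------------------------------------------------
# synthesis

def _irfft_cosines(coeffs: np.ndarray, n: int) -> np.ndarray:
    """sum_k Re(coeffs_k * exp(2i pi k t/n)) for k = 1..len(coeffs), via irfft."""
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[1:1 + coeffs.size] = coeffs
    return 0.5 * n * np.fft.irfft(spec, n)

_FREQ_CHUNK = 1024
_TIME_CHUNK = 4000


def _dense_cosine_sum(amps: np.ndarray, freqs: np.ndarray, phases: np.ndarray,
                      t: np.ndarray) -> np.ndarray:
    """sum_f amps[f, t] * cos(2 pi f t + phi_f), chunked over frequency."""
    out = np.zeros(t.size)
    for i in range(0, freqs.size, _FREQ_CHUNK):
        sl = slice(i, i + _FREQ_CHUNK)
        phase = 2 * np.pi * freqs[sl, None] * t[None, :] + phases[sl, None]
        out += np.einsum("ft,ft->t", amps[sl], np.cos(phase))
    return out


def synthesize_time_series(truth: GroundTruth, rng,
                           lowfreq_plateau: float = 0.8) -> TimeSeries:
    """Synthesize the cosine-bank realization of a ground-truth spectrogram.

    ``rng`` is a seeded numpy Generator; it is consumed in a fixed order
    (white-noise seed series first, then cosine phases), so identical
    seeds reproduce the trial bit for bit.

    Below ``lowfreq_plateau`` (Hz) the aperiodic curve is held at its
    plateau value instead of following its diverging 1/f form: real neural
    spectra flatten at very low frequencies, and letting the synthetic
    background diverge below the analysis band leaks spurious power into
    the lowest analyzed bins through the STFT window. The default 0.8 Hz
    makes the 1 s Hann-window power kernel unbiased at a 1 Hz analysis
    bin (computed from the kernel; the residual is < 0.01 log10 units for
    exponents 1.5-2). The target spectrogram at and above 1 Hz is
    unaffected.
    """
    fs, duration = truth.fs, truth.duration
    n = truth.n_samples
    freqs = truth.freq_grid
    df = 1.0 / duration
    t = truth.time_grid

    white = rng.standard_normal(n)
    mods = np.abs(np.fft.rfft(white))[1:1 + freqs.size]
    # E|W_k|^2 = n for unit-variance white noise -> unit expected power factor
    base = mods / np.sqrt(n) * np.sqrt(2 * df)
    phases = rng.uniform(0.0, 2 * np.pi, freqs.size)
    coeffs = base * np.exp(1j * phases)

    x = np.zeros(n)
    traj = truth.aperiodic
    f_ap = np.maximum(freqs, lowfreq_plateau)  # aperiodic plateau below floor
    log10f = np.log10(f_ap)

    # --- aperiodic background, per trajectory segment
    breaks = np.unique(np.clip(np.asarray(traj.times), 0.0, duration))
    breaks = np.unique(np.concatenate([[0.0, duration], breaks]))
    cache: dict[tuple, np.ndarray] = {}
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        i0, i1 = int(np.ceil(ta * fs - 1e-9)), int(np.ceil(tb * fs - 1e-9))
        if i1 <= i0:
            continue
        cols = slice(i0, min(i1, n))
        o0, o1 = float(traj.offset_at(ta)), float(traj.offset_at(tb))
        e0, e1 = float(traj.exponent_at(ta)), float(traj.exponent_at(tb))
        if np.isclose(o0, o1) and np.isclose(e0, e1):
            key = (round(o0, 12), round(e0, 12))
            if key not in cache:
                if traj.knee is None:
                    shape = np.exp(0.5 * _LN10 * (o0 - e0 * log10f))
                else:
                    shape = np.exp(0.5 * _LN10
                                   * (o0 - np.log10(traj.knee + f_ap ** e0)))
                cache[key] = _irfft_cosines(coeffs * shape, n)
            x[cols] = cache[key][cols]
        elif traj.knee is None:
            # exact separable factorization: amp = base0(f) * exp(s(t) w(f))
            shape0 = 10 ** ((o0 - e0 * log10f) / 2)
            w = 0.5 * _LN10 * ((o1 - o0) - (e1 - e0) * log10f)
            wmax = float(np.max(np.abs(w)))
            s = (t[cols] - ta) / (tb - ta)
            if wmax <= 8.0:
                term = coeffs * shape0
                acc = np.zeros(s.size)
                spow = np.ones_like(s)
                j = 0
                tail = 1.0  # wmax^j / j!, bounds the dropped series remainder
                while True:
                    acc += spow * _irfft_cosines(term, n)[cols]
                    j += 1
                    tail *= wmax / j
                    if (j > 4 and tail < 1e-13) or j > 80:
                        break
                    term = term * (w / j)
                    spow = spow * s
                x[cols] = acc
            else:  # extreme ramp: dense fallback
                A = (o0 + s[None, :] * (o1 - o0)) \
                    - (e0 + s[None, :] * (e1 - e0)) * log10f[:, None]
                x[cols] = _dense_cosine_sum(
                    base[:, None] * np.exp(0.5 * _LN10 * A),
                    freqs, phases, t[cols])
        else:
            # knee-mode ramp: dense evaluation on the shift columns
            tc = t[cols]
            for j0 in range(0, tc.size, _TIME_CHUNK):
                sub = slice(j0, j0 + _TIME_CHUNK)
                A = traj.value(f_ap, tc[sub])
                x[cols.start + j0:cols.start + j0 + A.shape[1]] += \
                    _dense_cosine_sum(base[:, None] * np.exp(0.5 * _LN10 * A),
                                      freqs, phases, tc[sub])

    # --- periodic events: dense patches over clusters that overlap in both
    # time and frequency (joint patches keep the additive log-power model
    # exact where Gaussians overlap); Gaussians are truncated at 5 SD,
    # where the remaining amplitude correction is below 4e-6
    if truth.peaks:
        rects = []
        for pk in truth.peaks:
            lo, hi = pk.cf_range()
            rects.append((lo - 5 * pk.sd, hi + 5 * pk.sd, pk.onset, pk.offset_time))
        n_pk = len(rects)
        parent = list(range(n_pk))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a in range(n_pk):
            for b in range(a + 1, n_pk):
                fa, fb = rects[a], rects[b]
                if fa[0] < fb[1] and fb[0] < fa[1] and fa[2] < fb[3] and fb[2] < fa[3]:
                    parent[find(a)] = find(b)
        clusters: dict[int, list[int]] = {}
        for a in range(n_pk):
            clusters.setdefault(find(a), []).append(a)

        for members in clusters.values():
            f_lo = max(min(rects[m][0] for m in members), freqs[0])
            f_hi = min(max(rects[m][1] for m in members), freqs[-1])
            t_lo = max(min(rects[m][2] for m in members), 0.0)
            t_hi = min(max(rects[m][3] for m in members), duration)
            fsel = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
            i0 = int(np.ceil(t_lo * fs - 1e-9))
            i1 = min(int(np.ceil(t_hi * fs - 1e-9)), n)
            if fsel.size == 0 or i1 <= i0:
                continue
            fband = freqs[fsel]
            for j0 in range(i0, i1, _TIME_CHUNK):
                j1 = min(j0 + _TIME_CHUNK, i1)
                tc = t[j0:j1]
                P = np.zeros((fband.size, tc.size))
                for m in members:
                    P += truth.peaks[m].contribution(fband, tc)
                A = traj.value(np.maximum(fband, lowfreq_plateau), tc)
                amps = (base[fsel, None] * np.exp(0.5 * _LN10 * A)
                        * np.expm1(0.5 * _LN10 * P))
                x[j0:j1] += _dense_cosine_sum(amps, fband, phases[fsel], tc)

    return TimeSeries(x, fs)


# ---------------------------------------------------------------------------
# challenge designs

def _as_rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng, None
    return np.random.default_rng(seed_or_rng), int(seed_or_rng)


def make_challenge1(seed) -> SimulatedTrial:
    """The fixed transient/chirp design (60 s at 200 Hz).

    Aperiodic exponent 1.5 -> 2.0 Hz^-1 and offset -2.56 -> -1.41 a.u.,
    both shifting linearly over 24-36 s. Alpha activity (8 Hz, 1.2 a.u.,
    SD 1.2 Hz) over 8-40, 41-46 and 47-52 s; beta activity (1.4 Hz SD,
    0.9 a.u.) over 15-25 s, down-chirping 18 -> 15 Hz between 18 and 22 s.
    """
    rng, seed_val = _as_rng(seed)
    traj = AperiodicTrajectory(times=(0.0, 24.0, 36.0),
                               offsets=(-2.56, -2.56, -1.41),
                               exponents=(1.5, 1.5, 2.0))
    alpha = dict(cf=8.0, amplitude=1.2, sd=1.2)
    peaks = (
        PeakEvent(onset=8.0, offset_time=40.0, **alpha),
        PeakEvent(onset=41.0, offset_time=46.0, **alpha),
        PeakEvent(onset=47.0, offset_time=52.0, **alpha),
        PeakEvent(cf=18.0, cf_end=15.0, chirp_interval=(18.0, 22.0),
                  amplitude=0.9, sd=1.4, onset=15.0, offset_time=25.0),
    )
    truth = build_ground_truth(traj, peaks, duration=60.0, fs=200.0)
    return SimulatedTrial(synthesize_time_series(truth, rng), truth, seed_val)


def _sample_nonoverlapping_cf(rng, accepted, cf_lo, cf_hi, sd, onset, offset,
                              max_attempts):
    """Draw a centre frequency at least 2.5 max-SDs away from every
    temporally overlapping accepted peak."""
    for _ in range(max_attempts):
        cf = rng.uniform(cf_lo, cf_hi)
        ok = all(not (pk.onset < offset and onset < pk.offset_time)
                 or abs(cf - pk.cf) >= 2.5 * max(sd, pk.sd)
                 for pk in accepted)
        if ok:
            return cf
    raise SimulationError(
        f"could not place a peak in [{cf_lo}, {cf_hi}] Hz at >= 2.5 SD "
        f"separation after {max_attempts} attempts")


def draw_challenge2_design(rng, duration: float = 60.0,
                           max_attempts: int = 1000):
    """Draw one randomized-parameter design (trajectory + peak events)."""
    e0 = rng.uniform(0.8, 2.2)
    o0 = rng.uniform(-8.1, -1.5)
    de = rng.uniform(-0.5, 0.5)
    do = rng.uniform(-1.0, 1.0)
    t0 = rng.uniform(12.0, 36.0)
    shift_dur = rng.uniform(6.0, 24.0)
    traj = AperiodicTrajectory.ramp(offset=(o0, o0 + do),
                                    exponent=(e0, e0 + de),
                                    interval=(t0, t0 + shift_dur))
    n_peaks = int(rng.integers(0, 5))
    peaks: list[PeakEvent] = []
    for _ in range(n_peaks):
        amp = rng.uniform(0.6, 1.6)
        sd = rng.uniform(1.0, 2.0)
        onset = rng.uniform(5.0, 40.0)
        dur = rng.uniform(3.0, 20.0)
        cf = _sample_nonoverlapping_cf(rng, peaks, 3.0, 35.0, sd, onset,
                                       onset + dur, max_attempts)
        peaks.append(PeakEvent(cf=float(cf), amplitude=float(amp),
                               sd=float(sd), onset=float(onset),
                               offset_time=float(onset + dur)))
    return traj, tuple(peaks)


def sample_challenge2(seed, duration: float = 60.0, fs: float = 200.0,
                      max_attempts: int = 1000) -> SimulatedTrial:
    """Randomized-parameter trial: uniform aperiodic/periodic parameters.

    Exponent init 0.8-2.2 Hz^-1, offset init -8.1..-1.5 a.u.; both shift
    linearly by -0.5..0.5 Hz^-1 / -1..1 a.u., onset 12-36 s, duration
    6-24 s. 0-4 peaks with cf 3-35 Hz, amplitude 0.6-1.6 a.u., SD 1-2 Hz,
    onset 5-40 s, duration 3-20 s; temporally overlapping peaks are at
    least 2.5 max-SDs apart in centre frequency (rejection-resampled).
    """
    rng, seed_val = _as_rng(seed)
    traj, peaks = draw_challenge2_design(rng, duration, max_attempts)
    truth = build_ground_truth(traj, peaks, duration=duration, fs=fs)
    return SimulatedTrial(synthesize_time_series(truth, rng), truth, seed_val)


def draw_knee_design(rng, max_attempts: int = 1000):
    """Draw one knee-challenge design (trajectory + two peak events)."""
    e0 = rng.uniform(0.8, 2.2)
    o0 = rng.uniform(-8.1, -1.5)
    knee_freq = rng.uniform(0.0, 30.0)
    knee = float(knee_freq ** e0)
    de = rng.uniform(-0.5, 0.5)
    do = rng.uniform(-1.0, 1.0)
    t0 = rng.uniform(12.0, 36.0)
    shift_dur = rng.uniform(1.0, 20.0)
    traj = AperiodicTrajectory.ramp(offset=(o0, o0 + do),
                                    exponent=(e0, e0 + de),
                                    interval=(t0, t0 + shift_dur), knee=knee)
    peaks: list[PeakEvent] = []
    for cf_lo, cf_hi in ((3.0, 30.0), (30.0, 80.0)):
        amp = rng.uniform(0.6, 1.6)
        sd = rng.uniform(1.0, 2.0)
        onset = rng.uniform(5.0, 25.0)
        offset = rng.uniform(35.0, 55.0)
        cf = _sample_nonoverlapping_cf(rng, peaks, cf_lo, cf_hi, sd, onset,
                                       offset, max_attempts)
        peaks.append(PeakEvent(cf=float(cf), amplitude=float(amp),
                               sd=float(sd), onset=float(onset),
                               offset_time=float(offset)))
    return traj, tuple(peaks)


def sample_knee_challenge(seed, duration: float = 60.0, fs: float = 200.0,
                          max_attempts: int = 1000) -> SimulatedTrial:
    """Knee-aperiodic trial: constant knee, two peaks in 3-30 / 30-80 Hz.

    The knee frequency f_k is uniform on 0-30 Hz and stored as the knee
    parameter k = f_k**chi using the trial's initial exponent chi. The
    aperiodic shift lasts 1-20 s; peak onsets are 5-25 s with offsets
    35-55 s and at least 2.5 max-SD centre-frequency separation.
    """
    rng, seed_val = _as_rng(seed)
    traj, peaks = draw_knee_design(rng, max_attempts)
    truth = build_ground_truth(traj, peaks, duration=duration, fs=fs)
    return SimulatedTrial(synthesize_time_series(truth, rng), truth, seed_val)
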