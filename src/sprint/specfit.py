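"""Parameterization of a power spectrum into aperiodic and periodic components.

The model decomposes a log10 power spectrum into a broadband aperiodic
component and a set of Gaussian peaks:

    log10 P(f) = L(f) + sum_k  a_k * exp(-(f - cf_k)^2 / (2 sd_k^2))

with the aperiodic component in "fixed" mode

    L(f) = offset - exponent * log10(f)

or, when a spectral bend is present, in "knee" mode

    L(f) = offset - log10(knee + f^exponent).

Fitting follows the sequential specparam strategy: a robust aperiodic fit,
iterative peak extraction from the flattened spectrum, joint Gaussian
refinement, proximity-based pruning, and a final aperiodic refit on the
peak-subtracted spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "AperiodicParams", "Peak", "FitOptions", "SpectralFit",
    "aperiodic_value", "gaussian_value", "robust_aperiodic_fit",
    "extract_peaks", "refit_gaussians", "prune_peaks",
    "parameterize_spectrum", "goodness_of_fit", "SpectralModel",
]

#: exponent acceptance window for knee-mode fits; bins outside are flagged
KNEE_EXPONENT_RANGE = (-5.0, 5.0)

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class AperiodicParams:
    """Aperiodic (1/f-like) component parameters.

    offset is in log10-power a.u., the exponent in Hz^-1 (the paper's
    convention for the negative log-log slope), and knee is the bend
    parameter of the knee form (absent in fixed mode).
    """

    offset: float
    exponent: float
    knee: float | None = None
    mode: str = "fixed"

    def __post_init__(self):
        if self.mode not in ("fixed", "knee"):
            raise ValueError(f"unknown aperiodic mode {self.mode!r}")
        if self.mode == "knee":
            if self.knee is None:
                raise ValueError("knee mode requires a knee parameter")
            if self.knee < 0:
                raise ValueError("knee must be >= 0")
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")

    @property
    def knee_frequency(self) -> float | None:
        """Knee frequency f_k = knee**(1/exponent), when defined."""
        if self.mode != "knee" or self.knee is None:
            return None
        if self.knee <= 0 or self.exponent <= 0:
            return 0.0 if self.knee == 0 else None
        return float(self.knee ** (1.0 / self.exponent))


@dataclass(frozen=True)
class Peak:
    """A Gaussian periodic component: centre frequency (Hz), amplitude
    (log10-power a.u. above the aperiodic curve), and SD (Hz)."""

    cf: float
    amplitude: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("peak sd must be > 0")
        if self.amplitude <= 0:
            raise ValueError("peak amplitude must be > 0")


@dataclass(frozen=True)
class FitOptions:
    """Settings of the spectral parameterization.

    Defaults follow the benchmark configuration for narrow-band analysis:
    1-40 Hz, at most 3 peaks of width 0.5-6 Hz, minimum peak amplitude
    0.6 a.u., peak threshold 2 SD of the flattened spectrum, proximity
    threshold 2 SD, fixed aperiodic mode.
    """

    freq_range: tuple[float, float] = (1.0, 40.0)
    peak_width_limits: tuple[float, float] = (0.5, 6.0)
    max_n_peaks: int = 3
    min_peak_height: float = 0.6
    peak_threshold: float = 2.0
    proximity_threshold: float = 2.0
    aperiodic_mode: str = "fixed"
    robust_percentile: float = 2.5

    def __post_init__(self):
        if self.freq_range[0] <= 0 or self.freq_range[1] <= self.freq_range[0]:
            raise ValueError("freq_range must be ordered and positive")
        if not 0 < self.peak_width_limits[0] < self.peak_width_limits[1]:
            raise ValueError("peak_width_limits must be ordered and positive")
        if self.max_n_peaks < 0 or self.min_peak_height < 0:
            raise ValueError("max_n_peaks and min_peak_height must be >= 0")
        if self.peak_threshold < 0 or self.proximity_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.aperiodic_mode not in ("fixed", "knee"):
            raise ValueError(f"unknown aperiodic mode {self.aperiodic_mode!r}")

    @property
    def gauss_sd_limits(self) -> tuple[float, float]:
        """Gaussian SD bounds = peak width (FWHM-like) limits halved."""
        return (self.peak_width_limits[0] / 2, self.peak_width_limits[1] / 2)


@dataclass(frozen=True)
class SpectralFit:
    """One spectrum's parameterization with goodness-of-fit."""

    aperiodic: AperiodicParams
    peaks: tuple[Peak, ...]
    mae: float
    r_squared: float
    time: float | None = None
    status: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        """True when the fit carries no warning flags."""
        return not self.status

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Modelled log10 power: aperiodic value plus all peak Gaussians."""
        return aperiodic_value(self.aperiodic, freqs) + peak_model(self.peaks, freqs)

    def aperiodic_model(self, freqs: np.ndarray) -> np.ndarray:
        return aperiodic_value(self.aperiodic, freqs)


def aperiodic_value(p: AperiodicParams, f) -> np.ndarray:
    """Evaluate the aperiodic component (log10 power) at frequencies f > 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("aperiodic component is undefined at f <= 0")
    if p.mode == "fixed":
        return p.offset - p.exponent * np.log10(f)
    return p.offset - np.log10(p.knee + f ** p.exponent)


def gaussian_value(pk: Peak, f) -> np.ndarray:
    """Evaluate one peak Gaussian (log10 power above the aperiodic curve)."""
    f = np.asarray(f, dtype=float)
    return pk.amplitude * np.exp(-((f - pk.cf) ** 2) / (2 * pk.sd ** 2))


def peak_model(peaks, f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    for pk in peaks:
        out += gaussian_value(pk, f)
    return out


def goodness_of_fit(modelled_log, data_log) -> tuple[float, float]:
    """MAE and R^2 (squared Pearson correlation) of modelled vs data log power.

    R^2 is NaN when the data has zero variance (undefined correlation);
    the MAE is still returned.
    """
    modelled_log = np.asarray(modelled_log, dtype=float)
    data_log = np.asarray(data_log, dtype=float)
    if modelled_log.shape != data_log.shape:
        raise ValueError("modelled and data vectors must have equal length")
    mae = float(np.mean(np.abs(modelled_log - data_log)))
    if np.std(data_log) == 0 or np.std(modelled_log) == 0:
        return mae, float("nan")
    r = np.corrcoef(modelled_log, data_log)[0, 1]
    return mae, float(r ** 2)


# ---------------------------------------------------------------------------
# aperiodic fitting

def _ap_fun(x, mode, freqs, log10f):
    if mode == "fixed":
        return x[0] - x[1] * log10f
    return x[0] - np.log10(x[1] + freqs ** x[2])


def _fit_ap_fixed(log10f, log_power):
    """Closed form: the fixed aperiodic form is linear in (offset, exponent)."""
    u = log10f - log10f.mean()
    denom = float(u @ u)
    exponent = -float(u @ (log_power - log_power.mean())) / denom \
        if denom > 0 else 0.0
    exponent = float(np.clip(exponent, -20.0, 20.0))
    offset = float(np.mean(log_power + exponent * log10f))
    return np.array([offset, exponent]), True


def _fit_ap_knee(freqs, log_power, x0):
    """Knee-mode fit by bounded trust-region least squares with analytic
    Jacobian (the knee enters additively; trust-region steps from a small
    knee reach large-knee solutions reliably, which compiled unconstrained
    Levenberg-Marquardt on transformed variables does not)."""
    lnf = np.log(freqs)
    log10f = np.log10(freqs)

    def resid(x):
        return _ap_fun(x, "knee", freqs, log10f) - log_power

    def jac(x):
        fchi = freqs ** x[2]
        denom = _LN10 * (x[1] + fchi)
        return np.column_stack([np.ones_like(freqs), -1.0 / denom,
                                -fchi * lnf / denom])

    bounds = ([-np.inf, 0.0, -20.0], [np.inf, np.inf, 20.0])
    x0 = np.clip(x0, bounds[0], bounds[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(resid, x0, jac=jac, bounds=bounds, max_nfev=500,
                            xtol=1e-7)
    return res.x, bool(res.success)


def _fit_ap(freqs, log_power, mode, x0):
    if mode == "fixed":
        return _fit_ap_fixed(np.log10(freqs), log_power)
    return _fit_ap_knee(freqs, log_power, x0)


def _params_to_x(p: AperiodicParams) -> np.ndarray:
    if p.mode == "fixed":
        return np.array([p.offset, p.exponent])
    return np.array([p.offset, p.knee, p.exponent])


def _x_to_params(x, mode) -> AperiodicParams:
    if mode == "fixed":
        return AperiodicParams(offset=float(x[0]), exponent=float(x[1]))
    return AperiodicParams(offset=float(x[0]), exponent=float(x[2]),
                           knee=float(max(x[1], 0.0)), mode="knee")


def _cold_start(freqs, log_power, mode):
    span = np.log10(freqs[-1]) - np.log10(freqs[0])
    slope = abs(log_power[0] - log_power[-1]) / span if span > 0 else 1.0
    if mode == "fixed":
        return np.array([log_power[0], slope])
    return np.array([log_power[0], 0.0, slope])


def robust_aperiodic_fit(freqs, log_power, mode="fixed",
                         init_exponent=None, robust_percentile=2.5):
    """Two-stage robust fit of the aperiodic component.

    Stage 1 fits all points by bounded least squares, warm-starting the
    exponent when ``init_exponent`` is given (otherwise from the endpoint
    log-log slope). Stage 2 flattens the spectrum, clips negative residuals
    to zero, keeps the points at or below the ``robust_percentile`` of the
    positive residuals (so peak regions are excluded), and refits. A
    non-converged optimizer yields the stage-1 estimate flagged with
    ``'aperiodic_fit_warning'``.
    """
    freqs = np.asarray(freqs, dtype=float)
    log_power = np.asarray(log_power, dtype=float)
    if freqs.size < 5:
        raise ValueError("need at least 5 frequency points")
    x0 = _cold_start(freqs, log_power, mode)
    if init_exponent is not None:
        x0[-1] = init_exponent
    x1, ok1 = _fit_ap(freqs, log_power, mode, x0)

    flat = log_power - _ap_fun(x1, mode, freqs, np.log10(freqs))
    flat = np.where(flat < 0, 0.0, flat)
    pos = flat[flat > 0]
    thresh = np.percentile(pos, robust_percentile) if pos.size else 0.0
    mask = flat <= thresh
    n_params = 2 if mode == "fixed" else 3
    status = []
    if mask.sum() >= n_params + 2:
        x2, ok2 = _fit_ap(freqs[mask], log_power[mask], mode, x1)
    else:
        x2, ok2 = x1, ok1
    if not ok2:
        x2 = x1
        status.append("aperiodic_fit_warning")
    if mode == "fixed":
        p = AperiodicParams(offset=float(x2[0]), exponent=float(x2[1]))
    else:
        p = AperiodicParams(offset=float(x2[0]), exponent=float(x2[2]),
                            knee=float(max(x2[1], 0.0)), mode="knee")
    return (p, tuple(status)) if status else (p, ())


# ---------------------------------------------------------------------------
# peak extraction and refinement

def extract_peaks(freqs, flattened, opts: FitOptions) -> list[Peak]:
    """Iteratively extract Gaussian peak guesses from a flattened spectrum.

    The tallest point is taken while it exceeds both ``peak_threshold`` SDs
    of the current flattened spectrum and ``min_peak_height``; its SD is
    guessed from the half-height width (clipped to the width limits), the
    guess Gaussian subtracted, and the search repeated up to
    ``max_n_peaks``. Equal maxima resolve to the lower frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    flat = np.array(flattened, dtype=float)
    sd_lo, sd_hi = opts.gauss_sd_limits
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    guesses: list[Peak] = []
    while len(guesses) < opts.max_n_peaks:
        ind = int(np.argmax(flat))  # first (lowest-frequency) max on ties
        height = flat[ind]
        if height <= max(opts.peak_threshold * np.std(flat), opts.min_peak_height):
            break
        cf = freqs[ind]
        half = height / 2
        le = next((i for i in range(ind - 1, -1, -1) if flat[i] <= half), None)
        ri = next((i for i in range(ind + 1, len(flat)) if flat[i] <= half), None)
        sides = [abs(ind - i) for i in (le, ri) if i is not None]
        if sides:
            fwhm = 2 * min(sides) * df
            sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
        else:
            sd = (sd_lo + sd_hi) / 2
        sd = float(np.clip(sd, sd_lo, sd_hi))
        guesses.append(Peak(cf=float(cf), amplitude=float(height), sd=sd))
        flat -= gaussian_value(guesses[-1], freqs)
    return guesses


def refit_gaussians(freqs, flattened, guesses, opts: FitOptions,
                    cf_bound_sd: float = 2.0):
    """Jointly refine all peak guesses by bounded least squares.

    Centre frequencies are bounded to guess +- ``cf_bound_sd`` guess SDs
    (clipped to the fitted range) to prevent peak migration; SDs are held
    within the width limits. Optimizer failure falls back to the guesses
    with an ``'peak_fit_warning'`` status.
    """
    if not guesses:
        return [], ()
    freqs = np.asarray(freqs, dtype=float)
    flattened = np.asarray(flattened, dtype=float)
    sd_lo, sd_hi = opts.gauss_sd_limits
    f_lo, f_hi = freqs[0], freqs[-1]
    x0, lo, hi = [], [], []
    for g in guesses:
        x0 += [g.cf, g.amplitude, g.sd]
        lo += [max(f_lo, g.cf - cf_bound_sd * g.sd), 1e-8, sd_lo]
        hi += [min(f_hi, g.cf + cf_bound_sd * g.sd), np.inf, sd_hi]
    x0 = np.clip(x0, lo, hi)

    def resid(x):
        model = np.zeros_like(freqs)
        for k in range(0, len(x), 3):
            cf, amp, sd = x[k], x[k + 1], x[k + 2]
            model += amp * np.exp(-((freqs - cf) ** 2) / (2 * sd ** 2))
        return model - flattened

    def jac(x):
        J = np.empty((freqs.size, len(x)))
        for k in range(0, len(x), 3):
            cf, amp, sd = x[k], x[k + 1], x[k + 2]
            d = freqs - cf
            g = np.exp(-d ** 2 / (2 * sd ** 2))
            J[:, k] = amp * g * d / sd ** 2
            J[:, k + 1] = g
            J[:, k + 2] = amp * g * d ** 2 / sd ** 3
        return J

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(resid, x0, jac=jac, bounds=(lo, hi), max_nfev=1000,
                            xtol=1e-7)
    if not res.success:
        return list(guesses), ("peak_fit_warning",)
    out = [Peak(cf=float(res.x[k]), amplitude=float(max(res.x[k + 1], 1e-8)),
                sd=float(res.x[k + 2]))
           for k in range(0, len(res.x), 3)]
    return out, ()


def prune_peaks(peaks, opts: FitOptions, freq_range) -> list[Peak]:
    """Drop edge-hugging and overlapping peaks, repeated until stable.

    A peak is dropped when its centre frequency lies closer than
    ``proximity_threshold`` * its SD to either edge of ``freq_range``, and
    for any pair closer than ``proximity_threshold`` * max(SD) in centre
    frequency the lower-amplitude peak is dropped. Surviving peaks are
    never altered.
    """
    lo, hi = freq_range
    thr = opts.proximity_threshold
    peaks = [p for p in peaks
             if (p.cf - lo) >= thr * p.sd and (hi - p.cf) >= thr * p.sd]
    stable = False
    while not stable:
        stable = True
        order = sorted(range(len(peaks)), key=lambda i: peaks[i].cf)
        drop = None
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                i, j = order[a], order[b]
                if abs(peaks[i].cf - peaks[j].cf) < thr * max(peaks[i].sd, peaks[j].sd):
                    # lower amplitude loses; ties resolve to higher frequency
                    if peaks[i].amplitude < peaks[j].amplitude:
                        drop = i
                    elif peaks[j].amplitude < peaks[i].amplitude:
                        drop = j
                    else:
                        drop = i if peaks[i].cf > peaks[j].cf else j
                    break
            if drop is not None:
                break
        if drop is not None:
            peaks = [p for k, p in enumerate(peaks) if k != drop]
            stable = False
    return peaks


# ---------------------------------------------------------------------------
# full pipeline

def parameterize_spectrum(freqs, power, opts: FitOptions | None = None,
                          warm_start_exponent=None, time=None) -> SpectralFit:
    """Parameterize one power spectrum (linear power, f > 0).

    Pipeline: log10 -> robust aperiodic fit -> flatten -> peak extraction
    -> joint Gaussian refit -> pruning -> final aperiodic refit on the
    peak-subtracted spectrum -> goodness of fit (MAE, R^2). When
    ``warm_start_exponent`` is given, the first aperiodic fit starts from
    it (used for bin-to-bin tracking).
    """
    opts = opts or FitOptions()
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive on the fitted range")
    log_power = np.log10(power)

    ap1, st1 = robust_aperiodic_fit(freqs, log_power, opts.aperiodic_mode,
                                    init_exponent=warm_start_exponent,
                                    robust_percentile=opts.robust_percentile)
    flat = log_power - aperiodic_value(ap1, freqs)
    guesses = extract_peaks(freqs, flat, opts)
    peaks, st2 = refit_gaussians(freqs, flat, guesses, opts)
    peaks = prune_peaks(peaks, opts, (freqs[0], freqs[-1]))

    # self-consistency refinement: the stage-1 aperiodic estimate is made
    # with the peaks still in the spectrum, which biases the flattened
    # spectrum the peaks are fit to; alternate a plain aperiodic fit of the
    # peak-subtracted spectrum with a peak refit against its flattened
    # spectrum until the peak parameters settle
    ap2 = ap1
    last_change = np.inf
    for _ in range(6 if peaks else 0):
        prev = np.array([v for pk in peaks for v in (pk.cf, pk.amplitude, pk.sd)])
        x, _ok = _fit_ap(freqs, log_power - peak_model(peaks, freqs),
                         opts.aperiodic_mode, _params_to_x(ap2))
        ap2 = _x_to_params(x, opts.aperiodic_mode)
        flat = log_power - aperiodic_value(ap2, freqs)
        peaks, st2b = refit_gaussians(freqs, flat, peaks, opts)
        peaks = prune_peaks(peaks, opts, (freqs[0], freqs[-1]))
        st2 = tuple(st2) + tuple(st2b)
        cur = np.array([v for pk in peaks for v in (pk.cf, pk.amplitude, pk.sd)])
        if cur.size != prev.size:
            continue
        change = np.max(np.abs(cur - prev), initial=0)
        # stop when settled, or when the alternation stops contracting
        # (it then only tracks the residual noise, not the fixed point)
        if change < 1e-4 or change > 0.7 * last_change:
            break
        last_change = change
    # final aperiodic fit: plain bounded least squares on the
    # peak-subtracted spectrum (all points contribute; the robust
    # lower-envelope stage is only used to expose peaks, since fitting the
    # lower envelope of a noisy spectrum biases the offset downward)
    pk_model = peak_model(peaks, freqs)
    x, ok_final = _fit_ap(freqs, log_power - pk_model, opts.aperiodic_mode,
                          _params_to_x(ap2))
    ap2 = _x_to_params(x, opts.aperiodic_mode)
    st3 = () if ok_final else ("aperiodic_fit_warning",)
    status = tuple(st1) + tuple(st2) + tuple(st3)
    if opts.aperiodic_mode == "knee" and not (
            KNEE_EXPONENT_RANGE[0] < ap2.exponent < KNEE_EXPONENT_RANGE[1]):
        status = status + ("exponent_out_of_range",)
    model = aperiodic_value(ap2, freqs) + pk_model
    mae, r2 = goodness_of_fit(model, log_power)
    return SpectralFit(aperiodic=ap2, peaks=tuple(peaks), mae=mae,
                       r_squared=r2, time=time, status=status)


class SpectralModel(BaseEstimator):
    """Estimator interface to the spectral parameterization engine.

    Mirrors :class:`FitOptions` as constructor parameters and exposes the
    fitted decomposition through trailing-underscore attributes, so it can
    be cloned and configured with the scikit-learn parameter API.

    Examples
    --------
    >>> freqs = np.arange(1.0, 41.0)
    >>> power = 10 ** (-2.0 - 1.5 * np.log10(freqs))
    >>> m = SpectralModel().fit(freqs, power)
    >>> round(m.aperiodic_.exponent, 3)
    1.5
    """

    def __init__(self, freq_range=(1.0, 40.0), peak_width_limits=(0.5, 6.0),
                 max_n_peaks=3, min_peak_height=0.6, peak_threshold=2.0,
                 proximity_threshold=2.0, aperiodic_mode="fixed",
                 robust_percentile=2.5):
        self.freq_range = freq_range
        self.peak_width_limits = peak_width_limits
        self.max_n_peaks = max_n_peaks
        self.min_peak_height = min_peak_height
        self.peak_threshold = peak_threshold
        self.proximity_threshold = proximity_threshold
        self.aperiodic_mode = aperiodic_mode
        self.robust_percentile = robust_percentile

    def _options(self) -> FitOptions:
        return FitOptions(
            freq_range=tuple(self.freq_range),
            peak_width_limits=tuple(self.peak_width_limits),
            max_n_peaks=self.max_n_peaks,
            min_peak_height=self.min_peak_height,
            peak_threshold=self.peak_threshold,
            proximity_threshold=self.proximity_threshold,
            aperiodic_mode=self.aperiodic_mode,
            robust_percentile=self.robust_percentile,
        )

    def fit(self, freqs, power, warm_start_exponent=None):
        """Fit one spectrum; frequencies outside ``freq_range`` are cropped."""
        freqs = np.asarray(freqs, dtype=float)
        power = np.asarray(power, dtype=float)
        opts = self._options()
        lo, hi = opts.freq_range
        sel = (freqs >= lo) & (freqs <= hi)
        fit = parameterize_spectrum(freqs[sel], power[sel], opts,
                                    warm_start_exponent=warm_start_exponent)
        self.freqs_ = freqs[sel]
        self.aperiodic_ = fit.aperiodic
        self.peaks_ = fit.peaks
        self.mae_ = fit.mae
        self.r_squared_ = fit.r_squared
        self.status_ = fit.status
        self.fit_ = fit
        return self

    def predict(self, freqs) -> np.ndarray:
        """Modelled log10 power at the given frequencies."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("SpectralModel is not fitted")
        return self.fit_.model(np.asarray(freqs, dtype=float))
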