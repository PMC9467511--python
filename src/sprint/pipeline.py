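"""Time-resolved spectral parameterization: per-bin fitting with exponent
warm-starting across time, and pruning of outlier transient peaks with
aperiodic refit at the modified bins."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .spectral import Spectrogram, StftOptions, stft_spectrogram
from .specfit import (FitOptions, SpectralFit, aperiodic_value, peak_model,
                      goodness_of_fit, parameterize_spectrum,
                      robust_aperiodic_fit, KNEE_EXPONENT_RANGE)
from .timeseries import TimeSeries

__all__ = ["OutlierOptions", "ParameterizedSpectrogram", "run_sprint",
           "remove_outlier_peaks", "parameterize_spectrogram", "SPRiNT"]


@dataclass(frozen=True)
class OutlierOptions:
    """Outlier-peak pruning settings: a peak needs at least ``n_required``
    similar peaks (centre frequency within ``freq_bound`` Hz) among the
    bins up to ``time_bound`` bins away (both sides) to survive."""

    n_required: int = 3
    freq_bound: float = 2.5
    time_bound: int = 6

    def __post_init__(self):
        if self.n_required < 0 or self.freq_bound < 0 or self.time_bound < 0:
            raise ValueError("outlier options must be >= 0")


@dataclass(frozen=True)
class ParameterizedSpectrogram:
    """Time-ordered spectral fits with their source spectrogram."""

    fits: tuple[SpectralFit, ...]
    spectrogram: Spectrogram = field(repr=False)
    options: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.array([f.time for f in self.fits], dtype=float)
        if times.size != self.spectrogram.times.size or \
                not np.allclose(times, self.spectrogram.times):
            raise ValueError("fit times must equal the spectrogram bin centres")

    @property
    def freqs(self) -> np.ndarray:
        return self.spectrogram.freqs

    @property
    def times(self) -> np.ndarray:
        return self.spectrogram.times

    @property
    def n_bins(self) -> int:
        return len(self.fits)

    def ok_mask(self) -> np.ndarray:
        """Bins without warning flags (used for downstream aggregation)."""
        return np.array([f.ok for f in self.fits], dtype=bool)

    def exponents(self) -> np.ndarray:
        return np.array([f.aperiodic.exponent for f in self.fits])

    def offsets(self) -> np.ndarray:
        return np.array([f.aperiodic.offset for f in self.fits])

    def knees(self) -> np.ndarray:
        return np.array([f.aperiodic.knee if f.aperiodic.knee is not None
                         else np.nan for f in self.fits])

    def maes(self) -> np.ndarray:
        return np.array([f.mae for f in self.fits])

    def peak_table(self) -> pd.DataFrame:
        """Long-format peak table: bin, time, cf, amplitude, sd."""
        rows = [(i, f.time, pk.cf, pk.amplitude, pk.sd)
                for i, f in enumerate(self.fits) for pk in f.peaks]
        return pd.DataFrame(rows, columns=["bin", "time", "cf", "amplitude", "sd"])

    def model_spectrogram(self, component: str = "full") -> np.ndarray:
        """Modelled log10-power matrix (freq x time) by component."""
        freqs = self.freqs
        out = np.empty((freqs.size, self.n_bins))
        for i, f in enumerate(self.fits):
            if component == "aperiodic":
                out[:, i] = aperiodic_value(f.aperiodic, freqs)
            elif component == "periodic":
                out[:, i] = peak_model(f.peaks, freqs)
            elif component == "full":
                out[:, i] = f.model(freqs)
            else:
                raise ValueError(f"unknown component {component!r}")
        return out


def parameterize_spectrogram(spec: Spectrogram, fit_opts: FitOptions,
                             warm_start: bool = False,
                             provenance: dict | None = None,
                             ) -> ParameterizedSpectrogram:
    """Parameterize each time bin of a spectrogram.

    With ``warm_start`` the aperiodic exponent of bin t initializes from
    bin t-1's estimate (the first bin is cold-started); otherwise all bins
    are fitted independently (the wavelet-comparator path). Per-bin fit
    warnings are collected in the fit statuses and never abort the run.
    """
    lo, hi = fit_opts.freq_range
    spec = spec.crop_freqs(lo, hi)
    fits = []
    prev_exponent = None
    for i, tbin in enumerate(spec.times):
        fit = parameterize_spectrum(
            spec.freqs, spec.power[:, i], fit_opts,
            warm_start_exponent=prev_exponent if warm_start else None,
            time=float(tbin))
        fits.append(fit)
        if warm_start:
            prev_exponent = fit.aperiodic.exponent
    return ParameterizedSpectrogram(
        fits=tuple(fits), spectrogram=spec,
        options={"fit": fit_opts.__dict__.copy(), "warm_start": warm_start},
        provenance=provenance or {})


def run_sprint(ts: TimeSeries, stft_opts: StftOptions | None = None,
               fit_opts: FitOptions | None = None,
               outlier_opts: OutlierOptions | None = None,
               provenance: dict | None = None) -> ParameterizedSpectrogram:
    """Full pipeline: STFT spectrogram -> sequential warm-started per-bin
    parameterization -> optional outlier-peak pruning with aperiodic refit."""
    stft_opts = stft_opts or StftOptions()
    fit_opts = fit_opts or FitOptions(freq_range=stft_opts.freq_range)
    spec = stft_spectrogram(ts, stft_opts)
    prov = {"fs": ts.fs, "n_samples": ts.n_samples}
    prov.update(provenance or {})
    ps = parameterize_spectrogram(spec, fit_opts, warm_start=True,
                                  provenance=prov)
    ps = replace(ps, options={**ps.options, "stft": stft_opts.__dict__.copy(),
                              "outlier": (outlier_opts.__dict__.copy()
                                          if outlier_opts else None)})
    if outlier_opts is not None:
        ps = remove_outlier_peaks(ps, outlier_opts)
    return ps


def remove_outlier_peaks(ps: ParameterizedSpectrogram,
                         opts: OutlierOptions | None = None,
                         ) -> ParameterizedSpectrogram:
    """Remove transient peaks lacking enough similar neighbours in time.

    For every peak, the number of other peaks with centre frequency within
    ``freq_bound`` Hz among bins at most ``time_bound`` bins away (own bin
    included) is counted on the *original* peak set; all removal marks are
    then applied in a single pass, so removals cannot cascade. At modified
    bins the aperiodic component is refit against the spectrum minus the
    surviving peak model and the goodness of fit recomputed. Aperiodic
    parameters at unmodified bins are untouched.
    """
    opts = opts or OutlierOptions()
    bins = np.array([i for i, f in enumerate(ps.fits) for _ in f.peaks])
    cfs = np.array([pk.cf for f in ps.fits for pk in f.peaks])
    if bins.size == 0:
        return ps
    keep = np.empty(bins.size, dtype=bool)
    for k in range(bins.size):
        near = (np.abs(bins - bins[k]) <= opts.time_bound) \
            & (np.abs(cfs - cfs[k]) <= opts.freq_bound)
        near[k] = False
        keep[k] = near.sum() >= opts.n_required
    if keep.all():
        return ps

    fit_opts_d = ps.options.get("fit", {})
    mode = fit_opts_d.get("aperiodic_mode", ps.fits[0].aperiodic.mode)
    percentile = fit_opts_d.get("robust_percentile", 2.5)
    new_fits = list(ps.fits)
    idx = 0
    for i, fit in enumerate(ps.fits):
        n_here = len(fit.peaks)
        if n_here == 0:
            continue
        k_here = keep[idx:idx + n_here]
        idx += n_here
        if k_here.all():
            continue
        surviving = tuple(pk for pk, k in zip(fit.peaks, k_here) if k)
        log_power = np.log10(ps.spectrogram.power[:, i])
        pk_mod = peak_model(surviving, ps.freqs)
        ap, st = robust_aperiodic_fit(ps.freqs, log_power - pk_mod, mode,
                                      init_exponent=fit.aperiodic.exponent,
                                      robust_percentile=percentile)
        status = tuple(s for s in fit.status if s != "exponent_out_of_range") \
            + tuple(st)
        if mode == "knee" and not (KNEE_EXPONENT_RANGE[0] < ap.exponent
                                   < KNEE_EXPONENT_RANGE[1]):
            status = status + ("exponent_out_of_range",)
        model = aperiodic_value(ap, ps.freqs) + pk_mod
        mae, r2 = goodness_of_fit(model, log_power)
        new_fits[i] = replace(fit, aperiodic=ap, peaks=surviving, mae=mae,
                              r_squared=r2, status=status)
    return replace(ps, fits=tuple(new_fits))


class SPRiNT(BaseEstimator):
    """Estimator interface to the full time-resolved parameterization.

    Parameters mirror the STFT, fitting and pruning options; ``fit``
    accepts a :class:`TimeSeries` (or a 1-D array together with the ``fs``
    parameter) and exposes the result through trailing-underscore
    attributes (``result_``, ``exponent_``, ``offset_``, ``times_``).
    """

    def __init__(self, fs=None, window_length=1.0, overlap_fraction=0.5,
                 n_average=5, freq_range=(1.0, 40.0),
                 peak_width_limits=(0.5, 6.0), max_n_peaks=3,
                 min_peak_height=0.6, peak_threshold=2.0,
                 proximity_threshold=2.0, aperiodic_mode="fixed",
                 robust_percentile=2.5, prune_outliers=True,
                 outlier_n_required=3, outlier_freq_bound=2.5,
                 outlier_time_bound=6):
        self.fs = fs
        self.window_length = window_length
        self.overlap_fraction = overlap_fraction
        self.n_average = n_average
        self.freq_range = freq_range
        self.peak_width_limits = peak_width_limits
        self.max_n_peaks = max_n_peaks
        self.min_peak_height = min_peak_height
        self.peak_threshold = peak_threshold
        self.proximity_threshold = proximity_threshold
        self.aperiodic_mode = aperiodic_mode
        self.robust_percentile = robust_percentile
        self.prune_outliers = prune_outliers
        self.outlier_n_required = outlier_n_required
        self.outlier_freq_bound = outlier_freq_bound
        self.outlier_time_bound = outlier_time_bound

    def _option_objects(self):
        stft = StftOptions(window_length=self.window_length,
                           overlap_fraction=self.overlap_fraction,
                           n_average=self.n_average,
                           freq_range=tuple(self.freq_range))
        fit = FitOptions(freq_range=tuple(self.freq_range),
                         peak_width_limits=tuple(self.peak_width_limits),
                         max_n_peaks=self.max_n_peaks,
                         min_peak_height=self.min_peak_height,
                         peak_threshold=self.peak_threshold,
                         proximity_threshold=self.proximity_threshold,
                         aperiodic_mode=self.aperiodic_mode,
                         robust_percentile=self.robust_percentile)
        outlier = OutlierOptions(n_required=self.outlier_n_required,
                                 freq_bound=self.outlier_freq_bound,
                                 time_bound=self.outlier_time_bound) \
            if self.prune_outliers else None
        return stft, fit, outlier

    def fit(self, X, y=None):
        """Run the pipeline on a time series."""
        if isinstance(X, TimeSeries):
            ts = X
        else:
            if self.fs is None:
                raise ValueError("pass a TimeSeries or set fs")
            ts = TimeSeries(np.asarray(X, dtype=float).ravel(), self.fs)
        stft, fopt, outlier = self._option_objects()
        self.result_ = run_sprint(ts, stft, fopt, outlier)
        self.times_ = self.result_.times
        self.freqs_ = self.result_.freqs
        self.exponent_ = self.result_.exponents()
        self.offset_ = self.result_.offsets()
        return self

    def peak_table(self) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("SPRiNT is not fitted")
        return self.result_.peak_table()
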