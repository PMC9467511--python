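"""Tests of peak matching, detection statistics and the challenge harness."""

import numpy as np
import pytest

from sprint.benchmark import (ALPHA_BAND, band_peak_series, detection_stats,
                              match_peaks, parameter_mae, run_challenge,
                              spectrogram_mae)
from sprint.pipeline import ParameterizedSpectrogram
from sprint.sim import (AperiodicTrajectory, PeakEvent, build_ground_truth)
from sprint.specfit import (AperiodicParams, Peak, SpectralFit,
                            aperiodic_value)
from sprint.spectral import Spectrogram


def _ps_with(peak_lists, t0=1.5, step=0.5):
    freqs = np.arange(1.0, 41.0)
    times = t0 + step * np.arange(len(peak_lists))
    ap = AperiodicParams(offset=-2.0, exponent=1.5)
    power = np.tile(10 ** aperiodic_value(ap, freqs)[:, None], (1, times.size))
    fits = tuple(SpectralFit(aperiodic=ap, peaks=tuple(pks), mae=0.0,
                             r_squared=1.0, time=float(t))
                 for t, pks in zip(times, peak_lists))
    return ParameterizedSpectrogram(fits=fits,
                                    spectrogram=Spectrogram(freqs, times, power))


def _truth_with(events):
    traj = AperiodicTrajectory.constant(-2.0, 1.5)
    return build_ground_truth(traj, events, duration=60.0, fs=200.0)


ALPHA_EVENT = PeakEvent(cf=8.0, amplitude=1.2, sd=1.2, onset=0.0,
                        offset_time=60.0, taper_fraction=0.0)


class TestMatchPeaks:
    def test_within_tolerance_is_correct(self):
        ps = _ps_with([[Peak(cf=8.4, amplitude=1.0, sd=1.2)]])
        m = match_peaks(ps, _truth_with([ALPHA_EVENT]))
        assert [x.classification for x in m] == ["correct"]

    def test_far_peak_is_incorrect_and_event_missed(self):
        ps = _ps_with([[Peak(cf=20.0, amplitude=1.0, sd=1.2)]])
        m = match_peaks(ps, _truth_with([ALPHA_EVENT]))
        assert sorted(x.classification for x in m) == ["incorrect", "missed"]

    def test_largest_amplitude_candidate_wins(self):
        ps = _ps_with([[Peak(cf=7.5, amplitude=0.7, sd=1.0),
                        Peak(cf=8.5, amplitude=1.1, sd=1.0)]])
        m = match_peaks(ps, _truth_with([ALPHA_EVENT]))
        correct = [x for x in m if x.classification == "correct"]
        assert len(correct) == 1
        assert ps.fits[0].peaks[correct[0].peak_index].amplitude == 1.1
        assert sum(x.classification == "incorrect" for x in m) == 1

    def test_estimated_peak_maps_to_one_event_only(self):
        ev2 = PeakEvent(cf=13.0, amplitude=1.0, sd=1.2, onset=0.0,
                        offset_time=60.0, taper_fraction=0.0)
        ps = _ps_with([[Peak(cf=10.5, amplitude=1.0, sd=1.0)]])
        m = match_peaks(ps, _truth_with([ALPHA_EVENT, ev2]))
        assert sum(x.classification == "correct" for x in m) == 1
        assert sum(x.classification == "missed" for x in m) == 1

    def test_matching_invariant_to_peak_order(self):
        peaks = [Peak(cf=7.5, amplitude=0.7, sd=1.0),
                 Peak(cf=8.5, amplitude=1.1, sd=1.0)]
        truth = _truth_with([ALPHA_EVENT])
        m1 = match_peaks(_ps_with([peaks]), truth)
        m2 = match_peaks(_ps_with([peaks[::-1]]), truth)
        assert sorted(x.classification for x in m1) == \
            sorted(x.classification for x in m2)


class TestBandPeakSeries:
    def test_highest_amplitude_in_band(self):
        ps = _ps_with([[Peak(cf=8.0, amplitude=1.2, sd=1.0),
                        Peak(cf=9.0, amplitude=0.8, sd=1.0)]])
        series = band_peak_series(ps, ALPHA_BAND)
        assert series[0].cf == 8.0

    def test_no_in_band_peak_is_absent(self):
        ps = _ps_with([[Peak(cf=20.0, amplitude=1.2, sd=1.0)], []])
        assert band_peak_series(ps, ALPHA_BAND) == [None, None]


class TestDetectionStats:
    def test_perfect_detector(self):
        ps = _ps_with([[Peak(cf=8.0, amplitude=1.2, sd=1.2)]] * 10)
        truth = _truth_with([PeakEvent(cf=8.0, amplitude=1.2, sd=1.2,
                                       onset=0.0, offset_time=60.0,
                                       taper_fraction=0.0)])
        m = match_peaks(ps, truth)
        sens, spec = detection_stats(m, truth, "all_bins")
        assert sens == 100.0 and spec == 100.0

    def test_silent_detector_in_plateau_mode(self):
        ps = _ps_with([[]] * 10)
        ev = PeakEvent(cf=8.0, amplitude=1.2, sd=1.2, onset=2.0,
                       offset_time=4.0)
        truth = _truth_with([ev])
        sens, spec = detection_stats([], truth, "plateau", ps=ps,
                                     band=ALPHA_BAND)
        assert sens == 0.0 and spec == 100.0

    def test_hand_counted_fixture(self, detection_table):
        """10 bins, event active at 6, detections miss 2 of them and add
        one false alarm: sensitivity 4/6, specificity 3/4."""
        active, detected = detection_table
        peak_lists = [[Peak(cf=8.0, amplitude=1.0, sd=1.0)] if d else []
                      for d in detected]
        ps = _ps_with(peak_lists, t0=0.25, step=0.5)
        t_on = ps.times[2] - 0.01
        t_off = ps.times[7] + 0.01
        ev = PeakEvent(cf=8.0, amplitude=1.0, sd=1.0, onset=t_on,
                       offset_time=t_off, taper_fraction=0.0)
        truth = _truth_with([ev])
        m = match_peaks(ps, truth)
        sens, spec = detection_stats(m, truth, "all_bins")
        assert sens == pytest.approx(100 * 4 / 6)
        assert spec == pytest.approx(100 * 4 / 5)  # 4 correct of 5 fitted
        sens_p, spec_p = detection_stats(m, truth, "plateau", ps=ps,
                                         band=ALPHA_BAND)
        assert sens_p == pytest.approx(100 * 4 / 6)
        assert spec_p == pytest.approx(100 * 3 / 4)

    def test_empty_denominator_is_undefined(self):
        truth = _truth_with([])
        sens, spec = detection_stats([], truth, "all_bins")
        assert sens is None and spec is None


class TestParameterMae:
    def test_exact_estimates_give_zero(self):
        ps = _ps_with([[Peak(cf=8.0, amplitude=1.2, sd=1.2)]] * 4)
        truth = _truth_with([PeakEvent(cf=8.0, amplitude=1.2, sd=1.2,
                                       onset=0.0, offset_time=60.0,
                                       taper_fraction=0.0)])
        out = parameter_mae(match_peaks(ps, truth), ps, truth)
        for key in ("exponent_mae", "offset_mae", "cf_mae", "amplitude_mae",
                    "sd_mae"):
            assert out[key] == pytest.approx(0.0, abs=1e-12)

    def test_constant_exponent_bias(self):
        ps = _ps_with([[]] * 5)
        truth = _truth_with([])
        truth_shift = build_ground_truth(
            AperiodicTrajectory.constant(-2.0, 1.6), [], 60.0, 200.0)
        out = parameter_mae([], ps, truth_shift)
        assert out["exponent_mae"] == pytest.approx(0.1)
        assert out["cf_mae"] is None

    def test_three_bin_hand_arithmetic(self):
        """Peak cf errors 0.2, 0.4, 0.0 -> MAE 0.2; amplitude error uses
        the tapered truth amplitude."""
        ev = PeakEvent(cf=8.0, amplitude=1.0, sd=1.0, onset=0.0,
                       offset_time=60.0, taper_fraction=0.0)
        ps = _ps_with([[Peak(cf=8.2, amplitude=1.0, sd=1.0)],
                       [Peak(cf=7.6, amplitude=1.0, sd=1.0)],
                       [Peak(cf=8.0, amplitude=0.7, sd=1.5)]])
        truth = _truth_with([ev])
        out = parameter_mae(match_peaks(ps, truth), ps, truth)
        assert out["cf_mae"] == pytest.approx((0.2 + 0.4 + 0.0) / 3)
        assert out["amplitude_mae"] == pytest.approx(0.3 / 3)
        assert out["sd_mae"] == pytest.approx(0.5 / 3)


class TestSpectrogramMae:
    def test_identical_and_offset(self):
        a = np.ones((3, 4))
        assert spectrogram_mae(a, a) == 0.0
        assert spectrogram_mae(a + 0.5, a) == pytest.approx(0.5)

    def test_two_by_two_hand_value(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = np.array([[0.5, 1.0], [1.0, 3.0]])
        assert spectrogram_mae(a, b) == pytest.approx((0.5 + 0 + 1 + 0) / 4)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            spectrogram_mae(np.ones((2, 2)), np.ones((2, 3)))


class TestRunChallenge:
    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            run_challenge("1", 0, 0)

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="engine"):
            run_challenge("1", 1, 0, engine="fourier")

    def test_static_engine_restricted_to_challenge1(self):
        with pytest.raises(ValueError, match="static"):
            run_challenge("2", 1, 0, engine="static")

    def test_single_trial_report_structure(self):
        r = run_challenge("1", 1, 7)
        assert r.n_trials == 1 and r.challenge == "1"
        assert 0 <= r.extras["alpha_sensitivity"] <= 100
        assert r.exponent_mae >= 0 and r.spectrogram_mae >= 0

    def test_shared_trials_across_engines(self):
        """A sequence of engines analyses identical simulated trials and
        returns one report per engine."""
        rr = run_challenge("1", 1, 7, engine=("sprint", "static"))
        assert set(rr) == {"sprint", "static"}
        assert rr["static"].extras["mean_exponent"] is not None

    def test_wavelet_comparator_detects_plateau_alpha(self):
        """The smoothed Morlet comparator finds the alpha peak on its
        plateau bins of a transient/chirp trial."""
        r = run_challenge("1", 1, 7, engine="wavelet")
        assert r.extras["alpha_sensitivity"] > 50.0
        assert r.exponent_mae is not None
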