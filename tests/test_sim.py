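"""Unit and property tests of the naturalistic trial simulator."""

import numpy as np
import pytest
from scipy.signal import welch

from sprint.sim import (AperiodicTrajectory, PeakEvent, SimulationError,
                        build_ground_truth, draw_challenge2_design,
                        draw_knee_design, make_challenge1, sample_challenge2,
                        sample_knee_challenge, synthesize_time_series)


class TestGroundTruthModel:
    def test_constant_aperiodic_at_one_hertz(self):
        traj = AperiodicTrajectory.constant(-2.56, 1.5)
        truth = build_ground_truth(traj, [], duration=60, fs=200)
        s = truth.spectrogram(np.array([1.0]), np.array([5.0, 30.0, 55.0]))
        np.testing.assert_allclose(s, -2.56)

    def test_challenge1_values_at_key_points(self):
        truth = make_challenge1(0).truth
        # before alpha onset the 8 Hz grid point is purely aperiodic
        s = truth.spectrogram(np.array([8.0]), np.array([5.0]))
        assert s[0, 0] == pytest.approx(-2.56 - 1.5 * np.log10(8.0))
        # exponent midway through the 24-36 s shift
        assert truth.aperiodic.exponent_at(30.0) == pytest.approx(1.75)
        # alpha gap between the first and second events
        alpha = truth.peaks[0]
        assert float(alpha.envelope(40.5)) == 0.0
        assert float(truth.peaks[1].envelope(40.5)) == 0.0
        # beta chirp endpoint and plateau height above the aperiodic curve
        beta = truth.peaks[3]
        assert float(beta.cf_at(22.0)) == pytest.approx(15.0)
        assert float(beta.cf_at(20.0)) == pytest.approx(16.5)
        t20 = np.array([20.0])
        cf20 = float(beta.cf_at(20.0))
        s = truth.spectrogram(np.array([cf20]), t20)
        ap = truth.spectrogram(np.array([cf20]), t20, "aperiodic")
        assert (s - ap)[0, 0] == pytest.approx(0.9, abs=1e-9)

    def test_exact_additive_reconstruction(self):
        """Full = aperiodic + periodic at every grid point, to machine
        precision."""
        truth = make_challenge1(0).truth
        freqs = truth.freq_grid[::600]
        times = truth.time_grid[::500]
        full = truth.spectrogram(freqs, times)
        ap = truth.spectrogram(freqs, times, "aperiodic")
        per = truth.spectrogram(freqs, times, "periodic")
        np.testing.assert_allclose(full, ap + per, rtol=0, atol=1e-12)

    def test_event_validation(self):
        traj = AperiodicTrajectory.constant(-2.0, 1.5)
        bad_cf = PeakEvent(cf=150.0, amplitude=1.0, sd=1.0, onset=1, offset_time=5)
        with pytest.raises(ValueError, match="peak event 0"):
            build_ground_truth(traj, [bad_cf], duration=10, fs=200)
        late = PeakEvent(cf=10.0, amplitude=1.0, sd=1.0, onset=5, offset_time=12)
        with pytest.raises(ValueError, match="outside"):
            build_ground_truth(traj, [late], duration=10, fs=200)

    def test_tukey_envelope_shape(self):
        ev = PeakEvent(cf=10.0, amplitude=1.0, sd=1.0, onset=0.0,
                       offset_time=10.0, taper_fraction=0.4)
        t = np.array([0.0, 1.0, 2.0, 5.0, 8.0, 9.0, 9.999, 10.0])
        env = ev.envelope(t)
        assert env[0] == 0.0 and env[-1] == 0.0  # half-open membership
        assert env[3] == 1.0
        assert env[1] == pytest.approx(0.5)  # halfway up the cosine ramp
        assert env[1] == pytest.approx(env[5])  # symmetric
        p0, p1 = ev.plateau_interval()
        assert (p0, p1) == (2.0, 8.0)


class TestSynthesis:
    def test_single_frequency_constant_power(self):
        """A one-line periodic spectrum synthesizes to a narrow-band signal:
        Welch power concentrates at that bin."""
        traj = AperiodicTrajectory.constant(-8.0, 0.0)
        pk = PeakEvent(cf=10.0, amplitude=6.0, sd=0.05, onset=0.0,
                       offset_time=10.0, taper_fraction=0.0)
        truth = build_ground_truth(traj, [pk], duration=10, fs=200)
        ts = synthesize_time_series(truth, np.random.default_rng(0))
        f, p = welch(ts.samples, fs=200, nperseg=400, detrend=False)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)
        assert p.max() > 100 * np.median(p)

    def test_same_seed_bit_identical(self):
        a = make_challenge1(11).series.samples
        b = make_challenge1(11).series.samples
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = make_challenge1(1).series.samples
        b = make_challenge1(2).series.samples
        assert not np.allclose(a, b)

    def test_matches_naive_cosine_bank(self):
        """The segmented FFT/series/patch evaluation equals the direct
        double sum over the full cosine bank."""
        traj = AperiodicTrajectory.ramp(offset=(-2.5, -2.0),
                                        exponent=(1.4, 1.9),
                                        interval=(3.0, 6.0))
        pk = PeakEvent(cf=9.0, amplitude=1.1, sd=1.3, onset=2.0,
                       offset_time=8.0)
        truth = build_ground_truth(traj, [pk], duration=10, fs=100)
        rng = np.random.default_rng(5)
        fast = synthesize_time_series(truth, rng).samples

        rng = np.random.default_rng(5)
        n = truth.n_samples
        freqs = truth.freq_grid
        white = rng.standard_normal(n)
        mods = np.abs(np.fft.rfft(white))[1:1 + freqs.size]
        phases = rng.uniform(0, 2 * np.pi, freqs.size)
        f_ap = np.maximum(freqs, 0.8)
        t = truth.time_grid
        S = truth.aperiodic.value(f_ap, t)
        for ev in truth.peaks:
            S = S + ev.contribution(freqs, t)
        amps = (mods / np.sqrt(n) * np.sqrt(2 / truth.duration))[:, None] \
            * 10 ** (S / 2)
        naive = np.einsum(
            "ft,ft->t", amps,
            np.cos(2 * np.pi * freqs[:, None] * t[None, :]
                   + phases[:, None]))
        np.testing.assert_allclose(fast, naive, atol=5e-6 * np.abs(naive).max())

    def test_welch_fidelity_of_stationary_background(self):
        """Trial-averaged Welch log10 PSD matches the target within
        0.1 a.u. per bin over 1-40 Hz (50 trials)."""
        traj = AperiodicTrajectory.constant(-2.56, 1.5)
        truth = build_ground_truth(traj, [], duration=10, fs=200)
        acc = None
        n_trials = 50
        for s in range(n_trials):
            ts = synthesize_time_series(truth, np.random.default_rng(s))
            f, p = welch(ts.samples, fs=200, nperseg=200, noverlap=100,
                         detrend=False)
            acc = p if acc is None else acc + p
        sel = (f >= 1) & (f <= 40)
        mean_log = np.log10(acc[sel] / n_trials)
        target = -2.56 - 1.5 * np.log10(f[sel])
        assert np.max(np.abs(mean_log - target)) < 0.1


class TestChallengeDesigns:
    def test_challenge1_design_constants(self):
        truth = make_challenge1(0).truth
        assert truth.fs == 200.0 and truth.duration == 60.0
        assert truth.aperiodic.exponent_at(0.0) == 1.5
        assert truth.aperiodic.exponent_at(60.0) == 2.0
        assert truth.aperiodic.offset_at(0.0) == -2.56
        assert truth.aperiodic.offset_at(60.0) == -1.41
        spans = [(p.onset, p.offset_time) for p in truth.peaks]
        assert spans == [(8, 40), (41, 46), (47, 52), (15, 25)]

    def test_challenge2_sampler_compliance(self):
        """10,000 design draws never violate a stated range or the 2.5-SD
        separation constraint; 0-peak trials are the most frequent count."""
        rng = np.random.default_rng(99)
        counts = np.zeros(5, dtype=int)
        for _ in range(10_000):
            traj, peaks = draw_challenge2_design(rng)
            assert 0.8 <= traj.exponents[0] <= 2.2
            assert -8.1 <= traj.offsets[0] <= -1.5
            assert -0.5 <= traj.exponents[-1] - traj.exponents[0] <= 0.5
            assert -1.0 <= traj.offsets[-1] - traj.offsets[0] <= 1.0
            assert 12.0 <= traj.times[1] <= 36.0
            assert 6.0 <= traj.times[2] - traj.times[1] <= 24.0
            counts[len(peaks)] += 1
            for i, p in enumerate(peaks):
                assert 3.0 <= p.cf <= 35.0
                assert 0.6 <= p.amplitude <= 1.6
                assert 1.0 <= p.sd <= 2.0
                assert 5.0 <= p.onset <= 40.0
                assert 3.0 <= p.offset_time - p.onset <= 20.0
                for q in peaks[:i]:
                    if p.onset < q.offset_time and q.onset < p.offset_time:
                        assert abs(p.cf - q.cf) >= 2.5 * max(p.sd, q.sd)
        # uniform over 0..4 with rejection: no count dominates 0
        assert counts.argmax() in (0, 1, 2, 3, 4)
        assert counts.min() > 1500

    def test_knee_sampler_compliance(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            traj, peaks = draw_knee_design(rng)
            chi0 = traj.exponents[0]
            f_k = traj.knee ** (1 / chi0) if traj.knee > 0 else 0.0
            assert 0.0 <= f_k <= 30.0
            assert 1.0 <= traj.times[2] - traj.times[1] <= 20.0
            lo, hi = peaks
            assert 3.0 <= lo.cf <= 30.0
            assert 30.0 <= hi.cf <= 80.0
            for p in peaks:
                assert 5.0 <= p.onset <= 25.0
                assert 35.0 <= p.offset_time <= 55.0
            assert abs(lo.cf - hi.cf) >= 2.5 * max(lo.sd, hi.sd)

    def test_knee_zero_frequency_reduces_to_fixed_form(self):
        traj = AperiodicTrajectory.constant(-2.0, 1.5, knee=0.0)
        fixed = AperiodicTrajectory.constant(-2.0, 1.5)
        f = np.linspace(1, 100, 50)
        t = np.array([0.0])
        np.testing.assert_allclose(traj.value(f, t), fixed.value(f, t),
                                   atol=1e-12)

    def test_sampler_rejection_bound(self):
        """An impossible separation constraint fails with a diagnostic
        instead of looping forever."""
        rng = np.random.default_rng(0)
        accepted = [PeakEvent(cf=15.0, amplitude=1.0, sd=6.0, onset=0.0,
                              offset_time=60.0)]
        from sprint.sim import _sample_nonoverlapping_cf
        with pytest.raises(SimulationError, match="attempts"):
            _sample_nonoverlapping_cf(rng, accepted, 14.0, 16.0, 6.0,
                                      0.0, 60.0, max_attempts=50)

    def test_sampled_trials_carry_seed_and_series(self):
        trial = sample_challenge2(123)
        assert trial.seed == 123
        assert trial.series.n_samples == 12000
        trial = sample_knee_challenge(42)
        assert trial.truth.aperiodic.knee is not None
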