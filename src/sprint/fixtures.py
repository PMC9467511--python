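"""Deterministic small fixtures shared by the test suite and the CLI."""

from __future__ import annotations

import numpy as np

from .sim import (AperiodicTrajectory, PeakEvent, build_ground_truth,
                  synthesize_time_series, SimulatedTrial)
from .specfit import AperiodicParams, Peak, aperiodic_value, peak_model

__all__ = ["make_fixtures", "short_transient_trial", "noiseless_model_spectrum",
           "detection_fixture"]


def short_transient_trial(seed: int = 0) -> SimulatedTrial:
    """A 10 s miniature of the transient-alpha design (200 Hz): constant
    aperiodic background with one tapered 8 Hz peak event over 3-8 s."""
    traj = AperiodicTrajectory.constant(offset=-2.56, exponent=1.5)
    peaks = (PeakEvent(cf=8.0, amplitude=1.2, sd=1.2, onset=3.0,
                       offset_time=8.0),)
    truth = build_ground_truth(traj, peaks, duration=10.0, fs=200.0)
    rng = np.random.default_rng(seed)
    return SimulatedTrial(synthesize_time_series(truth, rng), truth, seed)


def noiseless_model_spectrum(seed: int = 0):
    """An exact model spectrum (freqs, linear power, truth params) for
    round-trip recovery tests; parameters drawn from in-range uniforms."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(1.0, 40.5, 0.5)
    ap = AperiodicParams(offset=float(rng.uniform(-4, -1)),
                         exponent=float(rng.uniform(1.0, 2.2)))
    pk = Peak(cf=float(rng.uniform(8, 25)), amplitude=float(rng.uniform(0.8, 1.4)),
              sd=float(rng.uniform(1.0, 2.0)))
    log_power = aperiodic_value(ap, freqs) + peak_model([pk], freqs)
    return freqs, 10.0 ** log_power, ap, pk


def detection_fixture():
    """A hand-countable 10-bin detection table.

    Returns (per-bin truth activity, per-bin detections) for a single
    8 Hz event active at bins 2-7 with detections missing at bins 3 and 6
    and one false alarm at bin 9: 4 hits, 2 misses, 1 false alarm.
    """
    active = np.zeros(10, dtype=bool)
    active[2:8] = True
    detected = active.copy()
    detected[[3, 6]] = False
    detected[9] = True
    return active, detected


def make_fixtures(seed: int = 0) -> dict:
    """All fixtures keyed by name; same seed, same bytes."""
    return {"short_transient_trial": short_transient_trial(seed),
            "noiseless_model_spectrum": noiseless_model_spectrum(seed),
            "detection_fixture": detection_fixture()}
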