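"""In-flight decoding, cycle-averaged error and sweep detection."""

import numpy as np
import pandas as pd
import pytest

from flightreplay import sweeps as sw
from flightreplay import wingbeat as wb
from flightreplay.pipeline import match_events
from flightreplay.replay_bayes import PosteriorMatrix


def _phases(dur=30.0, f=8.0, rate=500.0):
    t = np.arange(0, dur, 1 / rate)
    az = 1.0 - 0.4 * np.cos(2 * np.pi * f * t)
    accel = pd.DataFrame({"t": t, "ax": 0.0, "ay": 0.0, "az": az})
    return wb.wingbeat_phase(accel)


def _result(times, err, length=10.0, qc=True, flight_idx=0):
    actual = np.linspace(0.2 * length, 0.8 * length, len(times))
    decoded = actual + err
    return sw.FlightDecodeResult(
        flight_idx=flight_idx, times=times, decoded_m=decoded,
        actual_m=actual, rms_m=0.1 if qc else 5.0,
        frac_decoded=1.0 if qc else 0.1, qc_pass=qc, length_m=length)


def test_decode_flight_qc_fail_on_silence():
    from flightreplay.replay_bayes import SpatialResponseSet
    rates = np.random.default_rng(0).uniform(1, 8, (6, 67))
    resp = SpatialResponseSet(np.arange(6), rates, 0, 10.0)
    t = np.arange(0, 3, 1 / 120)
    lin = pd.DataFrame({"t": t, "d_m": np.linspace(0, 10, len(t)),
                        "d_norm": np.linspace(0, 1, len(t))})
    res = sw.decode_flight({i: np.empty(0) for i in range(6)}, resp, lin)
    assert res.frac_decoded == 0.0
    assert not res.qc_pass


def test_decode_flight_requires_units():
    from flightreplay.replay_bayes import SpatialResponseSet
    resp = SpatialResponseSet(np.arange(2), np.ones((2, 67)), 0, 10.0)
    lin = pd.DataFrame({"t": [0, 1], "d_m": [0, 10], "d_norm": [0, 1.0]})
    with pytest.raises(ValueError, match="units"):
        sw.decode_flight({0: np.empty(0), 1: np.empty(0)}, resp, lin)


def test_in_flight_decoding_accuracy(sweep_run):
    """Dense-ensemble decoding: every flight passes QC and the median
    absolute error is below two position bins."""
    flights = sweep_run["flights"]
    assert all(r.qc_pass for r in flights)
    errs = np.concatenate([r.error_m[np.isfinite(r.error_m)]
                           for r in flights])
    assert np.median(np.abs(errs)) < 0.3


def test_zero_error_no_sweeps_flat_cycle_curve():
    phases = _phases()
    times = np.arange(5.0, 25.0, 0.005)
    res = _result(times, np.zeros_like(times))
    assert sw.detect_sweeps(res, phases) == []
    rng = np.random.default_rng(0)
    obs, shuf, p = sw.cycle_average_error([res], phases, rng)
    np.testing.assert_allclose(obs[np.isfinite(obs)], 0.0, atol=1e-12)
    assert not (p < 0.05).any()


def test_matched_filter_recovers_constructed_bumps():
    phases = _phases()
    times = np.arange(5.0, 25.0, 0.005)
    rng = np.random.default_rng(1)
    err = 0.05 * rng.standard_normal(len(times))
    truth = np.arange(5.5, 24.5, 0.35)
    sd = 0.06 / 2.3548
    for tc in truth:
        err += 0.9 * np.exp(-0.5 * ((times - tc) / sd) ** 2)
    res = _result(times, err)
    events = sw.detect_sweeps(res, phases)
    det = np.array([e.t for e in events])
    di, _ = match_events(det, truth, 0.02)
    # bumps in the central 15-85% portion of the flight are all found
    frac = (truth - 5.0) / 20.0
    n_mid = ((frac > 0.15) & (frac < 0.85)).sum()
    assert len(di) >= 0.95 * n_mid


def test_matched_filter_linearity():
    """Doubling the error amplitude doubles the raw template projection
    (the normalized score is scale-free)."""
    dt = 0.005
    tmpl = sw._gaussian_template(0.06, 0.9, dt)
    bump = sw._gaussian_template(0.06, 0.45, dt)
    assert np.dot(2 * bump, tmpl) == pytest.approx(
        2 * np.dot(bump, tmpl), rel=1e-12)


def test_sweep_pair_instantaneous_frequency():
    phases = _phases()
    times = np.arange(5.0, 25.0, 0.005)
    res = _result(times, np.zeros_like(times))
    sweeps = [sw.SweepEvent(t=10.0, phase_rad=0.0, match_score=1.0,
                            flight_idx=0),
              sw.SweepEvent(t=10.1, phase_rad=0.0, match_score=1.0,
                            flight_idx=0)]
    _, inst = sw.sweep_frequency(res, sweeps)
    assert inst == pytest.approx(10.0)


def test_sweep_frequency_8hz_periodicity():
    """Bumps every 125 ms: both estimators return ~8 Hz."""
    phases = _phases()
    times = np.arange(5.0, 25.0, 0.005)
    rng = np.random.default_rng(2)
    err = 0.05 * rng.standard_normal(len(times))
    truth = np.arange(5.5, 24.4, 0.125)
    sd = 0.06 / 2.3548
    for tc in truth:
        err += 0.9 * np.exp(-0.5 * ((times - tc) / sd) ** 2)
    res = _result(times, err)
    events = sw.detect_sweeps(res, phases)
    spec_hz, inst_hz = sw.sweep_frequency(res, events)
    assert spec_hz == pytest.approx(8.0, abs=0.5)
    assert inst_hz == pytest.approx(8.0, abs=0.5)


def test_cycle_average_error_detects_locked_embedding(sweep_run):
    rng = np.random.default_rng(3)
    qc = [r for r in sweep_run["flights"] if r.qc_pass]
    obs, shuf, p = sw.cycle_average_error(qc, sweep_run["phases"], rng)
    centres = np.linspace(-180, 180, 20, endpoint=False) + 9
    peak = centres[np.nanargmax(obs)]
    assert abs(peak - 116.0) <= 36.0
    assert p[np.nanargmax(obs)] < 0.05


def test_echolocation_interaction(sweep_run):
    rng = np.random.default_rng(4)
    out = sw.sweeps_vs_echolocation(sweep_run["sweeps"],
                                    sweep_run["bundle"].clicks,
                                    sweep_run["flights"], rng)
    assert not out["skipped"]
    # generator suppresses clicks within 150 ms of sweeps
    assert out["sweep_click_rate_hz"] < out["random_click_rate_hz"]
    assert out["p_lower"] < 0.05
    out0 = sw.sweeps_vs_echolocation(sweep_run["sweeps"], np.empty(0),
                                     sweep_run["flights"], rng)
    assert out0["skipped"]


def test_lfp_frame_score_lower_than_wingbeat_frame(sweep_run):
    """Sweeps locked to the wing-beat, LFP independent: the wing-beat-frame
    normalized modulation exceeds the LFP-frame one."""
    from flightreplay import lfp as lm
    bundle = sweep_run["bundle"]
    truth = sweep_run["truth"]
    rng = np.random.default_rng(5)
    qc = [r for r in sweep_run["flights"] if r.qc_pass]
    ch = lm.select_theta_channel(bundle.lfp, bundle.lfp_rate)
    nono = lm.nonosc_phase(np.asarray(bundle.lfp[:, ch], float),
                           bundle.lfp_rate, truth.flights[["start", "stop"]])
    _, lfp_score = sw.lfp_cycle_average_error(qc, nono, rng)
    # wing-beat frame score computed the same way, via the phase series
    obs, shuf, _ = sw.cycle_average_error(qc, sweep_run["phases"], rng)
    centre = np.abs(np.linspace(-np.pi, np.pi, 20, endpoint=False)
                    + np.pi / 20) <= np.pi / 2
    wb_obs = np.nanmean(obs[centre])
    wb_shuf = np.nanmean(shuf[:, centre], axis=1)
    wb_score = (wb_obs - wb_shuf.mean()) / wb_shuf.std()
    # the sign depends on where the locked phase sits relative to the
    # central averaging window; the modulation magnitude is what differs
    assert abs(wb_score) > abs(lfp_score)
    assert abs(lfp_score) < 3.0      # no locking in the LFP frame
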