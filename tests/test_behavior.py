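"""Flight segmentation, Fréchet clustering, turns and click detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightreplay import behavior as bh
from flightreplay.pipeline import match_events


def brute_force_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive search over all monotone couplings (independent oracle)."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = d.shape
    best = [np.inf]

    def rec(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i < n - 1:
            rec(i + 1, j, cur)
        if j < m - 1:
            rec(i, j + 1, cur)
        if i < n - 1 and j < m - 1:
            rec(i + 1, j + 1, cur)

    rec(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# segmentation

def test_constant_position_one_rest():
    t = np.arange(0, 10, 1 / 120)
    tr = pd.DataFrame({"t": t, "x": 1.0, "y": 2.0, "z": 1.5})
    flights, rests = bh.segment_flights(tr)
    assert flights == []
    assert len(rests) == 1
    assert rests.iloc[0]["start"] == 0.0


def test_threshold_crossing_on_constructed_profile():
    """Speed ramp 0 -> 3 -> 0 m/s crossing 0.5 near t=2 and t=8."""
    t = np.arange(0, 10, 1 / 120)
    speed = np.where((t >= 2) & (t <= 8),
                     3.0 * np.sin(np.pi * (t - 2) / 6) ** 2 + 0.51, 0.0)
    x = np.concatenate([[0.0], np.cumsum(speed[:-1]) / 120])
    tr = pd.DataFrame({"t": t, "x": x, "y": 0.0, "z": 1.0})
    flights, rests = bh.segment_flights(tr)
    assert len(flights) == 1
    assert flights[0].start == pytest.approx(2.0, abs=0.1)
    assert flights[0].stop == pytest.approx(8.0, abs=0.1)


def test_synthetic_flight_boundary_recovery(small_session):
    _, bundle, truth = small_session
    flights, _ = bh.segment_flights(bundle.tracking)
    assert len(flights) == len(truth.flights)
    for f, (_, tr) in zip(flights, truth.flights.iterrows()):
        assert abs(f.start - tr["start"]) < 0.05
        assert abs(f.stop - tr["stop"]) < 0.05


# ---------------------------------------------------------------------------
# Fréchet distance and clustering

def test_frechet_identical_zero():
    p = np.random.default_rng(0).uniform(0, 5, (7, 3))
    assert bh.frechet_distance(p, p) == 0.0


def test_frechet_parallel_offset():
    a = np.column_stack([np.linspace(0, 6, 7), np.zeros(7), np.zeros(7)])
    b = a + np.array([0.0, 0.5, 0.0])
    assert bh.frechet_distance(a, b) == pytest.approx(0.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_frechet_equals_bruteforce(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 10, (7, 3))
    b = rng.uniform(0, 10, (7, 3))
    assert bh.frechet_distance(a, b) == pytest.approx(
        brute_force_frechet(a, b), abs=1e-12)


def _jittered_copies(rng, base, n, sd=0.02):
    out = []
    for _ in range(n):
        path = base + rng.normal(0, sd, base.shape)
        t = np.arange(len(path)) / 120
        out.append(bh.FlightSegment(start=0, stop=t[-1], path=path, t=t))
    return out


def test_cluster_copies_single_cluster():
    rng = np.random.default_rng(1)
    base = np.column_stack([np.linspace(0, 8, 100),
                            np.sin(np.linspace(0, np.pi, 100)),
                            np.full(100, 1.5)])
    flights = _jittered_copies(rng, base, 10)
    clusters, labels = bh.cluster_flights(flights, linkage_m=1.0)
    assert len(clusters) == 1
    assert len(clusters[0].members) == 10


def test_cluster_two_separated_families():
    rng = np.random.default_rng(2)
    base1 = np.column_stack([np.linspace(0, 8, 100), np.zeros(100),
                             np.full(100, 1.5)])
    base2 = base1 + np.array([0, 5.0, 0])
    flights = (_jittered_copies(rng, base1, 6)
               + _jittered_copies(rng, base2, 6))
    clusters, labels = bh.cluster_flights(flights, linkage_m=1.0)
    assert len(clusters) == 2
    assert sorted(len(c.members) for c in clusters) == [6, 6]


def test_small_cluster_excluded():
    rng = np.random.default_rng(3)
    base1 = np.column_stack([np.linspace(0, 8, 100), np.zeros(100),
                             np.full(100, 1.5)])
    base2 = base1 + np.array([0, 5.0, 0])
    flights = (_jittered_copies(rng, base1, 6)
               + _jittered_copies(rng, base2, 4))
    clusters, labels = bh.cluster_flights(flights, linkage_m=1.0)
    assert len(clusters) == 1
    assert (labels[6:] == -1).all()


def test_clustering_invariant_to_order():
    rng = np.random.default_rng(4)
    base1 = np.column_stack([np.linspace(0, 8, 100), np.zeros(100),
                             np.full(100, 1.5)])
    base2 = base1 + np.array([0, 5.0, 0])
    flights = (_jittered_copies(rng, base1, 6)
               + _jittered_copies(rng, base2, 6))
    _, labels = bh.cluster_flights(flights, linkage_m=1.0)
    perm = rng.permutation(len(flights))
    _, labels_p = bh.cluster_flights([flights[i] for i in perm],
                                     linkage_m=1.0)
    # same partition up to label names
    for i in range(len(flights)):
        for j in range(i + 1, len(flights)):
            same = labels[perm[i]] == labels[perm[j]] != -1
            same_p = labels_p[i] == labels_p[j] != -1
            assert same == same_p


# ---------------------------------------------------------------------------
# turns, linearization, movement, clicks

def _flight_from_path(path, rate=120.0):
    t = np.arange(len(path)) / rate
    return bh.FlightSegment(start=0, stop=t[-1], path=path, t=t)


def test_straight_flight_zero_curvature():
    path = np.column_stack([np.linspace(0, 9, 300), np.zeros(300),
                            np.full(300, 1.5)])
    cls, mx = bh.detect_turns(_flight_from_path(path))
    assert cls == "straight"
    assert mx < 0.05


def test_midflight_arc_curvature_matches_radius():
    """A circular arc of radius 0.5 m gives curvature 1/R = 2 within the
    smoothing tolerance, classifying the flight as a loop."""
    v, R, rate = 1.0, 0.5, 120.0
    t = np.arange(0, 6, 1 / rate)
    pts = []
    for tt in t:
        if tt < 2:
            pts.append([tt * v, 0.0, 1.0])
        elif tt < 4:
            th = (tt - 2) * v / R
            pts.append([2 + R * np.sin(th), R - R * np.cos(th), 1.0])
        else:
            th = 2 * v / R
            d = np.array([np.cos(th), np.sin(th), 0.0])
            base = np.array([2 + R * np.sin(th), R - R * np.cos(th), 1.0])
            pts.append(base + (tt - 4) * v * d)
    cls, mx = bh.detect_turns(_flight_from_path(np.asarray(pts)))
    assert cls == "loop"
    assert mx == pytest.approx(2.0, rel=0.15)


def test_arc_in_tail_zeroed():
    """The same arc confined to the first 20% of the path is forced to zero
    curvature."""
    v, R, rate = 1.0, 0.25, 120.0
    t = np.arange(0, 6, 1 / rate)
    pts = []
    for tt in t:
        if tt < 1:
            th = tt * v / R
            pts.append([R * np.sin(th), R - R * np.cos(th), 1.0])
        else:
            th = 1 * v / R
            d = np.array([np.cos(th), np.sin(th), 0.0])
            base = np.array([R * np.sin(th), R - R * np.cos(th), 1.0])
            pts.append(base + (tt - 1) * v * d)
    cls, mx = bh.detect_turns(_flight_from_path(np.asarray(pts)))
    assert cls == "straight"


def test_linearization_contract():
    path = np.column_stack([np.linspace(0, 9, 200),
                            np.sin(np.linspace(0, np.pi, 200)),
                            np.full(200, 1.5)])
    fl = _flight_from_path(path)
    lin = bh.linearize_flight(fl)
    d = lin["d_norm"].to_numpy()
    assert d[0] == 0.0 and d[-1] == 1.0
    assert (np.diff(d) >= 0).all()
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
    assert lin["d_m"].iloc[-1] == pytest.approx(seg)


@pytest.mark.parametrize("a, expected", [
    ((0.0, 0.0, 1.0), 0.0),
    ((0.0, 0.0, 1.2), 0.2),
    ((0.6, 0.0, 0.8), 0.0),      # |a| = 1 exactly
])
def test_movement_level(a, expected):
    df = pd.DataFrame({"t": [0.0], "ax": [a[0]], "ay": [a[1]],
                       "az": [a[2]]})
    assert bh.movement_level(df)["level"].iloc[0] == pytest.approx(expected)


def test_clicks_silence_empty():
    assert len(bh.detect_clicks(np.zeros(1000), 10000.0)) == 0


def test_clicks_min_separation():
    sig = np.zeros(10000)
    sig[5000] = 100.0
    sig[5050] = 90.0                 # 5 ms later at 10 kHz
    sig += np.random.default_rng(0).standard_normal(10000) * 0.01
    det = bh.detect_clicks(sig, 10000.0)
    assert len(det) == 1


def test_clicks_recovery_at_high_snr():
    rng = np.random.default_rng(2)
    rate = 10000.0
    sig = rng.standard_normal(int(60 * rate)) * 0.1
    truth = np.sort(rng.uniform(1, 59, 100))
    for c in truth:
        sig[int(c * rate)] += 3.0
    det = bh.detect_clicks(sig, rate)
    di, _ = match_events(det, truth, 0.001)
    assert len(di) >= 99
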