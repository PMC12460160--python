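"""Rank-order replay detection and the replay-dynamics analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, spearmanr

from flightreplay import replay_rank as rr
from flightreplay import synthdata


def _event(unit_ids, first_ts):
    return rr.CandidateEvent(start=float(min(first_ts)) - 0.01,
                             stop=float(max(first_ts)) + 0.01,
                             peak_density=3.0,
                             unit_ids=np.asarray(unit_ids),
                             first_spike_t=np.asarray(first_ts))


def exhaustive_perm_p(ranks, times):
    """Exact permutation p: fraction of all orderings with |rho| greater
    than observed (independent oracle)."""
    rho = spearmanr(ranks, times)[0]
    count, total = 0, 0
    for perm in itertools.permutations(ranks):
        r = spearmanr(perm, times)[0]
        total += 1
        if abs(r) > abs(rho):
            count += 1
    return count / total


def test_rank_exact_orders():
    order = {u: u for u in range(5)}
    ev = _event(range(5), [0.0, 0.05, 0.1, 0.15, 0.2])
    rho, _ = rr.rank_order_test(ev, order)
    assert rho == pytest.approx(1.0)
    ev_r = _event(range(5), [0.2, 0.15, 0.1, 0.05, 0.0])
    rho_r, _ = rr.rank_order_test(ev_r, order)
    assert rho_r == pytest.approx(-1.0)


def test_rank_shuffle_p_matches_exhaustive():
    """The 100-draw shuffle p is consistent (99.9% binomial envelope) with
    exhaustive enumeration of all 120 identity permutations, under the
    strictly-greater counting rule (a perfect order therefore has exact
    p = 0: no permutation beats |rho| = 1 strictly)."""
    order = {u: u for u in range(5)}
    perfect = [0.0, 0.05, 0.1, 0.15, 0.2]
    ev = _event(range(5), perfect)
    assert exhaustive_perm_p([order[u] for u in ev.unit_ids], perfect) == 0.0
    rng = np.random.default_rng(0)
    _, p_hat = rr.rank_order_test(ev, order, n_shuffle=100, rng=rng)
    assert p_hat == 0.0
    # non-degenerate ordering: shuffle estimate within the binomial CI
    times = [0.0, 0.1, 0.05, 0.15, 0.2]     # one swap, |rho| < 1
    ev2 = _event(range(5), times)
    p_exact = exhaustive_perm_p([order[u] for u in ev2.unit_ids], times)
    assert 0.0 < p_exact < 0.5
    _, p_hat2 = rr.rank_order_test(ev2, order, n_shuffle=100, rng=rng)
    lo = binom.ppf(0.0005, 100, p_exact) / 100
    hi = binom.ppf(0.9995, 100, p_exact) / 100
    assert lo <= p_hat2 <= hi


def test_rank_ties_rejected():
    order = {0: 1, 1: 1, 2: 1}
    ev = _event(range(3), [0.0, 0.1, 0.2])
    rho, p = rr.rank_order_test(ev, order)
    assert np.isnan(rho)


def test_null_p_uniform_small():
    rng = np.random.default_rng(1)
    n_sig, N = 0, 200
    for _ in range(N):
        ev = _event(range(8), np.sort(rng.uniform(0, 0.3, 8)))
        order = dict(zip(rng.permutation(8), range(8)))
        _, p = rr.rank_order_test(ev, order, 100, rng)
        n_sig += p < 0.05
    assert 0.01 <= n_sig / N <= 0.11


# ---------------------------------------------------------------------------
# speed

def test_speed_arithmetic_example():
    """10 units over 0.3 s on a 10-cell trajectory spanning 9 m:
    30 units/s x 0.9 m/unit = 27 m/s."""
    ts = np.linspace(0.0, 0.3, 10)
    ev = _event(range(10), ts)
    order = {u: u for u in range(10)}
    v = rr.replay_speed_rank(ev, order, trajectory_span_m=9.0,
                             n_place_cells=10)
    assert v == pytest.approx(27.0, rel=1e-9)


def test_speed_halves_when_duration_doubles():
    order = {u: u for u in range(10)}
    v1 = rr.replay_speed_rank(_event(range(10), np.linspace(0, 0.3, 10)),
                              order, 9.0, 10)
    v2 = rr.replay_speed_rank(_event(range(10), np.linspace(0, 0.6, 10)),
                              order, 9.0, 10)
    assert v2 == pytest.approx(v1 / 2)


def test_speed_recovery_on_embedded_replays():
    rng = np.random.default_rng(2)
    trains, rests, centres, _ = synthdata.generate_rest_replay_trains(
        rng, n_units=15, length_m=10.0, n_replays=50)
    cands = rr.spike_density_candidates(trains, rests,
                                        rests["stop"].iloc[0])
    order = {u: i for i, u in enumerate(np.argsort(centres))}
    span = centres.max() - centres.min()
    reps = rr.score_candidates(cands, order, len(centres), span, rng=rng)
    speeds = [r.speed_mps for r in reps if np.isfinite(r.speed_mps)]
    true_speed = span / 0.3          # template sweeps the span in 0.3 s
    assert abs(np.median(speeds) - true_speed) / true_speed < 0.2


# ---------------------------------------------------------------------------
# candidates

def test_candidates_empty_without_spikes():
    rests = pd.DataFrame({"start": [0.0], "stop": [60.0]})
    assert rr.spike_density_candidates({0: np.empty(0)}, rests, 60.0) == []


def test_candidates_translation_equivariant():
    rng = np.random.default_rng(3)
    trains, rests, centres, truth = synthdata.generate_rest_replay_trains(
        rng, n_units=12, n_replays=5)
    T = rests["stop"].iloc[0]
    c1 = rr.spike_density_candidates(trains, rests, T)
    shift = 10.0
    trains2 = {u: t + shift for u, t in trains.items()}
    rests2 = rests + shift
    c2 = rr.spike_density_candidates(trains2,
                                     pd.DataFrame({"start": [shift],
                                                   "stop": [T + shift]}),
                                     T + shift)
    assert len(c1) == len(c2)
    for a, b in zip(c1, c2):
        assert b.start - a.start == pytest.approx(shift, abs=0.006)


def test_candidate_recovery_of_embedded_bursts():
    rng = np.random.default_rng(4)
    trains, rests, centres, truth = synthdata.generate_rest_replay_trains(
        rng, n_units=15, n_replays=20)
    cands = rr.spike_density_candidates(trains, rests,
                                        rests["stop"].iloc[0])
    hits = 0
    for t0 in truth:
        if any(c.start - 0.1 <= t0 + 0.15 <= c.stop + 0.1 for c in cands):
            hits += 1
    assert hits / len(truth) >= 0.95


# ---------------------------------------------------------------------------
# dynamics analyses

def test_rate_analysis_classes():
    flights = pd.DataFrame({"start": [100.0], "stop": [110.0]})
    rests = pd.DataFrame({"start": [0.0, 110.0], "stop": [100.0, 300.0]})
    deep_rest_times = np.array([10.0, 20.0, 30.0])
    df = rr.replay_rate_analysis({0: deep_rest_times}, flights, rests)
    assert df["rate_peri_per_min"].iloc[0] == 0.0
    assert df["rate_rest_per_min"].iloc[0] > 0


def test_locality_classes():
    ev = _event(range(6), np.linspace(100.0, 100.3, 6))
    rep = rr.RankReplay(event=ev, rho=0.9, p=0.0, active_fraction=1.0,
                        direction="forward",
                        bat_xyz=np.array([0.0, 0.0, 1.5]))
    takeoff = np.array([0.0, 0.0, 1.5])
    landing = np.array([10.0, 0.0, 1.5])
    flights = pd.DataFrame({"start": [95.0], "stop": [98.0],
                            "trajectory_id": [0]})
    out = rr.classify_locality(rep, takeoff, landing, flights, 0, 0.5, 30.0)
    assert out.locality == "local"
    rep2 = rr.RankReplay(event=ev, rho=0.9, p=0.0, active_fraction=1.0,
                         direction="forward",
                         bat_xyz=np.array([10.0, 0.0, 1.5]))
    out2 = rr.classify_locality(rep2, takeoff, landing, flights, 0, 0.5,
                                30.0)
    assert out2.locality == "remote"


def test_categorize_vs_behaviour():
    flights = pd.DataFrame({"start": [0.0, 100.0, 200.0],
                            "stop": [10.0, 110.0, 210.0],
                            "trajectory_id": [0, 1, 0]})
    reps = [(50.0, 0), (50.0, 1), (150.0, 0), (-5.0, 1), (250.0, 1)]
    df, chance = rr.categorize_vs_behaviour(reps, flights)
    assert chance == pytest.approx(0.5)
    cats = dict(zip(df["t"], df["category"]))
    assert cats[50.0] in ("previous", "next")
    got = df[df["t"] == 50.0]
    assert list(got["category"]) == ["previous", "next"]
    assert df[df["t"] == 150.0]["category"].iloc[0] == "other" or \
        df[df["t"] == 150.0]["category"].iloc[0] in ("previous", "next")
    assert -5.0 not in df["t"].values        # before first flight
    assert 250.0 not in df["t"].values       # after last flight


def test_categorize_loop_overlap_excluded():
    flights = pd.DataFrame({"start": [0.0, 100.0], "stop": [10.0, 110.0],
                            "trajectory_id": [0, 0]})
    df, chance = rr.categorize_vs_behaviour([(50.0, 0)], flights)
    assert len(df) == 0              # both previous and next -> excluded


def test_categorize_uniform_assignment_near_chance():
    rng = np.random.default_rng(5)
    n_fl = 80
    flights = pd.DataFrame({
        "start": 100.0 * np.arange(n_fl),
        "stop": 100.0 * np.arange(n_fl) + 10.0,
        "trajectory_id": rng.integers(0, 4, n_fl)})
    reps = [(100.0 * i + 50.0, int(rng.integers(0, 4)))
            for i in range(n_fl - 1) for _ in range(5)]
    df, chance = rr.categorize_vs_behaviour(reps, flights)
    assert chance == pytest.approx(0.25)
    frac_prev = (df["category"] == "previous").mean()
    assert abs(frac_prev - chance) < 0.1


def test_duration_length_single_group_warns():
    df = pd.DataFrame({"cluster_id": [0, 1], "length_m": [5.0, 5.0],
                       "mean_duration_s": [0.3, 0.31],
                       "mean_speed_mps": [15.0, 16.0],
                       "group": ["short", "short"]})
    summary, stats = rr.duration_length_scaling(df)
    assert "warning" in stats
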