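"""Shared synthetic-session fixtures.

Sessions are expensive enough to build once per test session; every fixture
is deterministic (fixed seeds) so reruns are bit-identical.
"""

import numpy as np
import pytest

from flightreplay import synthdata
from flightreplay.pipeline import (analyze_behavior, analyze_place_fields,
                                   analyze_replays_bayes,
                                   analyze_replays_rank, analyze_wingbeat)


@pytest.fixture(scope="session")
def small_session():
    """A short session with a handful of flights and replays."""
    cfg = synthdata.SynthConfig(
        seed=11, n_flights=5, rest_gap_s=8.0,
        replay=synthdata.ReplaySpec(n_forward=6, n_reverse=3,
                                    spikes_per_unit=3))
    bundle, truth = synthdata.generate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def replay_run():
    """A ~10-minute session with 50 forward + 20 reverse embedded replays,
    analysed by both replay detectors."""
    cfg = synthdata.SynthConfig(
        seed=101, n_flights=10, rest_gap_s=24.0, rest_gap_jitter_s=3.0,
        final_rest_s=30.0,
        replay=synthdata.ReplaySpec(n_forward=50, n_reverse=20,
                                    spikes_per_unit=3))
    bundle, truth = synthdata.generate_session(cfg)
    behav = analyze_behavior(bundle)
    fields = analyze_place_fields(bundle, behav)
    rank = analyze_replays_rank(bundle, behav, fields, seed=101)
    bayes = analyze_replays_bayes(bundle, behav, fields, seed=101)
    return {"cfg": cfg, "bundle": bundle, "truth": truth, "behav": behav,
            "fields": fields, "rank": rank, "bayes": bayes}


@pytest.fixture(scope="session")
def sweep_run():
    """A dense-ensemble session with wing-beat-locked sweeps at 116 degrees
    and per-cycle echolocation clicks suppressed around sweeps."""
    import flightreplay.replay_bayes as rb
    from flightreplay import sweeps as sw

    cfg = synthdata.SynthConfig(
        seed=55, n_flights=8, n_units=150, peak_rate_hz=40.0,
        rest_gap_s=8.0,
        replay=synthdata.ReplaySpec(n_forward=0, n_reverse=0),
        sweeps=synthdata.SweepSpec(enabled=True),
        clicks=synthdata.ClickSpec(enabled=True,
                                   suppress_near_sweeps_s=0.15))
    bundle, truth = synthdata.generate_session(cfg)
    behav = analyze_behavior(bundle)
    fields = analyze_place_fields(bundle, behav)
    wbres = analyze_wingbeat(bundle, behav, fields, seed=55)
    trains = bundle.spike_trains()
    flights, sweeps = [], []
    for cid, info in fields.items():
        stable = [u for u, f in info["fields"].items()
                  if np.isfinite(f.stability) and f.stability > 0.6]
        cl = next(c for c in behav["clusters"] if c.cluster_id == cid)
        lin = [behav["lin"][i] for i in cl.members]
        n_bins = max(2, int(round(info["length_m"] / 0.15)))
        resp = rb.compute_responses({u: trains[u] for u in stable}, lin,
                                    info["length_m"], cid, n_bins=n_bins)
        for i in cl.members:
            r = sw.decode_flight({u: trains[u] for u in stable}, resp,
                                 behav["lin"][i], flight_idx=i)
            flights.append(r)
            sweeps.extend(sw.detect_sweeps(r, wbres["phases"]))
    return {"cfg": cfg, "bundle": bundle, "truth": truth, "behav": behav,
            "phases": wbres["phases"], "flights": flights, "sweeps": sweeps}


@pytest.fixture(scope="session")
def event_session():
    """Replay-free session with independent SWRs and theta bouts."""
    cfg = synthdata.SynthConfig(
        seed=4, n_flights=10, rest_gap_s=12.0,
        swr=synthdata.SwrSpec(rate_hz=0.1, couple_to_replays=False),
        replay=synthdata.ReplaySpec(n_forward=0, n_reverse=0))
    bundle, truth = synthdata.generate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def noise_lfp():
    """10 minutes of 8-channel pink noise at 500 Hz (no events)."""
    rng = np.random.default_rng(9)
    n = int(600 * 500)
    return np.column_stack([synthdata.pink_noise(n, rng) * 50
                            for _ in range(8)]).astype(np.float32)
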